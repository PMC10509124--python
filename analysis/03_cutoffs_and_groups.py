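#!/usr/bin/env python
"""Derive 2-SD normal-range cutoffs and compare the groups.

Cutoffs come in two flavours: from the published control summaries (the
three arithmetically consistent ones: LVEF < 53%, RVEF < 48%, LV-AVPD <
12.0 mm) and from the simulated control subjects of results/cohort.csv.
Also runs the distribution-gated two-group tests on every metric.
"""

import sys
from pathlib import Path

import pandas as pd

from cmrpump.stats import DEFAULT_DIRECTIONS, CutoffSet, compare_groups, derive_cutoffs

RESULTS = Path(__file__).resolve().parents[1] / "results"

PUBLISHED_CONTROL_SUMMARIES = {
    "lvef": (61.0, 4.0),
    "rvef": (56.0, 4.0),
    "lv_avpd": (16.0, 2.0),
}


def main() -> int:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    controls = cohort[cohort["group"] == "control"]
    pah = cohort[cohort["group"] == "pah"]

    published = CutoffSet.from_summary(
        PUBLISHED_CONTROL_SUMMARIES, {m: "below" for m in PUBLISHED_CONTROL_SUMMARIES}
    ).as_frame()
    published["source"] = "published_summary"
    directions = {m: d for m, d in DEFAULT_DIRECTIONS.items() if m in cohort.columns}
    simulated = derive_cutoffs(controls, directions).as_frame()
    simulated["source"] = "simulated_controls"
    cutoffs = pd.concat([published, simulated], ignore_index=True)
    cutoffs.to_csv(RESULTS / "cutoffs.csv", index=False)
    print("cutoffs (published control summaries):")
    print(published.round(1).to_string(index=False))

    rows = []
    for metric in directions:
        res = compare_groups(controls[metric].dropna(), pah[metric].dropna())
        rows.append({"metric": metric, "test": res.test, "statistic": res.statistic, "p": res.p})
    tests = pd.DataFrame(rows)
    tests.to_csv(RESULTS / "group_comparisons.csv", index=False)
    print("\ngroup comparisons (control vs PAH) on the simulated cohort:")
    print(tests.round(4).to_string(index=False))
    print(f"\nwrote {RESULTS / 'cutoffs.csv'} and {RESULTS / 'group_comparisons.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
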