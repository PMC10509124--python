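import numpy as np
import pytest

from cmrpump.data import ContourStack, SliceContours, SliceSegmentation
from cmrpump.errors import DomainError, GeometryError
from cmrpump.phantom import Motion, PhantomSpec, generate_phantom
from cmrpump.phantom import _lv_epi_polygon, _rv_endo_polygon, _rv_epi_polygon
from cmrpump.regional import (
    SeptumPartition,
    SlicePartition,
    basal_epicardial_area,
    decompose,
    partition_septum,
    sv_lat,
    sv_long,
    sv_sept,
)
from cmrpump.volumetry import compute_volumetry
from cmrpump.avpd import compute_displacements
from conftest import square


def circle(r, n=64, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def one_slice_stack(ed: SliceContours, es: SliceContours | None = None, thickness=10.0):
    phases = {"ED": ed}
    if es is not None:
        phases["ES"] = es
    return ContourStack(
        slices=[SliceSegmentation(index=0, thickness=thickness, gap=0.0, phases=phases)]
    )


def septum_supported(lv_epi, lv_endo=None, insertions=((0.0, 25.0), (0.0, -25.0))):
    return SliceContours(
        lv_epi=lv_epi,
        lv_endo=lv_endo if lv_endo is not None else circle(20.0),
        rv_endo=circle(6.0, center=(-35.0, 0.0)),
        rv_epi=circle(9.0, center=(-35.0, 0.0)),
        rv_insertion_anterior=np.asarray(insertions[0], dtype=float),
        rv_insertion_inferior=np.asarray(insertions[1], dtype=float),
    )


class TestPartitionSeptum:
    def test_circular_lv_with_opposite_insertions_halves_the_circumference(self):
        contours = septum_supported(circle(30.0, 128), insertions=((0.0, 30.0), (0.0, -30.0)))
        part = partition_septum(one_slice_stack(contours))
        septal = part.parts[(0, "ED")].septal
        from cmrpump.geometry import polyline_length

        frac = polyline_length(septal) / (2 * np.pi * 30.0)
        assert frac == pytest.approx(0.5, rel=0.02)
        # the septal arc faces the RV (x < 0 here)
        assert np.mean(septal[:, 0]) < 0

    def test_phantom_septal_fraction_matches_geometry(self, default_phantom):
        bundle, _ = default_phantom
        part = partition_septum(bundle.contour_stack)
        sp = part.parts[(0, "ED")]
        from cmrpump.geometry import polyline_length

        total = polyline_length(sp.septal) + polyline_length(sp.lv_free)
        assert polyline_length(sp.septal) / total == pytest.approx(0.5, rel=0.02)

    def test_slice_without_rv_is_flagged(self):
        contours = SliceContours(lv_epi=circle(30.0), lv_endo=circle(25.0))
        part = partition_septum(one_slice_stack(contours))
        assert part.parts == {}
        assert (0, "ED") in part.flagged

    def test_coincident_insertions_rejected(self):
        contours = septum_supported(circle(30.0), insertions=((0.0, 30.0), (0.0, 30.0)))
        with pytest.raises(GeometryError):
            partition_septum(one_slice_stack(contours))


class TestBasalArea:
    def test_mean_of_two_largest(self):
        slices = [
            SliceSegmentation(
                index=i, thickness=10.0, gap=0.0,
                phases={"ED": SliceContours(lv_epi=square(0, 0, np.sqrt(a)))},
            )
            for i, a in enumerate([4000.0, 3900.0, 3000.0])
        ]
        assert basal_epicardial_area(ContourStack(slices=slices), "LV") == pytest.approx(3950.0)

    def test_equal_areas_return_that_area(self):
        slices = [
            SliceSegmentation(
                index=i, thickness=10.0, gap=0.0,
                phases={"ED": SliceContours(lv_epi=square(0, 0, 50.0))},
            )
            for i in range(4)
        ]
        assert basal_epicardial_area(ContourStack(slices=slices), "LV") == pytest.approx(2500.0)

    def test_single_slice_insufficient(self):
        slices = [
            SliceSegmentation(
                index=0, thickness=10.0, gap=0.0,
                phases={"ED": SliceContours(lv_epi=square(0, 0, 50.0))},
            )
        ]
        with pytest.raises(DomainError):
            basal_epicardial_area(ContourStack(slices=slices), "LV")


class TestSvLong:
    def test_hand_arithmetic_healthy_values(self):
        ml, pct = sv_long(16.0, 4000.0, 101.0)
        assert ml == pytest.approx(64.0)
        assert pct == pytest.approx(63.4, abs=0.05)

    def test_zero_avpd(self):
        assert sv_long(0.0, 4000.0, 101.0) == (0.0, 0.0)

    def test_nonpositive_sv_rejected(self):
        with pytest.raises(DomainError):
            sv_long(16.0, 4000.0, 0.0)


def two_phase_partition_stack(ed_epi, es_epi):
    """One slice whose LV epicardium moves ED -> ES; RV support present."""
    ed = septum_supported(ed_epi)
    es = septum_supported(es_epi)
    return one_slice_stack(ed, es)


class TestSvLatAndSept:
    def test_no_motion_sweeps_zero(self):
        epi = _lv_epi_polygon(25.0, 25.0, 0.0, 128)
        stack = two_phase_partition_stack(epi, epi.copy())
        part = partition_septum(stack)
        ml, _ = sv_lat(stack, part, "LV", 10.0)
        assert ml == pytest.approx(0.0, abs=1e-9)

    def test_half_annulus_closed_form(self):
        """Free wall r 25 -> 20 over half the circumference, 10 mm slice:
        0.5 pi (25^2 - 20^2) x 10 mm^3 = 3.53 ml."""
        stack = two_phase_partition_stack(
            _lv_epi_polygon(25.0, 25.0, 0.0, 128), _lv_epi_polygon(25.0, 20.0, 0.0, 128)
        )
        part = partition_septum(stack)
        ml, pct = sv_lat(stack, part, "LV", 10.0)
        assert ml == pytest.approx(0.5 * np.pi * (625 - 400) * 10 / 1000.0, rel=0.01)
        assert pct == pytest.approx(100.0 * ml / 10.0)

    def test_outward_bulge_is_negative(self):
        stack = two_phase_partition_stack(
            _lv_epi_polygon(25.0, 20.0, 0.0, 128), _lv_epi_polygon(25.0, 25.0, 0.0, 128)
        )
        part = partition_septum(stack)
        ml, _ = sv_lat(stack, part, "LV", 10.0)
        assert ml < 0

    def test_septal_translation_rectangle_sweep(self):
        """2 mm shift toward the LV along a 40 mm septal span, one 10 mm
        slice: +0.8 ml; mirrored shift: -0.8 ml."""
        seg = np.array([[-10.0, -20.0], [-10.0, 0.0], [-10.0, 20.0]])
        lv_endo = square(10.0, 0.0, 10.0)

        def run(shift):
            ed = SlicePartition(septal=seg, lv_free=seg + [40, 0], rv_free=seg - [10, 0])
            es = SlicePartition(septal=seg + [shift, 0.0], lv_free=seg + [40, 0], rv_free=seg - [10, 0])
            part = SeptumPartition(parts={(0, "ED"): ed, (0, "ES"): es})
            stack = one_slice_stack(
                SliceContours(lv_endo=lv_endo), SliceContours(lv_endo=lv_endo)
            )
            return sv_sept(stack, part, 101.0)

        ml_plus, _ = run(+2.0)
        ml_minus, _ = run(-2.0)
        assert ml_plus == pytest.approx(0.8, rel=1e-9)
        assert ml_minus == pytest.approx(-0.8, rel=1e-9)
        assert ml_plus + ml_minus == pytest.approx(0.0, abs=1e-12)

    def test_no_included_slices_rejected(self):
        epi = _lv_epi_polygon(25.0, 25.0, 0.0, 64)
        stack = one_slice_stack(septum_supported(epi))  # no ES phase
        part = partition_septum(stack)
        with pytest.raises(DomainError):
            sv_lat(stack, part, "LV", 10.0)


class TestDecompose:
    def test_zero_motion_phantom_surfaces_domain_error(self):
        bundle, _ = generate_phantom(PhantomSpec(motion=Motion(0, 0, 0, 0, 0)))
        with pytest.raises(DomainError):
            decompose(bundle)

    def test_mixed_phantom_conserves_stroke_volume(self, default_phantom):
        bundle, _ = default_phantom
        vol = compute_volumetry(bundle)
        dec = decompose(bundle, vol)
        lv_sum = dec.lv_sv_long + dec.lv_sv_lat + dec.sv_sept
        rv_sum = dec.rv_sv_long + dec.rv_sv_lat - dec.sv_sept
        assert lv_sum == pytest.approx(vol.lv.sv, rel=0.10)
        assert rv_sum == pytest.approx(vol.rv.sv, rel=0.10)
        assert dec.included_slices == [s.index for s in bundle.contour_stack.slices
                                       if s.index in dec.included_slices]

    def test_percentages_are_component_over_sv(self, default_phantom):
        bundle, _ = default_phantom
        vol = compute_volumetry(bundle)
        dec = decompose(bundle, vol)
        assert dec.lv_sv_long_pct == pytest.approx(100 * dec.lv_sv_long / vol.lv.sv, rel=1e-12)
        assert dec.sv_sept_pct == pytest.approx(100 * dec.sv_sept / vol.lv.sv, rel=1e-12)

    def test_healthy_phantom_longitudinal_shares(self, default_phantom):
        """Control-like motion: LV longitudinal share near 57%, RV near 85%."""
        bundle, _ = default_phantom
        dec = decompose(bundle)
        assert dec.lv_sv_long_pct == pytest.approx(57.0, abs=10.0)
        assert dec.rv_sv_long_pct == pytest.approx(85.0, abs=10.0)

    def test_tapse_at_least_rv_avpd_when_lateral_dominates(self, default_phantom):
        bundle, _ = default_phantom
        disp = compute_displacements(bundle.av_annotations)
        assert disp.tapse >= disp.rv_avpd
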