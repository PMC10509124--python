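"""Parametric two-ventricle phantoms with closed-form ground truth.

The phantom is a pair of stacked cylinders: a circular LV (endocardial
radius ``a``, epicardial radius ``b``) and a crescent-shaped RV occupying
the half-plane on one side of the LV, between the LV epicardium and an
outer arc (cavity outer radius ``c = b + crescent_width``, free-wall
epicardial radius ``R = c + epi_offset``).  The RV insertion points sit
where the RV free wall meets the LV epicardium; the LV epicardial half
facing the RV cavity is the septum.

End-systole is built from three prescribed motions:

* longitudinal — the basal boundary moves apically by the AVPD; slices
  vacated by the AV plane lose their ventricular contours;
* radial — free-wall epicardial radii scale inward by ``radial_fraction``;
* septal — the septal arc translates by ``septal_shift`` (positive toward
  the LV cavity).

The myocardium is treated as incompressible: end-systolic *endocardial*
cross-sections are derived from wall-volume conservation given the
prescribed epicardial motion.  This is what makes the basal epicardial
area x AVPD equal the displaced blood volume, so a pure-translation
phantom has a longitudinal stroke-volume fraction of 100%.

Septal AV-plane points move with the LV excursion, the RVOT and lateral RV
points with the RV excursion, so the ground-truth RV-AVPD is the weighted
mean ``(avpd_lv + 2*avpd_rv) / 3`` and the ground-truth TAPSE equals
``avpd_rv``.  The RV basal truncation depth uses that weighted mean.

All ground-truth quantities are closed forms (cylinder and annulus-sector
volumes); nothing is measured from the generated contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import (
    AVAnnotation,
    ContourStack,
    SegmentationBundle,
    SliceContours,
    SliceSegmentation,
)
from .errors import DomainError, GeometryError, ValidationError

__all__ = ["LVGeometry", "RVGeometry", "Motion", "Sampling", "PhantomSpec", "PhantomTruth", "generate_phantom"]


@dataclass
class LVGeometry:
    endo_radius: float = 23.0  # mm; pi*a^2*L ~ healthy LV-EDV
    epi_radius: float = 28.0  # mm
    length: float = 100.0  # mm, base to apex


@dataclass
class RVGeometry:
    crescent_width: float = 16.0  # mm, cavity outer radius minus LV epi radius
    epi_offset: float = 4.0  # mm, RV free-wall thickness


@dataclass
class Motion:
    """Prescribed ED->ES motion.  Defaults approximate a healthy subject:
    LV excursion 16 mm, lateral tricuspid excursion 25 mm (RV mean 22 mm),
    and radial/septal fractions chosen so the longitudinal share of stroke
    volume lands near 57% (LV) and 85% (RV)."""

    avpd_lv: float = 16.0  # mm
    avpd_rv: float = 25.0  # mm, lateral/RVOT excursion (TAPSE)
    radial_fraction_lv: float = 0.104  # unitless in [0, 1)
    radial_fraction_rv: float = 0.031
    septal_shift: float = 1.42  # mm, signed toward the LV cavity


@dataclass
class Sampling:
    n_slices: int = 20
    n_vertices: int = 128  # vertices per full contour (arcs get half each)
    thickness: float = 5.0  # mm
    gap: float = 0.0  # mm


@dataclass
class PhantomTruth:
    """Analytic ground truth, volumes in ml, lengths mm, areas mm^2."""

    lv_edv: float
    lv_esv: float
    lv_sv: float
    rv_edv: float
    rv_esv: float
    rv_sv: float
    lv_mass: float
    rv_mass: float
    lv_avpd: float
    rv_avpd: float
    tapse: float
    lv_basal_epi_area: float
    rv_basal_epi_area: float
    sv_long_lv: float
    sv_lat_lv: float
    sv_sept: float
    sv_long_rv: float
    sv_lat_rv: float

    @property
    def sv_long_lv_pct(self) -> float:
        return 100.0 * self.sv_long_lv / self.lv_sv

    @property
    def sv_long_rv_pct(self) -> float:
        return 100.0 * self.sv_long_rv / self.rv_sv

    def conservation_residual(self) -> tuple[float, float]:
        """Relative residual of component-sum vs stroke volume, per
        ventricle.  Nonzero only through the septal-scaling cross term; it
        bounds the self-consistency of the analytic model."""
        lv = (self.sv_long_lv + self.sv_lat_lv + self.sv_sept - self.lv_sv) / self.lv_sv
        rv = (self.sv_long_rv + self.sv_lat_rv - self.sv_sept - self.rv_sv) / self.rv_sv
        return lv, rv


@dataclass
class PhantomSpec:
    lv: LVGeometry = field(default_factory=LVGeometry)
    rv: RVGeometry = field(default_factory=RVGeometry)
    motion: Motion = field(default_factory=Motion)
    sampling: Sampling = field(default_factory=Sampling)
    noise_mm: float = 0.0  # optional Gaussian jitter on every point
    ground_truth: PhantomTruth | None = None

    def validate(self) -> None:
        if not (self.lv.epi_radius > self.lv.endo_radius > 0):
            raise ValidationError("need epi_radius > endo_radius > 0")
        if self.rv.crescent_width <= 0 or self.rv.epi_offset <= 0:
            raise ValidationError("RV crescent width and epi offset must be > 0")
        if self.sampling.n_slices < 3:
            raise ValidationError("need n_slices >= 3")
        if self.sampling.n_vertices < 16:
            raise ValidationError("need n_vertices >= 16")
        if not (0 <= self.motion.radial_fraction_lv < 1):
            raise ValidationError("radial_fraction_lv must be in [0, 1)")
        if not (0 <= self.motion.radial_fraction_rv < 1):
            raise ValidationError("radial_fraction_rv must be in [0, 1)")
        spacing = self.sampling.thickness + self.sampling.gap
        if abs(self.sampling.n_slices * spacing - self.lv.length) > 1e-6:
            raise ValidationError(
                "n_slices * (thickness + gap) must equal the ventricle length"
            )
        if max(self.motion.avpd_lv, self.motion.avpd_rv) >= self.lv.length:
            raise DomainError("degenerate phantom: AVPD >= ventricle length")


def _arc(radius: float, th0_deg: float, th1_deg: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    th = np.deg2rad(np.linspace(th0_deg, th1_deg, n))
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def _circle(radius: float, n: int, center=(0.0, 0.0)) -> np.ndarray:
    th = np.deg2rad(np.linspace(0.0, 360.0, n, endpoint=False))
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def _dedup(poly: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices (arc junctions can coincide)."""
    keep = [0]
    for i in range(1, len(poly)):
        if not np.allclose(poly[i], poly[keep[-1]], atol=1e-9):
            keep.append(i)
    if np.allclose(poly[keep[-1]], poly[keep[0]], atol=1e-9):
        keep.pop()
    return poly[keep]


def _lv_epi_polygon(b_sept: float, b_free: float, shift: float, n: int) -> np.ndarray:
    """LV epicardium: septal half-arc of radius ``b_sept`` centred at
    (shift, 0) on the RV side (x < 0), free-wall half-arc of radius
    ``b_free`` on the far side."""
    half = max(8, n // 2)
    septal = _arc(b_sept, 90.0, 270.0, half, center=(shift, 0.0))
    free = _arc(b_free, 270.0, 450.0, half)
    return _dedup(np.vstack([septal, free]))


def _rv_endo_polygon(c_outer: float, b_inner: float, shift: float, n: int) -> np.ndarray:
    half = max(8, n // 2)
    outer = _arc(c_outer, 90.0, 270.0, half)
    inner = _arc(b_inner, 270.0, 90.0, half, center=(shift, 0.0))
    return _dedup(np.vstack([outer, inner]))


def _rv_epi_polygon(r_outer: float, n: int) -> np.ndarray:
    half = max(8, n // 2)
    outer = _arc(r_outer, 90.0, 270.0, half)
    ys = np.linspace(-r_outer, r_outer, max(4, half // 2) + 2)[1:-1]
    chord = np.column_stack([np.zeros_like(ys), ys])
    return _dedup(np.vstack([outer, chord]))


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[SegmentationBundle, PhantomTruth]:
    """Build the segmentation bundle and analytic ground truth of a phantom.

    ``seed`` drives the optional point jitter (``spec.noise_mm``); with the
    default of zero noise the output is a pure function of ``spec``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    a = spec.lv.endo_radius
    b = spec.lv.epi_radius
    c = b + spec.rv.crescent_width
    big_r = c + spec.rv.epi_offset
    length = spec.lv.length
    d_lv = spec.motion.avpd_lv
    d_rvp = spec.motion.avpd_rv
    d_rv = (d_lv + 2.0 * d_rvp) / 3.0  # RV-AVPD weighted mean of the motions
    if d_rv >= length:
        raise DomainError("degenerate phantom: AVPD >= ventricle length")
    f_lv = spec.motion.radial_fraction_lv
    f_rv = spec.motion.radial_fraction_rv
    shift = spec.motion.septal_shift
    b_free = b * (1.0 - f_lv)
    r_es = big_r * (1.0 - f_rv)
    if shift != 0.0 and abs(shift) + b_free >= b:
        # otherwise the shifted septal arc crosses the free-wall arc and the
        # ES epicardial polygon self-intersects at the insertion junctions
        raise GeometryError(
            "septal shift needs free-wall clearance: require "
            "|septal_shift| + epi_radius*(1 - radial_fraction_lv) < epi_radius"
        )

    # --- closed-form cross-sections -------------------------------------
    area_lv_endo = math.pi * a**2
    area_lv_epi = math.pi * b**2
    area_rv_endo = math.pi * (c**2 - b**2) / 2.0
    area_rv_epi = math.pi * (big_r**2 - b**2) / 2.0  # excludes LV overlap

    area_lv_epi_es = math.pi * (b**2 + b_free**2) / 2.0 - shift * (b + b_free)
    wall_lv = math.pi * (b**2 - a**2) * length
    area_lv_endo_es = area_lv_epi_es - wall_lv / (length - d_lv)
    if area_lv_endo_es <= 0:
        raise GeometryError("phantom motion collapses the LV cavity at ES")
    a_es = math.sqrt(area_lv_endo_es / math.pi)

    area_rv_epi_es = math.pi * (r_es**2 - b**2) / 2.0 + shift * (b + r_es)
    wall_rv = math.pi * (big_r**2 - c**2) / 2.0 * length
    area_rv_endo_es = area_rv_epi_es - wall_rv / (length - d_rv)
    if area_rv_endo_es <= 0:
        raise GeometryError("phantom motion collapses the RV cavity at ES")
    # outer ES cavity radius from pi*(c_es^2 - b^2)/2 + shift*(b + c_es) = A
    k = area_rv_endo_es - shift * b + math.pi * b**2 / 2.0
    c_es = (-shift + math.sqrt(shift**2 + 2.0 * math.pi * k)) / math.pi
    if c_es <= b + abs(shift) + 0.5:
        raise GeometryError("phantom motion collapses the RV crescent at ES")
    if a_es >= b_free:
        raise GeometryError("phantom motion collapses the LV wall at ES")

    # --- ground truth ----------------------------------------------------
    ml = 1e-3
    included_length = length - d_rv
    truth = PhantomTruth(
        lv_edv=area_lv_endo * length * ml,
        lv_esv=area_lv_endo_es * (length - d_lv) * ml,
        lv_sv=(area_lv_endo * length - area_lv_endo_es * (length - d_lv)) * ml,
        rv_edv=area_rv_endo * length * ml,
        rv_esv=area_rv_endo_es * (length - d_rv) * ml,
        rv_sv=(area_rv_endo * length - area_rv_endo_es * (length - d_rv)) * ml,
        lv_mass=wall_lv * ml * 1.05,
        rv_mass=wall_rv * ml * 1.05,
        lv_avpd=d_lv,
        rv_avpd=d_rv,
        tapse=d_rvp,
        lv_basal_epi_area=area_lv_epi,
        rv_basal_epi_area=area_rv_epi,
        sv_long_lv=d_lv * area_lv_epi * ml,
        sv_lat_lv=math.pi * (b**2 - b_free**2) / 2.0 * included_length * ml,
        sv_sept=2.0 * b * shift * included_length * ml,
        sv_long_rv=d_rv * area_rv_epi * ml,
        sv_lat_rv=math.pi * (big_r**2 - r_es**2) / 2.0 * included_length * ml,
    )
    spec.ground_truth = truth

    # --- contour stack ---------------------------------------------------
    n_v = spec.sampling.n_vertices
    spacing = spec.sampling.thickness + spec.sampling.gap

    def contours(phase: str) -> SliceContours:
        if phase == "ED":
            return SliceContours(
                lv_endo=_circle(a, n_v),
                lv_epi=_lv_epi_polygon(b, b, 0.0, n_v),
                rv_endo=_rv_endo_polygon(c, b, 0.0, n_v),
                rv_epi=_rv_epi_polygon(big_r, n_v),
                rv_insertion_anterior=np.array([0.0, b]),
                rv_insertion_inferior=np.array([0.0, -b]),
            )
        return SliceContours(
            lv_endo=_circle(a_es, n_v),
            lv_epi=_lv_epi_polygon(b, b_free, shift, n_v),
            rv_endo=_rv_endo_polygon(c_es, b, shift, n_v),
            rv_epi=_rv_epi_polygon(r_es, n_v),
            rv_insertion_anterior=np.array([shift, b]),
            rv_insertion_inferior=np.array([shift, -b]),
        )

    ed_template = contours("ED")
    es_template = contours("ES")

    slices = []
    for i in range(spec.sampling.n_slices):
        z_center = (i + 0.5) * spacing
        phases = {"ED": _copy_contours(ed_template, rng, spec.noise_mm)}
        es = SliceContours()
        if z_center >= d_lv:
            src = _copy_contours(es_template, rng, spec.noise_mm)
            es.lv_endo, es.lv_epi = src.lv_endo, src.lv_epi
            if z_center >= d_rv:
                es.rv_endo = src.rv_endo
                es.rv_epi = src.rv_epi
                es.rv_insertion_anterior = src.rv_insertion_anterior
                es.rv_insertion_inferior = src.rv_insertion_inferior
        phases["ES"] = es
        slices.append(
            SliceSegmentation(
                index=i,
                thickness=spec.sampling.thickness,
                gap=spec.sampling.gap,
                phases=phases,
            )
        )

    # --- long-axis AV annotations ----------------------------------------
    def jitter(pt):
        pt = np.asarray(pt, dtype=float)
        if spec.noise_mm > 0:
            pt = pt + rng.normal(0.0, spec.noise_mm, size=pt.shape)
        return pt

    def view(view_id: str, entries: dict[str, tuple[float, float, float]]) -> AVAnnotation:
        points = {
            label: {
                "ED": jitter([x_ed, 0.0]),
                "ES": jitter([x_es, dy]),
            }
            for label, (x_ed, x_es, dy) in entries.items()
        }
        return AVAnnotation(view=view_id, apex=np.array([0.0, length]), points=points)

    annotations = [
        view("2ch", {"ant": (b, b_free, d_lv), "inf": (-b, -b_free, d_lv)}),
        view(
            "3ch",
            {
                "RVOT": (-big_r, -r_es, d_rvp),
                "ant_sep": (-b, -b + shift, d_lv),
                "inf_lat": (b, b_free, d_lv),
            },
        ),
        view(
            "4ch",
            {
                "RV_lat": (-big_r, -r_es, d_rvp),
                "inf_sep": (-b, -b + shift, d_lv),
                "ant_lat": (b, b_free, d_lv),
            },
        ),
    ]

    bundle = SegmentationBundle(
        subject_id=f"phantom-{seed}",
        contour_stack=ContourStack(slices=slices),
        av_annotations=annotations,
        heart_rate=61.0,
        height=170.0,
        weight=70.0,
    )
    bundle.validate()
    return bundle, truth


def _copy_contours(template: SliceContours, rng, noise_mm: float) -> SliceContours:
    out = SliceContours()
    for key in (
        "lv_endo",
        "lv_epi",
        "rv_endo",
        "rv_epi",
        "rv_insertion_anterior",
        "rv_insertion_inferior",
    ):
        val = getattr(template, key)
        if val is None:
            continue
        val = np.array(val, copy=True)
        if noise_mm > 0:
            val = val + rng.normal(0.0, noise_mm, size=val.shape)
        setattr(out, key, val)
    return out
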