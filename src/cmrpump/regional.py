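"""Decomposition of stroke volume into longitudinal, lateral and septal
contributions.

The longitudinal component of each ventricle is its AVPD times the mean
end-diastolic epicardial cross-section of the two largest basal slices of
that ventricle.  The lateral (free-wall) and septal components are swept
areas between the end-diastolic and end-systolic epicardial borders,
multiplied by the effective slice spacing and summed over the slices where
the interventricular septum exists at both phases (basal slices vacated by
the descending AV plane at ES are excluded).  The RV insertion points
delimit the septum on every slice.

Sign conventions: lateral sweeps are positive for inward (toward-cavity)
systolic motion; the septal sweep is positive when the septum moves toward
the LV cavity (contributing to LV stroke volume) and negative when it moves
toward the RV.  SV_sept% is expressed relative to LV stroke volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .avpd import DisplacementSet, compute_displacements
from .data import ContourStack, SegmentationBundle
from .errors import DomainError, GeometryError
from .volumetry import Volumetry, _slice_area, compute_volumetry

logger = logging.getLogger(__name__)

__all__ = [
    "SlicePartition",
    "SeptumPartition",
    "partition_septum",
    "basal_epicardial_area",
    "included_slices",
    "sv_long",
    "sv_lat",
    "sv_sept",
    "decompose",
    "SVDecomposition",
]


@dataclass
class SlicePartition:
    """Septal and free-wall epicardial polylines of one slice at one phase.

    All three polylines are open vertex chains, oriented to start at the end
    nearest the anterior insertion point, and jointly cover the epicardial
    contours with shared endpoints only.
    """

    septal: np.ndarray
    lv_free: np.ndarray
    rv_free: np.ndarray


@dataclass
class SeptumPartition:
    """Per-(slice index, phase) partitions plus the slices that could not be
    partitioned for lack of RV contours or insertion points."""

    parts: dict[tuple[int, str], SlicePartition] = field(default_factory=dict)
    flagged: list[tuple[int, str]] = field(default_factory=list)

    def slices_with_septum_both_phases(self) -> list[int]:
        return sorted(
            i for (i, ph) in self.parts if ph == "ED" and (i, "ES") in self.parts
        )


def _arc_midpoint(arc: np.ndarray) -> np.ndarray:
    return geometry.resample_polyline(arc, 3)[1]


def _orient_from(arc: np.ndarray, start_near: np.ndarray) -> np.ndarray:
    if np.linalg.norm(arc[-1] - start_near) < np.linalg.norm(arc[0] - start_near):
        return arc[::-1]
    return arc


def _split_at_insertions(polygon, anterior, inferior) -> tuple[np.ndarray, np.ndarray]:
    ia = geometry.nearest_vertex(polygon, anterior)
    ib = geometry.nearest_vertex(polygon, inferior)
    if ia == ib:
        raise GeometryError("RV insertion points coincide on this contour")
    return geometry.split_closed_polygon(polygon, ia, ib)


def partition_septum(stack: ContourStack) -> SeptumPartition:
    """Split every slice's epicardial contours into septal, LV free-wall and
    RV free-wall polylines using the RV insertion points.

    Slices (per phase) without an RV cavity contour or without both
    insertion points are flagged and carry no partition.
    """
    out = SeptumPartition()
    for slc in stack.slices:
        for phase, contours in slc.phases.items():
            if not contours.has_septum_support() or contours.lv_epi is None:
                out.flagged.append((slc.index, phase))
                continue
            ant = contours.rv_insertion_anterior
            inf = contours.rv_insertion_inferior
            if np.allclose(ant, inf):
                raise GeometryError(
                    f"slice {slc.index} {phase}: RV insertion points coincide"
                )
            rv_centroid = geometry.polygon_centroid(contours.rv_endo)

            arc_a, arc_b = _split_at_insertions(contours.lv_epi, ant, inf)
            d_a = np.linalg.norm(_arc_midpoint(arc_a) - rv_centroid)
            d_b = np.linalg.norm(_arc_midpoint(arc_b) - rv_centroid)
            septal, lv_free = (arc_a, arc_b) if d_a <= d_b else (arc_b, arc_a)

            rv_free = None
            if contours.rv_epi is not None:
                lv_centroid = geometry.polygon_centroid(contours.lv_epi)
                arc_a, arc_b = _split_at_insertions(contours.rv_epi, ant, inf)
                d_a = np.linalg.norm(_arc_midpoint(arc_a) - lv_centroid)
                d_b = np.linalg.norm(_arc_midpoint(arc_b) - lv_centroid)
                rv_free = arc_a if d_a >= d_b else arc_b
            if rv_free is None:
                out.flagged.append((slc.index, phase))
                continue

            out.parts[(slc.index, phase)] = SlicePartition(
                septal=_orient_from(septal, ant),
                lv_free=_orient_from(lv_free, ant),
                rv_free=_orient_from(rv_free, ant),
            )
    return out


def basal_epicardial_area(stack: ContourStack, ventricle: str) -> float:
    """Mean of the two largest end-diastolic epicardial cross-sections of
    the requested ventricle (mm^2).

    "Largest" is by area, not by basal slice index, which is robust to
    over-segmented atrial slices.  RV areas exclude the overlap with the LV
    epicardium.
    """
    areas = []
    for slc in stack.slices:
        contours = slc.contours("ED")
        if contours is None:
            continue
        area = _slice_area(contours, ventricle, "epi")
        if area is not None:
            areas.append(area)
    if len(areas) < 2:
        raise DomainError(
            f"need >= 2 slices with the {ventricle} epicardial contour at ED, "
            f"found {len(areas)}"
        )
    top_two = sorted(areas, reverse=True)[:2]
    return float(np.mean(top_two))


def included_slices(stack: ContourStack) -> list[int]:
    """Slices with the septum present at both ED and ES: an RV cavity
    contour and both insertion points exist at each phase."""
    out = []
    for slc in stack.slices:
        ed, es = slc.contours("ED"), slc.contours("ES")
        if (
            ed is not None
            and es is not None
            and ed.has_septum_support()
            and es.has_septum_support()
        ):
            out.append(slc.index)
    return out


def sv_long(avpd_mm: float, basal_area_mm2: float, sv_ml: float) -> tuple[float, float]:
    """Longitudinal stroke-volume contribution: AVPD x basal epicardial
    area.  Returns (ml, percent of the ventricle's SV)."""
    if sv_ml <= 0:
        raise DomainError("stroke volume must be positive for SV_long%")
    volume_ml = avpd_mm * basal_area_mm2 / 1000.0
    return volume_ml, 100.0 * volume_ml / sv_ml


def _swept_sum(
    stack: ContourStack,
    partition: SeptumPartition,
    polyline_attr: str,
    reference_contour: str,
    sv_ml: float,
) -> tuple[float, float, list[int]]:
    spacing = stack.spacing
    included = [
        i
        for i in partition.slices_with_septum_both_phases()
        if i in {s.index for s in stack.slices}
    ]
    if not included:
        raise DomainError("no slices with septum present at both ED and ES")
    by_index = {s.index: s for s in stack.slices}
    total_mm3 = 0.0
    for i in included:
        slc = by_index[i]
        ed_part = partition.parts[(i, "ED")]
        es_part = partition.parts[(i, "ES")]
        ref_poly = slc.contours("ED").contour(reference_contour)
        if ref_poly is None:
            raise DomainError(
                f"slice {i}: missing {reference_contour} ED contour for sweep reference"
            )
        toward = geometry.polygon_centroid(ref_poly)
        area = geometry.swept_area(
            getattr(ed_part, polyline_attr), getattr(es_part, polyline_attr), toward
        )
        total_mm3 += area * spacing
    volume_ml = total_mm3 / 1000.0
    return volume_ml, 100.0 * volume_ml / sv_ml, included


def sv_lat(
    stack: ContourStack, partition: SeptumPartition, ventricle: str, sv_ml: float
) -> tuple[float, float]:
    """Lateral (free-wall) stroke-volume contribution of one ventricle.

    Swept area between the ED and ES free-wall epicardial polylines, closed
    by the chords joining corresponding endpoints, positive for inward ES
    motion, times the slice spacing, summed over included slices.
    """
    if sv_ml <= 0:
        raise DomainError("stroke volume must be positive for SV_lat%")
    attr = "lv_free" if ventricle == "LV" else "rv_free"
    ref = "lv_endo" if ventricle == "LV" else "rv_endo"
    ml, pct, _ = _swept_sum(stack, partition, attr, ref, sv_ml)
    return ml, pct


def sv_sept(
    stack: ContourStack, partition: SeptumPartition, lv_sv_ml: float
) -> tuple[float, float]:
    """Septal stroke-volume contribution (signed), relative to LV-SV.

    Positive when the ES septum is displaced toward the LV cavity.
    """
    if lv_sv_ml <= 0:
        raise DomainError("LV stroke volume must be positive for SV_sept%")
    ml, pct, _ = _swept_sum(stack, partition, "septal", "lv_endo", lv_sv_ml)
    return ml, pct


@dataclass
class SVDecomposition:
    """Longitudinal/lateral/septal stroke-volume components (ml and % of the
    relevant ventricle's SV; the septal percent is relative to LV-SV)."""

    lv_sv_long: float
    lv_sv_long_pct: float
    lv_sv_lat: float
    lv_sv_lat_pct: float
    rv_sv_long: float
    rv_sv_long_pct: float
    rv_sv_lat: float
    rv_sv_lat_pct: float
    sv_sept: float
    sv_sept_pct: float
    included_slices: list[int]


def decompose(
    bundle: SegmentationBundle,
    volumetry: Volumetry | None = None,
    displacements: DisplacementSet | None = None,
) -> SVDecomposition:
    """Full stroke-volume decomposition of one subject."""
    if volumetry is None:
        volumetry = compute_volumetry(bundle)
    if displacements is None:
        displacements = compute_displacements(bundle.av_annotations)
    stack = bundle.contour_stack
    partition = partition_septum(stack)

    lv_long_ml, lv_long_pct = sv_long(
        displacements.lv_avpd, basal_epicardial_area(stack, "LV"), volumetry.lv.sv
    )
    rv_long_ml, rv_long_pct = sv_long(
        displacements.rv_avpd, basal_epicardial_area(stack, "RV"), volumetry.rv.sv
    )
    lv_lat_ml, lv_lat_pct = sv_lat(stack, partition, "LV", volumetry.lv.sv)
    rv_lat_ml, rv_lat_pct = sv_lat(stack, partition, "RV", volumetry.rv.sv)
    sept_ml, sept_pct = sv_sept(stack, partition, volumetry.lv.sv)

    return SVDecomposition(
        lv_sv_long=lv_long_ml,
        lv_sv_long_pct=lv_long_pct,
        lv_sv_lat=lv_lat_ml,
        lv_sv_lat_pct=lv_lat_pct,
        rv_sv_long=rv_long_ml,
        rv_sv_long_pct=rv_long_pct,
        rv_sv_lat=rv_lat_ml,
        rv_sv_lat_pct=rv_lat_pct,
        sv_sept=sept_ml,
        sv_sept_pct=sept_pct,
        included_slices=partition.slices_with_septum_both_phases(),
    )
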