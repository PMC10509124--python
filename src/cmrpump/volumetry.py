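"""Global ventricular volumetry from short-axis contour stacks.

Volumes follow slice summation: each slice contributes its cross-sectional
contour area times the effective slice spacing (thickness + gap), converted
mm^3 -> ml.  Papillary muscles and trabeculations are part of the blood
pool by convention (the contours are taken as authoritative).  The RV
epicardial cross-section on a slice is the area enclosed by the RV
epicardial polygon minus its overlap with the LV epicardial polygon, so the
septum is never counted twice.

Myocardial mass uses the end-diastolic shell times a myocardial density of
1.05 g/ml.  Cardiac output is LV stroke volume times heart rate.  Indices
are divided by Du Bois body surface area when height and weight are known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import geometry
from .data import ContourStack, SegmentationBundle, SliceContours
from .errors import DomainError

logger = logging.getLogger(__name__)

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

__all__ = [
    "polygon_area",
    "ventricular_volume",
    "compute_volumetry",
    "bsa_du_bois",
    "pvr",
    "VentricleVolumetry",
    "Volumetry",
]

# re-exported: slice-wise volumetry is built on the shoelace magnitude
polygon_area = geometry.polygon_area


def bsa_du_bois(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area (m^2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def _slice_area(contours: SliceContours, ventricle: str, surface: str) -> float | None:
    """Cross-sectional area (mm^2) of one ventricle surface on one slice, or
    ``None`` when the contour is absent."""
    if ventricle == "LV":
        poly = contours.contour("lv_endo" if surface == "endo" else "lv_epi")
        return None if poly is None else geometry.polygon_area(poly)
    if ventricle == "RV":
        poly = contours.contour("rv_endo" if surface == "endo" else "rv_epi")
        if poly is None:
            return None
        area = geometry.polygon_area(poly)
        if surface == "epi":
            lv_epi = contours.contour("lv_epi")
            if lv_epi is not None:
                area -= geometry.overlap_area(poly, lv_epi)
        return area
    raise DomainError(f"unknown ventricle {ventricle!r}")


def ventricular_volume(
    stack: ContourStack, phase: str, ventricle: str, surface: str
) -> float:
    """Slice-summation volume (ml) of one ventricle surface at one phase.

    Slices lacking the contour contribute zero; if no slice carries it the
    stack is considered empty for this request.
    """
    spacing = stack.spacing
    total = 0.0
    seen = False
    for slc in stack.slices:
        contours = slc.contours(phase)
        if contours is None:
            continue
        area = _slice_area(contours, ventricle, surface)
        if area is None:
            continue
        seen = True
        total += area * spacing
    if not seen:
        raise DomainError(
            f"no slice carries the {ventricle} {surface} contour at {phase}"
        )
    return total / 1000.0  # mm^3 -> ml


@dataclass
class VentricleVolumetry:
    """Per-ventricle global function (volumes ml, EF as a fraction, mass g)."""

    edv: float
    esv: float
    sv: float
    ef: float
    mass: float
    edv_index: float | None = None
    esv_index: float | None = None
    sv_index: float | None = None
    mass_index: float | None = None


@dataclass
class Volumetry:
    lv: VentricleVolumetry
    rv: VentricleVolumetry
    cardiac_output: float  # L/min
    bsa: float | None  # m^2


def _ventricle(stack: ContourStack, ventricle: str, bsa: float | None) -> VentricleVolumetry:
    edv = ventricular_volume(stack, "ED", ventricle, "endo")
    esv = ventricular_volume(stack, "ES", ventricle, "endo")
    sv = edv - esv
    if edv <= 0:
        raise DomainError(f"{ventricle} EDV is zero: EF undefined")
    if esv > edv:
        logger.warning("%s ESV exceeds EDV; EF reported negative", ventricle)
    ef = sv / edv
    epi_ed = ventricular_volume(stack, "ED", ventricle, "epi")
    mass = (epi_ed - edv) * MYOCARDIAL_DENSITY_G_PER_ML
    out = VentricleVolumetry(edv=edv, esv=esv, sv=sv, ef=ef, mass=mass)
    if bsa is not None:
        out.edv_index = edv / bsa
        out.esv_index = esv / bsa
        out.sv_index = sv / bsa
        out.mass_index = mass / bsa
    return out


def compute_volumetry(bundle: SegmentationBundle) -> Volumetry:
    """EDV/ESV/SV/EF/mass for both ventricles, cardiac output and BSA
    indices.  Indices are omitted (``None``) when height or weight is
    unknown."""
    bsa = None
    if bundle.height is not None and bundle.weight is not None:
        bsa = bsa_du_bois(bundle.height, bundle.weight)
    lv = _ventricle(bundle.contour_stack, "LV", bsa)
    rv = _ventricle(bundle.contour_stack, "RV", bsa)
    cardiac_output = lv.sv * bundle.heart_rate / 1000.0  # ml/beat * bpm -> L/min
    return Volumetry(lv=lv, rv=rv, cardiac_output=cardiac_output, bsa=bsa)


def pvr(mpap: float, pawp: float, co: float) -> float:
    """Pulmonary vascular resistance in Wood units: (mPAP - PAWP) / CO."""
    if co <= 0:
        raise DomainError("cardiac output must be positive")
    return (mpap - pawp) / co
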