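"""Domain containers: segmentation contour stacks, AV-plane annotations and
the per-subject segmentation bundle.

Units: lengths mm, areas mm^2, volumes are reported in ml downstream.
Slices are indexed 0 = most basal, increasing toward the apex.  All slices
of a stack share one slice thickness and gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import GeometryError, ValidationError

logger = logging.getLogger(__name__)

PHASES = ("ED", "ES")
CONTOUR_KEYS = ("lv_endo", "lv_epi", "rv_endo", "rv_epi")

#: labels required per long-axis view
VIEW_LABELS: dict[str, tuple[str, ...]] = {
    "2ch": ("ant", "inf"),
    "3ch": ("RVOT", "ant_sep", "inf_lat"),
    "4ch": ("RV_lat", "inf_sep", "ant_lat"),
}

#: the six labels entering the LV mean and the four entering the RV mean
LV_LABELS = ("ant", "ant_lat", "inf_lat", "inf", "inf_sep", "ant_sep")
RV_SEPTAL_LABELS = ("ant_sep", "inf_sep")
RV_FREE_LABELS = ("RVOT", "RV_lat")


@dataclass
class SliceContours:
    """Closed endo/epicardial polygons and RV insertion points of one slice
    at one cardiac phase.  Any field may be ``None`` when the structure is
    absent (e.g. slices vacated by the descending AV plane at ES)."""

    lv_endo: np.ndarray | None = None
    lv_epi: np.ndarray | None = None
    rv_endo: np.ndarray | None = None
    rv_epi: np.ndarray | None = None
    rv_insertion_anterior: np.ndarray | None = None
    rv_insertion_inferior: np.ndarray | None = None

    def contour(self, key: str) -> np.ndarray | None:
        if key not in CONTOUR_KEYS:
            raise ValidationError(f"unknown contour key {key!r}")
        return getattr(self, key)

    def has_septum_support(self) -> bool:
        """True when an RV cavity contour and both insertion points exist."""
        return (
            self.rv_endo is not None
            and self.rv_insertion_anterior is not None
            and self.rv_insertion_inferior is not None
        )


@dataclass
class SliceSegmentation:
    index: int
    thickness: float  # mm
    gap: float  # mm
    phases: dict[str, SliceContours] = field(default_factory=dict)

    def contours(self, phase: str) -> SliceContours | None:
        return self.phases.get(phase)


@dataclass
class ContourStack:
    """Ordered short-axis slice segmentations; the volumetric substrate."""

    slices: list[SliceSegmentation]

    @property
    def thickness(self) -> float:
        return self.slices[0].thickness

    @property
    def gap(self) -> float:
        return self.slices[0].gap

    @property
    def spacing(self) -> float:
        """Effective slice spacing: thickness + gap (mm)."""
        return self.thickness + self.gap

    def validate(self) -> None:
        if not self.slices:
            raise ValidationError("contour stack has no slices")
        t0, g0 = self.slices[0].thickness, self.slices[0].gap
        for slc in self.slices:
            if slc.thickness <= 0:
                raise ValidationError(f"slice {slc.index}: thickness must be > 0")
            if slc.gap < 0:
                raise ValidationError(f"slice {slc.index}: gap must be >= 0")
            if slc.thickness != t0 or slc.gap != g0:
                raise ValidationError("all slices must share thickness and gap")
            for phase, contours in slc.phases.items():
                if phase not in PHASES:
                    raise ValidationError(f"slice {slc.index}: unknown phase {phase!r}")
                for key in CONTOUR_KEYS:
                    poly = contours.contour(key)
                    if poly is None:
                        continue
                    try:
                        geometry.polygon_area(poly)
                    except GeometryError as exc:
                        raise ValidationError(
                            f"slice {slc.index} {phase} {key}: {exc}"
                        ) from exc
                for endo, epi in (("lv_endo", "lv_epi"), ("rv_endo", "rv_epi")):
                    pe, pp = contours.contour(endo), contours.contour(epi)
                    if pe is not None and pp is not None:
                        if geometry.polygon_area(pp) < geometry.polygon_area(pe):
                            raise ValidationError(
                                f"slice {slc.index} {phase}: {epi} area < {endo} area"
                            )
        if [s.index for s in self.slices] != sorted(s.index for s in self.slices):
            raise ValidationError("slices must be ordered base (index 0) to apex")


@dataclass
class AVAnnotation:
    """Labelled AV-plane points of one long-axis view.

    ``points`` maps label -> {"ED": (x, y), "ES": (x, y)} in mm; ``apex`` is
    the apex landmark orienting "toward the apex" for displacement signs.
    """

    view: str
    apex: np.ndarray
    points: dict[str, dict[str, np.ndarray]]

    def validate(self) -> None:
        if self.view not in VIEW_LABELS:
            raise ValidationError(f"unknown view {self.view!r}")
        required = set(VIEW_LABELS[self.view])
        present = set(self.points)
        if present != required:
            raise ValidationError(
                f"view {self.view}: expected labels {sorted(required)}, got {sorted(present)}"
            )
        for label, phases in self.points.items():
            if set(phases) != set(PHASES):
                raise ValidationError(
                    f"view {self.view} label {label}: both ED and ES points required"
                )
        ed = self.ed_points()
        point, direction = geometry.fit_line_tls(ed)
        if geometry.point_line_distance(self.apex, point, direction) <= 1.0:
            raise ValidationError(
                f"view {self.view}: apex is degenerate with the ED AV line "
                "(perpendicular distance <= 1 mm)"
            )

    def ed_points(self) -> np.ndarray:
        return np.array([self.points[lab]["ED"] for lab in VIEW_LABELS[self.view]])


@dataclass
class SegmentationBundle:
    """Everything needed to quantify one subject: the short-axis contour
    stack, the long-axis AV annotations, heart rate and optional biometrics."""

    subject_id: str
    contour_stack: ContourStack
    av_annotations: list[AVAnnotation]
    heart_rate: float  # beats/min
    height: float | None = None  # cm
    weight: float | None = None  # kg

    def validate(self) -> None:
        self.contour_stack.validate()
        views = [a.view for a in self.av_annotations]
        if len(views) != len(set(views)):
            raise ValidationError(f"duplicate AV annotation views: {views}")
        for ann in self.av_annotations:
            ann.validate()
        if self.heart_rate is None or self.heart_rate <= 0:
            raise ValidationError("heart_rate must be > 0")

    def annotation(self, view: str) -> AVAnnotation:
        for ann in self.av_annotations:
            if ann.view == view:
                return ann
        from .errors import MissingViewError

        raise MissingViewError(f"no {view} annotation for subject {self.subject_id}")
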