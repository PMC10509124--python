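"""Atrioventricular plane displacement (AVPD) from labelled long-axis points.

The AV plane of each long-axis view (2-, 3-, 4-chamber) is the 2-D line
through that view's end-diastolic points: the exact line for two points,
the orthogonal-regression (total-least-squares) line for three.  Each
labelled point's displacement Delta is the ED->ES motion projected on the
line normal oriented toward the apex landmark, so systolic motion toward
the apex is positive and in-plane sliding along the AV line contributes
nothing.

LV-AVPD is the unweighted mean of the six LV labels::

    LV-AVPD = (D_ant + D_ant_lat + D_inf_lat + D_inf + D_inf_sep + D_ant_sep) / 6

RV-AVPD averages the septal pair first::

    RV-AVPD = ((D_ant_sep + D_inf_sep)/2 + D_RVOT + D_RV_lat) / 3

and CMR-TAPSE is the displacement of the lateral tricuspid annulus point
(RV_lat) in the 4-chamber view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import geometry
from .data import (
    LV_LABELS,
    RV_FREE_LABELS,
    RV_SEPTAL_LABELS,
    VIEW_LABELS,
    AVAnnotation,
)
from .errors import GeometryError, MissingLandmarkError, MissingViewError

__all__ = [
    "Line",
    "fit_av_line",
    "perpendicular_displacement",
    "view_displacements",
    "compute_displacements",
    "lv_avpd",
    "rv_avpd",
    "cmr_tapse",
    "DisplacementSet",
]


@dataclass(frozen=True)
class Line:
    """An infinite 2-D line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray


def fit_av_line(annotation: AVAnnotation) -> Line:
    """AV line of one view: TLS line through the view's ED points."""
    point, direction = geometry.fit_line_tls(annotation.ed_points())
    return Line(point=point, direction=direction)


def perpendicular_displacement(p_ed, p_es, line: Line, apex) -> float:
    """Signed displacement of one AV point perpendicular to the AV line (mm).

    Positive toward the apex landmark; motion parallel to the line is
    discarded.
    """
    p_ed = np.asarray(p_ed, dtype=float)
    p_es = np.asarray(p_es, dtype=float)
    apex = np.asarray(apex, dtype=float)
    d = line.direction / np.linalg.norm(line.direction)
    normal = np.array([-d[1], d[0]])
    toward_apex = float(np.dot(apex - line.point, normal))
    if abs(toward_apex) < 1e-9:
        raise GeometryError("apex lies on the AV line; displacement sign undefined")
    normal = normal * np.sign(toward_apex)
    return float(np.dot(p_es - p_ed, normal))


def view_displacements(annotation: AVAnnotation) -> dict[str, float]:
    """Delta for every label of one view, against that view's ED line."""
    line = fit_av_line(annotation)
    return {
        label: perpendicular_displacement(
            phases["ED"], phases["ES"], line, annotation.apex
        )
        for label, phases in annotation.points.items()
    }


def _collect(annotations: Iterable[AVAnnotation]) -> dict[str, float]:
    deltas: dict[str, float] = {}
    for ann in annotations:
        deltas.update(view_displacements(ann))
    return deltas


def _need(deltas: dict[str, float], label: str) -> float:
    if label not in deltas:
        view = next((v for v, labs in VIEW_LABELS.items() if label in labs), "?")
        raise MissingLandmarkError(f"missing AV-plane landmark {label!r} ({view} view)")
    return deltas[label]


def lv_avpd_from_deltas(deltas: dict[str, float]) -> float:
    return float(np.mean([_need(deltas, lab) for lab in LV_LABELS]))


def rv_avpd_from_deltas(deltas: dict[str, float]) -> float:
    septal = np.mean([_need(deltas, lab) for lab in RV_SEPTAL_LABELS])
    free = [_need(deltas, lab) for lab in RV_FREE_LABELS]
    return float((septal + np.sum(free)) / 3.0)


def lv_avpd(annotations: Iterable[AVAnnotation]) -> float:
    """LV-AVPD (mm): unweighted mean of the six LV labels."""
    return lv_avpd_from_deltas(_collect(annotations))


def rv_avpd(annotations: Iterable[AVAnnotation]) -> float:
    """RV-AVPD (mm): septal pair averaged first, then RVOT and RV lat."""
    return rv_avpd_from_deltas(_collect(annotations))


def cmr_tapse(annotations: Iterable[AVAnnotation]) -> float:
    """CMR-TAPSE (mm): displacement of RV_lat in the 4-chamber view."""
    anns = list(annotations)
    four = [a for a in anns if a.view == "4ch"]
    if not four:
        raise MissingViewError("CMR-TAPSE requires a 4ch annotation")
    return view_displacements(four[0])["RV_lat"]


@dataclass
class DisplacementSet:
    """All eight Delta values plus the derived AVPD summaries (mm)."""

    delta: dict[str, float]
    lv_avpd: float
    rv_avpd: float
    tapse: float


def compute_displacements(annotations: Iterable[AVAnnotation]) -> DisplacementSet:
    """Compute every labelled Delta and the LV/RV AVPD and TAPSE summaries."""
    anns = list(annotations)
    deltas = _collect(anns)
    return DisplacementSet(
        delta=deltas,
        lv_avpd=lv_avpd_from_deltas(deltas),
        rv_avpd=rv_avpd_from_deltas(deltas),
        tapse=cmr_tapse(anns),
    )
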