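"""Reading and writing the package's file formats.

Two formats are supported, both plain text:

* **Contour JSON** — one document per subject::

      {"subject_id": str, "heart_rate": float, "height": float?, "weight": float?,
       "slices": [{"index": int, "thickness_mm": float, "gap_mm": float,
                   "ED": {"lv_endo": [[x, y], ...], "lv_epi": ..., "rv_endo": ...,
                          "rv_epi": ..., "rv_insertion_anterior": [x, y],
                          "rv_insertion_inferior": [x, y]},
                   "ES": {...}}, ...],
       "views": [{"id": "2ch"|"3ch"|"4ch", "apex": [x, y],
                  "points": [{"label": str, "phase": "ED"|"ES", "x": f, "y": f}]}]}

  Polygons are closed implicitly; coordinates are mm, origin top-left,
  y increasing downward.  Unknown fields are ignored with a logged warning.

* **Cohort CSV** — header ``subject_id, group, age_years, sex,
  followup_years, event, incident`` plus one column per metric.  Group is
  ``control`` or ``pah``; control rows carry no survival data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CONTOUR_KEYS,
    PHASES,
    AVAnnotation,
    ContourStack,
    SegmentationBundle,
    SliceContours,
    SliceSegmentation,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

_BUNDLE_KEYS = {"subject_id", "heart_rate", "height", "weight", "slices", "views"}
_SLICE_KEYS = {"index", "thickness_mm", "gap_mm"} | set(PHASES)
_PHASE_KEYS = set(CONTOUR_KEYS) | {"rv_insertion_anterior", "rv_insertion_inferior"}

GROUPS = ("control", "pah")
COHORT_REQUIRED = (
    "subject_id",
    "group",
    "age_years",
    "sex",
    "followup_years",
    "event",
    "incident",
)


def _warn_unknown(doc: dict, known: set, where: str) -> None:
    for key in set(doc) - known:
        logger.warning("ignoring unknown field %r in %s", key, where)


def _require(doc: dict, key: str, where: str):
    if key not in doc or doc[key] is None:
        raise ValidationError(f"missing mandatory field {key!r} in {where}")
    return doc[key]


def _point(obj, where: str) -> np.ndarray:
    arr = np.asarray(obj, dtype=float)
    if arr.shape != (2,):
        raise ValidationError(f"{where}: expected an [x, y] point")
    return arr


def read_bundle(path) -> SegmentationBundle:
    """Read and validate a contour JSON document into a bundle."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: top-level JSON must be an object")
    _warn_unknown(doc, _BUNDLE_KEYS, "bundle")

    subject_id = str(_require(doc, "subject_id", "bundle"))
    heart_rate = float(_require(doc, "heart_rate", "bundle"))

    slices = []
    for raw in _require(doc, "slices", "bundle"):
        _warn_unknown(raw, _SLICE_KEYS, f"slice of {subject_id}")
        index = int(_require(raw, "index", "slice"))
        thickness = float(_require(raw, "thickness_mm", f"slice {index}"))
        gap = float(_require(raw, "gap_mm", f"slice {index}"))
        phases: dict[str, SliceContours] = {}
        for phase in PHASES:
            if phase not in raw:
                continue
            pdoc = raw[phase]
            _warn_unknown(pdoc, _PHASE_KEYS, f"slice {index} {phase}")
            contours = SliceContours()
            for key in CONTOUR_KEYS:
                if pdoc.get(key) is not None:
                    setattr(contours, key, np.asarray(pdoc[key], dtype=float))
            for key in ("rv_insertion_anterior", "rv_insertion_inferior"):
                if pdoc.get(key) is not None:
                    setattr(contours, key, _point(pdoc[key], f"slice {index} {key}"))
            phases[phase] = contours
        slices.append(SliceSegmentation(index=index, thickness=thickness, gap=gap, phases=phases))
    slices.sort(key=lambda s: s.index)

    annotations = []
    for raw in _require(doc, "views", "bundle"):
        _warn_unknown(raw, {"id", "apex", "points"}, "view")
        view = str(_require(raw, "id", "view"))
        apex = _point(_require(raw, "apex", f"view {view}"), f"view {view} apex")
        points: dict[str, dict[str, np.ndarray]] = {}
        for entry in _require(raw, "points", f"view {view}"):
            label = str(_require(entry, "label", "view point"))
            phase = str(_require(entry, "phase", "view point"))
            if phase not in PHASES:
                raise ValidationError(f"view {view} label {label}: bad phase {phase!r}")
            points.setdefault(label, {})[phase] = np.array(
                [float(_require(entry, "x", "view point")), float(_require(entry, "y", "view point"))]
            )
        annotations.append(AVAnnotation(view=view, apex=apex, points=points))

    bundle = SegmentationBundle(
        subject_id=subject_id,
        contour_stack=ContourStack(slices=slices),
        av_annotations=annotations,
        heart_rate=heart_rate,
        height=float(doc["height"]) if doc.get("height") is not None else None,
        weight=float(doc["weight"]) if doc.get("weight") is not None else None,
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: SegmentationBundle, path) -> None:
    """Serialize a bundle to contour JSON, preserving full float precision."""
    doc: dict = {
        "subject_id": bundle.subject_id,
        "heart_rate": bundle.heart_rate,
        "slices": [],
        "views": [],
    }
    if bundle.height is not None:
        doc["height"] = bundle.height
    if bundle.weight is not None:
        doc["weight"] = bundle.weight
    for slc in bundle.contour_stack.slices:
        raw: dict = {"index": slc.index, "thickness_mm": slc.thickness, "gap_mm": slc.gap}
        for phase, contours in slc.phases.items():
            pdoc = {}
            for key in CONTOUR_KEYS:
                poly = contours.contour(key)
                if poly is not None:
                    pdoc[key] = np.asarray(poly, dtype=float).tolist()
            for key in ("rv_insertion_anterior", "rv_insertion_inferior"):
                pt = getattr(contours, key)
                if pt is not None:
                    pdoc[key] = np.asarray(pt, dtype=float).tolist()
            raw[phase] = pdoc
        doc["slices"].append(raw)
    for ann in bundle.av_annotations:
        doc["views"].append(
            {
                "id": ann.view,
                "apex": np.asarray(ann.apex, dtype=float).tolist(),
                "points": [
                    {"label": label, "phase": phase, "x": float(pt[0]), "y": float(pt[1])}
                    for label, phases in ann.points.items()
                    for phase, pt in phases.items()
                ],
            }
        )
    Path(path).write_text(json.dumps(doc))


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Returns a typed DataFrame.  PAH rows must carry positive follow-up and a
    0/1 event flag; control rows must not carry events.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty cohort file") from exc
    if table.empty:
        raise ValidationError(f"{path}: cohort file has no rows")
    missing = [c for c in COHORT_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    bad_group = sorted(set(table["group"]) - set(GROUPS))
    if bad_group:
        raise ValidationError(f"{path}: unknown group label(s) {bad_group}")

    pah = table["group"] == "pah"
    bad_rows = table.index[pah & (table["followup_years"].isna() | table["event"].isna())]
    if len(bad_rows):
        raise ValidationError(
            f"{path}: PAH rows missing follow-up or event flag at row index "
            f"{list(bad_rows)}"
        )
    nonpos = table.index[pah & (table["followup_years"] <= 0)]
    if len(nonpos):
        raise ValidationError(f"{path}: non-positive follow-up time at row index {list(nonpos)}")
    bad_event = table.index[pah & ~table["event"].isin([0, 1])]
    if len(bad_event):
        raise ValidationError(f"{path}: event flag not in {{0,1}} at row index {list(bad_event)}")
    ctrl_event = table.index[(table["group"] == "control") & (table["event"] == 1)]
    if len(ctrl_event):
        raise ValidationError(f"{path}: control rows carry events at row index {list(ctrl_event)}")

    table = table.copy()
    for col in table.columns:
        if col not in ("subject_id", "group", "sex"):
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
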