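"""File formats: lesion tables (CSV), landmark sets (JSON), transforms,
match results, truth links and outcome reports.

All formats are plain text. Lesion tables are comma-separated UTF-8 with a
required header; unknown columns are preserved on round trip. Landmark files
hold one JSON object per exam (``{"exam_id": ..., "landmarks": [{"label",
"x_mm", "y_mm", "z_mm"}, ...]}``); study-level files hold a list of such
objects. JSON artifacts written by the CLI embed the resolved configuration
and seed under a ``"provenance"`` key.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .synthetic import CasePair
from .types import (
    AffineTransform,
    MatchResult,
    NoduleRecord,
    OutcomeRecord,
    PointSet,
    SchemaError,
)

LESION_COLUMNS = [
    "case_id",
    "exam_id",
    "lesion_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "diameter_mm",
    "localization",
    "texture",
    "true_lesion_id",
]
_FLOAT_COLUMNS = ("x_mm", "y_mm", "z_mm", "diameter_mm")


def read_lesion_table(path) -> list[NoduleRecord]:
    """Read a lesion CSV into records; extra columns land in ``record.extra``.

    A missing required column raises :class:`SchemaError` naming the column; a
    malformed number raises :class:`SchemaError` naming the file line.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in LESION_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path.name}: missing required column {col!r}")
        extra_cols = [c for c in header if c not in LESION_COLUMNS]
        records = []
        for lineno, row in enumerate(reader, start=2):
            vals = {}
            for col in _FLOAT_COLUMNS:
                try:
                    vals[col] = float(row[col])
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"{path.name} line {lineno}: malformed number in "
                        f"{col!r}: {row[col]!r}"
                    ) from None
            records.append(
                NoduleRecord(
                    lesion_id=row["lesion_id"],
                    exam_id=row["exam_id"],
                    centroid=(vals["x_mm"], vals["y_mm"], vals["z_mm"]),
                    diameter_mm=vals["diameter_mm"],
                    localization=row["localization"],
                    texture=row["texture"],
                    true_lesion_id=row["true_lesion_id"] or None,
                    case_id=row["case_id"],
                    extra={c: row[c] for c in extra_cols},
                )
            )
    return records


def write_lesion_table(records: Sequence[NoduleRecord], path) -> None:
    path = Path(path)
    extra_cols: list[str] = []
    for r in records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LESION_COLUMNS + extra_cols)
        for r in records:
            writer.writerow(
                [
                    r.case_id,
                    r.exam_id,
                    r.lesion_id,
                    repr(float(r.centroid[0])),
                    repr(float(r.centroid[1])),
                    repr(float(r.centroid[2])),
                    repr(float(r.diameter_mm)),
                    r.localization,
                    r.texture,
                    r.true_lesion_id or "",
                ]
                + [r.extra.get(c, "") for c in extra_cols]
            )


def _pointset_to_obj(ps: PointSet) -> dict:
    return {
        "exam_id": ps.exam_id,
        "landmarks": [
            {
                "label": ps.labels[i] if ps.labels is not None else None,
                "x_mm": float(p[0]),
                "y_mm": float(p[1]),
                "z_mm": float(p[2]),
            }
            for i, p in enumerate(ps.points)
        ],
    }


def _obj_to_pointset(obj: Mapping) -> PointSet:
    try:
        lms = obj["landmarks"]
        pts = [(lm["x_mm"], lm["y_mm"], lm["z_mm"]) for lm in lms]
    except KeyError as e:
        raise SchemaError(f"landmark object missing key {e}") from None
    labels = [lm.get("label") for lm in lms]
    if any(l is None for l in labels):
        labels = None
    return PointSet(
        np.asarray(pts, dtype=float).reshape(-1, 3),
        labels=labels,
        exam_id=obj.get("exam_id", ""),
    )


def read_landmarks(path) -> PointSet:
    """Read a single-exam landmark JSON file."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        raise SchemaError("expected a single exam object; use read_landmark_sets")
    return _obj_to_pointset(obj)


def write_landmarks(ps: PointSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_pointset_to_obj(ps), fh, indent=1)


def read_landmark_sets(path) -> dict[str, PointSet]:
    """Read a study-level landmark file (list of exam objects) keyed by exam."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    objs = data["exams"] if isinstance(data, dict) else data
    out = {}
    for obj in objs:
        ps = _obj_to_pointset(obj)
        out[ps.exam_id] = ps
    return out


def write_landmark_sets(sets: Sequence[PointSet], path, provenance: dict | None = None) -> None:
    doc: dict = {"exams": [_pointset_to_obj(ps) for ps in sets]}
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def write_match_result(result: MatchResult, path, provenance: dict | None = None) -> None:
    doc = result.to_dict()
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_match_result(path) -> MatchResult:
    with open(path, encoding="utf-8") as fh:
        return MatchResult.from_dict(json.load(fh))


def write_truth(pairs: Sequence[CasePair], path, provenance: dict | None = None) -> None:
    """Ground-truth file: per pair, the true transform, truth links, and the
    total nodule count of the exam (the count-bin stratum source)."""
    doc = {
        "pairs": {
            p.pair_id: {
                "case_id": p.case_id,
                "baseline_exam": p.baseline_landmarks.exam_id,
                "followup_exam": p.followup_landmarks.exam_id,
                "true_transform": p.true_transform.to_dict(),
                "truth_links": p.truth_links,
                "n_true_nodules": p.n_true_nodules,
            }
            for p in pairs
        }
    }
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    out = {}
    for pid, entry in doc["pairs"].items():
        entry = dict(entry)
        entry["true_transform"] = AffineTransform.from_dict(entry["true_transform"])
        out[pid] = entry
    return out


def write_transforms(transforms: Mapping[str, AffineTransform], path, provenance: dict | None = None) -> None:
    doc = {"pairs": {pid: t.to_dict() for pid, t in transforms.items()}}
    if provenance:
        doc["provenance"] = provenance
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_transforms(path) -> dict[str, AffineTransform]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return {pid: AffineTransform.from_dict(d) for pid, d in doc["pairs"].items()}


def write_outcome_report(outcomes: Sequence[OutcomeRecord], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "lesion_id", "outcome", "localization", "count_bin"])
        for o in outcomes:
            writer.writerow(
                [o.case_id, o.lesion_id, o.outcome, o.localization, o.case_nodule_count_bin]
            )


def read_outcome_report(path) -> list[OutcomeRecord]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [
            OutcomeRecord(
                case_id=row["case_id"],
                lesion_id=row["lesion_id"],
                outcome=row["outcome"],
                localization=row["localization"],
                case_nodule_count_bin=row["count_bin"],
            )
            for row in csv.DictReader(fh)
        ]
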