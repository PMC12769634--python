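"""File I/O for ground truth, marks and study design, plus study validation.

CSV schemas
-----------
``ground_truth.csv``: case_id, lesion_id, x_mm, y_mm, z_mm, diameter_mm, type
``marks.csv``:        case_id, source_id, modality, x_mm, y_mm, z_mm, rating
``study.yaml``:       readers, modalities, cases, spacing, seed

Positions round-trip to 0.001 mm; ratings are written exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .types import GroundTruthLesion, Mark, StudyDesign, PAIRED_MODALITIES

GT_COLUMNS = ["case_id", "lesion_id", "x_mm", "y_mm", "z_mm", "diameter_mm", "type"]
MARK_COLUMNS = ["case_id", "source_id", "modality", "x_mm", "y_mm", "z_mm", "rating"]

# Study-population lesion-count bounds: cases with fewer than 2 or more than
# 11 lesions are excluded from an enriched detection study of this design.
MIN_LESIONS_PER_CASE = 2
MAX_LESIONS_PER_CASE = 11


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def read_ground_truth(path) -> list[GroundTruthLesion]:
    df = pd.read_csv(path)
    _require_columns(df, GT_COLUMNS, f"ground truth file {path}")
    lesions = []
    for i, row in df.iterrows():
        try:
            lesions.append(
                GroundTruthLesion(
                    case_id=str(row.case_id),
                    lesion_id=str(row.lesion_id),
                    center=np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
                    diameter=float(row.diameter_mm),
                    lesion_type=str(row["type"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"ground truth row {i}: {exc}") from exc
    keys = [(g.case_id, g.lesion_id) for g in lesions]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (case_id, lesion_id): {dupes[:5]}")
    return lesions


def write_ground_truth(lesions: list[GroundTruthLesion], path) -> None:
    df = pd.DataFrame(
        {
            "case_id": [g.case_id for g in lesions],
            "lesion_id": [g.lesion_id for g in lesions],
            "x_mm": [round(float(g.center[0]), 3) for g in lesions],
            "y_mm": [round(float(g.center[1]), 3) for g in lesions],
            "z_mm": [round(float(g.center[2]), 3) for g in lesions],
            "diameter_mm": [round(float(g.diameter), 3) for g in lesions],
            "type": [g.lesion_type.value for g in lesions],
        }
    )
    df.to_csv(path, index=False)


def read_marks(path, ground_truth: list[GroundTruthLesion] | None = None) -> list[Mark]:
    """Read marks; if ground truth is given, reject marks on unknown cases."""
    df = pd.read_csv(path)
    _require_columns(df, MARK_COLUMNS, f"marks file {path}")
    marks = []
    for i, row in df.iterrows():
        try:
            marks.append(
                Mark(
                    case_id=str(row.case_id),
                    source_id=str(row.source_id),
                    modality=str(row.modality),
                    position=np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
                    rating=float(row.rating),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"marks row {i}: {exc}") from exc
    if ground_truth is not None:
        known = {g.case_id for g in ground_truth}
        orphan = sorted({m.case_id for m in marks} - known)
        if orphan:
            raise ValidationError(f"marks reference unknown case(s): {orphan[:5]}")
    return marks


def write_marks(marks: list[Mark], path) -> None:
    df = marks_to_frame(marks)
    df.to_csv(path, index=False)


def marks_to_frame(marks: list[Mark]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [m.case_id for m in marks],
            "source_id": [m.source_id for m in marks],
            "modality": [m.modality for m in marks],
            "x_mm": [round(float(m.position[0]), 3) for m in marks],
            "y_mm": [round(float(m.position[1]), 3) for m in marks],
            "z_mm": [round(float(m.position[2]), 3) for m in marks],
            "rating": [float(m.rating) for m in marks],
        }
    )


def read_study_design(path) -> StudyDesign:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"study file {path}: invalid YAML ({exc})") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"study file {path}: expected a mapping")
    try:
        return StudyDesign(
            reader_ids=[str(r) for r in cfg["readers"]],
            modalities=[str(m) for m in cfg.get("modalities", list(PAIRED_MODALITIES))],
            case_ids=[str(c) for c in cfg["cases"]],
            voxel_spacing=tuple(cfg.get("spacing", (1.2, 1.2, 3.0))),
        )
    except KeyError as exc:
        raise FormatError(f"study file {path}: missing key {exc}") from exc


def write_study_design(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "readers": list(design.reader_ids),
                "modalities": list(design.modalities),
                "cases": list(design.case_ids),
                "spacing": list(design.voxel_spacing),
            },
            fh,
            sort_keys=False,
        )


@dataclass
class StudyValidationReport:
    """Report-only output of :func:`validate_study`; inputs are never mutated."""

    lesion_count_violations: list[tuple[str, int]] = field(default_factory=list)
    orphan_marks: list[tuple[str, str]] = field(default_factory=list)
    missing_blocks: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.lesion_count_violations or self.orphan_marks or self.missing_blocks
        )


def validate_study(
    design: StudyDesign,
    ground_truth: list[GroundTruthLesion],
    marks: list[Mark],
    min_lesions: int = MIN_LESIONS_PER_CASE,
    max_lesions: int = MAX_LESIONS_PER_CASE,
) -> StudyValidationReport:
    """Check lesion-count bounds, orphan marks and missing reader blocks."""
    report = StudyValidationReport()
    counts: dict[str, int] = {}
    for g in ground_truth:
        counts[g.case_id] = counts.get(g.case_id, 0) + 1
    for case_id in design.case_ids:
        n = counts.get(case_id, 0)
        if n < min_lesions or n > max_lesions:
            report.lesion_count_violations.append((case_id, n))
    known = set(design.case_ids) | set(counts)
    seen_blocks = {(m.source_id, m.modality) for m in marks}
    for m in marks:
        if m.case_id not in known:
            report.orphan_marks.append((m.case_id, m.source_id))
    paired = [m for m in design.modalities if m in PAIRED_MODALITIES]
    for reader in design.reader_ids:
        for modality in paired:
            if (reader, modality) not in seen_blocks:
                report.missing_blocks.append((reader, modality))
    return report
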