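"""Lesion localization fraction (LLF), FPs per case (NLF) and FROC curves.

LLF is lesion-level sensitivity computed without regard to confidence
ratings: any TP mark counts, however low its rating.  NLF is the mean number
of FP marks per case over the full case list (cases without marks included
in the denominator).  The FROC curve applies a descending rating threshold
to both quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .matching import FP, MatchedStudy


@dataclass(frozen=True)
class FrocPoint:
    threshold: float
    nlf: float
    llf: float


def _lesion_block(matched: MatchedStudy, source_id: str, modality: str) -> pd.DataFrame:
    ll = matched.lesions
    block = ll[(ll.source_id == source_id) & (ll.modality == modality)]
    if block.empty:
        raise UndefinedMetricError(
            f"no lesion block for source {source_id!r}, modality {modality!r}"
        )
    return block


def compute_llf(
    matched: MatchedStudy,
    source_id: str,
    modality: str,
    lesion_filter=None,
) -> float:
    """Fraction of lesions (optionally filtered) with a TP mark, ratings ignored.

    ``lesion_filter`` is a boolean function of the per-lesion row
    (fields: case_id, lesion_id, diameter_mm, ...).
    """
    block = _lesion_block(matched, source_id, modality)
    if lesion_filter is not None:
        keep = block.apply(lesion_filter, axis=1).astype(bool)
        block = block[keep]
    if block.empty:
        raise UndefinedMetricError("lesion filter selected an empty lesion set")
    return float(block.localized.mean())


def compute_nlf(matched: MatchedStudy, source_id: str, modality: str) -> float:
    """Mean FP marks per case over the full study case list."""
    if not matched.case_ids:
        raise UndefinedMetricError("study has zero cases")
    mm = matched.marks
    n_fp = int(
        (
            (mm.source_id == source_id)
            & (mm.modality == modality)
            & (mm.label == FP)
        ).sum()
    )
    return n_fp / len(matched.case_ids)


def froc_points(
    matched: MatchedStudy, source_id: str, modality: str
) -> list[FrocPoint]:
    """FROC operating points, one per distinct mark rating, descending.

    At threshold t only marks rated >= t count; the endpoint at t=0 equals
    (compute_nlf, compute_llf).
    """
    block = _lesion_block(matched, source_id, modality)
    n_lesions = len(block)
    n_cases = len(matched.case_ids)
    mm = matched.marks
    mine = mm[(mm.source_id == source_id) & (mm.modality == modality)]
    ratings = np.unique(mine.rating.to_numpy())[::-1] if len(mine) else np.array([])
    thresholds = list(ratings)
    if 0.0 not in thresholds:
        thresholds.append(0.0)
    # best TP rating per lesion (absorbed duplicates already folded in)
    best = block.best_rating.to_numpy()
    fp_ratings = mine[mine.label == FP].rating.to_numpy()
    points = []
    for t in thresholds:
        llf = float((best >= t).sum() / n_lesions)
        nlf = float((fp_ratings >= t).sum() / n_cases)
        points.append(FrocPoint(threshold=float(t), nlf=nlf, llf=llf))
    return points


#: size brackets reported in enriched liver studies, mm, inclusive
DEFAULT_SIZE_THRESHOLDS = (12.0, 10.0, 8.0, 6.0)


def subgroup_llf(
    matched: MatchedStudy,
    thresholds_mm=DEFAULT_SIZE_THRESHOLDS,
    include_all: bool = True,
) -> pd.DataFrame:
    """Size-stratified LLF per reader x modality; filters are diameter <= t.

    Returns a tidy frame with columns source_id, modality, bracket
    ('all' or '<=T'), threshold_mm (inf for 'all'), n_lesions, llf.
    """
    rows = []
    for source_id, modality in matched.blocks():
        block = _lesion_block(matched, source_id, modality)
        brackets = []
        if include_all:
            brackets.append(("all", np.inf))
        brackets += [(f"<={t:g}", float(t)) for t in thresholds_mm]
        for name, t in brackets:
            sub = block[block.diameter_mm <= t]
            if sub.empty:
                raise UndefinedMetricError(
                    f"no lesions with diameter <= {t} mm for bracket {name!r}"
                )
            rows.append(
                {
                    "source_id": source_id,
                    "modality": modality,
                    "bracket": name,
                    "threshold_mm": t,
                    "n_lesions": len(sub),
                    "llf": float(sub.localized.mean()),
                }
            )
    return pd.DataFrame(rows)
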