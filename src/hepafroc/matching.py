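"""Label marks TP/FP against 3D ground truth and link findings across sessions.

A mark is a TP candidate for a lesion when the 3D Euclidean distance between
the mark and the lesion centre is within the rule threshold (3/4 of the
lesion diameter, with a 3 mm clause acting as a floor by default).
Candidates are resolved one-to-one greedily by ascending distance, ties
broken by (lesion_id, mark order).  With the default dedup policy, a second
mark landing inside the threshold of an already-claimed lesion is absorbed
(labelled TP on that lesion) rather than counted as a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import GroundTruthLesion, Mark, MatchRule

#: mark labels
TP = "TP"
FP = "FP"


@dataclass
class MatchedStudy:
    """Marks labelled TP/FP plus per-lesion localization status.

    ``marks``:   one row per mark — case_id, source_id, modality, x/y/z_mm,
                 rating, label (TP/FP), lesion_id (NaN for FP), distance_mm.
    ``lesions``: one row per lesion x source x modality — localized flag and
                 best (max) rating among the TP marks assigned to it.
    ``case_ids``: all cases in the study (denominator for FPs/case).
    """

    marks: pd.DataFrame
    lesions: pd.DataFrame
    case_ids: list[str]
    rule: MatchRule

    def blocks(self) -> list[tuple[str, str]]:
        """(source_id, modality) pairs present in the mark table or lesion table."""
        out = {
            (s, m)
            for s, m in self.lesions[["source_id", "modality"]].itertuples(index=False)
        }
        return sorted(out)

    def select(self, source_id: str, modality: str) -> "MatchedStudy":
        """View restricted to one reader x modality block (copies the frames)."""
        mm = self.marks[
            (self.marks.source_id == source_id) & (self.marks.modality == modality)
        ].reset_index(drop=True)
        ll = self.lesions[
            (self.lesions.source_id == source_id) & (self.lesions.modality == modality)
        ].reset_index(drop=True)
        return MatchedStudy(mm, ll, self.case_ids, self.rule)

    def fp_counts(self) -> pd.DataFrame:
        """FP marks per case x source x modality (cases with zero FPs included)."""
        rows = []
        fp = self.marks[self.marks.label == FP]
        for source_id, modality in self.blocks():
            sub = fp[(fp.source_id == source_id) & (fp.modality == modality)]
            by_case = sub.groupby("case_id").size()
            for case_id in self.case_ids:
                rows.append(
                    {
                        "source_id": source_id,
                        "modality": modality,
                        "case_id": case_id,
                        "fp_count": int(by_case.get(case_id, 0)),
                    }
                )
        return pd.DataFrame(rows)


def _match_one_case(
    pos: np.ndarray,
    ratings: np.ndarray,
    centers: np.ndarray,
    thresholds: np.ndarray,
    lesion_order: np.ndarray,
    absorb: bool,
):
    """Greedy one-to-one assignment for a single case.

    Returns (mark labels, matched lesion index or -1, distances,
    localized flags per lesion, best rating per lesion).
    """
    n_marks, n_lesions = len(pos), len(centers)
    label = np.full(n_marks, FP, dtype=object)
    matched = np.full(n_marks, -1, dtype=int)
    dist_out = np.full(n_marks, np.nan)
    localized = np.zeros(n_lesions, dtype=bool)
    best = np.full(n_lesions, -np.inf)
    if n_marks == 0 or n_lesions == 0:
        return label, matched, dist_out, localized, best

    d = np.linalg.norm(pos[:, None, :] - centers[None, :, :], axis=2)
    cand_m, cand_l = np.nonzero(d <= thresholds[None, :])
    # sort by distance, then lesion identity, then mark order
    order = np.lexsort((cand_m, lesion_order[cand_l], d[cand_m, cand_l]))
    mark_used = np.zeros(n_marks, dtype=bool)
    for k in order:
        m, l = cand_m[k], cand_l[k]
        if mark_used[m] or localized[l]:
            continue
        mark_used[m] = True
        localized[l] = True
        label[m] = TP
        matched[m] = l
        dist_out[m] = d[m, l]
        best[l] = max(best[l], ratings[m])
    if absorb:
        # unassigned marks inside the threshold of an already-claimed lesion
        # are duplicate detections of that lesion, not FPs
        for m in range(n_marks):
            if mark_used[m]:
                continue
            within = np.nonzero((d[m] <= thresholds) & localized)[0]
            if len(within):
                l = within[np.argmin(d[m, within])]
                label[m] = TP
                matched[m] = l
                dist_out[m] = d[m, l]
                best[l] = max(best[l], ratings[m])
    return label, matched, dist_out, localized, best


def match_marks(
    marks: list[Mark],
    ground_truth: list[GroundTruthLesion],
    rule: MatchRule | None = None,
    case_ids: list[str] | None = None,
    blocks: list[tuple[str, str]] | None = None,
) -> MatchedStudy:
    """Label every mark TP/FP against ground truth, per reader x modality x case.

    ``blocks`` forces lesion-status rows for (source, modality) pairs even
    when that observer made no marks (every lesion then counts as missed).
    """
    rule = rule or MatchRule()
    gt_cases = sorted({g.case_id for g in ground_truth})
    if case_ids is None:
        case_ids = gt_cases
    known = set(case_ids) | set(gt_cases)
    bad = sorted({m.case_id for m in marks} - known)
    if bad:
        raise ValidationError(f"marks reference unknown case(s): {bad[:5]}")

    # lesion lookup per case, in stable input order
    by_case: dict[str, list[tuple[int, GroundTruthLesion]]] = {}
    for idx, g in enumerate(ground_truth):
        by_case.setdefault(g.case_id, []).append((idx, g))

    mark_rows = []
    lesion_rows = []
    groups: dict[tuple[str, str], dict[str, list[tuple[int, Mark]]]] = {}
    for idx, m in enumerate(marks):
        groups.setdefault((m.source_id, m.modality), {}).setdefault(
            m.case_id, []
        ).append((idx, m))
    for key in blocks or ():
        groups.setdefault(tuple(key), {})

    for (source_id, modality), cases in sorted(groups.items()):
        for case_id in case_ids:
            gts = by_case.get(case_id, [])
            case_marks = cases.get(case_id, [])
            centers = np.array([g.center for _, g in gts]).reshape(-1, 3)
            thresholds = rule.threshold(np.array([g.diameter for _, g in gts]))
            lesion_order = np.argsort(
                np.argsort([g.lesion_id for _, g in gts])
            ) if gts else np.empty(0, dtype=int)
            pos = np.array([m.position for _, m in case_marks]).reshape(-1, 3)
            ratings = np.array([m.rating for _, m in case_marks])
            label, matched, dist, localized, best = _match_one_case(
                pos, ratings, centers, np.atleast_1d(thresholds), lesion_order,
                rule.absorb_duplicates,
            )
            for j, (_, m) in enumerate(case_marks):
                mark_rows.append(
                    {
                        "case_id": case_id,
                        "source_id": source_id,
                        "modality": modality,
                        "x_mm": m.position[0],
                        "y_mm": m.position[1],
                        "z_mm": m.position[2],
                        "rating": m.rating,
                        "label": label[j],
                        "lesion_id": gts[matched[j]][1].lesion_id
                        if matched[j] >= 0
                        else None,
                        "distance_mm": dist[j],
                    }
                )
            for j, (_, g) in enumerate(gts):
                lesion_rows.append(
                    {
                        "source_id": source_id,
                        "modality": modality,
                        "case_id": case_id,
                        "lesion_id": g.lesion_id,
                        "diameter_mm": g.diameter,
                        "localized": bool(localized[j]),
                        "best_rating": best[j] if localized[j] else -np.inf,
                    }
                )

    marks_df = pd.DataFrame(
        mark_rows,
        columns=[
            "case_id", "source_id", "modality", "x_mm", "y_mm", "z_mm",
            "rating", "label", "lesion_id", "distance_mm",
        ],
    )
    lesions_df = pd.DataFrame(
        lesion_rows,
        columns=[
            "source_id", "modality", "case_id", "lesion_id", "diameter_mm",
            "localized", "best_rating",
        ],
    )
    return MatchedStudy(marks_df, lesions_df, list(case_ids), rule)


# states used by the linked-finding table
_LESION_STATES = ("TP", "FN")
_NONLESION_STATES = ("FP", "TN")


def link_findings_across_sessions(
    matched_without: MatchedStudy,
    matched_with: MatchedStudy,
    link_radius_mm: float = 3.0,
) -> pd.DataFrame:
    """Pair findings between the two sessions of one reader.

    Lesions are linked by identity and carry (TP/FN, TP/FN) states from their
    localized flags.  FP marks are linked across sessions one-to-one by
    ascending distance when within ``link_radius_mm``; an unlinked FP pairs
    with an implicit TN in the other session.  (TN, TN) rows do not exist.

    Returns a DataFrame with columns: case_id, finding_id, kind
    ('lesion'/'non_lesion'), state_without, state_with.
    """
    lw, lv = matched_without.lesions, matched_with.lesions
    readers_w = set(lw.source_id.unique())
    readers_v = set(lv.source_id.unique())
    if readers_w != readers_v:
        raise ValidationError(f"reader mismatch: {readers_w} vs {readers_v}")
    if len(readers_w) != 1:
        raise ValidationError("link_findings_across_sessions expects one reader")
    mod_w = set(lw.modality.unique())
    mod_v = set(lv.modality.unique())
    if len(mod_w) != 1 or len(mod_v) != 1 or mod_w == mod_v:
        raise ValidationError(
            f"expected two distinct single modalities, got {mod_w} and {mod_v}"
        )

    rows = []
    loc_w = {
        (r.case_id, r.lesion_id): bool(r.localized) for r in lw.itertuples()
    }
    loc_v = {
        (r.case_id, r.lesion_id): bool(r.localized) for r in lv.itertuples()
    }
    for key in loc_w:
        if key not in loc_v:
            raise ValidationError(f"lesion {key} missing from the paired session")
        rows.append(
            {
                "case_id": key[0],
                "finding_id": key[1],
                "kind": "lesion",
                "state_without": "TP" if loc_w[key] else "FN",
                "state_with": "TP" if loc_v[key] else "FN",
            }
        )

    fw = matched_without.marks[matched_without.marks.label == FP]
    fv = matched_with.marks[matched_with.marks.label == FP]
    all_cases = sorted(set(fw.case_id) | set(fv.case_id))
    for case_id in all_cases:
        pw = fw[fw.case_id == case_id][["x_mm", "y_mm", "z_mm"]].to_numpy()
        pv = fv[fv.case_id == case_id][["x_mm", "y_mm", "z_mm"]].to_numpy()
        linked_w = np.zeros(len(pw), dtype=bool)
        linked_v = np.zeros(len(pv), dtype=bool)
        if len(pw) and len(pv):
            d = np.linalg.norm(pw[:, None, :] - pv[None, :, :], axis=2)
            ci, cj = np.nonzero(d <= link_radius_mm)
            for k in np.lexsort((cj, ci, d[ci, cj])):
                i, j = ci[k], cj[k]
                if linked_w[i] or linked_v[j]:
                    continue
                linked_w[i] = linked_v[j] = True
                rows.append(
                    {
                        "case_id": case_id,
                        "finding_id": f"fp_{case_id}_{len(rows)}",
                        "kind": "non_lesion",
                        "state_without": "FP",
                        "state_with": "FP",
                    }
                )
        for i in range(len(pw)):
            if not linked_w[i]:
                rows.append(
                    {
                        "case_id": case_id,
                        "finding_id": f"fp_{case_id}_{len(rows)}",
                        "kind": "non_lesion",
                        "state_without": "FP",
                        "state_with": "TN",
                    }
                )
        for j in range(len(pv)):
            if not linked_v[j]:
                rows.append(
                    {
                        "case_id": case_id,
                        "finding_id": f"fp_{case_id}_{len(rows)}",
                        "kind": "non_lesion",
                        "state_without": "TN",
                        "state_with": "FP",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["case_id", "finding_id", "kind", "state_without", "state_with"],
    )
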