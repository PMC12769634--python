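"""Study evaluation and report tables/figures.

Turns a study bundle (ground truth + marks + design) into the standard
reader-study summaries: a size-bracket table of LLF and FOM per modality
with paired-t / DBM p-values, an NCR-stratified table, and per-reader
series for FP counts, LLF and FOM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError
from .froc import DEFAULT_SIZE_THRESHOLDS, compute_llf, compute_nlf
from .matching import MatchedStudy, link_findings_across_sessions, match_marks
from .ncr import DEFAULT_NCR_THRESHOLD, NcrResult, compute_ncr, stratify_readers
from .observer import (
    RatingTable,
    build_rating_table,
    dbm_significance,
    jafroc1_fom,
    paired_t_llf,
    pseudovalue_array,
)
from .simulate import StudyBundle
from .types import AI_SOURCE, AI_STANDALONE, WITH_AI, WITHOUT_AI, MatchRule


def filter_lesions(table: RatingTable, keep: np.ndarray) -> RatingTable:
    """Rating table restricted to a lesion subset (NL vectors unchanged)."""
    keep = np.asarray(keep, dtype=bool)
    return RatingTable(
        modalities=table.modalities,
        readers=table.readers,
        case_ids=table.case_ids,
        lesion_ids=[l for l, k in zip(table.lesion_ids, keep) if k],
        lesion_case_idx=table.lesion_case_idx[keep],
        ll=table.ll[:, :, keep],
        nl=table.nl,
        lesion_diameters=None
        if table.lesion_diameters is None
        else table.lesion_diameters[keep],
    )


@dataclass
class ReportBundle:
    """All tables of one evaluation run."""

    size_table: pd.DataFrame       # bracket x modality LLF/FOM + p-values
    ncr_table: pd.DataFrame        # per-reader NCR and pattern counts
    strata_table: pd.DataFrame     # all readers vs low-NCR stratum
    reader_series: pd.DataFrame    # per-reader FP count, LLF, FOM by modality
    metadata: dict


def _dbm_p(table: RatingTable, readers: list[str]) -> float:
    """DBM modality p-value for a reader subset; NaN when the jackknife is
    degenerate (e.g. a size bracket whose lesions sit in a single case)."""
    sub = RatingTable(
        modalities=table.modalities,
        readers=readers,
        case_ids=table.case_ids,
        lesion_ids=table.lesion_ids,
        lesion_case_idx=table.lesion_case_idx,
        ll=table.ll[:, [table.readers.index(r) for r in readers]],
        nl=table.nl[:, [table.readers.index(r) for r in readers]],
        lesion_diameters=table.lesion_diameters,
    )
    try:
        pv = pseudovalue_array(sub)
    except DegenerateStatisticError:
        return float("nan")
    if np.allclose(pv.var(axis=(1, 2)), 0) and np.allclose(pv[0], pv[1]):
        return 1.0
    return dbm_significance(pv).p_value


def evaluate_study(
    bundle: StudyBundle,
    rule: MatchRule | None = None,
    size_thresholds=DEFAULT_SIZE_THRESHOLDS,
    ncr_threshold: float = DEFAULT_NCR_THRESHOLD,
    link_radius_mm: float = 3.0,
) -> ReportBundle:
    rule = rule or MatchRule()
    readers = list(bundle.design.reader_ids)
    matched = match_marks(bundle.marks, bundle.ground_truth, rule,
                          case_ids=bundle.design.case_ids)
    has_ai = any(m.modality == AI_STANDALONE for m in bundle.marks)

    # --- per-reader series (FP counts, LLF, FOM) --------------------------
    reader_rows = []
    table = build_rating_table(matched, readers=readers,
                               modalities=[WITHOUT_AI, WITH_AI])
    for reader in readers:
        for modality in (WITHOUT_AI, WITH_AI):
            reader_rows.append(
                {
                    "source_id": reader,
                    "modality": modality,
                    "fp_total": int(
                        compute_nlf(matched, reader, modality)
                        * len(bundle.design.case_ids)
                    ),
                    "llf": compute_llf(matched, reader, modality),
                    "fom": jafroc1_fom(table, reader, modality),
                }
            )
    reader_series = pd.DataFrame(reader_rows)

    # --- size-bracket table ----------------------------------------------
    diam = table.lesion_diameters
    brackets = [("all", np.inf)] + [(f"<={t:g}", float(t)) for t in size_thresholds]
    size_rows = []
    for name, t in brackets:
        keep = diam <= t
        filt = (lambda row, tt=t: row.diameter_mm <= tt) if np.isfinite(t) else None
        llf_wo = [compute_llf(matched, r, WITHOUT_AI, filt) for r in readers]
        llf_wi = [compute_llf(matched, r, WITH_AI, filt) for r in readers]
        try:
            _, _, p_llf = paired_t_llf(llf_wo, llf_wi)
        except DegenerateStatisticError:
            p_llf = float("nan")
        sub = filter_lesions(table, keep)
        fom_wo = [jafroc1_fom(sub, r, WITHOUT_AI) for r in readers]
        fom_wi = [jafroc1_fom(sub, r, WITH_AI) for r in readers]
        p_fom = _dbm_p(sub, readers) if len(readers) > 1 else float("nan")
        ai_llf = (
            compute_llf(matched, AI_SOURCE, AI_STANDALONE, filt) if has_ai else float("nan")
        )
        size_rows.append(
            {
                "bracket": name,
                "n_lesions": int(keep.sum()),
                "llf_without": float(np.mean(llf_wo)),
                "llf_with": float(np.mean(llf_wi)),
                "llf_p": p_llf,
                "llf_ai": ai_llf,
                "fom_without": float(np.mean(fom_wo)),
                "fom_with": float(np.mean(fom_wi)),
                "fom_p": p_fom,
            }
        )
    size_table = pd.DataFrame(size_rows)

    # --- NCR per reader ---------------------------------------------------
    ncr_results: dict[str, NcrResult] = {}
    ncr_rows = []
    for reader in readers:
        linked = link_findings_across_sessions(
            matched.select(reader, WITHOUT_AI),
            matched.select(reader, WITH_AI),
            link_radius_mm=link_radius_mm,
        )
        res = compute_ncr(linked, threshold=ncr_threshold)
        ncr_results[reader] = res
        ncr_rows.append(
            {
                "source_id": reader,
                "negative": res.negative,
                "denominator": res.denominator,
                "ncr": res.ncr,
                "stratum": res.stratum,
                **{f"n_{k.replace('->', '_to_')}": v for k, v in sorted(res.counts.items())},
            }
        )
    ncr_table = pd.DataFrame(ncr_rows).fillna(0)
    strata = stratify_readers(ncr_results, ncr_threshold)

    # --- stratified table (all readers vs low-NCR readers) ----------------
    strata_rows = []
    for label, group in (
        ("all", readers),
        (f"ncr<{ncr_threshold:g}", sorted(strata["low"])),
    ):
        if not group:
            continue
        llf_wo = [compute_llf(matched, r, WITHOUT_AI) for r in group]
        llf_wi = [compute_llf(matched, r, WITH_AI) for r in group]
        try:
            _, _, p_llf = paired_t_llf(llf_wo, llf_wi) if len(group) > 1 else (0, 0, float("nan"))
        except DegenerateStatisticError:
            p_llf = float("nan")
        fom_wo = [jafroc1_fom(table, r, WITHOUT_AI) for r in group]
        fom_wi = [jafroc1_fom(table, r, WITH_AI) for r in group]
        p_fom = _dbm_p(table, group) if len(group) > 1 else float("nan")
        strata_rows.append(
            {
                "stratum": label,
                "n_readers": len(group),
                "llf_without": float(np.mean(llf_wo)),
                "llf_with": float(np.mean(llf_wi)),
                "llf_p": p_llf,
                "fom_without": float(np.mean(fom_wo)),
                "fom_with": float(np.mean(fom_wi)),
                "fom_p": p_fom,
            }
        )
    strata_table = pd.DataFrame(strata_rows)

    metadata = {
        "n_readers": len(readers),
        "n_cases": len(bundle.design.case_ids),
        "n_lesions": len(bundle.ground_truth),
        "rule": {
            "diameter_fraction": rule.diameter_fraction,
            "floor_mm": rule.floor_mm,
            "combine": rule.combine,
        },
        "ncr_threshold": ncr_threshold,
        "link_radius_mm": link_radius_mm,
    }
    return ReportBundle(size_table, ncr_table, strata_table, reader_series, metadata)


def write_report(report: ReportBundle, outdir, plots: bool = True) -> None:
    """Write CSV tables, a JSON twin and (optionally) per-reader figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.size_table.to_csv(outdir / "size_table.csv", index=False)
    report.ncr_table.to_csv(outdir / "ncr_table.csv", index=False)
    report.strata_table.to_csv(outdir / "strata_table.csv", index=False)
    report.reader_series.to_csv(outdir / "reader_series.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "metadata": report.metadata,
                "size_table": report.size_table.to_dict(orient="records"),
                "ncr_table": report.ncr_table.to_dict(orient="records"),
                "strata_table": report.strata_table.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    if plots:
        plot_reader_series(report, outdir)


def plot_reader_series(report: ReportBundle, outdir) -> None:
    """Per-reader bar charts of FP totals, LLF and FOM, paired by session."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    rs = report.reader_series
    readers = sorted(rs.source_id.unique())
    x = np.arange(len(readers))
    for metric, fname, ylabel in (
        ("fp_total", "fp_per_reader.svg", "False-positive marks"),
        ("llf", "llf_per_reader.svg", "Lesion localization fraction"),
        ("fom", "fom_per_reader.svg", "JAFROC1 figure of merit"),
    ):
        fig, ax = plt.subplots(figsize=(8, 3.2))
        for off, modality, color in ((-0.2, WITHOUT_AI, "#777777"),
                                     (0.2, WITH_AI, "#cc3311")):
            vals = [
                float(rs[(rs.source_id == r) & (rs.modality == modality)][metric].iloc[0])
                for r in readers
            ]
            ax.bar(x + off, vals, width=0.38, label=modality, color=color)
        ax.set_xticks(x, readers, rotation=60, fontsize=7)
        ax.set_ylabel(ylabel)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / fname)
        plt.close(fig)
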