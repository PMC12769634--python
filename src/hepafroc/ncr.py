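"""Negative consultation ratio: how often AI assistance flips a correct call.

A *negative consultation* is a finding whose status changes from correct to
incorrect between the unassisted and the AI-assisted session: a lesion
detected without but missed with the software (TP -> FN), or a non-lesion
location clean without but marked with it (TN -> FP).  The NCR divides the
negative consultations by all findings detected in at least one session;
(TN, TN) locations do not exist as findings, and undetected lesions
((FN, FN)) are excluded from the denominator by default on the same
"detected in at least one session" reading (a flag includes them).

Readers with NCR >= 10% form the high-automation-bias stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UndefinedMetricError, ValidationError

NEGATIVE_PATTERNS = (("TP", "FN"), ("TN", "FP"))
DEFAULT_NCR_THRESHOLD = 0.10

_LESION_STATES = {"TP", "FN"}
_NONLESION_STATES = {"FP", "TN"}


def classify_findings(linked: pd.DataFrame) -> pd.DataFrame:
    """Validate a linked-finding table and add a 'pattern' column.

    Input comes from :func:`hepafroc.matching.link_findings_across_sessions`
    (columns case_id, finding_id, kind, state_without, state_with).
    """
    required = {"case_id", "finding_id", "kind", "state_without", "state_with"}
    missing = required - set(linked.columns)
    if missing:
        raise ValidationError(f"linked table missing column(s) {sorted(missing)}")
    for row in linked.itertuples():
        states = _LESION_STATES if row.kind == "lesion" else _NONLESION_STATES
        if row.state_without not in states or row.state_with not in states:
            raise ValidationError(
                f"finding {row.finding_id}: states ({row.state_without}, "
                f"{row.state_with}) invalid for kind {row.kind!r}"
            )
        if row.state_without == "TN" and row.state_with == "TN":
            raise ValidationError(
                f"finding {row.finding_id}: (TN, TN) rows must not exist"
            )
    out = linked.copy()
    out["pattern"] = out.state_without + "->" + out.state_with
    return out


@dataclass
class NcrResult:
    """Per-reader negative-consultation summary."""

    counts: dict[str, int]
    negative: int
    denominator: int
    ncr: float
    stratum: str  # 'low' (< threshold) or 'high' (>= threshold)


def compute_ncr(
    patterns: pd.DataFrame,
    include_fn_fn: bool = False,
    threshold: float = DEFAULT_NCR_THRESHOLD,
) -> NcrResult:
    """NCR for one reader's classified finding table."""
    if "pattern" not in patterns.columns:
        patterns = classify_findings(patterns)
    counts = patterns.pattern.value_counts().to_dict()
    negative = sum(counts.get(f"{a}->{b}", 0) for a, b in NEGATIVE_PATTERNS)
    denom = int(len(patterns))
    if not include_fn_fn:
        denom -= counts.get("FN->FN", 0)
    if denom == 0:
        raise UndefinedMetricError("NCR undefined: no findings in the denominator")
    ncr = negative / denom
    return NcrResult(
        counts={k: int(v) for k, v in counts.items()},
        negative=int(negative),
        denominator=denom,
        ncr=float(ncr),
        stratum="low" if ncr < threshold else "high",
    )


def stratify_readers(
    results: dict[str, NcrResult], threshold: float = DEFAULT_NCR_THRESHOLD
) -> dict[str, set[str]]:
    """Partition readers into {'low', 'high'} strata by strict ncr < threshold."""
    low = {r for r, res in results.items() if res.ncr < threshold}
    return {"low": low, "high": set(results) - low}
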