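"""JAFROC figure of merit, jackknife pseudovalues, DBM testing and power.

The figure of merit used here is the JAFROC1 variant: every lesion's
localization rating is compared against the highest false-positive rating of
every case (not just lesion-containing ones).  In an enriched study where
all cases harbor lesions, JAFROC1 is the only applicable variant.

theta = (1 / (N_c * N_L)) * sum_c sum_l psi(NL_c, LL_l)

with the Wilcoxon kernel psi(a, b) = 1 if b > a, 0.5 if b == a (both
finite), 0 otherwise.  An unmarked lesion carries LL = -inf, a case without
FP marks carries NL = -inf; the tie psi(-inf, -inf) scores 0 by default, so
a reader who marks nothing scores 0 (a config flag restores the 0.5 tie
convention).

Significance across modalities uses the Dorfman-Berbaum-Metz jackknife
pseudovalue ANOVA with the Hillis denominator and degrees of freedom by
default (classic Satterthwaite selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError, UndefinedMetricError, ValidationError
from .matching import MatchedStudy

NEG_INF = -np.inf


@dataclass
class RatingTable:
    """Per reader x modality rating vectors feeding the figure of merit.

    ``ll[i, j, l]``: rating of lesion l by reader j under modality i
    (-inf when unmarked).  ``nl[i, j, c]``: highest FP rating on case c
    (-inf when the case has no FP mark).
    """

    modalities: list[str]
    readers: list[str]
    case_ids: list[str]
    lesion_ids: list[str]
    lesion_case_idx: np.ndarray  # (n_lesions,) index into case_ids
    ll: np.ndarray  # (I, J, n_lesions)
    nl: np.ndarray  # (I, J, n_cases)
    lesion_diameters: np.ndarray | None = None

    def __post_init__(self):
        I, J = len(self.modalities), len(self.readers)
        if self.ll.shape != (I, J, len(self.lesion_ids)):
            raise ValidationError(f"LL shape {self.ll.shape} inconsistent")
        if self.nl.shape != (I, J, len(self.case_ids)):
            raise ValidationError(f"NL shape {self.nl.shape} inconsistent")

    def index(self, reader: str, modality: str) -> tuple[int, int]:
        return self.modalities.index(modality), self.readers.index(reader)


def build_rating_table(
    matched: MatchedStudy,
    readers: list[str] | None = None,
    modalities: list[str] | None = None,
) -> RatingTable:
    """Collapse a matched study to LL/NL vectors (max rating per group)."""
    lesions = matched.lesions
    if readers is None:
        readers = sorted(lesions.source_id.unique())
    if modalities is None:
        modalities = sorted(lesions.modality.unique())
    case_ids = list(matched.case_ids)
    case_pos = {c: k for k, c in enumerate(case_ids)}

    # lesion universe from the first block (identical across blocks)
    first = lesions[
        (lesions.source_id == readers[0]) & (lesions.modality == modalities[0])
    ]
    lesion_keys = list(zip(first.case_id, first.lesion_id))
    lesion_ids = [lid for _, lid in lesion_keys]
    lesion_case_idx = np.array([case_pos[c] for c, _ in lesion_keys], dtype=int)
    diameters = first.diameter_mm.to_numpy(dtype=float)
    key_pos = {k: n for n, k in enumerate(lesion_keys)}

    I, J = len(modalities), len(readers)
    ll = np.full((I, J, len(lesion_ids)), NEG_INF)
    nl = np.full((I, J, len(case_ids)), NEG_INF)
    for i, modality in enumerate(modalities):
        for j, reader in enumerate(readers):
            block = lesions[
                (lesions.source_id == reader) & (lesions.modality == modality)
            ]
            for row in block.itertuples():
                ll[i, j, key_pos[(row.case_id, row.lesion_id)]] = row.best_rating
            mm = matched.marks
            fps = mm[
                (mm.source_id == reader)
                & (mm.modality == modality)
                & (mm.label == "FP")
            ]
            for case_id, grp in fps.groupby("case_id"):
                nl[i, j, case_pos[case_id]] = grp.rating.max()
    return RatingTable(
        modalities=list(modalities),
        readers=list(readers),
        case_ids=case_ids,
        lesion_ids=lesion_ids,
        lesion_case_idx=lesion_case_idx,
        ll=ll,
        nl=nl,
        lesion_diameters=diameters,
    )


def _kernel_matrix(nl: np.ndarray, ll: np.ndarray, neg_inf_tie: float) -> np.ndarray:
    """psi(NL_c, LL_l) for all (case, lesion) pairs -> (n_cases, n_lesions)."""
    a = nl[:, None]
    b = ll[None, :]
    k = (b > a).astype(float)
    both_finite = np.isfinite(a) & np.isfinite(b)
    k += 0.5 * ((b == a) & both_finite)
    k += neg_inf_tie * (np.isneginf(a) & np.isneginf(b))
    return k


def jafroc1_fom(
    table: RatingTable,
    reader: str,
    modality: str,
    neg_inf_tie: float = 0.0,
) -> float:
    """JAFROC1 figure of merit for one reader x modality."""
    if len(table.lesion_ids) == 0:
        raise UndefinedMetricError("figure of merit undefined with zero lesions")
    i, j = table.index(reader, modality)
    k = _kernel_matrix(table.nl[i, j], table.ll[i, j], neg_inf_tie)
    return float(k.mean())


def jackknife_pseudovalues(
    table: RatingTable,
    reader: str,
    modality: str,
    neg_inf_tie: float = 0.0,
    center: bool = True,
) -> np.ndarray:
    """Leave-one-case-out pseudovalues Y_c = N*theta - (N-1)*theta_(-c).

    Removing case c drops its NL entry and all its lesions' LL entries.
    Centered pseudovalues (default) are shifted so their mean equals theta;
    centering preserves all ANOVA contrasts.
    """
    n_cases = len(table.case_ids)
    if n_cases < 2:
        raise DegenerateStatisticError("jackknife requires at least 2 cases")
    i, j = table.index(reader, modality)
    k = _kernel_matrix(table.nl[i, j], table.ll[i, j], neg_inf_tie)
    n_lesions = k.shape[1]
    total = k.sum()
    theta = total / (n_cases * n_lesions)
    row = k.sum(axis=1)
    lesions_of = table.lesion_case_idx
    col_by_case = np.zeros(n_cases)
    np.add.at(col_by_case, lesions_of, k.sum(axis=0))
    block = np.zeros(n_cases)
    np.add.at(block, lesions_of, k[np.arange(n_cases)[lesions_of], np.arange(n_lesions)])
    n_l_case = np.bincount(lesions_of, minlength=n_cases)
    remaining = (n_cases - 1) * (n_lesions - n_l_case)
    if np.any(remaining == 0):
        raise DegenerateStatisticError(
            "leave-one-out removes every lesion; need lesions in >= 2 cases"
        )
    theta_loo = (total - row - col_by_case + block) / remaining
    pv = n_cases * theta - (n_cases - 1) * theta_loo
    if center:
        pv = pv + (theta - pv.mean())
    return pv


def pseudovalue_array(
    table: RatingTable, neg_inf_tie: float = 0.0, center: bool = True
) -> np.ndarray:
    """Pseudovalues for every modality x reader -> array (I, J, n_cases)."""
    I, J = len(table.modalities), len(table.readers)
    out = np.empty((I, J, len(table.case_ids)))
    for i, modality in enumerate(table.modalities):
        for j, reader in enumerate(table.readers):
            out[i, j] = jackknife_pseudovalues(
                table, reader, modality, neg_inf_tie=neg_inf_tie, center=center
            )
    return out


@dataclass
class DbmResult:
    """Mean squares and the modality F test of the DBM pseudovalue ANOVA."""

    ms: dict[str, float]
    f_statistic: float
    ddf1: float
    ddf2: float
    p_value: float
    fom_means: np.ndarray  # per-modality mean pseudovalue (= mean FOM estimate)
    fom_difference: float  # modality[1] - modality[0] when I == 2, else nan
    method: str = "hillis"


def dbm_significance(pseudovalues: np.ndarray, method: str = "hillis") -> DbmResult:
    """Dorfman-Berbaum-Metz test for a modality effect.

    ``pseudovalues``: array (I, J, N) of jackknife pseudovalues, fully
    crossed (modality x reader x case).  Readers and cases are treated as
    random, modality as fixed.  ``method`` is 'hillis' (default) or
    'satterthwaite' (classic DBM denominator and df).
    """
    y = np.asarray(pseudovalues, dtype=float)
    if y.ndim != 3:
        raise ValidationError("pseudovalues must be a 3D (I, J, N) array")
    I, J, N = y.shape
    if I < 2 or J < 1 or N < 2:
        raise ValidationError(f"need I>=2, N>=2 in a crossed design, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValidationError("pseudovalues contain non-finite entries")
    if method not in ("hillis", "satterthwaite"):
        raise ValidationError("method must be 'hillis' or 'satterthwaite'")

    grand = y.mean()
    # numerically-zero modality effect (identical pseudovalue blocks)
    zero_scale = 1e-18 * max(float(grand) ** 2, float(y.var()), 1e-30)
    m_t = y.mean(axis=(1, 2))
    m_r = y.mean(axis=(0, 2))
    m_c = y.mean(axis=(0, 1))
    m_tr = y.mean(axis=2)
    m_tc = y.mean(axis=1)
    m_rc = y.mean(axis=0)

    ss_t = J * N * np.sum((m_t - grand) ** 2)
    ss_r = I * N * np.sum((m_r - grand) ** 2)
    ss_c = I * J * np.sum((m_c - grand) ** 2)
    ss_tr = N * np.sum((m_tr - m_t[:, None] - m_r[None, :] + grand) ** 2)
    ss_tc = J * np.sum((m_tc - m_t[:, None] - m_c[None, :] + grand) ** 2)
    ss_rc = I * np.sum((m_rc - m_r[:, None] - m_c[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_trc = ss_total - ss_t - ss_r - ss_c - ss_tr - ss_tc - ss_rc

    def _ms(ss, df):
        return ss / df if df > 0 else 0.0

    ms = {
        "T": _ms(ss_t, I - 1),
        "R": _ms(ss_r, J - 1),
        "C": _ms(ss_c, N - 1),
        "TR": _ms(ss_tr, (I - 1) * (J - 1)),
        "TC": _ms(ss_tc, (I - 1) * (N - 1)),
        "RC": _ms(ss_rc, (J - 1) * (N - 1)),
        "TRC": _ms(max(ss_trc, 0.0), (I - 1) * (J - 1) * (N - 1)),
    }

    ddf1 = float(I - 1)
    if method == "hillis":
        denom = ms["TR"] + max(ms["TC"] - ms["TRC"], 0.0)
        if denom <= 0:
            f = 0.0 if ms["T"] == 0 else np.inf
            ddf2 = float((I - 1) * (J - 1))
        else:
            f = ms["T"] / denom
            ddf2 = (
                denom**2 * (I - 1) * (J - 1) / ms["TR"] ** 2
                if ms["TR"] > 0
                else float((I - 1) * (N - 1))
            )
    else:
        denom = ms["TR"] + ms["TC"] - ms["TRC"]
        if denom <= 0:
            f = 0.0 if ms["T"] == 0 else np.inf
            ddf2 = float((I - 1) * (J - 1))
        else:
            f = ms["T"] / denom
            var_terms = 0.0
            if ms["TR"] > 0:
                var_terms += ms["TR"] ** 2 / ((I - 1) * (J - 1))
            if ms["TC"] > 0:
                var_terms += ms["TC"] ** 2 / ((I - 1) * (N - 1))
            if ms["TRC"] > 0:
                var_terms += ms["TRC"] ** 2 / ((I - 1) * (J - 1) * (N - 1))
            ddf2 = denom**2 / var_terms if var_terms > 0 else float((I - 1) * (J - 1))

    if ms["T"] <= zero_scale:
        f, p = 0.0, 1.0
    elif not np.isfinite(f):
        p = 0.0
    else:
        p = float(stats.f.sf(f, ddf1, ddf2))

    fom_means = y.mean(axis=(1, 2))
    diff = float(fom_means[1] - fom_means[0]) if I == 2 else float("nan")
    return DbmResult(
        ms=ms,
        f_statistic=float(f),
        ddf1=ddf1,
        ddf2=float(ddf2),
        p_value=float(p),
        fom_means=fom_means,
        fom_difference=diff,
        method=method,
    )


def paired_t_llf(llf_without, llf_with) -> tuple[float, int, float]:
    """Two-sided paired t test on per-reader LLF values -> (t, df, p)."""
    a = np.asarray(llf_without, dtype=float)
    b = np.asarray(llf_with, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired t requires two equal-length 1D vectors")
    n = len(a)
    if n < 2:
        raise ValidationError("paired t requires n >= 2")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticError(
            "paired differences have zero variance; the t statistic is undefined "
            "(identical per-reader LLF vectors)"
        )
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


# asymptotic relative efficiency of the Wilcoxon signed-rank test vs the
# paired t, by parent distribution of the differences
ARE_BY_PARENT = {
    "normal": 3.0 / math.pi,  # 0.955
    "uniform": 1.0,
    "logistic": math.pi**2 / 9.0,
    "laplace": 1.5,
    "min": 0.864,  # minimum possible ARE
}


@dataclass
class PowerSpec:
    """Inputs of the reader sample-size routine."""

    dz: float  # effect size of the paired differences (mean / sd)
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2
    parent: str = "normal"

    def __post_init__(self):
        if self.dz <= 0:
            raise ValidationError("effect size dz must be > 0")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValidationError("tails must be 1 or 2")
        if self.parent not in ARE_BY_PARENT:
            raise ValidationError(
                f"parent must be one of {sorted(ARE_BY_PARENT)}"
            )


def paired_t_power(n: float, dz: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact noncentral-t power of the one-sample/paired t test at size n."""
    df = n - 1
    if df <= 0:
        return 0.0
    ncp = dz * math.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, ncp))


def wilcoxon_power(n: int, spec: PowerSpec) -> float:
    """A.R.E.-method power of the Wilcoxon signed-rank test at n pairs.

    The Wilcoxon test at n pairs is treated as a paired t test at the
    reduced effective sample size n' = ARE * n (noncentral t with df =
    n' - 1 and noncentrality dz * sqrt(n')), following the sample-size
    methodology of the G*Power A.R.E. approach.
    """
    n_eff = ARE_BY_PARENT[spec.parent] * n
    return paired_t_power(n_eff, spec.dz, spec.alpha, spec.tails)


def wilcoxon_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest number of pairs giving Wilcoxon power >= the target."""
    for n in range(2, n_max + 1):
        if wilcoxon_power(n, spec) >= spec.power:
            return n
    raise DegenerateStatisticError(
        f"no n <= {n_max} reaches power {spec.power} at dz={spec.dz}"
    )
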