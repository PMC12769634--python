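"""Synthetic reader-study generator.

Emulates an enriched hepatobiliary-phase reader study: 30 cases bearing
2-11 lesions each (median 6 per case), lesion diameters with median 7.9 mm
in [4.1, 74.5] mm, a 85:66:35 cyst/hemangioma/metastasis mixture, an AI
reader calibrated to LLF ~0.82 at 14 FPs/case, and human readers whose
second (AI-assisted) session applies an explicit automation-bias model:
accept AI true positives, adopt AI false positives, drop own unflagged
detections.

Size distribution
-----------------
The default sampler interpolates the reference size table directly: a
monotone (PCHIP) quantile function through the knots (4.1, 6, 7.9, 8, 10,
12, 74.5) mm at cumulative fractions (0, 35/186, 1/2, 95/186, 125/186,
137/186, 1), so the per-bracket lesion counts are matched in expectation by
construction.  A truncated log-normal parameterized by its post-truncation
median is available as an alternative.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, special, stats

from .errors import PlacementError, ValidationError
from .types import (
    AI_SOURCE,
    AI_STANDALONE,
    WITH_AI,
    WITHOUT_AI,
    GroundTruthLesion,
    Mark,
    MatchRule,
    StudyDesign,
)

# ---------------------------------------------------------------------------
# size distributions

#: reference size-table knots: cumulative fraction -> diameter (mm)
SIZE_TABLE_KNOTS = (
    (0.0, 4.1),
    (35 / 186, 6.0),
    (0.5, 7.9),
    (95 / 186, 8.0),
    (125 / 186, 10.0),
    (137 / 186, 12.0),
    (1.0, 74.5),
)


class QuantileKnotSizes:
    """Sample diameters from a monotone interpolation of a tabulated size CDF."""

    def __init__(self, knots=SIZE_TABLE_KNOTS):
        p = np.array([k[0] for k in knots])
        d = np.array([k[1] for k in knots])
        if np.any(np.diff(p) <= 0) or np.any(np.diff(d) <= 0):
            raise ValidationError("quantile knots must be strictly increasing")
        self.lo, self.hi = float(d[0]), float(d[-1])
        self._q = interpolate.PchipInterpolator(p, np.log(d))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self._q(rng.uniform(size=n)))


class TruncatedLogNormalSizes:
    """Log-normal truncated to [lo, hi], re-solved so the truncated median
    equals the target median."""

    def __init__(self, median: float = 7.9, lo: float = 4.1, hi: float = 74.5,
                 sigma: float = 0.7):
        if not (lo < median < hi) or sigma <= 0:
            raise ValidationError("need lo < median < hi and sigma > 0")
        self.lo, self.hi, self.sigma = lo, hi, sigma

        def trunc_median(mu):
            a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
            fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
            return math.exp(mu + sigma * stats.norm.ppf(fa + 0.5 * (fb - fa)))

        self.mu = optimize.brentq(
            lambda m: trunc_median(m) - median, math.log(lo / 4), math.log(hi)
        )
        self._a = (math.log(lo) - self.mu) / sigma
        self._b = (math.log(hi) - self.mu) / sigma

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = stats.truncnorm.rvs(self._a, self._b, size=n, random_state=rng)
        return np.exp(self.mu + self.sigma * z)


# ---------------------------------------------------------------------------
# population spec

#: nominal world-mm bounding box of a case (liver-scale region)
CASE_BOX = np.array([[0.0, 180.0], [0.0, 140.0], [0.0, 120.0]])

LESION_TYPES = ("cyst", "hemangioma", "metastasis")
#: 85 cysts : 66 hemangiomas : 35 metastases
DEFAULT_TYPE_MIXTURE = (85 / 186, 66 / 186, 35 / 186)


def _default_count_probs() -> dict[int, float]:
    # 3 + Binomial(7, 3/7): support [3, 10], mean 6, median 6
    probs = {}
    for k in range(8):
        probs[3 + k] = float(stats.binom.pmf(k, 7, 3 / 7))
    return probs


@dataclass
class LesionPopulationSpec:
    """Ground-truth population: case count, lesions/case, sizes, types."""

    n_cases: int = 30
    count_probs: dict[int, float] = field(default_factory=_default_count_probs)
    size_distribution: object = field(default_factory=QuantileKnotSizes)
    type_mixture: tuple[float, float, float] = DEFAULT_TYPE_MIXTURE
    min_separation: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValidationError("n_cases must be >= 0")
        if abs(sum(self.count_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("lesion-count probabilities must sum to 1")
        if any(k < 2 or k > 11 for k in self.count_probs):
            raise ValidationError("lesions-per-case support must lie in [2, 11]")
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ValidationError("type mixture must sum to 1")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")


def gen_ground_truth(
    spec: LesionPopulationSpec, rng: np.random.Generator | None = None
) -> list[GroundTruthLesion]:
    """Sample a full ground-truth table; deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    counts = np.array(sorted(spec.count_probs))
    probs = np.array([spec.count_probs[int(k)] for k in counts])
    lesions = []
    for c in range(spec.n_cases):
        case_id = f"case{c + 1:02d}"
        n = int(rng.choice(counts, p=probs))
        sizes = spec.size_distribution.sample(n, rng)
        types = rng.choice(LESION_TYPES, size=n, p=spec.type_mixture)
        centers = _place_centers(sizes, spec.min_separation, rng)
        for k in range(n):
            lesions.append(
                GroundTruthLesion(
                    case_id=case_id,
                    lesion_id=f"{case_id}_L{k + 1:02d}",
                    center=centers[k],
                    diameter=float(sizes[k]),
                    lesion_type=str(types[k]),
                )
            )
    return lesions


def _place_centers(
    sizes: np.ndarray,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    centers = []
    for r in sizes / 2.0:
        lo = CASE_BOX[:, 0] + np.minimum(r, np.diff(CASE_BOX, axis=1).ravel() / 2 - 1)
        hi = CASE_BOX[:, 1] - np.minimum(r, np.diff(CASE_BOX, axis=1).ravel() / 2 - 1)
        for _ in range(max_tries):
            p = rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) >= min_separation for q in centers):
                centers.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {len(sizes)} lesions with separation "
                f">= {min_separation} mm in the case volume"
            )
    return np.array(centers).reshape(-1, 3)


# ---------------------------------------------------------------------------
# observer profiles

@dataclass
class ObserverProfile:
    """Generative behaviour of one observer (human reader or the AI).

    Detection is a Bernoulli draw per lesion with probability given by a
    logistic curve in log-diameter; false positives are Poisson per case,
    placed beyond the matching threshold of every lesion.  The three
    consultation probabilities model automation bias in the AI-assisted
    session; ``session_noise`` is the probability that a finding's status is
    independently re-drawn at the second read, so the two sessions are
    exchangeable (same marginal distribution) but not identical.
    """

    sensitivity_slope: float = 3.06
    sensitivity_midpoint_mm: float = 5.57
    fp_rate: float = 1.0
    rating_tp: tuple[float, float] = (75.0, 15.0)
    rating_fp: tuple[float, float] = (40.0, 20.0)
    constant_rating: float | None = None
    accept_ai_tp: float = 0.0
    accept_ai_fp: float = 0.0
    drop_own_tp_when_unflagged: float = 0.0
    session_noise: float = 0.02
    mark_jitter_mm: float = 0.5

    def __post_init__(self):
        for name in (
            "accept_ai_tp",
            "accept_ai_fp",
            "drop_own_tp_when_unflagged",
            "session_noise",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.fp_rate < 0:
            raise ValidationError("fp_rate must be >= 0")
        if self.sensitivity_slope < 0:
            raise ValidationError(
                "sensitivity_slope must be >= 0 (detection probability must be "
                "non-decreasing in diameter)"
            )

    def sensitivity(self, diameter) -> np.ndarray:
        """Detection probability for a lesion of the given diameter (mm)."""
        d = np.asarray(diameter, dtype=float)
        return special.expit(
            self.sensitivity_slope * (np.log(d) - math.log(self.sensitivity_midpoint_mm))
        )

    def sample_rating(self, kind: str, size: int, rng: np.random.Generator):
        if self.constant_rating is not None:
            return np.full(size, float(self.constant_rating))
        mean, sd = self.rating_tp if kind == "tp" else self.rating_fp
        return np.clip(rng.normal(mean, sd, size=size), 0.0, 100.0)


def default_ai_profile() -> ObserverProfile:
    """AI standalone profile calibrated to the Table-2-style bracket LLFs
    (~0.49 below 6 mm rising to ~0.82 overall) at 14 FPs per case."""
    return ObserverProfile(
        sensitivity_slope=4.66,
        sensitivity_midpoint_mm=5.08,
        fp_rate=14.0,
        constant_rating=100.0,
        session_noise=0.0,
        mark_jitter_mm=0.5,
    )


def default_reader_profile(bias: str = "low") -> ObserverProfile:
    """Human reader calibrated to ~0.74 unassisted LLF; 'low' or 'high'
    automation bias."""
    if bias == "low":
        return ObserverProfile(accept_ai_tp=0.5, accept_ai_fp=0.005,
                               drop_own_tp_when_unflagged=0.0)
    if bias == "high":
        return ObserverProfile(accept_ai_tp=0.7, accept_ai_fp=0.06,
                               drop_own_tp_when_unflagged=0.15)
    raise ValidationError("bias must be 'low' or 'high'")


def default_reader_profiles(n_low: int = 10, n_high: int = 4) -> dict[str, ObserverProfile]:
    """14-reader panel: 10 low-bias, 4 high-bias (high-bias readers first,
    mirroring the numbering convention where readers 1-4 are the
    less-experienced, high-NCR readers)."""
    profiles = {}
    for k in range(n_high):
        profiles[f"reader{k + 1:02d}"] = default_reader_profile("high")
    for k in range(n_low):
        profiles[f"reader{n_high + k + 1:02d}"] = default_reader_profile("low")
    return profiles


# ---------------------------------------------------------------------------
# mark generation

def _capped_jitter(rng, sd, cap):
    v = rng.normal(0.0, sd, size=3)
    n = np.linalg.norm(v)
    if n > cap:
        v *= cap / n
    return v


def _tp_mark_position(center, threshold, profile, rng):
    # jitter capped inside the matching threshold, so a detection always
    # resolves to a TP of its own lesion
    cap = min(0.95 * threshold, 2.9)
    return center + _capped_jitter(rng, profile.mark_jitter_mm, cap)


def _fp_positions(n, lesions, rule, rng, max_tries=2000):
    """Uniform positions in the case box, beyond every lesion's threshold."""
    centers = np.array([g.center for g in lesions]).reshape(-1, 3)
    thr = rule.threshold(np.array([g.diameter for g in lesions]))
    out = []
    for _ in range(n):
        for _ in range(max_tries):
            p = rng.uniform(CASE_BOX[:, 0], CASE_BOX[:, 1])
            if len(centers) == 0 or np.all(
                np.linalg.norm(centers - p, axis=1) > thr + 1e-6
            ):
                out.append(p)
                break
        else:
            raise PlacementError("could not place an FP mark away from all lesions")
    return out


def gen_ai_marks(
    ground_truth: list[GroundTruthLesion],
    profile: ObserverProfile | None = None,
    rng: np.random.Generator | int | None = None,
    rule: MatchRule | None = None,
) -> list[Mark]:
    """Standalone AI marks: per-lesion Bernoulli detections plus Poisson FPs."""
    profile = profile or default_ai_profile()
    rule = rule or MatchRule()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    marks = []
    by_case: dict[str, list[GroundTruthLesion]] = {}
    for g in ground_truth:
        by_case.setdefault(g.case_id, []).append(g)
    for case_id in sorted(by_case):
        lesions = by_case[case_id]
        for g in lesions:
            if rng.uniform() < profile.sensitivity(g.diameter):
                pos = _tp_mark_position(
                    g.center, float(rule.threshold(g.diameter)), profile, rng
                )
                rating = float(profile.sample_rating("tp", 1, rng)[0])
                marks.append(Mark(case_id, AI_SOURCE, AI_STANDALONE, pos, rating))
        n_fp = int(rng.poisson(profile.fp_rate))
        for p in _fp_positions(n_fp, lesions, rule, rng):
            rating = float(profile.sample_rating("fp", 1, rng)[0])
            marks.append(Mark(case_id, AI_SOURCE, AI_STANDALONE, p, rating))
    return marks


def _ai_flags(ground_truth, ai_marks, rule):
    """Which lesions the AI localized, and the AI's FP marks."""
    from .matching import match_marks  # local import to avoid a cycle

    if not ai_marks:
        return set(), []
    matched = match_marks(ai_marks, ground_truth, rule)
    flagged = {
        (r.case_id, r.lesion_id)
        for r in matched.lesions.itertuples()
        if r.localized
    }
    fp_marks = [
        m
        for m, lab in zip(ai_marks, matched.marks.label)
        if lab == "FP"
    ]
    return flagged, fp_marks


def gen_reader_marks(
    ground_truth: list[GroundTruthLesion],
    ai_marks: list[Mark],
    profile: ObserverProfile,
    source_id: str = "reader01",
    rng: np.random.Generator | int | None = None,
    rule: MatchRule | None = None,
) -> list[Mark]:
    """Marks for both paired sessions of one reader.

    The unassisted session is drawn from the profile's sensitivity/FP model.
    The assisted session starts from the same realization, independently
    re-draws each finding with probability ``session_noise``, then applies
    the consultation model: gains AI-flagged lesions the reader missed with
    ``accept_ai_tp``, adopts AI false-positive marks with ``accept_ai_fp``,
    and drops own detections unflagged by the AI with
    ``drop_own_tp_when_unflagged``.
    """
    rule = rule or MatchRule()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    flagged, ai_fp_marks = _ai_flags(ground_truth, ai_marks, rule)
    ai_tp_pos = {}
    if ai_marks:
        from .matching import match_marks

        m = match_marks(ai_marks, ground_truth, rule)
        for row in m.marks.itertuples():
            if row.label == "TP":
                key = (row.case_id, row.lesion_id)
                if key not in ai_tp_pos:
                    ai_tp_pos[key] = np.array([row.x_mm, row.y_mm, row.z_mm])

    by_case: dict[str, list[GroundTruthLesion]] = {}
    for g in ground_truth:
        by_case.setdefault(g.case_id, []).append(g)
    ai_fp_by_case: dict[str, list[Mark]] = {}
    for m in ai_fp_marks:
        ai_fp_by_case.setdefault(m.case_id, []).append(m)

    marks: list[Mark] = []
    for case_id in sorted(by_case):
        lesions = by_case[case_id]
        for g in lesions:
            key = (g.case_id, g.lesion_id)
            thr = float(rule.threshold(g.diameter))
            p_det = float(profile.sensitivity(g.diameter))
            detected_without = rng.uniform() < p_det
            pos_without = None
            if detected_without:
                pos_without = _tp_mark_position(g.center, thr, profile, rng)
                marks.append(
                    Mark(case_id, source_id, WITHOUT_AI, pos_without,
                         float(profile.sample_rating("tp", 1, rng)[0]))
                )
            # assisted session
            base = detected_without
            pos_with = pos_without if detected_without else None
            if rng.uniform() < profile.session_noise:
                base = rng.uniform() < p_det
                if base:
                    pos_with = _tp_mark_position(g.center, thr, profile, rng)
            if base and key not in flagged:
                if rng.uniform() < profile.drop_own_tp_when_unflagged:
                    base = False
            if not base and key in flagged:
                if rng.uniform() < profile.accept_ai_tp:
                    base = True
                    pos_with = ai_tp_pos.get(key, g.center)
            if base:
                marks.append(
                    Mark(case_id, source_id, WITH_AI, np.asarray(pos_with),
                         float(profile.sample_rating("tp", 1, rng)[0]))
                )
        # own false positives, unassisted
        n_fp = int(rng.poisson(profile.fp_rate))
        own_fps = _fp_positions(n_fp, lesions, rule, rng)
        for p in own_fps:
            marks.append(
                Mark(case_id, source_id, WITHOUT_AI, p,
                     float(profile.sample_rating("fp", 1, rng)[0]))
            )
        # assisted session: thin own FPs by the noise, add fresh noise FPs,
        # adopt AI FPs
        for p in own_fps:
            if rng.uniform() >= profile.session_noise:
                marks.append(
                    Mark(case_id, source_id, WITH_AI, p,
                         float(profile.sample_rating("fp", 1, rng)[0]))
                )
        n_new = int(rng.poisson(profile.session_noise * profile.fp_rate))
        for p in _fp_positions(n_new, lesions, rule, rng):
            marks.append(
                Mark(case_id, source_id, WITH_AI, p,
                     float(profile.sample_rating("fp", 1, rng)[0]))
            )
        for am in ai_fp_by_case.get(case_id, []):
            if rng.uniform() < profile.accept_ai_fp:
                marks.append(
                    Mark(case_id, source_id, WITH_AI, am.position,
                         float(profile.sample_rating("fp", 1, rng)[0]))
                )
    return marks


# ---------------------------------------------------------------------------
# full study

@dataclass
class StudyBundle:
    design: StudyDesign
    ground_truth: list[GroundTruthLesion]
    marks: list[Mark]


def simulate_study(
    population: LesionPopulationSpec | None = None,
    ai_profile: ObserverProfile | None = None,
    reader_profiles: dict[str, ObserverProfile] | None = None,
    seed: int = 0,
    rule: MatchRule | None = None,
) -> StudyBundle:
    """Ground truth + AI marks + all readers' paired-session marks."""
    population = population or LesionPopulationSpec()
    ai_profile = ai_profile or default_ai_profile()
    if reader_profiles is None:
        reader_profiles = default_reader_profiles()
    rule = rule or MatchRule()
    root = np.random.SeedSequence(seed)
    gt_seed, ai_seed, *reader_seeds = root.spawn(2 + len(reader_profiles))
    gts = gen_ground_truth(population, np.random.default_rng(gt_seed))
    ai_marks = gen_ai_marks(gts, ai_profile, np.random.default_rng(ai_seed), rule)
    marks = list(ai_marks)
    for (reader, profile), ss in zip(sorted(reader_profiles.items()), reader_seeds):
        marks.extend(
            gen_reader_marks(
                gts, ai_marks, profile, source_id=reader,
                rng=np.random.default_rng(ss), rule=rule,
            )
        )
    design = StudyDesign(
        reader_ids=sorted(reader_profiles),
        modalities=[WITHOUT_AI, WITH_AI],
        case_ids=sorted({g.case_id for g in gts}),
    )
    return StudyBundle(design=design, ground_truth=gts, marks=marks)


# ---------------------------------------------------------------------------
# fast rating-table simulation (no spatial placement)

def simulate_rating_table_null(
    ground_truth: list[GroundTruthLesion],
    profile: ObserverProfile,
    n_readers: int,
    rng: np.random.Generator | int | None = None,
):
    """Two modalities drawn independently from ONE observer profile.

    Bypasses spatial mark placement: a detection is a TP by construction
    (jitter is capped inside the matching threshold and FPs are planted
    beyond it), so the rating table can be sampled directly.  Used for
    null-calibration studies of the DBM test.
    """
    from .observer import RatingTable

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    case_ids = sorted({g.case_id for g in ground_truth})
    case_pos = {c: k for k, c in enumerate(case_ids)}
    diam = np.array([g.diameter for g in ground_truth])
    lesion_case_idx = np.array([case_pos[g.case_id] for g in ground_truth])
    sens = profile.sensitivity(diam)
    I, J, L, C = 2, n_readers, len(ground_truth), len(case_ids)
    ll = np.full((I, J, L), -np.inf)
    nl = np.full((I, J, C), -np.inf)
    for i in range(I):
        for j in range(J):
            det = rng.uniform(size=L) < sens
            ll[i, j, det] = profile.sample_rating("tp", int(det.sum()), rng)
            n_fp = rng.poisson(profile.fp_rate, size=C)
            for c in range(C):
                if n_fp[c] > 0:
                    nl[i, j, c] = profile.sample_rating("fp", int(n_fp[c]), rng).max()
    return RatingTable(
        modalities=[WITHOUT_AI, WITH_AI],
        readers=[f"reader{j + 1:02d}" for j in range(J)],
        case_ids=case_ids,
        lesion_ids=[g.lesion_id for g in ground_truth],
        lesion_case_idx=lesion_case_idx,
        ll=ll,
        nl=nl,
        lesion_diameters=diam,
    )
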