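"""JAFROC1 FOM, jackknife pseudovalues, DBM ANOVA, paired t and power."""

import math

import numpy as np
import pytest
from scipy import stats

import hepafroc as hf
from hepafroc.errors import DegenerateStatisticError, ValidationError
from hepafroc.observer import (
    ARE_BY_PARENT,
    PowerSpec,
    RatingTable,
    jackknife_pseudovalues,
    paired_t_power,
)

NEG = -np.inf


def _table(ll, nl, lesion_case_idx):
    """One-reader, one-modality rating table from raw vectors."""
    ll = np.asarray(ll, float)[None, None, :]
    nl = np.asarray(nl, float)[None, None, :]
    return RatingTable(
        modalities=["without_AI"],
        readers=["r1"],
        case_ids=[f"c{k}" for k in range(nl.shape[2])],
        lesion_ids=[f"L{k}" for k in range(ll.shape[2])],
        lesion_case_idx=np.asarray(lesion_case_idx, int),
        ll=ll,
        nl=nl,
    )


def brute_force_fom(ll, nl, neg_inf_tie=0.0):
    """Independent double sum over every (case, lesion) pair."""
    total = 0.0
    for a in nl:
        for b in ll:
            if b > a:
                total += 1.0
            elif b == a and math.isfinite(a):
                total += 0.5
            elif a == NEG and b == NEG:
                total += neg_inf_tie
    return total / (len(nl) * len(ll))


def test_fom_worked_example_quarter():
    # 2 cases, 1 lesion each; LL = (60, -inf); NL = (50, 70)
    t = _table([60.0, NEG], [50.0, 70.0], [0, 1])
    assert hf.jafroc1_fom(t, "r1", "without_AI") == pytest.approx(0.25)


def test_fom_perfect_reader_is_one():
    t = _table([100.0] * 5, [NEG, NEG], [0, 0, 0, 1, 1])
    assert hf.jafroc1_fom(t, "r1", "without_AI") == 1.0


def test_fom_silent_reader_scores_zero():
    t = _table([NEG, NEG], [NEG, NEG], [0, 1])
    assert hf.jafroc1_fom(t, "r1", "without_AI") == 0.0
    # the optional tie convention credits silence with 0.5
    assert hf.jafroc1_fom(t, "r1", "without_AI", neg_inf_tie=0.5) == 0.5


def test_fom_fp_above_all_lesions_decreases_theta():
    base = _table([80.0, 70.0], [NEG, 40.0], [0, 1])
    worse = _table([80.0, 70.0], [95.0, 40.0], [0, 1])
    assert hf.jafroc1_fom(worse, "r1", "without_AI") < hf.jafroc1_fom(
        base, "r1", "without_AI"
    )


def test_fom_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    ll = np.where(rng.uniform(size=8) < 0.7, rng.uniform(0, 100, 8), NEG)
    nl = np.where(rng.uniform(size=4) < 0.6, rng.uniform(0, 100, 4), NEG)
    idx = rng.integers(0, 4, size=8)
    t1 = _table(ll, nl, idx)
    f = lambda x: np.where(np.isfinite(x), 100 * (x / 100) ** 3, x)  # strictly increasing
    t2 = _table(f(ll), f(nl), idx)
    assert hf.jafroc1_fom(t2, "r1", "without_AI") == pytest.approx(
        hf.jafroc1_fom(t1, "r1", "without_AI"), abs=1e-12
    )


def test_fom_matches_brute_force_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n_c = rng.integers(2, 6)
        n_l = rng.integers(1, 9)
        ll = np.where(rng.uniform(size=n_l) < 0.7,
                      rng.integers(0, 101, n_l).astype(float), NEG)
        nl = np.where(rng.uniform(size=n_c) < 0.6,
                      rng.integers(0, 101, n_c).astype(float), NEG)
        idx = rng.integers(0, n_c, size=n_l)
        t = _table(ll, nl, idx)
        assert hf.jafroc1_fom(t, "r1", "without_AI") == pytest.approx(
            brute_force_fom(ll, nl), abs=1e-12
        )


def test_build_rating_table_group_max(full_matched, full_bundle):
    table = hf.build_rating_table(
        full_matched, readers=full_bundle.design.reader_ids,
        modalities=[hf.WITHOUT_AI, hf.WITH_AI],
    )
    reader = full_bundle.design.reader_ids[3]
    i, j = table.index(reader, hf.WITH_AI)
    mm = full_matched.marks
    mine = mm[(mm.source_id == reader) & (mm.modality == hf.WITH_AI)]
    # NL: brute-force per-case max over FP ratings
    for c, case in enumerate(table.case_ids):
        fps = mine[(mine.case_id == case) & (mine.label == "FP")].rating
        expected = fps.max() if len(fps) else NEG
        assert table.nl[i, j, c] == pytest.approx(expected)
    # LL: brute-force per-lesion max over TP ratings
    for l, lid in enumerate(table.lesion_ids):
        tps = mine[(mine.lesion_id == lid) & (mine.label == "TP")].rating
        expected = tps.max() if len(tps) else NEG
        assert table.ll[i, j, l] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# jackknife


def test_pseudovalues_identical_cases_are_flat():
    # 3 identical single-lesion cases -> every leave-one-out theta equals theta
    t = _table([70.0, 70.0, 70.0], [50.0, 50.0, 50.0], [0, 1, 2])
    pv = jackknife_pseudovalues(t, "r1", "without_AI", center=False)
    theta = hf.jafroc1_fom(t, "r1", "without_AI")
    assert np.allclose(pv, theta)


def test_pseudovalues_match_hand_leave_one_out():
    ll = [60.0, NEG, 80.0]
    nl = [50.0, 70.0, NEG]
    idx = [0, 1, 2]
    t = _table(ll, nl, idx)
    theta = brute_force_fom(np.array(ll), np.array(nl))
    pv = jackknife_pseudovalues(t, "r1", "without_AI", center=False)
    for c in range(3):
        keep_l = [k for k in range(3) if idx[k] != c]
        keep_c = [k for k in range(3) if k != c]
        loo = brute_force_fom(np.array(ll)[keep_l], np.array(nl)[keep_c])
        assert pv[c] == pytest.approx(3 * theta - 2 * loo, abs=1e-12)


def test_centered_pseudovalues_mean_equals_theta(full_matched, full_bundle):
    table = hf.build_rating_table(
        full_matched, readers=full_bundle.design.reader_ids[:2],
        modalities=[hf.WITHOUT_AI, hf.WITH_AI],
    )
    r = full_bundle.design.reader_ids[0]
    pv = jackknife_pseudovalues(table, r, hf.WITH_AI)
    assert pv.mean() == pytest.approx(
        hf.jafroc1_fom(table, r, hf.WITH_AI), abs=1e-12
    )


def test_jackknife_requires_two_cases():
    t = _table([60.0], [50.0], [0])
    with pytest.raises(DegenerateStatisticError):
        jackknife_pseudovalues(t, "r1", "without_AI")


# ---------------------------------------------------------------------------
# DBM


def test_dbm_identical_modalities_null():
    rng = np.random.default_rng(1)
    block = rng.normal(0.7, 0.1, size=(1, 4, 10))
    y = np.concatenate([block, block], axis=0)
    res = hf.dbm_significance(y)
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0
    assert res.ms["T"] == pytest.approx(0.0, abs=1e-15)


def test_dbm_mean_squares_equal_explicit_sums():
    rng = np.random.default_rng(2)
    y = rng.normal(size=(2, 2, 4))
    res = hf.dbm_significance(y)
    I, J, N = y.shape
    grand = y.mean()
    # explicit sum-of-squares decomposition, no shortcuts
    ss = {"T": 0.0, "R": 0.0, "C": 0.0, "TR": 0.0, "TC": 0.0, "RC": 0.0, "TRC": 0.0}
    for i in range(I):
        ss["T"] += J * N * (y[i].mean() - grand) ** 2
    for j in range(J):
        ss["R"] += I * N * (y[:, j].mean() - grand) ** 2
    for c in range(N):
        ss["C"] += I * J * (y[:, :, c].mean() - grand) ** 2
    for i in range(I):
        for j in range(J):
            ss["TR"] += N * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
    for i in range(I):
        for c in range(N):
            ss["TC"] += J * (y[i, :, c].mean() - y[i].mean() - y[:, :, c].mean() + grand) ** 2
    for j in range(J):
        for c in range(N):
            ss["RC"] += I * (y[:, j, c].mean() - y[:, j].mean() - y[:, :, c].mean() + grand) ** 2
    for i in range(I):
        for j in range(J):
            for c in range(N):
                ss["TRC"] += (
                    y[i, j, c] - y[i, j].mean() - y[i, :, c].mean() - y[:, j, c].mean()
                    + y[i].mean() + y[:, j].mean() + y[:, :, c].mean() - grand
                ) ** 2
    df = {"T": I - 1, "R": J - 1, "C": N - 1, "TR": (I - 1) * (J - 1),
          "TC": (I - 1) * (N - 1), "RC": (J - 1) * (N - 1),
          "TRC": (I - 1) * (J - 1) * (N - 1)}
    for key in ss:
        assert res.ms[key] == pytest.approx(ss[key] / df[key], abs=1e-10), key


def test_dbm_single_reader_reduces_to_paired_t():
    rng = np.random.default_rng(3)
    y = rng.normal(size=(2, 1, 12))
    y[1] += 0.05
    res = hf.dbm_significance(y)
    t, p = stats.ttest_rel(y[1, 0], y[0, 0])
    assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
    assert res.ddf2 == pytest.approx(11)
    assert res.p_value == pytest.approx(p, rel=1e-9)


def test_dbm_rejects_bad_shapes():
    with pytest.raises(ValidationError):
        hf.dbm_significance(np.zeros((1, 3, 5)))
    with pytest.raises(ValidationError):
        hf.dbm_significance(np.zeros((2, 3)))


def test_dbm_detects_strong_modality_effect():
    rng = np.random.default_rng(4)
    y = rng.normal(0.7, 0.05, size=(2, 8, 30))
    y[1] += 0.15
    res = hf.dbm_significance(y)
    assert res.p_value < 0.01
    assert res.fom_difference == pytest.approx(0.15, abs=0.05)
    sat = hf.dbm_significance(y, method="satterthwaite")
    assert sat.p_value < 0.01


# ---------------------------------------------------------------------------
# paired t and power


def test_paired_t_matches_scipy():
    a = [0.70, 0.74, 0.68]
    b = [0.78, 0.80, 0.75]
    t, df, p = hf.paired_t_llf(a, b)
    t_ref, p_ref = stats.ttest_rel(b, a)
    assert t == pytest.approx(t_ref)
    assert df == 2
    assert p == pytest.approx(p_ref)


def test_paired_t_identical_vectors_degenerate():
    with pytest.raises(DegenerateStatisticError):
        hf.paired_t_llf([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])


def test_paired_t_power_grows_with_n():
    rng = np.random.default_rng(5)
    reject_small, reject_big = 0, 0
    for _ in range(200):
        d_small = rng.normal(0.08, 0.1, size=5)
        d_big = rng.normal(0.08, 0.1, size=25)
        _, _, p_s = hf.paired_t_llf(np.zeros(5), d_small)
        _, _, p_b = hf.paired_t_llf(np.zeros(25), d_big)
        reject_small += p_s < 0.05
        reject_big += p_b < 0.05
    assert reject_big > reject_small


def test_reader_sample_size_reproduces_nine():
    n = hf.wilcoxon_sample_size(PowerSpec(dz=1.15, alpha=0.05, power=0.80,
                                          tails=2, parent="normal"))
    assert n == 9


def test_sample_size_monotone_in_effect():
    n_big = hf.wilcoxon_sample_size(PowerSpec(dz=2.30))
    assert n_big < 9


def test_sample_size_matches_independent_power_iteration():
    """Oracle: re-derive power from scipy's noncentral t at the ARE-shrunk
    effective sample size, iterate n from 2 upward."""
    spec = PowerSpec(dz=0.5)
    are = ARE_BY_PARENT["normal"]
    n = 2
    while True:
        neff = are * n
        tc = stats.t.ppf(0.975, neff - 1)
        pw = 1 - stats.nct.cdf(tc, neff - 1, 0.5 * math.sqrt(neff)) + stats.nct.cdf(
            -tc, neff - 1, 0.5 * math.sqrt(neff)
        )
        if pw >= 0.80:
            break
        n += 1
    assert hf.wilcoxon_sample_size(spec) == n


def test_power_spec_validation():
    with pytest.raises(ValidationError):
        PowerSpec(dz=-1.0)
    with pytest.raises(ValidationError):
        PowerSpec(dz=1.0, parent="cauchy")


def test_one_tailed_power_exceeds_two_tailed():
    assert paired_t_power(10, 0.8, tails=1) > paired_t_power(10, 0.8, tails=2)
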