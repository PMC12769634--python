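"""Multiscale minIP detector: segmentation, sampling, projection, scoring, NMS."""

import numpy as np
import pytest
from scipy import stats

import hepafroc as hf
from hepafroc.detector import (
    Candidate,
    GeometricScorerConfig,
    detect,
    extract_patch,
    merge_candidates,
    minip_projections,
    sample_patches,
    score_patch,
    segment_liver_simple,
)
from hepafroc.errors import SegmentationError, ValidationError
from hepafroc.phantom import PhantomSpec, gen_phantom_volume, place_lesions_in_liver

SPACING = (1.5, 1.5, 3.0)


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="module")
def phantom():
    spec = PhantomSpec(seed=8)
    gts = place_lesions_in_liver("c1", [8, 10, 14], spec, rng=8)
    vol, _ = gen_phantom_volume(gts, spec, rng=8)
    return vol, gts, spec


def test_segmentation_recovers_liver_ellipsoid(phantom):
    vol, _, _ = phantom
    mask = segment_liver_simple(vol)
    assert _dice(mask, vol.mask) >= 0.90


def test_segmentation_robust_to_moderate_noise(phantom):
    vol, gts, spec = phantom
    noisy = PhantomSpec(seed=8, noise_sd=15.0)  # less than half the 80-unit contrast
    nvol, _ = gen_phantom_volume(gts, noisy, rng=8)
    mask = segment_liver_simple(nvol)
    assert _dice(mask, nvol.mask) >= 0.85


def test_all_background_volume_rejected():
    rng = np.random.default_rng(0)
    flat = hf.Volume(rng.normal(20, 2, size=(40, 40, 20)), SPACING)
    with pytest.raises(SegmentationError):
        segment_liver_simple(flat)
    const = hf.Volume(np.zeros((10, 10, 10)), SPACING)
    with pytest.raises(SegmentationError):
        segment_liver_simple(const)


# ---------------------------------------------------------------------------
# patch sampling


def test_empty_mask_no_patches():
    vol = hf.Volume(np.zeros((20, 20, 10)), SPACING)
    assert sample_patches(vol, np.zeros((20, 20, 10), bool)) == []


def test_single_voxel_mask_one_patch_per_scale():
    vol = hf.Volume(np.zeros((30, 30, 16)), SPACING)
    mask = np.zeros((30, 30, 16), bool)
    mask[13, 17, 9] = True
    patches = sample_patches(vol, mask)
    assert len(patches) == 3
    assert sorted({p.scale_mm for p in patches}) == [6.0, 12.0, 24.0]
    assert all(p.center_voxel == (13, 17, 9) for p in patches)


def test_scale_below_voxel_size_rejected():
    vol = hf.Volume(np.zeros((20, 20, 10)), SPACING)
    mask = np.ones((20, 20, 10), bool)
    with pytest.raises(ValidationError, match="smaller than one voxel"):
        sample_patches(vol, mask, scales_mm=[2.0])


def test_patch_count_matches_bin_enumeration():
    """Oracle: one patch per occupied stride bin, per scale."""
    rng = np.random.default_rng(1)
    vol = hf.Volume(np.zeros((40, 40, 20)), SPACING)
    mask = rng.uniform(size=(40, 40, 20)) < 0.03
    patches = sample_patches(vol, mask, scales_mm=[6.0, 12.0])
    for scale in (6.0, 12.0):
        step = np.maximum(1, np.round(0.5 * scale / np.array(SPACING))).astype(int)
        bins = {tuple(idx // step) for idx in np.argwhere(mask)}
        got = sum(p.scale_mm == scale for p in patches)
        assert got == len(bins)


# ---------------------------------------------------------------------------
# minIP


def test_minip_constant_patch():
    t = minip_projections(np.full((5, 5, 3), 7.0), SPACING)
    for img in t.images:
        assert np.all(img == 7.0)


def test_minip_single_dark_voxel_appears_in_all_planes():
    patch = np.full((6, 5, 4), 10.0)
    patch[2, 3, 1] = -5.0
    t = minip_projections(patch, SPACING)
    assert t.images[0][3, 1] == -5.0   # collapse x -> (y, z)
    assert t.images[1][2, 1] == -5.0   # collapse y -> (x, z)
    assert t.images[2][2, 3] == -5.0   # collapse z -> (x, y)


def test_minip_matches_brute_force_minima():
    rng = np.random.default_rng(2)
    patch = rng.normal(size=(5, 5, 5))
    t = minip_projections(patch, (1, 1, 1))
    for k in range(3):
        brute = np.apply_along_axis(min, k, patch)
        assert np.allclose(t.images[k], brute)


def test_minip_idempotent_on_extruded_patch():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(7, 7))
    extruded = np.repeat(base[:, :, None], 5, axis=2)
    t = minip_projections(extruded, (1, 1, 1))
    assert np.allclose(t.images[2], base)
    re_extruded = np.repeat(t.images[2][:, :, None], 5, axis=2)
    t2 = minip_projections(re_extruded, (1, 1, 1))
    assert np.allclose(t2.images[2], t.images[2])


# ---------------------------------------------------------------------------
# scoring


def _render_sphere_patch(rng, shape=(17, 17, 9), r=5.0, noise=2.0):
    sp = np.array(SPACING)
    ctr = (np.array(shape) - 1) / 2 * sp
    X, Y, Z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)],
                          indexing="ij")
    off = rng.uniform(-2, 2, 3)
    d2 = (X - ctr[0] - off[0]) ** 2 + (Y - ctr[1] - off[1]) ** 2 + (Z - ctr[2] - off[2]) ** 2
    data = np.full(shape, 100.0)
    data[d2 <= r**2] = 40.0
    return data + rng.normal(0, noise, shape)


def _render_tube_patch(rng, shape=(17, 17, 9), r=3.0, noise=2.0):
    sp = np.array(SPACING)
    ctr = (np.array(shape) - 1) / 2 * sp
    X, Y, Z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)],
                          indexing="ij")
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    p0, v = ctr - u * 50, u * 100
    t = ((X - p0[0]) * v[0] + (Y - p0[1]) * v[1] + (Z - p0[2]) * v[2]) / (v @ v)
    d2 = ((X - p0[0] - t * v[0]) ** 2 + (Y - p0[1] - t * v[1]) ** 2
          + (Z - p0[2] - t * v[2]) ** 2)
    data = np.full(shape, 100.0)
    data[d2 <= r**2] = 40.0
    return data + rng.normal(0, noise, shape)


def test_flat_patch_scores_zero():
    rng = np.random.default_rng(4)
    flat = np.full((9, 9, 5), 100.0) + rng.normal(0, 2.0, (9, 9, 5))
    assert score_patch(minip_projections(flat, SPACING)) == 0.0


def test_score_invariant_under_axis_permutation():
    rng = np.random.default_rng(5)
    patch = _render_sphere_patch(rng)
    t = minip_projections(patch, SPACING)
    perm = type(t)(images=(t.images[2], t.images[0], t.images[1]),
                   pixel_spacings=(t.pixel_spacings[2], t.pixel_spacings[0],
                                   t.pixel_spacings[1]),
                   scale_mm=t.scale_mm, center_mm=t.center_mm)
    assert score_patch(perm) == pytest.approx(score_patch(t))


def test_spheres_outscore_tubes():
    rng = np.random.default_rng(6)
    wins = 0
    sphere_scores, tube_scores = [], []
    for _ in range(60):
        s = score_patch(minip_projections(
            _render_sphere_patch(rng, r=rng.uniform(4, 7)), SPACING))
        t = score_patch(minip_projections(
            _render_tube_patch(rng, r=rng.uniform(2, 4)), SPACING))
        sphere_scores.append(s)
        tube_scores.append(t)
        wins += s > t
    assert wins >= 57  # >= 95% correct ordering
    # lesion-like patches stochastically dominate vessel-like ones
    p = stats.mannwhitneyu(sphere_scores, tube_scores, alternative="greater").pvalue
    assert p < 0.01


# ---------------------------------------------------------------------------
# merging


def test_overlapping_equal_candidates_one_survives():
    a = Candidate((10.0, 10.0, 10.0), 12.0, 0.9)
    b = Candidate((12.0, 10.0, 10.0), 12.0, 0.9)
    kept = merge_candidates([a, b], score_cutoff=0.5)
    assert len(kept) == 1


def test_disjoint_candidates_all_survive():
    cands = [Candidate((30.0 * k, 0.0, 0.0), 12.0, 0.8) for k in range(5)]
    assert len(merge_candidates(cands, score_cutoff=0.5)) == 5


def test_merge_matches_quadratic_suppression_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        cands = [
            Candidate(tuple(rng.uniform(0, 60, 3)),
                      float(rng.choice([6.0, 12.0, 24.0])),
                      float(rng.uniform(0.5, 1.0)))
            for _ in range(rng.integers(2, 30))
        ]
        kept = merge_candidates(cands, score_cutoff=0.5, nms_radius_frac=0.5)
        # independent O(n^2) pass with the same ordering rule
        pool = sorted(cands, key=lambda c: (-c.score, c.scale_mm, c.center_mm))
        oracle = []
        for c in pool:
            ok = True
            for k in oracle:
                r = 0.5 * max(c.scale_mm, k.scale_mm)
                if np.linalg.norm(np.subtract(c.center_mm, k.center_mm)) <= r:
                    ok = False
                    break
            if ok:
                oracle.append(c)
        assert kept == oracle


# ---------------------------------------------------------------------------
# end-to-end


def test_empty_liver_mask_no_candidates():
    vol = hf.Volume(np.full((30, 30, 16), 100.0), SPACING)
    cands = detect(vol, mask=np.zeros((30, 30, 16), bool))
    assert cands == []


def test_detect_translation_equivariant():
    spec = PhantomSpec(n_vessels=0, noise_sd=0.0, seed=0)
    gts = place_lesions_in_liver("c1", [12.0], spec, rng=10, min_separation=0)
    vol, _ = gen_phantom_volume(gts, spec, rng=10)
    shift_vox = np.array([3, -2, 1])
    shifted = np.roll(vol.data, shift_vox, axis=(0, 1, 2))
    vol2 = hf.Volume(shifted, SPACING,
                     mask=np.roll(vol.mask, shift_vox, axis=(0, 1, 2)))
    c1 = detect(vol, score_cutoff=0.8, mask=vol.mask)
    c2 = detect(vol2, score_cutoff=0.8, mask=vol2.mask)
    assert len(c1) >= 1 and len(c1) == len(c2)
    shift_mm = shift_vox * np.array(SPACING)
    best1 = max(c1, key=lambda c: c.score)
    best2 = max(c2, key=lambda c: c.score)
    # within one stride of the exact shifted position
    assert np.linalg.norm(
        np.subtract(best2.center_mm, np.add(best1.center_mm, shift_mm))
    ) <= 0.5 * best1.scale_mm


def test_small_lesions_need_the_small_scale():
    """4-6 mm lesions are recovered far better by the 6 mm scale than by
    the 24 mm scale alone - the motivation for multiscale sampling."""
    spec = PhantomSpec(n_vessels=0, noise_sd=1.0, seed=3)
    found = {6.0: 0, 24.0: 0}
    n_lesions = 0
    for seed in range(4):
        rng = np.random.default_rng(100 + seed)
        gts = place_lesions_in_liver("c1", [4.5, 5.0, 5.5, 6.0], spec, rng,
                                     min_separation=30.0)
        vol, _ = gen_phantom_volume(gts, spec, rng)
        n_lesions += len(gts)
        for scale in (6.0, 24.0):
            cands = detect(vol, scales_mm=[scale], score_cutoff=0.5,
                           mask=vol.mask)
            marks = [hf.Mark("c1", "AI", hf.AI_STANDALONE,
                             np.asarray(c.center_mm), 100 * c.score)
                     for c in cands]
            if marks:
                m = hf.match_marks(marks, gts)
                found[scale] += int(m.lesions.localized.sum())
    assert found[6.0] > found[24.0]
    assert found[6.0] >= 0.5 * n_lesions


def test_easy_phantom_perfect_operating_point():
    """High-contrast vessel-free phantom with >= 8 mm lesions: some score
    cutoff separates every lesion from every false positive."""
    rng = np.random.default_rng(3)
    spec = PhantomSpec(n_vessels=0, noise_sd=2.0)
    gts = place_lesions_in_liver("c1", [8.5, 10, 12, 16], spec, rng,
                                 min_separation=25)
    vol, _ = gen_phantom_volume(gts, spec, rng)
    cands = detect(vol, score_cutoff=0.0)
    marks = [hf.Mark("c1", "AI", hf.AI_STANDALONE, np.asarray(c.center_mm),
                     100 * c.score) for c in cands]
    m = hf.match_marks(marks, gts)
    mm = m.marks
    best_tp = mm[mm.label == "TP"].groupby("lesion_id").rating.max()
    worst_needed = best_tp.min()
    fp = mm[mm.label == "FP"].rating
    assert len(best_tp) == len(gts)
    assert len(fp) == 0 or fp.max() < worst_needed
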