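"""Multiscale-sampling minIP lesion detector (desk-scale re-implementation).

Pipeline: simple liver segmentation -> cubic patch sampling at 6/12/24 mm
physical scales -> minimum-intensity projection of each patch along the
three orthogonal axes -> per-patch lesion score -> cross-scale candidate
merging by non-maximum suppression.

The patch scorer is an interpretable geometric surrogate for the original
trained classifier: it exploits exactly the representation the minIP
triplet provides, namely that a hypointense *sphere* projects to a compact
dark blob in all three planes while a hypointense *tube* is elongated in at
least one plane.  The statistic is the worst-plane isotropy of the dark
blob's second moments, mapped to [0, 1] by a fixed logistic.  Any callable
``(MinipTriplet) -> float`` can be plugged in instead.

Liver segmentation is intentionally simple (threshold + largest component +
closing) and does not exclude vessels from the mask - the same limitation
the original software has.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import SegmentationError, ValidationError
from .types import AI_SOURCE, AI_STANDALONE, Mark
from .volume import Volume

DEFAULT_SCALES_MM = (6.0, 12.0, 24.0)


# ---------------------------------------------------------------------------
# liver segmentation

def segment_liver_simple(
    volume: Volume, min_bimodality: float = 0.75, closing_radius_mm: float = 3.0
) -> np.ndarray:
    """Bright-liver mask: Otsu threshold, largest component, closing, fill.

    Vessels and lesions inside the liver end up inside the mask (the holes
    are filled); large vessels are deliberately not excluded.  Raises
    SegmentationError when the volume has no bimodal bright/dark contrast
    (e.g. an all-background volume).
    """
    data = volume.data
    if float(data.max() - data.min()) == 0.0:
        raise SegmentationError("constant volume: no liver/background contrast")
    thr = filters.threshold_otsu(data)
    fg = data > thr
    if not fg.any() or fg.all():
        raise SegmentationError("threshold produced an empty or full mask")
    # Otsu between-class variance fraction as a bimodality check
    w1 = fg.mean()
    mu0, mu1 = float(data[~fg].mean()), float(data[fg].mean())
    between = w1 * (1 - w1) * (mu1 - mu0) ** 2
    total = float(data.var())
    if total == 0 or between / total < min_bimodality:
        raise SegmentationError(
            "no bimodal liver/background contrast "
            f"(between-class variance fraction {between / total:.2f})"
        )
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    rad = [max(1, int(round(closing_radius_mm / s))) for s in volume.spacing]
    footprint = np.ones((2 * rad[0] + 1, 2 * rad[1] + 1, 2 * rad[2] + 1), dtype=bool)
    mask = ndimage.binary_closing(mask, structure=footprint)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError("segmentation produced an empty mask")
    return mask


# ---------------------------------------------------------------------------
# patch sampling

@dataclass(frozen=True)
class PatchDescriptor:
    center_voxel: tuple[int, int, int]
    scale_mm: float
    half_voxels: tuple[int, int, int]  # window half-extent per axis

    def center_world(self, spacing) -> np.ndarray:
        return np.asarray(self.center_voxel, dtype=float) * np.asarray(spacing)


def _odd_voxels(scale_mm: float, spacing: float) -> int:
    return 2 * int(math.floor(scale_mm / (2.0 * spacing))) + 1


def sample_patches(
    volume: Volume,
    mask: np.ndarray,
    scales_mm=DEFAULT_SCALES_MM,
    stride_frac: float = 0.5,
) -> list[PatchDescriptor]:
    """Cubic patches of physical side ``scale`` centred inside the mask.

    Physical size converts to a nearest-odd per-axis voxel count.  Centres
    lie on a grid of step ``stride_frac * scale``: mask voxels are binned by
    the stride and the voxel nearest each bin centre is kept, so even a
    single-voxel mask yields one patch per scale.
    """
    if not mask.any():
        return []
    spacing = np.asarray(volume.spacing)
    idx = np.argwhere(mask)
    patches = []
    for scale in scales_mm:
        if any(scale < s for s in spacing):
            raise ValidationError(
                f"patch scale {scale} mm is smaller than one voxel "
                f"(spacing {tuple(spacing)})"
            )
        half = tuple(
            (_odd_voxels(scale, s) - 1) // 2 for s in spacing
        )
        step = np.maximum(1, np.round(stride_frac * scale / spacing)).astype(int)
        bins = idx // step
        bin_center = (bins + 0.5) * step - 0.5
        dist = np.linalg.norm((idx - bin_center) * spacing, axis=1)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], dist))
        seen = set()
        for k in order:
            key = (scale, *bins[k])
            if key in seen:
                continue
            seen.add(key)
            patches.append(
                PatchDescriptor(
                    center_voxel=tuple(int(v) for v in idx[k]),
                    scale_mm=float(scale),
                    half_voxels=half,
                )
            )
    return patches


def _patch_slices(volume: Volume, patch: PatchDescriptor) -> tuple[slice, ...]:
    return tuple(
        slice(max(0, c - h), min(n, c + h + 1))
        for c, h, n in zip(patch.center_voxel, patch.half_voxels, volume.shape)
    )


def extract_patch(volume: Volume, patch: PatchDescriptor) -> np.ndarray:
    """Clip-extract the cubic window around the patch centre."""
    return volume.data[_patch_slices(volume, patch)]


# ---------------------------------------------------------------------------
# minimum-intensity projection

@dataclass
class MinipTriplet:
    """Min-projections of a cubic patch along its three axes.

    ``images[k]`` collapses axis k; its pixel spacing is the spacing of the
    two remaining axes, recorded in ``pixel_spacings[k]``.
    """

    images: tuple[np.ndarray, np.ndarray, np.ndarray]
    pixel_spacings: tuple[tuple[float, float], ...]
    scale_mm: float
    center_mm: np.ndarray


def minip_projections(
    patch: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    scale_mm: float = 0.0,
    center_mm=(0.0, 0.0, 0.0),
) -> MinipTriplet:
    """Minimum-intensity projection along each of the three patch axes."""
    if patch.size == 0:
        raise ValidationError("cannot project an empty patch")
    images = tuple(patch.min(axis=k) for k in range(3))
    sp = tuple(
        tuple(s for a, s in enumerate(spacing) if a != k) for k in range(3)
    )
    return MinipTriplet(
        images=images,
        pixel_spacings=sp,
        scale_mm=scale_mm,
        center_mm=np.asarray(center_mm, dtype=float),
    )


# ---------------------------------------------------------------------------
# patch scoring

@dataclass(frozen=True)
class GeometricScorerConfig:
    dark_fraction: float = 0.5      # cutoff between patch min and max
    min_contrast: float = 10.0      # intensity units; below -> score 0
    min_blob_pixels: int = 3        # smallest credible blob per plane
    logistic_slope: float = 10.0
    logistic_midpoint: float = 0.45


def _plane_blob(img: np.ndarray, pix: tuple[float, float],
                cfg: GeometricScorerConfig):
    """Isotropy and centroid of the dominant dark blob in one projection.

    Returns (sqrt(lambda_min / lambda_max), centroid in plane mm) of the
    darkness-weighted second moments of the largest dark component: the
    isotropy is ~1 for a disk and ->0 for a bar.  (0, None) when the plane
    has no credible dark blob.
    """
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < cfg.min_contrast:
        return 0.0, None
    cutoff = lo + cfg.dark_fraction * (hi - lo)
    dark = img <= cutoff
    labels = measure.label(dark)
    if labels.max() == 0:
        return 0.0, None
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    blob = labels == largest
    if blob.sum() < cfg.min_blob_pixels:
        return 0.0, None
    w = np.where(blob, cutoff - img, 0.0)
    w = np.maximum(w, 0.0)
    ii, jj = np.nonzero(blob)
    wts = w[ii, jj]
    if wts.sum() <= 0:
        wts = np.ones_like(wts)
    # physical coordinates, so anisotropic pixels do not fake elongation
    y = np.stack([ii * pix[0], jj * pix[1]], axis=1)
    mu = np.average(y, axis=0, weights=wts)
    yc = y - mu
    cov = (yc * wts[:, None]).T @ yc / wts.sum()
    # half-pixel variance floor: a single-file line of pixels still has width
    cov[0, 0] += (pix[0] / 2) ** 2 / 3
    cov[1, 1] += (pix[1] / 2) ** 2 / 3
    ev = np.linalg.eigvalsh(cov)
    if ev[1] <= 0:
        return 0.0, None
    return float(math.sqrt(max(ev[0], 0.0) / ev[1])), mu


# image axes of projection k are the volume axes other than k
_PLANE_AXES = ((1, 2), (0, 2), (0, 1))


def localize_triplet(
    triplet: MinipTriplet, config: GeometricScorerConfig | None = None
) -> np.ndarray | None:
    """3D position (mm, patch frame) of the dark blob, from the three
    projections' centroids; each axis averages its two plane estimates."""
    cfg = config or GeometricScorerConfig()
    est = np.zeros(3)
    n = np.zeros(3)
    for k, (img, pix) in enumerate(zip(triplet.images, triplet.pixel_spacings)):
        _, mu = _plane_blob(img, pix, cfg)
        if mu is None:
            return None
        for a, axis in enumerate(_PLANE_AXES[k]):
            est[axis] += mu[a]
            n[axis] += 1
    return est / n


def score_patch(
    triplet: MinipTriplet, config: GeometricScorerConfig | None = None
) -> float:
    """Sphere-likeness score in [0, 1] for a minIP triplet.

    A compact dark blob in ALL three planes scores high; elongation in any
    plane drags the worst-plane statistic, and the score, down.  Degenerate
    (flat) triplets score 0.
    """
    cfg = config or GeometricScorerConfig()
    stats = [
        _plane_blob(img, pix, cfg)[0]
        for img, pix in zip(triplet.images, triplet.pixel_spacings)
    ]
    stat = min(stats)
    if stat == 0.0:
        return 0.0
    return float(
        1.0 / (1.0 + math.exp(-cfg.logistic_slope * (stat - cfg.logistic_midpoint)))
    )


# ---------------------------------------------------------------------------
# candidate merging

@dataclass(frozen=True)
class Candidate:
    center_mm: tuple[float, float, float]
    scale_mm: float
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")


def merge_candidates(
    candidates: list[Candidate],
    score_cutoff: float = 0.5,
    nms_radius_frac: float = 0.5,
) -> list[Candidate]:
    """Greedy cross-scale non-maximum suppression by descending score.

    Candidate j is suppressed by a kept candidate i when their centres are
    within ``nms_radius_frac * max(scale_i, scale_j)``.  Ties are broken by
    (higher score, smaller scale, lexicographic centre), so the result is
    deterministic.
    """
    pool = [c for c in candidates if c.score >= score_cutoff]
    pool.sort(key=lambda c: (-c.score, c.scale_mm, c.center_mm))
    kept: list[Candidate] = []
    for c in pool:
        p = np.asarray(c.center_mm)
        suppressed = False
        for k in kept:
            radius = nms_radius_frac * max(c.scale_mm, k.scale_mm)
            if np.linalg.norm(p - np.asarray(k.center_mm)) <= radius:
                suppressed = True
                break
        if not suppressed:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# full pipeline

def detect(
    volume: Volume,
    scales_mm=DEFAULT_SCALES_MM,
    score_cutoff: float = 0.5,
    stride_frac: float = 0.5,
    nms_radius_frac: float = 0.5,
    scorer=None,
    mask: np.ndarray | None = None,
) -> list[Candidate]:
    """Liver mask -> multiscale patches -> minIP -> score -> merge.

    Patch centres are restricted, per scale, to the liver mask eroded by the
    patch half-extent, so a patch never straddles the dark background at the
    organ boundary (lesions hugging the boundary are therefore missed - the
    same boundary limitation reported for detectors of this design).
    """
    if mask is None:
        mask = volume.mask if volume.mask is not None else segment_liver_simple(volume)
    scorer = scorer or score_patch
    patches = []
    for scale in scales_mm:
        half = [(_odd_voxels(scale, s) - 1) // 2 for s in volume.spacing]
        footprint = np.ones(
            (2 * half[0] + 1, 2 * half[1] + 1, 2 * half[2] + 1), dtype=bool
        )
        inner = ndimage.binary_erosion(mask, structure=footprint)
        if inner.any():
            patches += sample_patches(volume, inner, [scale], stride_frac)
    spacing = np.asarray(volume.spacing)
    scored = []
    for pd_ in patches:
        sl = _patch_slices(volume, pd_)
        sub = volume.data[sl]
        triplet = minip_projections(
            sub, volume.spacing, pd_.scale_mm, pd_.center_world(volume.spacing)
        )
        s = float(scorer(triplet))
        if s <= 0.0:
            continue
        # candidate sits at the dark blob's centroid, not the patch centre
        origin = np.array([s_.start for s_ in sl]) * spacing
        offset = localize_triplet(triplet) if scorer is score_patch else None
        center = origin + offset if offset is not None else pd_.center_world(spacing)
        scored.append(
            Candidate(center_mm=tuple(center), scale_mm=pd_.scale_mm, score=s)
        )
    return merge_candidates(scored, score_cutoff, nms_radius_frac)


def candidates_to_marks(candidates: list[Candidate], case_id: str) -> list[Mark]:
    """Express detector output as standalone-AI marks (rating = 100 * score)."""
    return [
        Mark(
            case_id=case_id,
            source_id=AI_SOURCE,
            modality=AI_STANDALONE,
            position=np.asarray(c.center_mm),
            rating=100.0 * c.score,
        )
        for c in candidates
    ]
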