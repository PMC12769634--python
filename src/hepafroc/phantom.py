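"""Synthetic hepatobiliary-phase phantom volumes.

The phantom emulates the contrast situation that makes small-lesion
detection hard on hepatobiliary-phase images: bright liver parenchyma with
*both* lesions and vessels hypointense.  The liver is an ellipsoid of
uniform intensity inside a darker background; lesions are hypointense
spheres of the ground-truth diameter; vessels are hypointense tubes
(piecewise-linear random walks swept by a radius); Gaussian noise is added
last.  Geometry is deliberately simple - no MRI physics, bias fields or
motion - so detector tests exercise the sphere-vs-tube shape problem, not
artefact robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError, ValidationError
from .types import GroundTruthLesion
from .volume import Volume


@dataclass
class PhantomSpec:
    """Geometry and intensities of one phantom case."""

    shape: tuple[int, int, int] = (96, 96, 40)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    background_intensity: float = 20.0
    liver_intensity: float = 100.0
    lesion_intensity: float = 40.0
    vessel_intensity: float = 40.0
    noise_sd: float = 2.0
    n_vessels: int = 3
    vessel_radius_mm: tuple[float, float] = (1.5, 3.0)
    vessel_segments: int = 4
    vessel_step_mm: tuple[float, float] = (12.0, 28.0)
    liver_center_mm: tuple[float, float, float] | None = None
    liver_semiaxes_mm: tuple[float, float, float] = (60.0, 52.0, 45.0)
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValidationError("shape and spacing must be positive")
        if self.lesion_intensity >= self.liver_intensity:
            raise ValidationError(
                "lesions must be hypointense: lesion_intensity < liver_intensity"
            )
        if self.vessel_intensity >= self.liver_intensity:
            raise ValidationError(
                "vessels must be hypointense: vessel_intensity < liver_intensity"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * np.array(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        if self.liver_center_mm is not None:
            return np.asarray(self.liver_center_mm, dtype=float)
        return self.extent_mm / 2.0


def _world_grids(spec: PhantomSpec):
    xs = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*xs, indexing="ij", sparse=True)


def _liver_mask(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _world_grids(spec)
    c = spec.center_mm
    a = np.asarray(spec.liver_semiaxes_mm)
    return (
        ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
    ) <= 1.0


def _inside_ellipsoid(point, spec: PhantomSpec, margin_mm: float = 0.0) -> bool:
    c, a = spec.center_mm, np.asarray(spec.liver_semiaxes_mm) - margin_mm
    if np.any(a <= 0):
        return False
    return float(np.sum(((np.asarray(point) - c) / a) ** 2)) <= 1.0


def _paint_sphere(data, spec, center_mm, radius_mm, value):
    X, Y, Z = _world_grids(spec)
    d2 = (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (Z - center_mm[2]) ** 2
    data[d2 <= radius_mm**2] = value


def _paint_tube(data, mask, spec, p0, p1, radius_mm, value):
    X, Y, Z = _world_grids(spec)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0:
        return
    t = ((X - p0[0]) * v[0] + (Y - p0[1]) * v[1] + (Z - p0[2]) * v[2]) / vv
    t = np.clip(t, 0.0, 1.0)
    d2 = (
        (X - (p0[0] + t * v[0])) ** 2
        + (Y - (p0[1] + t * v[1])) ** 2
        + (Z - (p0[2] + t * v[2])) ** 2
    )
    data[(d2 <= radius_mm**2) & mask] = value


def gen_phantom_volume(
    case_lesions: list[GroundTruthLesion],
    spec: PhantomSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Volume, list[dict]]:
    """Render one case as a Volume (with liver mask) plus a voxel-space
    lesion list.

    Lesion order of painting: liver, vessels, lesions, then noise - so a
    lesion overlapping a vessel keeps the lesion intensity at its core.
    Raises PlacementError for a lesion whose sphere does not fit inside the
    liver ellipsoid.
    """
    spec = spec or PhantomSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mask = _liver_mask(spec)
    data = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    data[mask] = spec.liver_intensity

    for _ in range(spec.n_vessels):
        radius = rng.uniform(*spec.vessel_radius_mm)
        # start near the liver centre, wander outward
        p = spec.center_mm + rng.normal(0, 8.0, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(spec.vessel_segments):
            step = rng.uniform(*spec.vessel_step_mm)
            q = p + direction * step
            _paint_tube(data, mask, spec, p, q, radius, spec.vessel_intensity)
            p = q
            direction += rng.normal(0, 0.4, size=3)
            direction /= np.linalg.norm(direction)

    for g in case_lesions:
        r = g.diameter / 2.0
        if not _inside_ellipsoid(g.center, spec, margin_mm=r):
            raise PlacementError(
                f"lesion {g.lesion_id} (r={r:.1f} mm) does not fit inside the "
                "liver ellipsoid"
            )
        _paint_sphere(data, spec, g.center, r, spec.lesion_intensity)

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    voxel_lesions = [
        {
            "lesion_id": g.lesion_id,
            "center_voxel": (np.asarray(g.center) / np.asarray(spec.spacing)).tolist(),
            "diameter_mm": g.diameter,
        }
        for g in case_lesions
    ]
    return Volume(data, spec.spacing, mask=mask), voxel_lesions


def place_lesions_in_liver(
    case_id: str,
    diameters_mm,
    spec: PhantomSpec | None = None,
    rng: np.random.Generator | int | None = None,
    min_separation: float = 12.0,
    lesion_type: str = "metastasis",
    max_tries: int = 2000,
) -> list[GroundTruthLesion]:
    """Sample lesion centres uniformly inside the liver ellipsoid, each
    sphere fully contained, pairwise centre separation >= min_separation."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    c = spec.center_mm
    axes = np.asarray(spec.liver_semiaxes_mm)
    out, centers = [], []
    for k, d in enumerate(np.atleast_1d(diameters_mm)):
        r = float(d) / 2.0
        inner = axes - r
        if np.any(inner <= 0):
            raise PlacementError(f"lesion of diameter {d} mm cannot fit the liver")
        for _ in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform() ** (1 / 3)
            p = c + u * rad * inner
            if all(np.linalg.norm(p - q) >= min_separation for q in centers):
                centers.append(p)
                break
        else:
            raise PlacementError("could not pack lesions inside the liver")
        out.append(
            GroundTruthLesion(
                case_id=case_id,
                lesion_id=f"{case_id}_L{k + 1:02d}",
                center=p,
                diameter=float(d),
                lesion_type=lesion_type,
            )
        )
    return out
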