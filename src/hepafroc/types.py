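"""Core domain types for the reader study.

All positions are world coordinates in millimetres.  A *mark* is a single
localization made by a human reader or by the AI software, carrying a
confidence rating on the study's 0-100 scale.  Ground-truth lesions are
points with a diameter; the matching rule (see :mod:`hepafroc.matching`)
turns the diameter into a 3D distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ValidationError

# Modality labels for the paired reading sessions and the standalone AI run.
WITHOUT_AI = "without_AI"
WITH_AI = "with_AI"
AI_STANDALONE = "AI_standalone"
MODALITIES = (WITHOUT_AI, WITH_AI, AI_STANDALONE)
PAIRED_MODALITIES = (WITHOUT_AI, WITH_AI)

AI_SOURCE = "AI"


class LesionType(str, Enum):
    CYST = "cyst"
    HEMANGIOMA = "hemangioma"
    METASTASIS = "metastasis"


def _as_point(v) -> np.ndarray:
    p = np.asarray(v, dtype=float)
    if p.shape != (3,):
        raise ValidationError(f"expected a 3-vector position, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValidationError(f"non-finite position {p}")
    return p


@dataclass(frozen=True)
class GroundTruthLesion:
    """One reference lesion: identity, 3D centre (mm) and diameter (mm)."""

    case_id: str
    lesion_id: str
    center: np.ndarray
    diameter: float
    lesion_type: LesionType

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        object.__setattr__(self, "lesion_type", LesionType(self.lesion_type))
        if not (self.diameter > 0):
            raise ValidationError(
                f"lesion {self.case_id}/{self.lesion_id}: diameter must be > 0, "
                f"got {self.diameter}"
            )


@dataclass(frozen=True)
class Mark:
    """One localization by a reader or the AI, with a 0-100 confidence rating."""

    case_id: str
    source_id: str
    modality: str
    position: np.ndarray
    rating: float

    def __post_init__(self):
        object.__setattr__(self, "position", _as_point(self.position))
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if not (0.0 <= self.rating <= 100.0):
            raise ValidationError(
                f"mark {self.case_id}/{self.source_id}: rating {self.rating} "
                "outside [0, 100]"
            )


@dataclass
class StudyDesign:
    """Who read what: readers, paired modalities and the full case list.

    ``voxel_spacing`` carries the acquisition grid for volume-backed studies;
    the default z-spacing of 3.0 mm matches a typical hepatobiliary-phase
    protocol (3 mm slices).
    """

    reader_ids: list[str]
    modalities: list[str] = field(default_factory=lambda: list(PAIRED_MODALITIES))
    case_ids: list[str] = field(default_factory=list)
    voxel_spacing: tuple[float, float, float] = (1.2, 1.2, 3.0)

    def __post_init__(self):
        if not self.case_ids:
            raise ValidationError("StudyDesign requires a non-empty case list")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValidationError(f"unknown modality {m!r}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel spacing must be positive")


@dataclass(frozen=True)
class MatchRule:
    """3D TP criterion: mark-to-centre distance vs a diameter-scaled threshold.

    A mark is a TP candidate for lesion *g* when its 3D Euclidean distance to
    the lesion centre is within ``diameter_fraction * diameter(g)``, with a
    3 mm clause combined either as a floor (``combine='max'``, default: small
    lesions still get a 3 mm tolerance) or as a cap (``combine='and'``: both
    conditions must hold).  Candidates are resolved one-to-one by ascending
    distance; with ``absorb_duplicates`` additional marks inside the threshold
    of an already-localized lesion are absorbed rather than counted as FPs.
    """

    diameter_fraction: float = 0.75
    floor_mm: float = 3.0
    combine: str = "max"
    absorb_duplicates: bool = True

    def __post_init__(self):
        if not (0.0 < self.diameter_fraction <= 1.0):
            raise ValidationError("diameter_fraction must be in (0, 1]")
        if self.floor_mm < 0:
            raise ValidationError("floor_mm must be >= 0")
        if self.combine not in ("max", "and"):
            raise ValidationError("combine must be 'max' or 'and'")

    def threshold(self, diameter) -> np.ndarray:
        """Distance threshold (mm) for a lesion of the given diameter (mm)."""
        d = np.asarray(diameter, dtype=float)
        frac = self.diameter_fraction * d
        if self.combine == "max":
            return np.maximum(frac, self.floor_mm)
        return np.minimum(frac, self.floor_mm)
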