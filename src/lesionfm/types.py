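"""Core containers shared across the package.

Conventions (fixed everywhere):

* Volumes are numpy arrays indexed ``[i, j, k]`` for the (x, y, z) axes, so
  the x index comes first.  World coordinates are millimetres; voxel indices
  are 0-based and map to world positions at the **voxel centre**:
  ``world = origin + index * spacing``.
* Intensities are Hounsfield units (HU) in ``[-1024, 2048]`` until a patch is
  normalized, after which values live in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

HU_MIN = -1024.0
HU_MAX = 2048.0
HU_RANGE = HU_MAX - HU_MIN  # 3072


@dataclass
class VolumeGrid:
    """A 3D scalar intensity grid in HU with physical geometry."""

    intensities: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("VolumeGrid requires a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("VolumeGrid intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def world_to_index(self, pos) -> np.ndarray:
        """Continuous voxel index of a world position (voxel-centre convention)."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def is_isotropic(self, tol: float = 1e-6) -> bool:
        sx, sy, sz = self.spacing
        return abs(sx - sy) <= tol and abs(sy - sz) <= tol


@dataclass(frozen=True)
class SeedPoint:
    """A lesion-identifying 3D location in world coordinates (mm)."""

    position: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError("seed coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class LesionRecord:
    """One annotated lesion with its task labels.

    ``label_2yr`` is the binary 2-year survival status; it is ``None`` for
    cases censored before 2 years (right-censoring of the binary endpoint).
    """

    scan_id: str
    seed: Optional[SeedPoint] = None
    mask_ref: Optional[str] = None
    site_class: Optional[int] = None
    malignant: Optional[int] = None
    event: Optional[int] = None
    time_days: Optional[float] = None
    label_2yr: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None and self.mask_ref is None:
            raise ValueError("LesionRecord needs a seed point or a mask reference")
        if self.time_days is not None and self.event is None:
            raise ValueError("time_days without an event indicator")
        if self.time_days is not None and self.time_days < 0:
            raise ValueError("time_days must be non-negative")


@dataclass
class Patch:
    """A cubic sub-volume centred on a seed point."""

    values: np.ndarray
    edge_voxels: int = 50
    normalized: bool = False
    source: Tuple[str, Tuple[float, float, float]] = ("", (0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        L = self.edge_voxels
        if self.values.shape != (L, L, L):
            raise ValueError(f"patch must be {L}^3, got {self.values.shape}")
        if self.normalized:
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("normalized patch values must lie in [0, 1]")

    def copy_with(self, values: np.ndarray) -> "Patch":
        return replace(self, values=values)


@dataclass
class MetricResult:
    """A scalar metric with a bootstrap confidence interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: Optional[int] = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate + 1e-12 and self.estimate <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the point estimate")

    def as_dict(self) -> dict:
        return {
            "metric": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "level": self.level,
        }
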