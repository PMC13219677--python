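"""Core domain types shared across the package.

World coordinates are taken exactly as written in the input files: the mask
header's origin/direction and the markup file's point coordinates are assumed
to live in the SAME world frame.  No RAS/LPS or other anatomical-convention
conversion is attempted anywhere in this package — if your masks and markups
come from tools with different conventions, convert them before loading.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaskVolume", "ApplicatorLine", "AblationRecord"]


@dataclass
class MaskVolume:
    """A 3D binary segmentation on a regular (possibly anisotropic) grid.

    Parameters
    ----------
    voxels
        3D array of {0,1}; index order (i, j, k) matches the header's axis
        order.
    spacing
        mm per voxel along each index axis; all entries positive.
    origin
        World coordinates (mm) of the centre of voxel (0, 0, 0).
    direction
        3x3 orthonormal voxel-to-world rotation; column d[:, a] is the world
        direction of index axis a.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.voxels = (self.voxels != 0).astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive values")
        if self.direction.shape != (3, 3) or abs(
            abs(np.linalg.det(self.direction)) - 1.0
        ) > 1e-6:
            raise ValueError("direction must be a 3x3 orthonormal matrix")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(indices, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) to continuous voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.direction / self.spacing


@dataclass
class ApplicatorLine:
    """Applicator (microwave antenna) geometry: tip point and unit insertion
    direction in world mm.  The direction points from the shaft toward and
    past the tip."""

    tip: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm < 1e-12:
            raise ValueError("applicator direction has zero length")
        if abs(norm - 1.0) > 1e-9:
            self.direction = self.direction / norm

    @classmethod
    def from_points(cls, shaft: np.ndarray, tip: np.ndarray) -> "ApplicatorLine":
        shaft = np.asarray(shaft, dtype=float)
        tip = np.asarray(tip, dtype=float)
        d = tip - shaft
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("shaft and tip points coincide")
        return cls(tip=tip, direction=d / n)


@dataclass
class AblationRecord:
    """Per-ablation metadata: treatment settings and covariates."""

    ablation_id: str
    patient_id: str
    power_w: float
    duration_min: float
    followup_days: float = np.nan
    tumor_volume_mm3: float = np.nan
    nodule_class: str = "solid"      # solid | subsolid | cavitary
    location: str = "peripheral"     # central | peripheral
    pleura_within_5mm: bool = False
    vessel_class: str = "<2mm"       # <2mm | 2-3mm | >3mm

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("ablation duration must be positive")

    @property
    def energy_wmin(self) -> float:
        """Total delivered energy: power × time, in watt-minutes."""
        return self.power_w * self.duration_min

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["energy_wmin"] = self.energy_wmin
        return d
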