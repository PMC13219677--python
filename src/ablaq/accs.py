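"""Applicator-centric coordinate system (ACCS).

Ablation zones are segmented in arbitrary patient orientations; to compare
them across patients each mask is resampled into a tip-centred grid whose
third axis is the applicator's insertion direction.  The default grid is
64 × 64 × 64 voxels at 1 mm isotropic sampling, with the applicator tip at
voxel (32, 32, 32), so slice index k corresponds to an axial offset of
(k − 32) mm from the tip and positive offsets lie distal to the tip (in the
insertion direction, "front").

All axis-referenced measurements — ablation length, slice-wise diameters and
areas, maximum width, tip-to-front-edge distance and the front/back split —
are computed on this grid, never on the native grid, so they are independent
of acquisition spacing and orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ApplicatorLine, MaskVolume

__all__ = [
    "ACCSFrame",
    "ACCSVolume",
    "AxialProfile",
    "AxialSummary",
    "build_accs_frame",
    "resample_to_accs",
    "axial_profile",
    "axial_summary",
    "caliper_widths",
]

logger = logging.getLogger(__name__)

GRID_SIZE = 64          # voxels per side
GRID_SPACING = 1.0      # mm, isotropic
TIP_INDEX = GRID_SIZE // 2


@dataclass
class ACCSFrame:
    """Rigid world → ACCS transform.

    ACCS coordinates of a world point p are ``rotation @ (p - tip)``: the tip
    maps to the origin and the insertion direction maps to +axis3.  The spin
    about the applicator axis is fixed by aligning the first transverse axis
    with the projection of world x̂ onto the transverse plane (world ŷ when
    the applicator is parallel to x̂); axial measurements are spin-invariant,
    the ECT embedding is not.
    """

    tip: np.ndarray
    rotation: np.ndarray  # rows are the ACCS basis vectors in world coords

    def world_to_accs(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.tip) @ self.rotation.T

    def accs_to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation + self.tip


@dataclass
class ACCSVolume:
    """Binary mask resampled onto the ACCS grid (1 mm isotropic).

    ``voxels[i, j, k]`` sits at ACCS coordinates (i−32, j−32, k−32) mm; the
    third index runs along the applicator axis.
    """

    voxels: np.ndarray
    truncated: bool = False
    spacing: float = GRID_SPACING

    def __post_init__(self) -> None:
        self.voxels = (np.asarray(self.voxels) != 0).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError("ACCS volume must be 3D")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def coordinates(self) -> np.ndarray:
        """ACCS coordinates (mm) of foreground voxel centres, shape (n, 3)."""
        idx = np.argwhere(self.voxels)
        centre = np.array(self.voxels.shape) // 2
        return (idx - centre) * self.spacing


@dataclass
class AxialProfile:
    """Per-1-mm-slice geometry along the applicator axis.

    ``slice_offsets[k]`` is the slice's axial position in mm relative to the
    tip (negative = proximal).  Diameter summaries are NaN on empty slices.
    """

    slice_offsets: np.ndarray
    area_mm2: np.ndarray
    mean_diameter_mm: np.ndarray
    median_diameter_mm: np.ndarray
    max_diameter_mm: np.ndarray
    occupied: np.ndarray

    def width(self, stat: str = "mean") -> np.ndarray:
        try:
            return {
                "mean": self.mean_diameter_mm,
                "median": self.median_diameter_mm,
                "max": self.max_diameter_mm,
            }[stat]
        except KeyError:
            raise ValueError(f"unknown width statistic {stat!r}") from None


@dataclass
class AxialSummary:
    length_mm: float
    max_width_mm: float
    max_area_mm2: float
    tip_to_front_edge_mm: float
    front_max_width_mm: float
    back_max_width_mm: float
    front_widths: np.ndarray = field(repr=False, default=None)
    back_widths: np.ndarray = field(repr=False, default=None)
    front_areas: np.ndarray = field(repr=False, default=None)
    back_areas: np.ndarray = field(repr=False, default=None)


def build_accs_frame(applicator: ApplicatorLine) -> ACCSFrame:
    """Construct the rigid world → ACCS transform for an applicator.

    The third ACCS axis is the insertion direction; the first transverse axis
    is world x̂ projected into the transverse plane (ŷ if degenerate); the
    second completes a right-handed orthonormal basis (det = +1).
    """
    d = np.asarray(applicator.direction, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("applicator direction has zero length")
    e3 = d / n
    ref = np.array([1.0, 0.0, 0.0])
    e1 = ref - np.dot(ref, e3) * e3
    if np.linalg.norm(e1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    rotation = np.stack([e1, e2, e3])
    return ACCSFrame(tip=np.asarray(applicator.tip, dtype=float), rotation=rotation)


def resample_to_accs(
    mask: MaskVolume,
    frame: ACCSFrame,
    grid_size: int = GRID_SIZE,
    spacing: float = GRID_SPACING,
) -> ACCSVolume:
    """Resample a binary mask onto the ACCS grid by nearest-neighbour sampling.

    Nearest-neighbour (not linear + threshold) keeps the label image binary.
    A truncation flag is set (and a warning logged) when foreground touches
    any face of the grid, meaning the zone may extend beyond it.

    Raises
    ------
    ValueError
        If no foreground falls inside the grid.
    """
    centre = grid_size // 2
    ax = (np.arange(grid_size) - centre) * spacing
    gi, gj, gk = np.meshgrid(ax, ax, ax, indexing="ij")
    accs_pts = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
    world_pts = frame.accs_to_world(accs_pts)
    vox = mask.world_to_voxel(world_pts)  # continuous indices
    out = ndimage.map_coordinates(
        mask.voxels, vox.T, order=0, mode="constant", cval=0, prefilter=False
    )
    vol = out.reshape(grid_size, grid_size, grid_size).astype(np.uint8)
    if vol.sum() == 0:
        raise ValueError("mask is entirely outside the ACCS grid")
    touches = (
        vol[0].any() or vol[-1].any()
        or vol[:, 0].any() or vol[:, -1].any()
        or vol[:, :, 0].any() or vol[:, :, -1].any()
    )
    if touches:
        logger.warning(
            "foreground touches the ACCS grid boundary; measurements may be truncated"
        )
    return ACCSVolume(voxels=vol, truncated=bool(touches), spacing=spacing)


def caliper_widths(slice_mask: np.ndarray, n_angles: int = 90) -> np.ndarray:
    """Rotating-caliper (Feret) widths of a 2D binary slice.

    At each of ``n_angles`` equally spaced angles in [0, π) the width is the
    extent of the foreground pixel-centre projections plus the 1-mm pixel
    footprint, so a single pixel has width 1 mm at every angle and widths are
    monotone under dilation.  Holes are ignored (convex support per angle).
    """
    pts = np.argwhere(slice_mask)
    if pts.size == 0:
        return np.full(n_angles, np.nan)
    angles = np.arange(n_angles) * np.pi / n_angles
    dirs = np.stack([np.cos(angles), np.sin(angles)])  # (2, n_angles)
    proj = pts @ dirs  # (n_pts, n_angles)
    return proj.max(axis=0) - proj.min(axis=0) + 1.0


def axial_profile(accs: ACCSVolume, n_angles: int = 90) -> AxialProfile:
    """Slice-wise area and caliper-diameter summaries perpendicular to the
    applicator axis."""
    if accs.n_foreground == 0:
        raise ValueError("empty ACCS volume")
    n = accs.voxels.shape[2]
    centre = n // 2
    offsets = np.arange(n) - centre
    area = accs.voxels.sum(axis=(0, 1)).astype(float) * accs.spacing**2
    occupied = area > 0
    mean_d = np.full(n, np.nan)
    med_d = np.full(n, np.nan)
    max_d = np.full(n, np.nan)
    for k in np.nonzero(occupied)[0]:
        w = caliper_widths(accs.voxels[:, :, k], n_angles) * accs.spacing
        mean_d[k] = w.mean()
        med_d[k] = np.median(w)
        max_d[k] = w.max()
    return AxialProfile(
        slice_offsets=offsets.astype(float) * accs.spacing,
        area_mm2=area,
        mean_diameter_mm=mean_d,
        median_diameter_mm=med_d,
        max_diameter_mm=max_d,
        occupied=occupied,
    )


def axial_summary(profile: AxialProfile, width_stat: str = "mean") -> AxialSummary:
    """Reduce an axial profile to the axis-referenced summary measurements.

    Length is the inclusive occupied-slice extent (a single-slice object has
    length 1 mm); internal unoccupied slices are ignored.  The front/back
    split is at the midpoint of the occupied extent; with an even slice count
    the mid-slice itself goes to the back half.  "Front" is distal — toward
    and past the tip in the insertion direction.
    """
    occ = np.nonzero(profile.occupied)[0]
    if occ.size == 0:
        raise ValueError("profile has no occupied slices")
    widths = profile.width(width_stat)
    offs = profile.slice_offsets
    first, last = offs[occ[0]], offs[occ[-1]]
    mid = 0.5 * (first + last)
    front = profile.occupied & (offs > mid)
    back = profile.occupied & (offs <= mid)
    front_w = widths[front]
    back_w = widths[back]
    return AxialSummary(
        length_mm=float(last - first + 1.0),
        max_width_mm=float(np.nanmax(widths[profile.occupied])),
        max_area_mm2=float(profile.area_mm2.max()),
        tip_to_front_edge_mm=float(last),
        front_max_width_mm=float(front_w.max()) if front_w.size else np.nan,
        back_max_width_mm=float(back_w.max()) if back_w.size else np.nan,
        front_widths=front_w,
        back_widths=back_w,
        front_areas=profile.area_mm2[front],
        back_areas=profile.area_mm2[back],
    )
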