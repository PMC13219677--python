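"""Vendor expected-ablation model.

Microwave ablation vendors publish a table of expected ellipsoidal ablation
dimensions per (power, duration) setting, derived from ex-vivo animal data.
This module represents such a table, interpolates it bilinearly to arbitrary
settings, synthesizes the corresponding prolate ellipsoid mask in the ACCS
for paired comparison and shape-space projection, and computes per-metric
log discrepancies between observed and predicted values.

The full proprietary table is not public; the packaged default covers the
four settings whose predictions are published (65 W at 2, 4, 5 and 6 min).
A complete table can be supplied as CSV with columns
``power_w,duration_min,length_mm,width_mm,tip_to_edge_mm,volume_cm3``.

Note the published vendor volumes disagree with the prolate-ellipsoid
closed form (π/6 · L·W² differs by roughly 5–8%); the vendor's volume is
therefore stored and reported as given, never recomputed from the axes.
Synthesized ellipsoids are used only for shape-space projection and
geometry round-trips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .accs import ACCSVolume, GRID_SIZE, GRID_SPACING

__all__ = [
    "VendorTable",
    "VendorPrediction",
    "default_vendor_table",
    "interpolate_vendor",
    "synthesize_ellipsoid_mask",
    "discrepancy_ratio",
]

SUPPORTED_POWER = (35.0, 65.0)      # watts
SUPPORTED_DURATION = (1.0, 10.0)    # minutes

# Published predictions for the 17-gauge probe at the four most common
# settings: length, max width, tip-to-front-edge (mm) and volume (cm^3).
_DEFAULT_TABLE_CSV = """\
power_w,duration_min,length_mm,width_mm,tip_to_edge_mm,volume_cm3
65,2,29.0,14.77,3.0,3.5
65,4,33.0,17.6,3.0,5.8
65,5,35.0,18.5,4.0,6.8
65,6,36.0,19.75,4.0,7.8
"""

_METRICS = ("length_mm", "width_mm", "tip_to_edge_mm", "volume_cm3")


@dataclass
class VendorPrediction:
    length_mm: float
    width_mm: float
    tip_to_edge_mm: float
    volume_cm3: float
    provenance: str = "exact-grid"  # exact-grid | interpolated | extrapolated

    def __post_init__(self) -> None:
        if self.width_mm > self.length_mm + 1e-9:
            raise ValueError("vendor width exceeds length")
        if self.volume_cm3 <= 0:
            raise ValueError("vendor volume must be positive")


class VendorTable:
    """Grid of vendor predictions over power (W) × duration (min).

    The table must be a complete rectangular grid; each dimension is
    interpolated bilinearly and independently.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"power_w", "duration_min", *_METRICS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"vendor table missing columns: {sorted(missing)}")
        self.frame = frame.sort_values(["power_w", "duration_min"]).reset_index(drop=True)
        self.powers = np.unique(self.frame["power_w"].to_numpy(float))
        self.durations = np.unique(self.frame["duration_min"].to_numpy(float))
        if len(self.frame) != len(self.powers) * len(self.durations):
            raise ValueError("vendor table is not a complete power × duration grid")
        if (self.frame[list(_METRICS)] <= 0).any().any():
            raise ValueError("vendor table entries must be positive")
        self._grids = {}
        for m in _METRICS:
            g = self.frame[m].to_numpy(float).reshape(len(self.powers), len(self.durations))
            self._grids[m] = g
            if np.any(np.diff(g, axis=1) <= 0) and m in ("length_mm", "width_mm"):
                raise ValueError(f"vendor {m} must increase with duration at fixed power")

    @classmethod
    def from_csv(cls, path) -> "VendorTable":
        return cls(pd.read_csv(path))

    def _interp(self, metric: str, power: float, duration: float) -> float:
        g = self._grids[metric]
        if len(self.powers) == 1:
            # single-power table: 1-D interpolation over duration
            return float(np.interp(duration, self.durations, g[0]))
        f = RegularGridInterpolator(
            (self.powers, self.durations), g, method="linear",
            bounds_error=False, fill_value=None,
        )
        return float(f([[power, duration]])[0])

    def is_grid_point(self, power: float, duration: float) -> bool:
        return bool(np.any(np.isclose(self.powers, power)) and
                    np.any(np.isclose(self.durations, duration)))


def default_vendor_table() -> VendorTable:
    return VendorTable(pd.read_csv(io.StringIO(_DEFAULT_TABLE_CSV)))


def interpolate_vendor(
    table: VendorTable,
    power: float,
    duration: float,
    extrapolate: bool = False,
) -> VendorPrediction:
    """Bilinear interpolation of the vendor table at (power, duration).

    Settings outside the supported range (35–65 W, 1–10 min) raise unless
    ``extrapolate`` is set, in which case the query is clamped to the
    nearest supported setting covered by the table (e.g. the occasional
    20 W ablation is mapped to the 35 W column) and flagged.
    """
    in_range = (
        SUPPORTED_POWER[0] <= power <= SUPPORTED_POWER[1]
        and SUPPORTED_DURATION[0] <= duration <= SUPPORTED_DURATION[1]
    )
    p, d = float(power), float(duration)
    clamped = False
    if not in_range:
        if not extrapolate:
            raise ValueError(
                f"({power} W, {duration} min) outside the vendor-supported range "
                f"{SUPPORTED_POWER} W x {SUPPORTED_DURATION} min; "
                "pass extrapolate=True to clamp"
            )
        clamped = True
    # clamp to the table's own node range as well (partial tables)
    p2 = float(np.clip(p, table.powers[0], table.powers[-1]))
    d2 = float(np.clip(d, table.durations[0], table.durations[-1]))
    if (p2, d2) != (p, d):
        if not (extrapolate or clamped):
            raise ValueError(
                f"({power} W, {duration} min) outside the supplied table's node range; "
                "pass extrapolate=True to clamp"
            )
        clamped = True
    vals = {m: table._interp(m, p2, d2) for m in _METRICS}
    if clamped:
        prov = "extrapolated"
    elif table.is_grid_point(p2, d2):
        prov = "exact-grid"
    else:
        prov = "interpolated"
    return VendorPrediction(provenance=prov, **vals)


def synthesize_ellipsoid_mask(
    pred: VendorPrediction,
    grid_size: int = GRID_SIZE,
    spacing: float = GRID_SPACING,
) -> ACCSVolume:
    """Voxelize the vendor-predicted prolate ellipsoid on the ACCS grid.

    The long semi-axis (length/2) lies along the applicator axis; both
    transverse semi-axes are width/2; the distal pole is anchored
    ``tip_to_edge_mm`` beyond the tip (the origin), which fixes the axial
    placement the same way the tip-to-edge comparison is made.
    """
    a = pred.length_mm / 2.0
    b = pred.width_mm / 2.0
    zc = pred.tip_to_edge_mm - a  # centre offset along axis
    half = grid_size / 2.0 * spacing
    if pred.tip_to_edge_mm - pred.length_mm < -half or pred.tip_to_edge_mm > half - 1 \
            or b >= half:
        raise ValueError("vendor ellipsoid exceeds the ACCS grid")
    centre = grid_size // 2
    ax = (np.arange(grid_size) - centre) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = (x / b) ** 2 + (y / b) ** 2 + ((z - zc) / a) ** 2 <= 1.0
    return ACCSVolume(voxels=inside.astype(np.uint8), spacing=spacing)


def discrepancy_ratio(observed: float, vendor: float) -> float:
    """Natural log of observed/vendor for one metric (0 = perfect agreement)."""
    if observed <= 0 or vendor <= 0:
        raise ValueError("discrepancy ratio requires positive inputs")
    return float(np.log(observed / vendor))
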