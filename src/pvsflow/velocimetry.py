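"""Time-averaged flow fields and downstream-flow statistics.

Velocity samples pooled from all trajectories are binned on a 70×70 grid of
7.5×7.5 px bins; bins with at least 15 measurements define the time-averaged
flow field and its unit-vector field û_avg (the local direction of mean
flow). Each instantaneous velocity u is reduced to its *downstream
component* u·û_avg, from which the mean downstream speed and the backflow
fraction (share of retrograde samples) follow. Cross-PVS velocity profiles
are extracted along a user-chosen transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator


@dataclass(frozen=True)
class GridSpec:
    """Binning grid anchored at the padded-image origin.

    The canonical grid (70×70 bins of 7.5 px) extends past a 512 px image;
    trailing bins simply stay empty.
    """

    origin: tuple[float, float] = (0.0, 0.0)   # (x, y) px of bin (0, 0) corner
    bin_size: float = 7.5                      # px
    shape: tuple[int, int] = (70, 70)          # (ny, nx) bins


@dataclass
class MeanFlowField:
    """Per-bin time-averaged velocities, counts and unit vectors.

    ``mean_v[j, i]`` is the mean (vx, vy) of the samples in bin row j,
    column i; ``unit`` is û_avg, NaN where the bin is invalid (fewer than
    ``min_count`` samples or mean speed below ``min_speed``).
    """

    grid: GridSpec
    mean_v: np.ndarray     # (ny, nx, 2) μm/s, NaN where count == 0
    count: np.ndarray      # (ny, nx) int
    valid: np.ndarray      # (ny, nx) bool
    unit: np.ndarray       # (ny, nx, 2), NaN where invalid

    def to_dataframe(self) -> pd.DataFrame:
        ny, nx = self.count.shape
        jj, ii = np.mgrid[0:ny, 0:nx]
        return pd.DataFrame({
            "bin_i": ii.ravel(), "bin_j": jj.ravel(),
            "mean_vx": self.mean_v[..., 0].ravel(),
            "mean_vy": self.mean_v[..., 1].ravel(),
            "count": self.count.ravel(),
            "valid": self.valid.ravel(),
        })


def _bin_indices(x, y, grid: GridSpec):
    ix = np.floor((x - grid.origin[0]) / grid.bin_size).astype(int)
    iy = np.floor((y - grid.origin[1]) / grid.bin_size).astype(int)
    ny, nx = grid.shape
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    return ix, iy, inside


def bin_time_average(
    measurements: pd.DataFrame,
    grid: GridSpec = GridSpec(),
    min_count: int = 15,
    min_speed: float = 0.5,
) -> MeanFlowField:
    """Bin velocity samples into the grid and average per bin.

    Each sample lands in exactly one bin (half-open intervals). Bins with
    fewer than ``min_count`` samples, or whose mean speed is below
    ``min_speed`` μm/s (a numerically null mean defines no direction), are
    marked invalid and excluded from û_avg.
    """
    ny, nx = grid.shape
    count = np.zeros((ny, nx), int)
    sums = np.zeros((ny, nx, 2))
    if len(measurements):
        x = measurements["x_px"].to_numpy(float)
        y = measurements["y_px"].to_numpy(float)
        vx = measurements["vx_um_s"].to_numpy(float)
        vy = measurements["vy_um_s"].to_numpy(float)
        ix, iy, inside = _bin_indices(x, y, grid)
        np.add.at(count, (iy[inside], ix[inside]), 1)
        np.add.at(sums, (iy[inside], ix[inside], 0), vx[inside])
        np.add.at(sums, (iy[inside], ix[inside], 1), vy[inside])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_v = sums / count[..., None]
    speed = np.hypot(mean_v[..., 0], mean_v[..., 1])
    valid = (count >= min_count) & (speed > min_speed)
    unit = np.full_like(mean_v, np.nan)
    unit[valid] = mean_v[valid] / speed[valid, None]
    return MeanFlowField(grid=grid, mean_v=mean_v, count=count, valid=valid,
                         unit=unit)


def downstream_series(
    measurements: pd.DataFrame,
    fld: MeanFlowField,
) -> tuple[np.ndarray, int]:
    """Project every sample onto the local mean-flow direction.

    Returns (samples of u·û_avg in μm/s, number of samples excluded because
    they fell in invalid bins or outside the grid).
    """
    if len(measurements) == 0:
        return np.empty(0), 0
    x = measurements["x_px"].to_numpy(float)
    y = measurements["y_px"].to_numpy(float)
    vx = measurements["vx_um_s"].to_numpy(float)
    vy = measurements["vy_um_s"].to_numpy(float)
    ix, iy, inside = _bin_indices(x, y, fld.grid)
    ok = inside.copy()
    ok[inside] &= fld.valid[iy[inside], ix[inside]]
    u = fld.unit[iy[ok], ix[ok]]
    values = vx[ok] * u[:, 0] + vy[ok] * u[:, 1]
    return values, int(len(x) - ok.sum())


def mean_downstream_speed(samples: np.ndarray) -> float:
    """Mean of the downstream series over space and time (μm/s)."""
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("empty downstream series")
    return float(samples.mean())


def backflow_fraction(samples: np.ndarray) -> float:
    """Fraction of downstream samples that are retrograde (strictly < 0)."""
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("empty downstream series")
    return float((samples < 0).mean())


@dataclass
class TransectProfile:
    """Mean flow speed vs arc-length position along a transect.

    ``position`` are bin centers (px along the line); ``mean_speed`` raw bin
    means (NaN where a bin got no samples); ``smooth(s)`` a shape-preserving
    cubic interpolant through the non-empty bins.
    """

    position: np.ndarray
    mean_speed: np.ndarray
    count: np.ndarray
    line: tuple
    band_width: float

    def smooth(self, s: np.ndarray) -> np.ndarray:
        good = ~np.isnan(self.mean_speed)
        if good.sum() < 2:
            raise ValueError("too few occupied bins to interpolate")
        interp = PchipInterpolator(self.position[good], self.mean_speed[good])
        return interp(s)


def transect_profile(
    measurements: pd.DataFrame,
    line: tuple[tuple[float, float], tuple[float, float]],
    band_width: float,
    n_points: int = 15,
) -> TransectProfile:
    """Average flow-speed profile across a line spanning the PVS.

    Samples within ``band_width``/2 of the line are projected onto it and
    averaged (speed = |u|) in ``n_points`` equal arc-length bins; a smooth
    interpolant through the bin means accompanies the raw means. Raises if
    no samples fall in the band.
    """
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    (x0, y0), (x1, y1) = line
    p0 = np.array([x0, y0], float)
    direction = np.array([x1 - x0, y1 - y0], float)
    length = np.hypot(*direction)
    if length == 0:
        raise ValueError("line endpoints coincide")
    direction /= length

    xy = measurements[["x_px", "y_px"]].to_numpy(float) - p0
    s = xy @ direction
    perp = xy[:, 0] * (-direction[1]) + xy[:, 1] * direction[0]
    in_band = (np.abs(perp) <= band_width / 2) & (s >= 0) & (s <= length)
    if not in_band.any():
        raise ValueError("no velocity samples within the transect band")
    speed = np.hypot(measurements["vx_um_s"].to_numpy(float),
                     measurements["vy_um_s"].to_numpy(float))[in_band]
    s = s[in_band]
    edges = np.linspace(0, length, n_points + 1)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_points - 1)
    count = np.bincount(idx, minlength=n_points)
    sums = np.bincount(idx, weights=speed, minlength=n_points)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TransectProfile(position=centers, mean_speed=means, count=count,
                           line=line, band_width=band_width)
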