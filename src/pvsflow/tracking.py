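"""Predictive particle tracking and kernel velocimetry on single tracks.

Per-frame detections are linked into trajectories with a predictive
nearest-neighbour scheme: each active track forecasts its next position by
constant-velocity extrapolation from its last two points, and detections are
assigned to forecasts by minimum-total-cost bipartite matching within a
displacement gate. Velocities are obtained by convolving each position
series with a truncated derivative-of-Gaussian kernel normalized to be exact
on linear ramps, scaled to μm/s by the frame rate and pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_UNMATCHABLE = 1e12


@dataclass
class Trajectory:
    """One particle track: consecutive frames, sub-pixel positions, velocities.

    ``velocities`` (μm/s) is aligned with ``positions``; samples where the
    differentiation kernel window does not fit inside the track are NaN.
    """

    track_id: int
    start_frame: int
    positions: np.ndarray                 # (N, 2) px
    velocities: np.ndarray | None = None  # (N, 2) μm/s, NaN at the edges

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(len(self.positions))


@dataclass
class TrajectorySet:
    """Linked tracks plus the acquisition scales needed to interpret them."""

    trajectories: list[Trajectory]
    frame_rate: float
    pixel_size: float

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.trajectories:
            v = tr.velocities if tr.velocities is not None else np.full_like(
                tr.positions, np.nan)
            rows.append(pd.DataFrame({
                "track_id": tr.track_id,
                "frame": tr.frames,
                "x_px": tr.positions[:, 0],
                "y_px": tr.positions[:, 1],
                "vx_um_s": v[:, 0],
                "vy_um_s": v[:, 1],
            }))
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "x_px", "y_px",
                                         "vx_um_s", "vy_um_s"])
        return pd.concat(rows, ignore_index=True)

    def measurements(self) -> pd.DataFrame:
        """Flattened velocity samples (frame, x, y, vx, vy), NaN rows dropped."""
        df = self.to_dataframe()
        return df.dropna(subset=["vx_um_s", "vy_um_s"]).reset_index(drop=True)


def link_tracks(
    detections: pd.DataFrame,
    frame_rate: float,
    pixel_size: float,
    max_displacement: float = 5.0,
    min_track_length: int = 5,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    For each frame, active tracks predict their next position
    (constant-velocity extrapolation; a one-point track predicts its last
    position) and the detections within ``max_displacement`` px of a
    prediction are assigned by minimizing the total squared prediction
    error (Hungarian algorithm). Unassigned detections seed new tracks;
    tracks with no match terminate; tracks shorter than
    ``min_track_length`` frames are discarded. Linking is deterministic and
    invariant to the ordering of detections within a frame (detections are
    canonically sorted before matching).
    """
    cols = ["frame", "x_px", "y_px"]
    if len(detections) == 0:
        return TrajectorySet([], frame_rate, pixel_size)
    det = detections[cols].to_numpy(float)
    frames = det[:, 0].astype(int)
    order = np.lexsort((det[:, 2], det[:, 1], frames))
    det, frames = det[order], frames[order]

    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0

    for f in range(frames.min(), frames.max() + 1):
        pts = det[frames == f, 1:3]
        # forecasts for tracks that survived the previous frame
        if active and len(pts):
            preds = np.array([
                2 * tr["pos"][-1] - tr["pos"][-2] if len(tr["pos"]) >= 2
                else tr["pos"][-1]
                for tr in active
            ])
            d2 = ((preds[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            cost = np.where(d2 <= max_displacement**2, d2, _UNMATCHABLE)
            rows, cols_ = linear_sum_assignment(cost)
            matched_tracks, matched_dets = set(), set()
            for r, c in zip(rows, cols_):
                if cost[r, c] < _UNMATCHABLE:
                    active[r]["pos"].append(pts[c])
                    matched_tracks.add(r)
                    matched_dets.add(c)
        else:
            matched_tracks, matched_dets = set(), set()
        # terminate unmatched tracks
        still = []
        for r, tr in enumerate(active):
            if r in matched_tracks:
                still.append(tr)
            else:
                finished.append(tr)
        active = still
        # new tracks from unmatched detections (canonical order)
        for c in range(len(pts)):
            if c not in matched_dets:
                active.append({"id": next_id, "start": f, "pos": [pts[c]]})
                next_id += 1
    finished.extend(active)

    finished = [tr for tr in finished if len(tr["pos"]) >= min_track_length]
    finished.sort(key=lambda tr: tr["id"])
    trajectories = [
        Trajectory(track_id=i, start_frame=tr["start"],
                   positions=np.asarray(tr["pos"]))
        for i, tr in enumerate(finished)
    ]
    return TrajectorySet(trajectories, frame_rate, pixel_size)


def derivative_kernel(sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Derivative-of-Gaussian differentiation kernel, exact on linear ramps.

    Weights k[j] ∝ j·exp(−j²/2σ²) over j = −R…R (R = ceil(truncate·σ)),
    normalized so Σ j·k[j] = 1: applied by correlation, a unit-slope ramp
    returns exactly 1 and any constant returns 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = max(1, int(np.ceil(truncate * sigma)))
    j = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(j**2) / (2 * sigma**2))
    return j * g / np.sum(j**2 * g)


def differentiate_track(
    positions: np.ndarray,
    frame_rate: float,
    pixel_size: float,
    kernel_sigma: float = 1.0,
    truncate: float = 3.0,
) -> np.ndarray:
    """Velocities (μm/s) of one track by Gaussian smoothing/differentiation.

    Returns an array aligned with ``positions``; the R samples at each end,
    where the kernel window is not fully supported, are NaN. A track shorter
    than the kernel support yields all-NaN velocities.
    """
    pos = np.asarray(positions, float)
    k = derivative_kernel(kernel_sigma, truncate)
    r = (len(k) - 1) // 2
    out = np.full(pos.shape, np.nan)
    if len(pos) < len(k):
        return out
    scale = frame_rate * pixel_size
    for c in range(pos.shape[1]):
        out[r:len(pos) - r, c] = np.correlate(pos[:, c], k, mode="valid") * scale
    return out


def compute_velocities(
    tracks: TrajectorySet,
    kernel_sigma: float = 1.0,
    truncate: float = 3.0,
) -> TrajectorySet:
    """Fill in kernel velocities for every trajectory (in place; returned)."""
    for tr in tracks:
        tr.velocities = differentiate_track(
            tr.positions, tracks.frame_rate, tracks.pixel_size,
            kernel_sigma, truncate,
        )
    return tracks
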