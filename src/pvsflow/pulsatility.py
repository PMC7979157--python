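"""Flow pulsatility: Vrms, cardiac/respiratory conditional averages, delays.

The pulsatility signal is Vrms, the spatial root-mean-square particle speed
at each instant. Its relation to the physiological cycles is quantified two
ways: by conditional (phase) averaging of Vrms over the cardiac or
respiratory cycle, and by the distribution of the delay Δt from each
physiological peak (ECG R-wave or respiration maximum) to the next Vrms
peak — for cardiac-driven flow the Vrms peak follows the R-wave by a few
tens of milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .tracking import TrajectorySet


@dataclass
class VrmsSeries:
    """Per-frame spatial RMS velocity magnitude with sample counts.

    Frames with no velocity samples are NaN gaps, not zeros.
    """

    values: np.ndarray      # (T,) μm/s, NaN gaps
    counts: np.ndarray      # (T,) int
    frame_rate: float

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.values)),
            "time_s": self.times(),
            "vrms_um_s": self.values,
            "n_particles": self.counts,
        })


def vrms_series(tracks: TrajectorySet, n_frames: int | None = None) -> VrmsSeries:
    """Vrms(t) = sqrt(mean over particles of vx² + vy²) for each frame."""
    m = tracks.measurements()
    if n_frames is None:
        n_frames = int(m["frame"].max()) + 1 if len(m) else 0
    values = np.full(n_frames, np.nan)
    counts = np.zeros(n_frames, int)
    if len(m):
        sq = m["vx_um_s"].to_numpy() ** 2 + m["vy_um_s"].to_numpy() ** 2
        frames = m["frame"].to_numpy(int)
        keep = frames < n_frames
        sums = np.bincount(frames[keep], weights=sq[keep], minlength=n_frames)
        n = np.bincount(frames[keep], minlength=n_frames)
        counts = n
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n > 0, np.sqrt(sums / np.maximum(n, 1)), np.nan)
    return VrmsSeries(values=values, counts=counts, frame_rate=tracks.frame_rate)


def moving_mean(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving mean, NaN-aware, same length as the input."""
    v = np.asarray(values, float)
    good = np.isfinite(v)
    num = np.convolve(np.where(good, v, 0.0), np.ones(window), "same")
    den = np.convolve(good.astype(float), np.ones(window), "same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def detect_peaks(
    series: np.ndarray,
    sampling_rate: float,
    min_prominence: float | None = None,
    min_separation: float | None = None,
    smooth_window: int = 0,
) -> np.ndarray:
    """Peak times (s) of a sampled series with sub-sample refinement.

    Local maxima passing the prominence and separation gates are refined by
    parabolic interpolation of the three samples around each maximum.
    ``min_prominence`` defaults to 0.25 × the interquartile range of the
    series; ``min_separation`` is in seconds. ``smooth_window`` > 1 applies
    a centered moving mean first (suppresses shot noise in Vrms). NaN gaps
    are bridged by linear interpolation before peak finding.
    """
    v = np.asarray(series, float)
    if len(v) < 3:
        raise ValueError("series too short for peak detection")
    good = np.isfinite(v)
    if not good.any():
        return np.empty(0)
    idx = np.arange(len(v))
    v = np.interp(idx, idx[good], v[good])
    if smooth_window and smooth_window > 1:
        v = moving_mean(v, smooth_window)
    if min_prominence is None:
        q75, q25 = np.percentile(v, [75, 25])
        min_prominence = 0.25 * (q75 - q25)
    distance = None
    if min_separation is not None:
        distance = max(1, int(round(min_separation * sampling_rate)))
    peaks, _ = find_peaks(v, prominence=min_prominence, distance=distance)
    times = []
    for p in peaks:
        if 0 < p < len(v) - 1:
            denom = v[p - 1] - 2 * v[p] + v[p + 1]
            delta = 0.5 * (v[p - 1] - v[p + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        times.append((p + delta) / sampling_rate)
    return np.asarray(times)


def conditional_average(
    vrms: VrmsSeries,
    cycle_peaks: np.ndarray,
    n_phase_bins: int = 20,
) -> pd.DataFrame:
    """Average Vrms as a function of phase within a physiological cycle.

    Each Vrms sample between two consecutive cycle peaks is assigned the
    phase (t − t_prev)/(t_next − t_prev) ∈ [0, 1); per-bin mean and SEM are
    reported. Samples outside the recorded cycles are dropped.
    """
    peaks = np.asarray(cycle_peaks, float)
    if len(peaks) < 2:
        raise ValueError("need at least 2 cycle peaks to define a phase")
    t = vrms.times()
    v = vrms.values
    good = np.isfinite(v) & (t >= peaks[0]) & (t < peaks[-1])
    t, v = t[good], v[good]
    k = np.searchsorted(peaks, t, side="right") - 1
    phase = (t - peaks[k]) / (peaks[k + 1] - peaks[k])
    bins = np.clip((phase * n_phase_bins).astype(int), 0, n_phase_bins - 1)
    n = np.bincount(bins, minlength=n_phase_bins)
    s1 = np.bincount(bins, weights=v, minlength=n_phase_bins)
    s2 = np.bincount(bins, weights=v**2, minlength=n_phase_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean**2) / np.maximum(n - 1, 1), np.nan)
        sem = np.sqrt(var / np.maximum(n, 1))
    centers = (np.arange(n_phase_bins) + 0.5) / n_phase_bins
    return pd.DataFrame({"phase": centers, "mean": mean, "sem": sem, "n": n})


@dataclass
class DelayDistribution:
    """Samples and histogram of the physio-peak → Vrms-peak delay Δt."""

    delays: np.ndarray        # s, one per paired physiological peak
    bin_edges: np.ndarray
    density: np.ndarray       # integrates to 1 over the binned support
    mean: float
    sem: float

    @property
    def n(self) -> int:
        return len(self.delays)


def delay_distribution(
    vrms_peaks: np.ndarray,
    physio_peaks: np.ndarray,
    bin_width: float = 0.025,
    max_delay: float | None = None,
) -> DelayDistribution:
    """Distribution of the delay from each physiological peak to the next
    Vrms peak.

    For each physiological peak, Δt is the time to the first subsequent
    Vrms peak; peaks whose next Vrms peak falls beyond the following
    physiological peak are skipped (each Vrms peak is attributed to one
    cycle). The histogram is density-normalized with ``bin_width`` s bins.
    """
    vp = np.sort(np.asarray(vrms_peaks, float))
    pp = np.sort(np.asarray(physio_peaks, float))
    if len(vp) == 0 or len(pp) == 0:
        raise ValueError("both peak lists must be non-empty")
    delays = []
    for i, p in enumerate(pp[:-1]):
        nxt = pp[i + 1]
        j = np.searchsorted(vp, p, side="right")
        if j < len(vp) and vp[j] < nxt:
            delays.append(vp[j] - p)
    delays = np.asarray(delays)
    if len(delays) == 0:
        raise ValueError("no pairable peaks")
    if max_delay is None:
        max_delay = float(delays.max()) + bin_width
    edges = np.arange(0.0, max_delay + bin_width, bin_width)
    density, edges = np.histogram(delays, bins=edges, density=True)
    mean = float(delays.mean())
    sem = float(delays.std(ddof=1) / np.sqrt(len(delays))) if len(delays) > 1 else 0.0
    return DelayDistribution(delays=delays, bin_edges=edges, density=density,
                             mean=mean, sem=sem)


def time_binned_summary(vrms: VrmsSeries, bin_width: float) -> pd.DataFrame:
    """Mean ± SEM of Vrms in non-overlapping time bins.

    Bins with no finite samples are reported with NaN mean (empty, not
    zero).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = vrms.times()
    v = vrms.values
    n_bins = int(np.ceil((t[-1] + 1e-12) / bin_width)) if len(t) else 0
    rows = []
    for b in range(n_bins):
        sel = (t >= b * bin_width) & (t < (b + 1) * bin_width) & np.isfinite(v)
        vals = v[sel]
        rows.append({
            "t_center": (b + 0.5) * bin_width,
            "mean": vals.mean() if len(vals) else np.nan,
            "sem": (vals.std(ddof=1) / np.sqrt(len(vals))
                    if len(vals) > 1 else np.nan),
            "n": len(vals),
        })
    return pd.DataFrame(rows)
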