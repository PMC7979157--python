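"""Vrms, peak detection, conditional averaging, delay distributions."""

import numpy as np

import pytest

from pvsflow.pulsatility import (
    VrmsSeries,
    conditional_average,
    delay_distribution,
    detect_peaks,
    time_binned_summary,
    vrms_series,
)
from pvsflow.tracking import Trajectory, TrajectorySet


def _tracks_with_velocities(per_frame_velocities):
    """One trajectory per listed particle; velocities given per frame."""
    trajectories = []
    for i, vs in enumerate(per_frame_velocities):
        vs = np.asarray(vs, float)
        pos = np.zeros_like(vs)
        trajectories.append(Trajectory(track_id=i, start_frame=0,
                                       positions=pos, velocities=vs))
    return TrajectorySet(trajectories, frame_rate=30.0, pixel_size=1.29)


class TestVrms:
    def test_single_particle_speed(self):
        tracks = _tracks_with_velocities([np.tile([6.0, 8.0], (5, 1))])
        s = vrms_series(tracks)
        np.testing.assert_allclose(s.values, 10.0)

    def test_two_particle_closed_form(self):
        tracks = _tracks_with_velocities([
            np.tile([3.0, 0.0], (4, 1)), np.tile([0.0, 4.0], (4, 1)),
        ])
        s = vrms_series(tracks)
        np.testing.assert_allclose(s.values, np.sqrt(25.0 / 2.0))

    def test_invariant_to_rigid_rotation_and_order(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 5, (3, 6, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        s1 = vrms_series(_tracks_with_velocities(list(v)))
        s2 = vrms_series(_tracks_with_velocities([vi @ rot.T for vi in v[::-1]]))
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)

    def test_empty_frames_are_gaps(self):
        tracks = _tracks_with_velocities([np.tile([5.0, 0.0], (3, 1))])
        s = vrms_series(tracks, n_frames=6)
        assert np.isnan(s.values[4]) and s.counts[4] == 0


class TestPeaks:
    def test_sinusoid_peaks_at_period_spacing(self):
        rate, period = 200.0, 0.5
        t = np.arange(0, 5, 1 / rate)
        peaks = detect_peaks(np.sin(2 * np.pi * t / period), rate)
        expected = np.arange(period / 4, 5, period)
        assert len(peaks) == len(expected)
        assert np.max(np.abs(peaks - expected)) <= 1 / rate

    def test_monotone_series_no_peaks(self):
        assert len(detect_peaks(np.arange(50.0), 10.0)) == 0

    def test_parabolic_refinement_is_subsample(self):
        rate = 30.0
        t = np.arange(0, 3, 1 / rate)
        true_peak = 1.517  # deliberately off the sample grid
        series = np.exp(-((t - true_peak) ** 2) / (2 * 0.05**2))
        peaks = detect_peaks(series, rate, min_prominence=0.5)
        assert len(peaks) == 1
        assert abs(peaks[0] - true_peak) < 0.5 / rate


class TestConditionalAverage:
    def test_constant_signal_flat_curve(self):
        v = VrmsSeries(values=np.full(300, 8.0), counts=np.full(300, 5),
                       frame_rate=30.0)
        peaks = np.arange(0.5, 9.5, 1.0)
        cond = conditional_average(v, peaks, n_phase_bins=10)
        np.testing.assert_allclose(cond["mean"], 8.0)
        assert np.nanmax(cond["sem"]) < 1e-12

    def test_cosine_phase_signal_recovered(self):
        rate, period = 100.0, 1.0
        t = np.arange(0, 30, 1 / rate)
        phase = np.mod(t, period) / period
        v = VrmsSeries(values=np.cos(2 * np.pi * phase),
                       counts=np.ones(len(t), int), frame_rate=rate)
        peaks = np.arange(0.0, 30.0, period)
        cond = conditional_average(v, peaks, n_phase_bins=20)
        expected = np.cos(2 * np.pi * cond["phase"])
        assert np.nanmax(np.abs(cond["mean"] - expected)) < 0.05  # binning res.

    def test_doubling_bins_preserves_cycle_mean(self):
        rng = np.random.default_rng(1)
        v = VrmsSeries(values=rng.random(1000), counts=np.ones(1000, int),
                       frame_rate=30.0)
        peaks = np.arange(0.2, 33.0, 0.21)
        c1 = conditional_average(v, peaks, n_phase_bins=10)
        c2 = conditional_average(v, peaks, n_phase_bins=20)
        m1 = np.sum(c1["mean"] * c1["n"]) / c1["n"].sum()
        m2 = np.sum(c2["mean"] * c2["n"]) / c2["n"].sum()
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_single_peak_rejected(self):
        v = VrmsSeries(values=np.ones(10), counts=np.ones(10, int),
                       frame_rate=30.0)
        with pytest.raises(ValueError):
            conditional_average(v, [0.1])


class TestDelays:
    def test_fixed_lag_zero_variance(self):
        physio = np.arange(1.0, 10.0, 0.2)
        vrms = physio + 0.05
        dist = delay_distribution(vrms, physio)
        assert dist.mean == pytest.approx(0.05)
        assert dist.sem == pytest.approx(0.0, abs=1e-12)
        # density integrates to 1
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0)

    def test_vrms_peak_after_next_cycle_is_skipped(self):
        physio = np.array([1.0, 2.0, 3.0])
        vrms = np.array([2.5])  # pairs only with the 2.0 peak
        dist = delay_distribution(vrms, physio)
        np.testing.assert_allclose(dist.delays, [0.5])

    def test_uniform_peaks_give_flat_delay_distribution(self):
        # one Vrms peak uniformly placed inside each cycle -> uniform delays
        rng = np.random.default_rng(2)
        period = 0.2
        physio = np.arange(0.0, 400.0, period)
        vrms = physio[:-1] + rng.uniform(0, period, len(physio) - 1)
        dist = delay_distribution(vrms, physio, bin_width=0.05,
                                  max_delay=period)
        np.testing.assert_allclose(dist.density, 1 / period,
                                   rtol=0.06)  # ~2000 samples per bin
        assert dist.mean == pytest.approx(period / 2, rel=0.02)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            delay_distribution([], [1.0])
        with pytest.raises(ValueError):
            delay_distribution([0.5], [1.0, 2.0])  # nothing pairable


class TestTimeBinned:
    def test_constant_series_every_bin_equal(self):
        v = VrmsSeries(values=np.full(90, 4.0), counts=np.full(90, 3),
                       frame_rate=30.0)
        out = time_binned_summary(v, 1.0)
        np.testing.assert_allclose(out["mean"], 4.0)

    def test_gap_bin_marked_empty_not_zero(self):
        vals = np.full(90, 4.0)
        vals[30:60] = np.nan
        v = VrmsSeries(values=vals, counts=np.full(90, 1), frame_rate=30.0)
        out = time_binned_summary(v, 1.0)
        assert np.isnan(out.loc[1, "mean"]) and out.loc[1, "n"] == 0

    def test_stationary_series_has_no_trend(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        v = VrmsSeries(values=10 + rng.normal(0, 1, 3000),
                       counts=np.ones(3000, int), frame_rate=30.0)
        out = time_binned_summary(v, 5.0)
        fit = stats.linregress(out["t_center"], out["mean"])
        assert fit.pvalue > 0.01  # slope CI contains zero

    def test_invalid_bin_width(self):
        v = VrmsSeries(values=np.ones(10), counts=np.ones(10, int),
                       frame_rate=30.0)
        with pytest.raises(ValueError):
            time_binned_summary(v, 0.0)
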