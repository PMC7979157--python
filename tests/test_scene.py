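"""Generator-level checks: physiology, flow field, advection, rendering."""

import numpy as np
import pytest

from pvsflow import SceneConfig, flow_velocity, generate_physio
from pvsflow.pulsatility import detect_peaks
from pvsflow.scene import (
    ChannelGeometry,
    _parabolic_profile,
    advect_particles,
    default_geometry,
    modulation,
    render_stack,
    simulate,
)


@pytest.fixture()
def small_cfg():
    # smooth flow (no sub-frame cardiac pulses) so RK4 at the frame
    # interval is in its convergent regime
    return SceneConfig(image_size=(96, 96), duration=2.0, n_particles=8,
                       stagnant_fraction=0.0, diffusivity=0.0,
                       cardiac_amplitude=0.0, rng_seed=1)


class TestPhysio:
    def test_length_and_periodic_events(self):
        trace = generate_physio(1000, 2.0, 5.0, "ecg", seed=0)
        assert len(trace.values) == 2000
        expected = np.arange(0.2, 2.0, 0.2)
        np.testing.assert_allclose(trace.event_times, expected, atol=1e-9)

    def test_jittered_events_recovered_by_peak_detection(self):
        trace = generate_physio(1000, 5.0, 5.0, "ecg", seed=3, cycle_jitter=0.05)
        peaks = detect_peaks(trace.values, trace.rate, min_prominence=0.5,
                             min_separation=0.1)
        assert len(peaks) == len(trace.event_times)
        # within one sample of the stored ground-truth events
        assert np.max(np.abs(peaks - trace.event_times)) <= 1.0 / trace.rate

    def test_respiration_peaks_at_events(self):
        trace = generate_physio(250, 4.0, 1.7, "resp", seed=0)
        t = trace.times()
        for e in trace.event_times:
            i = np.argmin(np.abs(t - e))
            assert trace.values[i] >= 0.999

    @pytest.mark.parametrize("kwargs", [
        dict(rate=0, duration=1, event_rate=1),
        dict(rate=100, duration=-1, event_rate=1),
        dict(rate=8, duration=1, event_rate=5),  # below Nyquist margin
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_physio(**kwargs)


class TestFlowField:
    def test_wall_zero_centerline_v0(self):
        cfg = SceneConfig(cardiac_amplitude=0.0, respiratory_amplitude=0.0,
                          centerline_speed=40.0)
        (y0, y1), _ = cfg.resolved_geometry.channels
        v_wall = flow_velocity(cfg, [[100.0, y0], [100.0, y1]], 0.3)
        np.testing.assert_allclose(v_wall, 0.0, atol=1e-12)
        v_mid = flow_velocity(cfg, [[100.0, (y0 + y1) / 2]], 0.3)
        np.testing.assert_allclose(v_mid, [[40.0, 0.0]], atol=1e-12)
        v_out = flow_velocity(cfg, [[100.0, 5.0]], 0.3)
        np.testing.assert_allclose(v_out, 0.0, atol=1e-12)

    def test_cross_channel_mean_is_two_thirds(self):
        # analytic: ∫ 4ŷ(1-ŷ) dŷ over [0,1] = 2/3
        geo = ChannelGeometry(channels=((10.0, 40.0),), artery_band=(40.0, 60.0))
        y = np.linspace(10.0, 40.0, 200001)
        assert abs(np.trapezoid(_parabolic_profile(y, geo), y) / 30.0 - 2 / 3) < 1e-6

    def test_modulation_locked_to_ecg_with_lag(self):
        # resolve the narrow cardiac pulses on the physiology clock (1 kHz)
        cfg = SceneConfig(cardiac_amplitude=0.02, cardiac_lag=0.05,
                          respiratory_amplitude=0.0, heart_rate=5.0)
        events = np.arange(1, 40) / cfg.heart_rate
        rate = 1000.0
        t = np.arange(0, 8.0, 1 / rate)
        m = modulation(cfg, t, ecg_events=events)
        train = np.zeros_like(t)
        train[np.round(events * rate).astype(int)] = 1.0
        lags = np.arange(0, 101)  # 0–100 ms
        xc = [np.dot(np.roll(train, k), m - m.mean()) for k in lags]
        best = lags[int(np.argmax(xc))] / rate
        assert abs(best - cfg.cardiac_lag) <= 1 / 30.0

    def test_clip_modulation_forbids_reversal(self):
        cfg = SceneConfig(cardiac_amplitude=0.0, respiratory_amplitude=3.0,
                          clip_modulation=True)
        t = np.linspace(0, 2, 500)
        assert modulation(cfg, t).min() >= 0.0


class TestAdvection:
    def test_zero_flow_keeps_positions(self, small_cfg):
        cfg = SceneConfig(**{**small_cfg.__dict__, "centerline_speed": 0.0,
                             "cardiac_amplitude": 0.0,
                             "respiratory_amplitude": 0.0})
        truth = advect_particles(cfg, n_frames=20)
        for _, g in truth.trajectories.groupby("particle_id"):
            assert g["x_px"].nunique() == 1 and g["y_px"].nunique() == 1

    def test_uniform_field_closed_form_displacement(self, small_cfg):
        u = np.array([25.8, 0.0])  # μm/s

        def field(pos, t):
            return np.broadcast_to(u, np.shape(pos)).copy()

        truth = advect_particles(small_cfg, n_frames=10, velocity_fn=field)
        step = u[0] / small_cfg.pixel_size / small_cfg.frame_rate
        for _, g in truth.trajectories.groupby("particle_id"):
            g = g.sort_values("frame")
            dx = np.diff(g["x_px"].to_numpy())
            if len(dx) and np.all(np.abs(dx) < 5):  # ignore wrap steps
                np.testing.assert_allclose(dx, step, atol=1e-9)

    def test_substep_refinement_converges(self, small_cfg):
        coarse = advect_particles(small_cfg, n_frames=30, seed=2)
        fine_cfg = SceneConfig(**{**small_cfg.__dict__, "substeps": 2})
        fine = advect_particles(fine_cfg, n_frames=30, seed=2)
        a = coarse.trajectories.set_index(["particle_id", "frame"])
        b = fine.trajectories.set_index(["particle_id", "frame"])
        common = a.index.intersection(b.index)
        diff = (a.loc[common, ["x_px", "y_px"]]
                - b.loc[common, ["x_px", "y_px"]]).abs().to_numpy()
        assert diff.max() < 1e-3  # px; smooth flow, RK4 headroom

    def test_stagnant_particles_never_move(self):
        cfg = SceneConfig(image_size=(96, 96), duration=2.0, n_particles=10,
                          stagnant_fraction=0.5, rng_seed=4)
        truth = advect_particles(cfg)
        stag = truth.trajectories[truth.trajectories["stagnant"]]
        assert set(stag["particle_id"]) == set(truth.stagnant_ids)
        for _, g in stag.groupby("particle_id"):
            assert g["x_px"].nunique() == 1 and g["y_px"].nunique() == 1
            assert (g[["vx_um_s", "vy_um_s"]] == 0).all().all()


class TestRendering:
    def test_no_particles_no_noise_is_blank(self):
        cfg = SceneConfig(image_size=(64, 64), duration=0.5, n_particles=0,
                          background_level=0.0, read_noise=0.0,
                          shot_noise=False, jitter_amplitude=0.0, rng_seed=0)
        stack = render_stack(advect_particles(cfg), cfg)
        assert stack.red.max() == 0

    def test_blob_mass_conservation(self):
        cfg = SceneConfig(image_size=(96, 96), duration=0.5, n_particles=6,
                          stagnant_fraction=0.0, background_level=0.0,
                          read_noise=0.0, shot_noise=False,
                          jitter_amplitude=0.0, rng_seed=6)
        truth = advect_particles(cfg)
        stack = render_stack(truth, cfg)
        blob_integral = 2 * np.pi * cfg.psf_sigma**2 * cfg.blob_amplitude
        for f in range(stack.n_frames):
            n_vis = (truth.trajectories["frame"] == f).sum()
            total = float(stack.red[f].sum())
            assert abs(total - n_vis * blob_integral) < 0.02 * n_vis * blob_integral

    def test_blob_occupies_3_to_4_pixels_above_threshold(self):
        # typical sub-pixel placement; detection threshold of the pipeline
        # on default-noise scenes sits near 50 counts
        from pvsflow.scene import _add_blobs

        cfg = SceneConfig()
        frame = np.zeros((32, 32))
        _add_blobs(frame, [15.3], [16.7], cfg.blob_amplitude, cfg.psf_sigma)
        footprint = int((frame >= 50.0).sum())
        assert footprint in (3, 4)

    def test_determinism_bit_identical(self):
        cfg = SceneConfig(image_size=(64, 64), duration=0.5, n_particles=5,
                          rng_seed=9)
        s1, t1 = simulate(cfg)
        s2, t2 = simulate(cfg)
        np.testing.assert_array_equal(s1.red, s2.red)
        np.testing.assert_array_equal(s1.green, s2.green)
        assert t1.trajectories.equals(t2.trajectories)
        np.testing.assert_array_equal(t1.true_shifts, t2.true_shifts)

    def test_saturation_warns_and_clips(self):
        cfg = SceneConfig(image_size=(48, 48), duration=0.2, n_particles=3,
                          stagnant_fraction=0.0, blob_amplitude=80000.0,
                          shot_noise=False, read_noise=0.0, rng_seed=2)
        truth = advect_particles(cfg, n_frames=3)
        with pytest.warns(RuntimeWarning, match="16-bit"):
            stack = render_stack(truth, cfg)
        assert stack.red.max() == 65535


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(centerline_speed=-1.0),
        dict(stagnant_fraction=1.5),
        dict(heart_rate=1.0, resp_rate=2.0),
        dict(geometry=ChannelGeometry(channels=((10.0, 600.0),),
                                      artery_band=(0.0, 5.0))),
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SceneConfig(**kwargs)

    def test_default_geometry_inside_image(self):
        geo = default_geometry((512, 512))
        for y0, y1 in geo.channels:
            assert 0 < y0 < y1 < 511
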