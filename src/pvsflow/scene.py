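"""Synthetic two-photon perivascular-flow scenes with ground truth.

Emulates in vivo two-photon movies of 1 μm fluorescent microspheres carried
by pulsatile cerebrospinal-fluid flow in the perivascular spaces (PVSs)
flanking a pial artery: the red channel renders Gaussian-blob tracers over a
noisy background, the green channel a static artery band with texture; the
whole scene jitters rigidly frame to frame (animal motion) and synchronized
ECG / respiration traces are generated on their own clocks.

The flow model is a steady parabolic (Poiseuille-like) downstream profile in
each PVS lane, zero at the walls, modulated in time by a cardiac pulse train
(velocity peaks lag the ECG R-wave by a configurable delay) and a smooth
respiratory oscillation. Exact trajectories, frame shifts and physiological
event times are kept as ground truth so every downstream analysis stage can
be validated against the generator.

Coordinates: pixel centers at integer coordinates, origin at the top-left,
x rightward (columns), y downward (rows), 0-based; flow is along +x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack

__all__ = [
    "PhysioTrace",
    "ChannelGeometry",
    "SceneConfig",
    "GroundTruth",
    "generate_physio",
    "default_geometry",
    "flow_velocity",
    "advect_particles",
    "render_stack",
    "simulate",
]


@dataclass(frozen=True)
class PhysioTrace:
    """A physiological recording: sampled values plus ground-truth event times.

    ``event_times`` are the true beat (R-wave) or breath times in seconds; for
    traces read from disk they are empty and must be recovered by peak
    detection.
    """

    rate: float
    values: np.ndarray
    event_times: np.ndarray

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate


def generate_physio(
    rate: float,
    duration: float,
    event_rate: float,
    waveform: str = "ecg",
    seed=None,
    cycle_jitter: float = 0.0,
    noise_level: float = 0.0,
) -> PhysioTrace:
    """Generate an ECG-like spike train or a smooth respiration trace.

    Events occur once per cycle; with ``cycle_jitter`` > 0 each cycle length
    is perturbed by a Gaussian factor (fractional s.d.), which keeps heart
    beats from locking to the imaging frame grid. The first event falls one
    mean period after t=0.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz (1000 for ECG, 250 for respiration in the
        emulated acquisition). Must exceed 2×``event_rate``.
    duration : float
        Trace length in seconds; the trace has ``round(rate*duration)``
        samples.
    event_rate : float
        Mean beats/breaths per second.
    waveform : {"ecg", "resp"}
        "ecg": sharp Gaussian R-wave spikes (σ = 5 ms) on a flat baseline.
        "resp": unit-amplitude cosine whose maxima coincide with the events.
    """
    if rate <= 0 or duration <= 0 or event_rate <= 0:
        raise ValueError("rate, duration and event_rate must be positive")
    if rate <= 2 * event_rate:
        raise ValueError("sampling rate must exceed twice the event rate")
    rng = np.random.default_rng(seed)
    period = 1.0 / event_rate
    n_events = int(np.ceil(duration * event_rate)) + 2
    periods = period * (1.0 + cycle_jitter * rng.standard_normal(n_events))
    periods = np.clip(periods, 0.3 * period, 3.0 * period)
    all_events = np.cumsum(periods)  # extends slightly past the trace
    events = all_events[all_events < duration - 1e-9]

    n = int(round(rate * duration))
    t = np.arange(n) / rate
    if waveform == "ecg":
        values = np.zeros(n)
        sigma = 0.005  # R-wave width, s
        half = int(np.ceil(4 * sigma * rate))
        for e in events:
            i = int(round(e * rate))
            lo, hi = max(0, i - half), min(n, i + half + 1)
            values[lo:hi] += np.exp(-((t[lo:hi] - e) ** 2) / (2 * sigma**2))
    elif waveform == "resp":
        values = np.cos(2 * np.pi * _event_phase(t, all_events))
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    if noise_level > 0:
        values = values + noise_level * rng.standard_normal(n)
    return PhysioTrace(rate=float(rate), values=values, event_times=events)


def _event_phase(t, events):
    """Continuous phase (in cycles) that is integer k at the k-th event.

    Linear between events; extrapolated with the first/last cycle length
    outside the recorded events.
    """
    events = np.asarray(events, float)
    if len(events) < 2:
        raise ValueError("need at least 2 events to define a phase")
    # pad one synthetic event on each side so np.interp extrapolates linearly
    ev = np.concatenate(
        [[events[0] - (events[1] - events[0])], events,
         [events[-1] + (events[-1] - events[-2])]]
    )
    k = np.arange(-1, len(events) + 1, dtype=float)
    return np.interp(t, ev, k)


@dataclass(frozen=True)
class ChannelGeometry:
    """Two PVS lanes flanking a central artery band; flow along +x.

    ``channels`` are (y_top, y_bottom) wall positions in px for each lane;
    ``artery_band`` the y-extent of the (static, bright-green) artery.
    """

    channels: tuple[tuple[float, float], ...]
    artery_band: tuple[float, float]


def default_geometry(image_size: tuple[int, int]) -> ChannelGeometry:
    """Proportional default: artery spans 42–58% of the height, one PVS lane
    of width 0.12×H on each side (≈ 60 px ≈ 80 μm at 512 px / 1.29 μm px)."""
    h = image_size[0]
    return ChannelGeometry(
        channels=((0.30 * h, 0.42 * h), (0.58 * h, 0.70 * h)),
        artery_band=(0.42 * h, 0.58 * h),
    )


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults emulate the acquisition this pipeline targets: 512×512 px at
    30 Hz, 1.29 μm/px, ECG at 1 kHz and respiration at 250 Hz, particles
    resolved over 3–4 px above the detection threshold, centerline speeds of
    tens of μm/s with a cardiac-locked pulsation lagging the R-wave by
    ~0.05 s, heart/respiration rates typical of ketamine/xylazine-
    anesthetized mice.
    """

    image_size: tuple[int, int] = (512, 512)
    frame_rate: float = 30.0          # Hz
    pixel_size: float = 1.29          # μm/px
    duration: float = 10.0            # s
    geometry: ChannelGeometry | None = None
    centerline_speed: float = 25.0    # V0, μm/s at the lane centerline
    cardiac_amplitude: float = 0.02   # a_c, weight of the unit-area pulse train
    cardiac_lag: float = 0.05         # s, velocity peak after the ECG R-wave
    respiratory_amplitude: float = 0.05  # a_r, weight of the respiratory cosine
    heart_rate: float = 5.0           # Hz
    resp_rate: float = 1.7            # Hz
    heart_jitter: float = 0.02        # fractional s.d. of the cardiac period
    resp_jitter: float = 0.0
    pulse_width_fraction: float = 0.15  # cardiac pulse width / cardiac period
    clip_modulation: bool = False     # clamp M(t) at 0 (no flow reversal)
    n_particles: int = 50
    stagnant_fraction: float = 0.1    # adhered particles that never move
    diffusivity: float = 0.6          # μm²/s; Stokes-Einstein, 1 μm sphere, 37°C
    psf_sigma: float = 0.6            # px; blob occupies 3–4 px above threshold
    blob_amplitude: float = 300.0     # counts above background at blob peak
    background_level: float = 300.0   # counts
    read_noise: float = 5.0           # counts, Gaussian
    shot_noise: bool = True           # Poisson noise on background + signal
    jitter_amplitude: float = 1.0     # px, per-frame rigid scene translation
    ecg_rate: float = 1000.0          # Hz
    resp_sample_rate: float = 250.0   # Hz
    substeps: int = 1                 # RK4 sub-steps per frame interval
    rng_seed: int = 0

    def __post_init__(self):
        if self.centerline_speed < 0:
            raise ValueError("centerline_speed must be >= 0")
        if not 0.0 <= self.stagnant_fraction <= 1.0:
            raise ValueError("stagnant_fraction must lie in [0, 1]")
        if not self.heart_rate > self.resp_rate > 0:
            raise ValueError("need heart_rate > resp_rate > 0")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        geo = self.resolved_geometry
        h, w = self.image_size
        for y0, y1 in geo.channels:
            if not (0 <= y0 < y1 <= h - 1):
                raise ValueError("channel walls must lie inside the image")

    @property
    def resolved_geometry(self) -> ChannelGeometry:
        return self.geometry if self.geometry is not None else default_geometry(
            self.image_size
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Everything the generator knows: trajectories, shifts, physiology.

    ``trajectories`` columns: particle_id, frame, x_px, y_px, vx_um_s,
    vy_um_s, stagnant. ``true_shifts`` is the per-frame rigid scene
    translation (dx, dy) in px.
    """

    trajectories: pd.DataFrame
    true_shifts: np.ndarray
    ecg: PhysioTrace
    respiration: PhysioTrace
    stagnant_ids: frozenset
    config: SceneConfig

    @property
    def n_frames(self) -> int:
        return len(self.true_shifts)


def _parabolic_profile(y, geometry: ChannelGeometry):
    """P(y): 1 at each lane centerline, 0 at the walls, 0 outside lanes."""
    y = np.asarray(y, float)
    p = np.zeros_like(y)
    for y0, y1 in geometry.channels:
        inside = (y >= y0) & (y <= y1)
        yh = (y - y0) / (y1 - y0)
        p = np.where(inside, 4.0 * yh * (1.0 - yh), p)
    return p


def _pulse_train(t, events, width):
    """Sum of unit-area raised-cosine pulses of the given width centered on
    each event time. Scalar or array ``t``."""
    t = np.asarray(t, float)
    events = np.asarray(events, float)
    if len(events) == 0:
        return np.zeros_like(t)
    idx = np.clip(np.searchsorted(events, t), 0, len(events) - 1)
    # nearest of the two neighbouring events
    lo = np.clip(idx - 1, 0, len(events) - 1)
    d_hi = np.abs(t - events[idx])
    d_lo = np.abs(t - events[lo])
    d = np.minimum(d_hi, d_lo)
    out = np.where(d < width / 2, (1.0 / width) * (1.0 + np.cos(2 * np.pi * d / width)), 0.0)
    return out


def modulation(config: SceneConfig, t, ecg_events=None, resp_events=None):
    """Temporal flow modulation M(t) = 1 + a_c·g(t−L) + a_r·h(t).

    g is a unit-area raised-cosine pulse train locked to the ECG events and
    shifted by the cardiac lag L; h a unit cosine locked to respiration.
    With ``clip_modulation`` the result is clamped at zero (no reversal);
    otherwise negative M means transient retrograde flow.
    """
    t = np.asarray(t, float)
    m = np.ones_like(t)
    if config.cardiac_amplitude != 0.0:
        if ecg_events is None:
            n = int(np.ceil((np.max(t) + 1) * config.heart_rate)) + 2
            ecg_events = np.arange(1, n + 1) / config.heart_rate
        width = config.pulse_width_fraction / config.heart_rate
        m = m + config.cardiac_amplitude * _pulse_train(
            t - config.cardiac_lag, ecg_events, width
        )
    if config.respiratory_amplitude != 0.0:
        if resp_events is None or len(np.atleast_1d(resp_events)) < 2:
            h = np.cos(2 * np.pi * config.resp_rate * t)
        else:
            h = np.cos(2 * np.pi * _event_phase(t, resp_events))
        m = m + config.respiratory_amplitude * h
    if config.clip_modulation:
        m = np.maximum(m, 0.0)
    return m


def flow_velocity(
    config: SceneConfig,
    position,
    time: float,
    ecg_events=None,
    resp_events=None,
) -> np.ndarray:
    """Flow velocity (μm/s) at pixel positions (..., 2) and a scalar time.

    Downstream (x) component = V0 · P(y) · M(t); cross-channel component is
    zero. Positions outside every lane get zero velocity. Passing the
    generator's actual (jittered) event lists phase-locks the modulation to
    the rendered physiology.
    """
    position = np.asarray(position, float)
    y = position[..., 1]
    p = _parabolic_profile(y, config.resolved_geometry)
    m = modulation(config, float(time), ecg_events, resp_events)
    v = np.zeros_like(position)
    v[..., 0] = config.centerline_speed * p * m
    return v


def advect_particles(
    config: SceneConfig,
    n_frames: int | None = None,
    seed=None,
    velocity_fn=None,
) -> GroundTruth:
    """Integrate tracer particles through the flow and record ground truth.

    Mobile particles are advanced with fixed-step RK4 at the frame interval
    (``config.substeps`` sub-steps) and receive a Brownian kick per frame
    (``config.diffusivity``, reflecting at the lane walls) so the tracer
    samples the whole channel cross-section; stagnant particles never move
    and are recorded with zero velocity. Recorded ground-truth velocities
    are the advective flow velocities (diffusion is displacement noise, not
    flow). A particle leaving the field of view along x is retired and a
    fresh particle id enters at the opposite lane edge at the same y
    (periodic wrap, preserving a spatially uniform seeding density).
    Physiological traces are generated here so the flow modulation is
    phase-locked to them.

    ``velocity_fn(positions_px, t) -> μm/s`` overrides the scene flow (used
    for integrator validation).
    """
    if n_frames is None:
        n_frames = config.n_frames
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    seed = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 0xA0])
    s_ecg, s_resp, s_part, s_jit = ss.spawn(4)

    duration = n_frames / config.frame_rate
    ecg = generate_physio(
        config.ecg_rate, duration + 1.0, config.heart_rate, "ecg",
        seed=s_ecg, cycle_jitter=config.heart_jitter,
    )
    resp = generate_physio(
        config.resp_sample_rate, duration + 1.0, config.resp_rate, "resp",
        seed=s_resp, cycle_jitter=config.resp_jitter,
    )
    if velocity_fn is None:
        def velocity_fn(pos, t):
            return flow_velocity(config, pos, t, ecg.event_times, resp.event_times)

    rng = np.random.default_rng(s_part)
    h, w = config.image_size
    geo = config.resolved_geometry
    n = config.n_particles
    n_stagnant = int(round(config.stagnant_fraction * n))

    widths = np.array([y1 - y0 for y0, y1 in geo.channels])
    lanes = rng.choice(len(geo.channels), size=n, p=widths / widths.sum())
    y0s = np.array([c[0] for c in geo.channels])
    pos = np.column_stack(
        [rng.uniform(0, w - 1, n), y0s[lanes] + rng.uniform(0, 1, n) * widths[lanes]]
    )
    stagnant_ids = frozenset(
        int(i) for i in rng.choice(n, size=n_stagnant, replace=False)
    ) if n else frozenset()
    mobile = np.ones(n, bool)
    mobile[list(stagnant_ids)] = False
    ids = np.arange(n)
    next_id = n

    dt_frame = 1.0 / config.frame_rate
    dt = dt_frame / max(1, int(config.substeps))
    rows_id, rows_f, rows_x, rows_y, rows_vx, rows_vy, rows_st = (
        [], [], [], [], [], [], []
    )

    for f in range(n_frames):
        t = f * dt_frame
        v = velocity_fn(pos, t)
        v = np.where(mobile[:, None], v, 0.0)
        rows_id.append(ids.copy())
        rows_f.append(np.full(len(ids), f))
        rows_x.append(pos[:, 0].copy())
        rows_y.append(pos[:, 1].copy())
        rows_vx.append(v[:, 0].copy())
        rows_vy.append(v[:, 1].copy())
        rows_st.append(~mobile)
        if f == n_frames - 1:
            break
        # RK4 in pixel units
        px = config.pixel_size
        p = pos[mobile]
        tau = t
        for _ in range(max(1, int(config.substeps))):
            k1 = velocity_fn(p, tau) / px
            k2 = velocity_fn(p + 0.5 * dt * k1, tau + 0.5 * dt) / px
            k3 = velocity_fn(p + 0.5 * dt * k2, tau + 0.5 * dt) / px
            k4 = velocity_fn(p + dt * k3, tau + dt) / px
            p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tau += dt
        if config.diffusivity > 0:
            sigma = np.sqrt(2.0 * config.diffusivity * dt_frame) / config.pixel_size
            p = p + rng.normal(0.0, sigma, p.shape)
            p[:, 1] = _reflect_into_lanes(p[:, 1], geo)
        pos[mobile] = p
        # periodic wrap along x with fresh particle ids
        span = w - 1.0
        out = mobile & ((pos[:, 0] < 0) | (pos[:, 0] > span))
        if out.any():
            pos[out, 0] = np.mod(pos[out, 0], span)
            n_out = int(out.sum())
            ids = ids.copy()
            ids[out] = np.arange(next_id, next_id + n_out)
            next_id += n_out

    traj = pd.DataFrame(
        {
            "particle_id": np.concatenate(rows_id),
            "frame": np.concatenate(rows_f),
            "x_px": np.concatenate(rows_x),
            "y_px": np.concatenate(rows_y),
            "vx_um_s": np.concatenate(rows_vx),
            "vy_um_s": np.concatenate(rows_vy),
            "stagnant": np.concatenate(rows_st),
        }
    )
    jit_rng = np.random.default_rng(s_jit)
    shifts = jit_rng.uniform(
        -config.jitter_amplitude, config.jitter_amplitude, size=(n_frames, 2)
    )
    return GroundTruth(
        trajectories=traj,
        true_shifts=shifts,
        ecg=ecg,
        respiration=resp,
        stagnant_ids=stagnant_ids,
        config=config,
    )


def _reflect_into_lanes(y, geometry: ChannelGeometry):
    """Reflect y-coordinates at the walls of whichever lane each is nearest.

    Brownian kicks are small relative to the lane width, so a single
    reflection suffices.
    """
    y = np.asarray(y, float).copy()
    centers = np.array([(y0 + y1) / 2 for y0, y1 in geometry.channels])
    lane = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
    for li, (y0, y1) in enumerate(geometry.channels):
        sel = lane == li
        y[sel] = np.where(y[sel] < y0, 2 * y0 - y[sel], y[sel])
        y[sel] = np.where(y[sel] > y1, 2 * y1 - y[sel], y[sel])
        y[sel] = np.clip(y[sel], y0, y1)
    return y


def _add_blobs(frame, xs, ys, amplitude, sigma):
    """Accumulate isotropic Gaussian blobs (point-sampled) into ``frame``."""
    h, w = frame.shape
    r = int(np.ceil(4 * sigma))
    for x, y in zip(xs, ys):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - x
        gy = np.arange(y0, y1) - y
        frame[y0:y1, x0:x1] += amplitude * np.exp(
            -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma**2)
        )


def render_stack(truth: GroundTruth, config: SceneConfig | None = None,
                 seed=None) -> ImageStack:
    """Render the two-channel 16-bit movie for a ground-truth scene.

    Red channel: Gaussian blobs (σ = ``psf_sigma``) at the jittered particle
    positions over a flat background, with optional Poisson shot noise and
    Gaussian read noise. Green channel: a static artery band plus a smooth
    speckle texture (vessel-wall features), rigidly shifted by the per-frame
    jitter. Intensities above the 16-bit range raise a warning and are
    clipped.
    """
    config = config or truth.config
    seed = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 0xB1])
    s_noise, s_tex = ss.spawn(2)
    rng = np.random.default_rng(s_noise)

    h, w = config.image_size
    n_frames = truth.n_frames
    traj = truth.trajectories
    by_frame = {f: g for f, g in traj.groupby("frame")}

    geo = config.resolved_geometry
    tex_rng = np.random.default_rng(s_tex)
    texture = np.full((h, w), 100.0)
    yb0, yb1 = geo.artery_band
    yy = np.arange(h)
    texture[(yy >= yb0) & (yy <= yb1)] += 800.0
    texture += ndimage.gaussian_filter(tex_rng.standard_normal((h, w)), 3.0) * 400.0
    texture = np.clip(texture, 0.0, None)

    red = np.empty((n_frames, h, w), np.uint16)
    green = np.empty((n_frames, h, w), np.uint16)
    saturated = False
    for f in range(n_frames):
        dx, dy = truth.true_shifts[f]
        frame = np.full((h, w), float(config.background_level))
        g = by_frame.get(f)
        if g is not None and len(g):
            _add_blobs(frame, g["x_px"].to_numpy() + dx,
                       g["y_px"].to_numpy() + dy,
                       config.blob_amplitude, config.psf_sigma)
        gframe = ndimage.shift(texture, (dy, dx), order=1, mode="nearest")
        if frame.max() > 65535 or gframe.max() > 65535:
            saturated = True
        for chan, img in ((red, frame), (green, gframe)):
            if config.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if config.read_noise > 0:
                img = img + config.read_noise * rng.standard_normal((h, w))
            chan[f] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    if saturated:
        warnings.warn("blob or background intensity exceeds the 16-bit range; "
                      "values were clipped", RuntimeWarning, stacklevel=2)
    return ImageStack(red=red, green=green, frame_rate=config.frame_rate,
                      pixel_size=config.pixel_size)


def simulate(config: SceneConfig, seed=None) -> tuple[ImageStack, GroundTruth]:
    """Advect and render a full scene; deterministic for a given config+seed."""
    truth = advect_particles(config, seed=seed)
    stack = render_stack(truth, config, seed=seed)
    return stack, truth
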