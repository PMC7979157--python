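"""Validation against generator ground truth.

Synthetic scenes come with exact trajectories and frame shifts; these
helpers compare a pipeline result to them: the coordinate offset between
ground-truth and registered frames, the fraction of ground-truth
frame-to-frame links the tracker recovered, and the registration-accuracy
benchmark (known sub-pixel translations of a rendered frame).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .registration import estimate_shift
from .scene import GroundTruth, SceneConfig, advect_particles, render_stack
from .tracking import TrajectorySet


def registered_offset(truth: GroundTruth, pad: int,
                      reference_frame: int = 0) -> np.ndarray:
    """Constant (dx, dy) mapping ground-truth coordinates into registered
    frames.

    Registration aligns every frame to the reference frame, which itself
    carries that frame's scene jitter; apply_shifts then adds the padding
    margin. Registered position = truth position + jitter[reference] + pad.
    """
    return np.asarray(truth.true_shifts[reference_frame]) + pad


def link_recovery_fraction(
    truth: GroundTruth,
    tracks: TrajectorySet,
    offset,
    match_radius: float = 1.5,
    edge_margin: float = 4.0,
) -> tuple[float, int, int]:
    """Fraction of mobile ground-truth frame-to-frame links the tracker found.

    A truth link (particle present in frames f and f+1) counts as recovered
    when both truth positions have a tracked point of the *same* track
    within ``match_radius`` px. Links whose truth position lies within
    ``edge_margin`` px of the x-boundary of the field of view are excluded:
    a particle there is only partially imaged (its blob is truncated at the
    frame edge), so it is not a fair detection target. Returns
    (fraction, recovered, total).
    """
    offset = np.asarray(offset, float)
    w = truth.config.image_size[1]
    df = tracks.to_dataframe()
    per_frame = {
        f: (cKDTree(g[["x_px", "y_px"]].to_numpy()), g["track_id"].to_numpy())
        for f, g in df.groupby("frame")
    }
    mobile = truth.trajectories[~truth.trajectories["stagnant"]]
    recovered = total = 0
    for _, g in mobile.groupby("particle_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        raw = g[["x_px", "y_px"]].to_numpy()
        xy = raw + offset
        for i in range(len(g) - 1):
            if frames[i + 1] != frames[i] + 1:
                continue
            if not (edge_margin <= raw[i, 0] <= w - 1 - edge_margin
                    and edge_margin <= raw[i + 1, 0] <= w - 1 - edge_margin):
                continue
            total += 1
            a = per_frame.get(frames[i])
            b = per_frame.get(frames[i + 1])
            if a is None or b is None:
                continue
            da, ia = a[0].query(xy[i])
            db, ib = b[0].query(xy[i + 1])
            if da < match_radius and db < match_radius and a[1][ia] == b[1][ib]:
                recovered += 1
    return (recovered / total if total else np.nan), recovered, total


def stationary_tracks_near(
    tracks: TrajectorySet,
    sites,
    net_displacement_max: float = 2.0,
    radius: float = 3.0,
) -> int:
    """Count tracks that barely move and sit near one of the given sites.

    Used to verify that dynamic-background masking leaves no tracks at
    stagnant-particle positions (``sites`` in registered coordinates).
    """
    sites = np.atleast_2d(np.asarray(sites, float))
    n = 0
    for tr in tracks:
        if np.linalg.norm(tr.positions[-1] - tr.positions[0]) < net_displacement_max:
            d = np.linalg.norm(sites - tr.positions.mean(axis=0), axis=1).min()
            if d < radius:
                n += 1
    return n


def registration_shift_errors(
    n_shifts: int = 50,
    seed: int = 0,
    shift_range: float = 5.0,
    image_size: tuple[int, int] = (256, 256),
) -> np.ndarray:
    """Registration benchmark: estimate known random sub-pixel translations.

    Renders one textured synthetic frame (the vessel channel of a default
    scene), Fourier-translates it by ``n_shifts`` shifts drawn uniformly
    from [−shift_range, shift_range] px per axis, runs the estimator
    against the original, and returns the maximum absolute component error
    for each shift.
    """
    cfg = SceneConfig(image_size=image_size, duration=0.2, n_particles=30,
                      jitter_amplitude=0.0, rng_seed=seed)
    truth = advect_particles(cfg, n_frames=6, seed=seed)
    stack = render_stack(truth, cfg, seed=seed)
    ref = stack.green[0].astype(float)
    rng = np.random.default_rng(seed)
    errors = np.empty(n_shifts)
    for i in range(n_shifts):
        d = rng.uniform(-shift_range, shift_range, 2)  # (dx, dy)
        moved = np.fft.ifft2(
            ndimage.fourier_shift(np.fft.fft2(ref), (d[1], d[0]))
        ).real
        est, _ = estimate_shift(ref, moved)
        errors[i] = np.abs(est - d).max()
    return errors
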