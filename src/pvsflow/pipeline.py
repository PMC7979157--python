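"""End-to-end runs: register → mask → detect → track → velocimetry → pulsatility.

:func:`analyze_stack` is the in-memory pipeline used programmatically and by
the tests; :func:`run_pipeline` wraps it with optional scene simulation,
file I/O for every intermediate table, a config hash and a run-metadata
record so identical configurations reproduce identical outputs.
"""

from __future__ import annotations


import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection, pulsatility, registration, tracking, velocimetry
from .io import ImageStack, write_physio, write_table, write_config
from .scene import PhysioTrace, SceneConfig, simulate

log = logging.getLogger("pvsflow")


@dataclass(frozen=True)
class PipelineParams:
    """Stage parameters with the pipeline's standard defaults."""

    reference_frame: int = 0
    upsample_factor: int = 10
    masking: str = "dynamic"            # or "static"
    background_half_window: int = 100   # frames
    threshold: float | None = None      # None -> robust automatic
    min_area: int = 2
    max_area: int = 30
    max_displacement: float = 5.0       # px
    min_track_length: int = 5           # frames
    kernel_sigma: float = 1.0           # frames
    grid: velocimetry.GridSpec = field(default_factory=velocimetry.GridSpec)
    min_bin_count: int = 15
    min_bin_speed: float = 0.5          # μm/s
    vrms_smooth_window: int = 3         # frames
    vrms_min_separation: float | None = None  # s; None -> half cardiac period
    n_phase_bins: int = 20
    delay_bin_width: float = 0.025      # s

    def validate(self) -> None:
        if self.masking not in ("dynamic", "static"):
            raise ValueError("masking must be 'dynamic' or 'static'")
        if self.max_displacement <= 0 or self.min_track_length < 2:
            raise ValueError("invalid tracking parameters")
        if self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be positive")


@dataclass
class AnalysisResult:
    """Everything one run computes, with per-stage counts in ``counts``."""

    shifts: registration.RigidShiftSeries
    pad: int
    detections: pd.DataFrame
    tracks: tracking.TrajectorySet
    field: velocimetry.MeanFlowField
    downstream: np.ndarray
    n_excluded: int
    mean_downstream: float | None
    backflow: float | None
    vrms: pulsatility.VrmsSeries
    vrms_peaks: np.ndarray
    cardiac: pd.DataFrame | None = None
    respiratory: pd.DataFrame | None = None
    cardiac_delay: pulsatility.DelayDistribution | None = None
    respiratory_delay: pulsatility.DelayDistribution | None = None
    counts: dict = field(default_factory=dict)

    def metrics(self) -> dict:
        out = {
            "mean_downstream_um_s": self.mean_downstream,
            "backflow_fraction": self.backflow,
            "n_samples": int(len(self.downstream)),
            "n_excluded": int(self.n_excluded),
            "n_tracks": len(self.tracks),
        }
        if self.cardiac_delay is not None:
            out["cardiac_delay_mean_s"] = self.cardiac_delay.mean
            out["cardiac_delay_sem_s"] = self.cardiac_delay.sem
        if self.respiratory_delay is not None:
            out["respiratory_delay_mean_s"] = self.respiratory_delay.mean
        return out


def _physio_peaks(trace: PhysioTrace, event_rate_hint: float | None = None):
    """Event times of a physiological trace: stored ground truth if present,
    otherwise detected from the samples."""
    if len(trace.event_times):
        return np.asarray(trace.event_times)
    sep = 0.4 / event_rate_hint if event_rate_hint else None
    return pulsatility.detect_peaks(
        trace.values, trace.rate,
        min_prominence=0.25 * np.ptp(trace.values[np.isfinite(trace.values)]),
        min_separation=sep,
    )


def analyze_stack(
    stack: ImageStack,
    ecg: PhysioTrace | None = None,
    respiration: PhysioTrace | None = None,
    params: PipelineParams = PipelineParams(),
    heart_rate_hint: float | None = None,
    resp_rate_hint: float | None = None,
) -> AnalysisResult:
    """Run the full analysis on an in-memory stack.

    Registration is driven by the green (static vessel) channel when
    present — particles move, the vessel does not — and applied to the red
    channel. Pulsatility delay statistics require the matching physiological
    trace; without it those stages are skipped with a logged notice.
    """
    params.validate()
    counts: dict = {"n_frames": stack.n_frames}

    reg_channel = stack.green if stack.green is not None else stack.red
    series = registration.estimate_series(
        reg_channel, reference=params.reference_frame,
        upsample_factor=params.upsample_factor,
    )
    series = registration.repair_shifts(series)
    counts["n_flagged_shifts"] = int(series.flagged.sum())
    registered = registration.apply_shifts(stack.red, series)
    pad = registration.pad_offset(series)

    masked = detection.subtract_background(
        registered, mode=params.masking,
        half_window=params.background_half_window,
    )
    threshold = params.threshold
    if threshold is None:
        threshold = detection.default_threshold(masked)
    counts["threshold"] = float(threshold)
    detections = detection.detect_stack(
        masked, threshold, params.min_area, params.max_area
    )
    counts["n_detections"] = int(len(detections))

    tracks = tracking.link_tracks(
        detections, stack.frame_rate, stack.pixel_size,
        params.max_displacement, params.min_track_length,
    )
    tracking.compute_velocities(tracks, params.kernel_sigma)
    counts["n_tracks"] = len(tracks)

    measurements = tracks.measurements()
    counts["n_velocity_samples"] = int(len(measurements))
    fld = velocimetry.bin_time_average(
        measurements, params.grid, params.min_bin_count, params.min_bin_speed
    )
    downstream, n_excluded = velocimetry.downstream_series(measurements, fld)
    mean_ds = velocimetry.mean_downstream_speed(downstream) if len(downstream) else None
    backflow = velocimetry.backflow_fraction(downstream) if len(downstream) else None

    vrms = pulsatility.vrms_series(tracks, n_frames=stack.n_frames)
    sep = params.vrms_min_separation
    if sep is None and heart_rate_hint:
        sep = 0.5 / heart_rate_hint
    vrms_peaks = np.empty(0)
    if np.isfinite(vrms.values).sum() >= 3:
        vrms_peaks = pulsatility.detect_peaks(
            vrms.values, stack.frame_rate,
            min_separation=sep, smooth_window=params.vrms_smooth_window,
        )

    result = AnalysisResult(
        shifts=series, pad=pad, detections=detections, tracks=tracks,
        field=fld, downstream=downstream, n_excluded=n_excluded,
        mean_downstream=mean_ds, backflow=backflow, vrms=vrms,
        vrms_peaks=vrms_peaks, counts=counts,
    )

    for name, trace, hint in (
        ("cardiac", ecg, heart_rate_hint),
        ("respiratory", respiration, resp_rate_hint),
    ):
        if trace is None:
            log.info("no %s trace supplied; skipping %s conditional/delay "
                     "stages", name, name)
            continue
        peaks = _physio_peaks(trace, hint)
        if len(peaks) < 2:
            log.warning("fewer than 2 %s peaks; skipping", name)
            continue
        cond = pulsatility.conditional_average(vrms, peaks, params.n_phase_bins)
        setattr(result, name, cond)
        if len(vrms_peaks):
            try:
                dist = pulsatility.delay_distribution(
                    vrms_peaks, peaks, params.delay_bin_width
                )
            except ValueError:
                dist = None
            setattr(result, f"{name}_delay", dist)
    return result


@dataclass
class RunConfig:
    """A reproducible run: either a synthetic scene or paths to inputs.

    Exactly one of ``scene`` / ``stack_path`` must be set. All stage
    parameters live in ``params``; ``seed`` drives every stochastic element
    of a simulated scene.
    """

    out_dir: str
    scene: SceneConfig | None = None
    stack_path: str | None = None
    ecg_path: str | None = None
    resp_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        """Digest of the scientific configuration (the output location does
        not affect what is computed)."""
        d = _plain(self.to_dict())
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Execute a configured run and write all outputs to ``out_dir``.

    Writes: shift series, detections, tracks, flow field and Vrms tables as
    CSV; conditional-average and delay tables when physiology is available;
    a metrics JSON and a run-metadata YAML (parameters, seed, config hash,
    per-stage counts). Reruns with an unchanged config reproduce identical
    metric files.
    """
    from .io import read_physio, read_stack

    config.params.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hints = {}
    if config.scene is not None:
        if config.stack_path is not None:
            raise ValueError("give either a scene or a stack path, not both")
        stack, truth = simulate(config.scene, seed=config.seed)
        ecg, resp = truth.ecg, truth.respiration
        hints = {"heart_rate_hint": config.scene.heart_rate,
                 "resp_rate_hint": config.scene.resp_rate}
        truth.trajectories.to_csv(out / "ground_truth.csv", index=False)
        write_physio(ecg, out / "ecg.csv")
        write_physio(resp, out / "respiration.csv")
    elif config.stack_path is not None:
        stack = read_stack(config.stack_path)
        ecg = read_physio(config.ecg_path) if config.ecg_path else None
        resp = read_physio(config.resp_path) if config.resp_path else None
    else:
        raise ValueError("config needs a scene or a stack path")

    result = analyze_stack(stack, ecg, resp, config.params, **hints)

    write_table(result.shifts.to_frame(), out / "shifts.csv")
    write_table(result.detections, out / "detections.csv")
    write_table(result.tracks.to_dataframe(), out / "tracks.csv")
    write_table(result.field.to_dataframe(), out / "flow_field.csv")
    write_table(result.vrms.to_dataframe(), out / "vrms.csv")
    for name in ("cardiac", "respiratory"):
        cond = getattr(result, name)
        if cond is not None:
            write_table(cond, out / f"conditional_{name}.csv")
        dist = getattr(result, f"{name}_delay")
        if dist is not None:
            write_table(
                pd.DataFrame({"delta_t_s": dist.delays}),
                out / f"delays_{name}.csv",
            )
    with open(out / "metrics.json", "w") as fh:
        json.dump(_plain({**result.metrics(), "config_hash": config.hash()}),
                  fh, indent=2, sort_keys=True)
    meta = {
        "config": _plain(config.to_dict()),
        "config_hash": config.hash(),
        "counts": _plain(result.counts),
    }
    write_config(meta, out / "run_metadata.yaml")
    return result
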