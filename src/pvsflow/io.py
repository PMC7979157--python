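"""File formats and containers: TIFF stacks, physiological traces, result tables.

Image data travel as :class:`ImageStack` (16-bit multi-page TIFF on disk),
physiological recordings as :class:`~pvsflow.scene.PhysioTrace` (CSV with a
``time_s`` column), and all derived tables (shifts, detections, tracks, flow
fields) as plain CSV so that every stage of a run can be inspected with
standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """Raised when a file exists but does not match the expected format."""


@dataclass
class ImageStack:
    """A time-lapse two-photon movie.

    Parameters
    ----------
    red : ndarray, shape (T, H, W), uint16
        Tracer-particle channel (fluorescent microspheres).
    green : ndarray or None
        Vessel-lumen channel (intravascular dye); None if single-channel.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size : float
        Lateral resolution in μm per pixel.
    """

    red: np.ndarray
    green: np.ndarray | None
    frame_rate: float
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape[1:]

    def times(self) -> np.ndarray:
        """Frame midpoint times in seconds, t=0 at the first frame."""
        return np.arange(self.n_frames) / self.frame_rate


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a 16-bit multi-page TIFF.

    Channels are interleaved as a (T, C, H, W) series; frame rate and pixel
    size are stored in the shaped-TIFF JSON metadata so that
    :func:`read_stack` round-trips bit-exactly.
    """
    path = Path(path)
    if stack.green is not None:
        data = np.stack([stack.red, stack.green], axis=1)
    else:
        data = stack.red[:, None]
    if data.dtype != np.uint16:
        raise FormatError(f"stack must be uint16, got {data.dtype}")
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        metadata={
            "frame_rate": float(stack.frame_rate),
            "pixel_size": float(stack.pixel_size),
            "axes": "TCYX",
        },
    )


def read_stack(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a 16-bit multi-page TIFF written by :func:`write_stack`.

    ``frame_rate`` / ``pixel_size`` override any values stored in the file
    (and are required if the file carries none).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.dtype != np.uint16:
        raise FormatError(
            f"{path}: expected 16-bit (uint16) pixel data, got {data.dtype}"
        )
    if data.ndim == 3:  # (T, H, W) single channel
        data = data[:, None]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a (T, C, H, W) series, got {data.shape}")
    frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    if frame_rate is None or pixel_size is None:
        raise FormatError(
            f"{path}: frame_rate/pixel_size neither in metadata nor given"
        )
    red = data[:, 0]
    green = data[:, 1] if data.shape[1] > 1 else None
    return ImageStack(red=red, green=green, frame_rate=float(frame_rate),
                      pixel_size=float(pixel_size))


def write_physio(trace, path: str | Path) -> None:
    """Write a physiological trace as CSV with columns time_s, value."""
    df = pd.DataFrame({"time_s": trace.times(), "value": trace.values})
    df.to_csv(path, index=False)


def read_physio(path: str | Path, rate: float | None = None):
    """Read a (time_s, value) CSV into a :class:`~pvsflow.scene.PhysioTrace`.

    The sampling rate is inferred from the time column and, when ``rate`` is
    given, validated against it (1% tolerance). Non-monotone time or NaN
    values are rejected.
    """
    from .scene import PhysioTrace  # local import to avoid a cycle

    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty physiological trace")
    if not {"time_s", "value"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if np.isnan(t).any() or np.isnan(v).any():
        raise FormatError(f"{path}: NaN in physiological trace")
    dt = np.diff(t)
    if len(t) < 2 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    inferred = 1.0 / np.median(dt)
    if rate is not None and abs(inferred - rate) > 0.01 * rate:
        raise FormatError(
            f"{path}: declared rate {rate} Hz does not match samples "
            f"({inferred:.3f} Hz)"
        )
    return PhysioTrace(rate=float(rate or inferred), values=v,
                       event_times=np.empty(0))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(obj: dict, path: str | Path) -> None:
    """Write a run/scene configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
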