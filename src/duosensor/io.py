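"""Core data model and file I/O.

Containers for movies, traces, z-stacks and the run configuration, plus
readers/writers for multi-page grayscale TIFF, CSV tables and the flat
key-value config format.

Conventions
-----------
Frame indices are 0-based throughout the package; the time of frame ``i``
is ``i / frame_rate_hz`` seconds.  Channels live in separate TIFF files
(one file per spectral channel).  ΔF/F movies are written as 32-bit float
TIFF; raw movies keep their acquired dtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Movie",
    "Trace",
    "ZStack",
    "RunConfig",
    "read_movie",
    "write_movie",
    "load_config",
    "write_table",
]


@dataclass
class Movie:
    """A fluorescence movie: one spectral channel of a time-lapse acquisition.

    Parameters
    ----------
    data
        3-D intensity raster indexed (frame, row, col), arbitrary
        fluorescence units.
    frame_rate_hz
        Acquisition rate in frames per second.
    pixel_size_um
        Lateral pixel size in micrometres.
    channel_label
        Free-text channel name, e.g. ``"visible"`` or ``"nir"``.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (frame, row, col), got {self.data.ndim}-D")
        if self.data.shape[0] < 2:
            raise ValueError("movie has fewer than 2 frames")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("movie intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def times_s(self) -> np.ndarray:
        """Time of each frame in seconds (frame i at i / frame_rate_hz)."""
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class Trace:
    """A 1-D fluorescence time series.

    ``kind`` is ``"raw"`` for intensities in acquisition units and
    ``"dff"`` for dimensionless ΔF/F values.
    """

    values: np.ndarray
    frame_rate_hz: float
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.values.size < 2:
            raise ValueError("trace must have length >= 2")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.kind not in ("raw", "dff"):
            raise ValueError(f"kind must be 'raw' or 'dff', got {self.kind!r}")

    def __len__(self) -> int:
        return self.values.size

    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate_hz


@dataclass
class ZStack:
    """An axial image stack: slices at regular z spacing."""

    data: np.ndarray
    z_step_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("z-stack data must be 3-D (slice, row, col)")
        if self.data.shape[0] < 3:
            raise ValueError("z-stack must have >= 3 slices")
        if not (self.z_step_um > 0):
            raise ValueError("z_step_um must be > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


# Analysis parameter defaults: 8x8 px grid, 2-SD ROI criterion, 0.68 Hz
# third-order low-pass, 3-SD event z threshold with >=10 s separation,
# 60 s triggered-average window, 3 s peak smoothing, 10 s pre/post windows.
@dataclass
class RunConfig:
    """All analysis parameters for a run, with standard defaults.

    Window lengths are in seconds unless the name says frames; frame
    indices are 0-based.
    """

    frame_rate_hz: float = 1.47
    pixel_size_um: float = 0.75
    stim_frames: tuple[int, ...] = ()
    grid_px: int = 8
    roi_threshold_sd: float = 2.0
    lowpass_hz: float = 0.68
    lowpass_order: int = 3
    event_z_sd: float = 3.0
    event_min_sep_s: float = 10.0
    window_s: float = 60.0
    peak_win_s: float = 3.0
    prepost_win_s: float = 10.0
    baseline_frames: int = 15
    response_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.stim_frames = tuple(int(f) for f in self.stim_frames)
        if self.grid_px < 1:
            raise ValueError("grid_px must be >= 1")
        for name in ("frame_rate_hz", "pixel_size_um", "lowpass_hz", "event_min_sep_s",
                     "window_s", "prepost_win_s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("baseline_frames", "response_frames", "lowpass_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.peak_win_s < 0:
            raise ValueError("peak_win_s must be >= 0")
        if any(f < 0 for f in self.stim_frames):
            raise ValueError("stim_frames must be non-negative")

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def read_movie(path: str | Path, config: RunConfig, channel_label: str = "") -> Movie:
    """Read a multi-page grayscale TIFF as a :class:`Movie`.

    Page order is frame order.  RGB / multi-sample TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ValueError("TIFF has fewer than 2 frames")
    if data.ndim != 3:
        raise ValueError("TIFF is not a grayscale multi-page stack (RGB or multi-sample pages?)")
    return Movie(
        data=data,
        frame_rate_hz=config.frame_rate_hz,
        pixel_size_um=config.pixel_size_um,
        channel_label=channel_label,
    )


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page grayscale TIFF (lossless round-trip)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = movie.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


_CONFIG_FIELDS = {f.name: f.type for f in fields(RunConfig)}
_INT_FIELDS = {"grid_px", "lowpass_order", "baseline_frames", "response_frames", "seed"}


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML-style) config file.

    Unspecified keys take the package defaults.  Unknown keys warn;
    non-numeric values for numeric keys raise.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _CONFIG_FIELDS:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        if key == "stim_frames":
            if not isinstance(value, (list, tuple)):
                raise ValueError("stim_frames must be a list of frame indices")
            try:
                kwargs[key] = tuple(int(v) for v in value)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric stim_frames entry: {value!r}") from exc
            continue
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
        kwargs[key] = int(value) if key in _INT_FIELDS else float(value)
    return RunConfig(**kwargs)


def write_table(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write tabular records as CSV with a header row.

    Column order is deterministic: the key order of the first record (or
    ``columns`` if given).  All records must share the same keys.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    rows = list(rows)
    if rows:
        cols = list(columns) if columns is not None else list(rows[0].keys())
        for i, row in enumerate(rows):
            if set(row.keys()) != set(cols):
                raise ValueError(f"record {i} keys {sorted(row)} do not match columns {sorted(cols)}")
        df = pd.DataFrame(rows, columns=cols)
    else:
        df = pd.DataFrame(columns=list(columns) if columns is not None else [])
    df.to_csv(path, index=False)
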