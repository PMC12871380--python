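"""Grid-mask hotspot (ROI) calling and condition / sensor comparisons.

The field of view is partitioned into square grid regions (8×8 px by
default).  For each square the spatially averaged trace is converted to
ΔF/F against the pre-stimulus baseline, and the square is called *active*
— a putative high-release hotspot — when the peak ΔF/F in the response
window exceeds the baseline mean by ``roi_threshold_sd`` standard
deviations of the baseline activity.

With repeated stimulations the peak is taken from the across-repeat mean
ΔF/F trace while the baseline mean/SD are pooled over the per-trial
(unaveraged) baselines.  Averaging repeats therefore suppresses
response-window noise relative to the threshold, which is what gives the
criterion its specificity: at a single trial the pure-noise activation
probability for a W-frame response window is 1 − Φ(k)^W, whereas with R
repeats the effective threshold is k·√R baseline SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dff import dff_prestim
from .io import Movie, RunConfig, Trace

__all__ = [
    "GridSpec",
    "HotspotResult",
    "ConditionReport",
    "RegressionReport",
    "make_grid",
    "grid_traces",
    "call_hotspots",
    "integrated_dff",
    "compare_conditions",
    "compare_sensor_amplitudes",
]


@dataclass
class GridSpec:
    """Partition of an image into full grid squares; partial edges dropped."""

    grid_px: int
    n_rows: int
    n_cols: int
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.grid_px < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid_px, n_rows, n_cols must be >= 1")

    @property
    def n_squares(self) -> int:
        return self.n_rows * self.n_cols

    def pixel_slices(self, row: int, col: int) -> tuple[slice, slice]:
        r0 = self.origin[0] + row * self.grid_px
        c0 = self.origin[1] + col * self.grid_px
        return slice(r0, r0 + self.grid_px), slice(c0, c0 + self.grid_px)


@dataclass
class HotspotResult:
    """Active-square map for one stimulus condition.

    ``threshold_per_square`` holds baseline mean + k·SD of the baseline
    ΔF/F activity; ``active[g]`` is True iff ``peak_dff[g]`` exceeds it
    (or exceeds the baseline mean where the SD is exactly zero).
    """

    grid: GridSpec
    peak_dff: np.ndarray
    active: np.ndarray
    n_active: int
    threshold_per_square: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.active.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("active map shape does not match grid")
        if self.n_active != int(self.active.sum()):
            raise ValueError("n_active inconsistent with active map")


def make_grid(image_shape: tuple[int, int], grid_px: int) -> GridSpec:
    """Build the grid mask for an image: floor(rows/g) × floor(cols/g) squares."""
    rows, cols = image_shape
    if grid_px > min(rows, cols):
        raise ValueError(f"grid_px={grid_px} exceeds image extent {image_shape}")
    return GridSpec(grid_px=grid_px, n_rows=rows // grid_px, n_cols=cols // grid_px)


def _grid_trace_array(movie: Movie, grid: GridSpec) -> np.ndarray:
    """(n_rows, n_cols, n_frames) array of per-square spatial-mean traces."""
    g = grid.grid_px
    r0, c0 = grid.origin
    sub = movie.data[:, r0:r0 + grid.n_rows * g, c0:c0 + grid.n_cols * g].astype(float)
    t = sub.shape[0]
    blocks = sub.reshape(t, grid.n_rows, g, grid.n_cols, g)
    return blocks.mean(axis=(2, 4)).transpose(1, 2, 0)


def grid_traces(movie: Movie, grid: GridSpec) -> dict[tuple[int, int], Trace]:
    """Per-square spatial-mean raw trace, keyed by (row, col) grid index."""
    if grid.origin[0] + grid.n_rows * grid.grid_px > movie.shape[1] or \
       grid.origin[1] + grid.n_cols * grid.grid_px > movie.shape[2]:
        raise ValueError("grid does not fit inside the movie frames")
    arr = _grid_trace_array(movie, grid)
    return {(r, c): Trace(arr[r, c], movie.frame_rate_hz, kind="raw")
            for r in range(grid.n_rows) for c in range(grid.n_cols)}


def call_hotspots(movie: Movie, grid: GridSpec, stim_frames: int | list[int],
                  cfg: RunConfig) -> HotspotResult:
    """Call active grid squares at the k-SD criterion.

    For each stimulus repeat, each square's ΔF/F trace is computed against
    that repeat's pre-stimulus baseline (``cfg.baseline_frames`` frames)
    and windowed to [stim − baseline, stim + response).  The peak is the
    maximum of the across-repeat mean trace over the response window; the
    threshold is the pooled per-trial baseline mean + k·SD.

    Squares with exactly zero baseline SD (noiseless synthetic input) use
    the degenerate rule: active ⇔ peak > baseline mean.
    """
    stims = [int(stim_frames)] if np.isscalar(stim_frames) else [int(s) for s in stim_frames]
    if not stims:
        raise ValueError("at least one stimulus frame required")
    b, w = cfg.baseline_frames, cfg.response_frames
    for s in stims:
        if s < b:
            raise ValueError(f"stim frame {s} has fewer than {b} baseline frames before it")
        if s + w > movie.n_frames:
            raise ValueError(f"response window for stim frame {s} exceeds the movie")

    arr = _grid_trace_array(movie, grid)  # (rows, cols, frames)
    base_trials, resp_trials = [], []
    for s in stims:
        f0 = arr[:, :, s - b:s].mean(axis=2)
        if np.any(f0 <= 0):
            raise ValueError("square with baseline F0 <= 0")
        dff = arr / f0[:, :, None] - 1.0
        base_trials.append(dff[:, :, s - b:s])
        resp_trials.append(dff[:, :, s:s + w])

    base = np.stack(base_trials, axis=0)   # (repeats, rows, cols, B)
    resp = np.stack(resp_trials, axis=0)   # (repeats, rows, cols, W)
    pooled = base.transpose(1, 2, 0, 3).reshape(grid.n_rows, grid.n_cols, -1)
    base_mean = pooled.mean(axis=2)
    base_sd = pooled.std(axis=2, ddof=1)
    peak = resp.mean(axis=0).max(axis=2)

    threshold = base_mean + cfg.roi_threshold_sd * base_sd
    active = np.where(base_sd == 0, peak > base_mean, peak > threshold)
    return HotspotResult(
        grid=grid,
        peak_dff=peak,
        active=active,
        n_active=int(active.sum()),
        threshold_per_square=threshold,
        params={"roi_threshold_sd": cfg.roi_threshold_sd,
                "baseline_frames": b, "response_frames": w,
                "stim_frames": stims, "n_repeats": len(stims)},
    )


def integrated_dff(movie: Movie, stim_frames: int | list[int],
                   cfg: RunConfig) -> tuple[Trace, list[Trace]]:
    """Stimulus-aligned ΔF/F of the whole-field spatial mean.

    Each trial is the window [stim − baseline_frames, stim +
    response_frames) of the full-frame mean trace, normalized to that
    trial's pre-stimulus baseline.  Returns the across-trial mean trace
    and the per-trial traces.
    """
    stims = [int(stim_frames)] if np.isscalar(stim_frames) else [int(s) for s in stim_frames]
    if not stims:
        raise ValueError("at least one stimulus frame required")
    field_trace = Trace(movie.data.mean(axis=(1, 2)), movie.frame_rate_hz, kind="raw")
    b, w = cfg.baseline_frames, cfg.response_frames
    trials = []
    for s in stims:
        if s < b or s + w > movie.n_frames:
            raise ValueError(f"window for stim frame {s} exceeds the trace")
        dff = dff_prestim(field_trace, s, b)
        trials.append(Trace(dff.values[s - b:s + w], movie.frame_rate_hz, kind="dff"))
    mean_trace = Trace(np.mean([t.values for t in trials], axis=0),
                       movie.frame_rate_hz, kind="dff")
    return mean_trace, trials


@dataclass
class ConditionReport:
    """Before/after comparison of hotspot results on the same grid."""

    n_active_pre: int
    n_active_post: int
    reduction: float | None          # (pre − post)/pre; None when pre == 0
    peak_dff_diff: np.ndarray        # post − pre, per square


def compare_conditions(pre: HotspotResult, post: HotspotResult) -> ConditionReport:
    """Compare hotspot maps before and after a perturbation (e.g. a D2 agonist)."""
    if (pre.grid.n_rows, pre.grid.n_cols, pre.grid.grid_px) != \
       (post.grid.n_rows, post.grid.n_cols, post.grid.grid_px):
        raise ValueError("hotspot results use different grids")
    reduction = None
    if pre.n_active > 0:
        reduction = (pre.n_active - post.n_active) / pre.n_active
    return ConditionReport(
        n_active_pre=pre.n_active,
        n_active_post=post.n_active,
        reduction=reduction,
        peak_dff_diff=post.peak_dff - pre.peak_dff,
    )


@dataclass
class RegressionReport:
    """OLS fit of paired per-slice response amplitudes from two sensors."""

    slope: float
    intercept: float
    r_squared: float
    ratio_of_means: float            # mean(y) / mean(x)
    n: int


def compare_sensor_amplitudes(pairs: list[tuple[float, float]]) -> RegressionReport:
    """Ordinary least-squares regression of paired (x, y) peak amplitudes.

    ``ratio_of_means`` quantifies the overall amplitude contrast between
    the two sensors (mean y over mean x).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        slope, intercept, rvalue = 0.0, float(np.mean(y)), 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, rvalue = res.slope, res.intercept, res.rvalue
    return RegressionReport(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(rvalue ** 2),
        ratio_of_means=float(np.mean(y) / np.mean(x)) if np.mean(x) != 0 else np.nan,
        n=pairs.shape[0],
    )
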