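"""Baseline normalization, decay detrending and low-pass filtering.

ΔF/F = (F − F₀)/F₀ with two baseline conventions: the pre-stimulus mean
(evoked-release experiments) or the whole-trial median (spontaneous-activity
experiments).  Slow fluorescence decays — common in the first 30–60 s of
near-infrared nanosensor recordings — are removed by fitting and
subtracting a double exponential, keeping the asymptotic level.  Low-pass
filtering is zero-phase (forward–backward Butterworth) so that event peaks
are not shifted in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .io import Movie, Trace

__all__ = [
    "DoubleExpFit",
    "dff_prestim",
    "dff_median",
    "detrend_double_exp",
    "lowpass",
    "pixelwise_dff",
]


@dataclass
class DoubleExpFit:
    """Fitted decay model f(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2) + offset."""

    a1: float
    tau1_s: float
    a2: float
    tau2_s: float
    offset: float
    rmse: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.tau1_s > 0 and self.tau2_s > 0):
                raise ValueError("time constants must be > 0")
            if self.rmse < 0:
                raise ValueError("rmse must be >= 0")

    def curve(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        return (self.a1 * np.exp(-t_s / self.tau1_s)
                + self.a2 * np.exp(-t_s / self.tau2_s)
                + self.offset)


def dff_prestim(trace: Trace, stim_frame: int, baseline_frames: int) -> Trace:
    """ΔF/F with F₀ = mean of the frames immediately preceding the stimulus.

    ``baseline_frames`` frames ending at ``stim_frame - 1`` define F₀.
    """
    if baseline_frames < 2:
        raise ValueError("baseline_frames must be >= 2")
    if stim_frame < baseline_frames:
        raise ValueError("stim_frame must be >= baseline_frames")
    if stim_frame >= len(trace):
        raise ValueError("stim_frame out of range")
    f = trace.values
    f0 = float(np.mean(f[stim_frame - baseline_frames:stim_frame]))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0} <= 0 (empty or pathological baseline)")
    return Trace((f - f0) / f0, trace.frame_rate_hz, kind="dff")


def dff_median(trace: Trace) -> Trace:
    """ΔF/F with F₀ = median intensity of the whole trial."""
    f = trace.values
    f0 = float(np.median(f))
    if f0 <= 0:
        raise ValueError(f"median F0 = {f0} <= 0")
    return Trace((f - f0) / f0, trace.frame_rate_hz, kind="dff")


def _double_exp(t, a1, tau1, a2, tau2, offset):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + offset


# Multi-start tau grid (seconds); covers fast bleach through slow drift.
_TAU_STARTS = (5.0, 20.0, 80.0)


def detrend_double_exp(trace: Trace, fit_end_s: float | None = None) -> tuple[Trace, DoubleExpFit]:
    """Fit a double exponential plus offset and subtract the decaying part.

    The returned trace is ``trace − (fit − offset)``, so the asymptotic
    (plateau) level is preserved.  The fit is least-squares over the whole
    trace (``fit_end_s`` restricts the fit window when given), multi-started
    over pairs of time constants; τ bounded to [0.5 s, 10 × duration].

    On non-convergence the input is returned unchanged with
    ``rmse = inf`` and ``converged = False``.
    """
    if len(trace) < 10:
        raise ValueError("trace must have >= 10 samples for a double-exponential fit")
    t = trace.times_s()
    y = trace.values
    if fit_end_s is not None:
        mask = t <= fit_end_s
        if mask.sum() < 10:
            raise ValueError("fit window contains fewer than 10 samples")
    else:
        mask = np.ones_like(t, dtype=bool)
    t_fit, y_fit = t[mask], y[mask]

    duration = t[-1] if t[-1] > 0 else 1.0
    tau_lo, tau_hi = 0.5, 10.0 * duration
    amp0 = y_fit[0] - y_fit[-1]
    offset0 = y_fit[-1]
    bounds = ([-np.inf, tau_lo, -np.inf, tau_lo, -np.inf],
              [np.inf, tau_hi, np.inf, tau_hi, np.inf])

    best = None
    for tau1 in _TAU_STARTS:
        for tau2 in _TAU_STARTS:
            if tau2 < tau1:
                continue
            p0 = [amp0 / 2, min(max(tau1, tau_lo), tau_hi),
                  amp0 / 2, min(max(tau2, tau_lo), tau_hi), offset0]
            try:
                popt, _ = optimize.curve_fit(_double_exp, t_fit, y_fit, p0=p0,
                                             bounds=bounds, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            resid = y_fit - _double_exp(t_fit, *popt)
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            if best is None or rmse < best[1]:
                best = (popt, rmse)

    if best is None:
        fit = DoubleExpFit(0.0, 1.0, 0.0, 1.0, 0.0, np.inf, converged=False)
        return Trace(y.copy(), trace.frame_rate_hz, kind=trace.kind), fit

    popt, rmse = best
    fit = DoubleExpFit(a1=float(popt[0]), tau1_s=float(popt[1]), a2=float(popt[2]),
                       tau2_s=float(popt[3]), offset=float(popt[4]), rmse=rmse)
    detrended = y - (fit.curve(t) - fit.offset)
    return Trace(detrended, trace.frame_rate_hz, kind=trace.kind), fit


def lowpass(trace: Trace, cutoff_hz: float, order: int = 3) -> Trace:
    """Zero-phase Butterworth low-pass filter (DC gain exactly 1).

    Forward-backward filtering (``filtfilt``) squares the magnitude
    response, so a unit sinusoid at the cutoff comes out with amplitude
    0.5 rather than 1/√2.
    """
    nyquist = trace.frame_rate_hz / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff {cutoff_hz} Hz must be in (0, Nyquist={nyquist} Hz)")
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(trace) <= 3 * (order + 1):
        raise ValueError("trace too short for the requested filter order")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.frame_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.values)
    return Trace(filtered, trace.frame_rate_hz, kind=trace.kind)


def pixelwise_dff(movie: Movie, mode: str = "prestim", stim_frame: int | None = None,
                  baseline_frames: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ΔF/F of a movie.

    Applies the chosen baseline convention independently to every pixel's
    trace.  Pixels whose F₀ ≤ 0 are flagged invalid (NaN in the output,
    False in the mask) rather than raising, so downstream steps can
    exclude them.

    Returns
    -------
    dff : float ndarray, same shape as the movie
    valid : bool ndarray (row, col), False where F₀ ≤ 0
    """
    f = movie.data.astype(float)
    if mode == "prestim":
        if stim_frame is None or baseline_frames is None:
            raise ValueError("prestim mode requires stim_frame and baseline_frames")
        if baseline_frames < 2 or stim_frame < baseline_frames or stim_frame >= movie.n_frames:
            raise ValueError("invalid stim_frame / baseline_frames")
        f0 = f[stim_frame - baseline_frames:stim_frame].mean(axis=0)
    elif mode == "median":
        f0 = np.median(f, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    valid = f0 > 0
    if not valid.any():
        raise ValueError("all pixels have F0 <= 0")
    dff = np.full_like(f, np.nan)
    dff[:, valid] = (f[:, valid] - f0[valid]) / f0[valid]
    return dff, valid
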