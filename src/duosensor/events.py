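"""Spontaneous-event detection, triggered averaging and response amplitudes.

Spontaneous transients (retinal waves) are detected on the calcium
channel by z-scoring the ΔF/F trace against its whole-trace mean and SD
and keeping strict local maxima whose z exceeds a threshold (3 SD by
default), enforcing a minimum separation (10 s) by greedy merging in
descending z order.  Detected events — or applied stimuli such as K⁺
puffs — then anchor triggered averages: fixed windows (60 s) centered on
the frame *prior to* the event peak, averaged across events.  The
response amplitude is the difference between the smoothed peak values in
the 10 s windows after and before the trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .dff import detrend_double_exp, dff_median, lowpass
from .io import RunConfig, Trace

__all__ = [
    "EventSet",
    "TriggeredAverage",
    "ResponseAmplitude",
    "detect_events",
    "triggered_average",
    "response_amplitude",
    "puff_response_pipeline",
]


@dataclass
class EventSet:
    """Sorted event frames with the detection parameters that produced them."""

    frames: np.ndarray
    kind: str = "wave"
    z_threshold_sd: float = 3.0
    min_sep_s: float = 10.0
    frame_rate_hz: float = 1.47
    z_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.kind not in ("wave", "puff"):
            raise ValueError("kind must be 'wave' or 'puff'")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("event frames must be strictly increasing")
        min_sep_frames = self.min_sep_s * self.frame_rate_hz
        if self.frames.size > 1 and np.any(np.diff(self.frames) < min_sep_frames - 1e-9):
            raise ValueError("events violate the minimum separation")

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class TriggeredAverage:
    """Event-aligned window matrix and its across-event mean."""

    window_s: float
    trigger_offset: int
    trials: np.ndarray               # (event, window sample) ΔF/F
    mean_trace: np.ndarray
    n_events: int
    frame_rate_hz: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trials.shape != (self.n_events, self.mean_trace.size):
            raise ValueError("trials matrix inconsistent with mean trace / event count")


@dataclass
class ResponseAmplitude:
    """Peak-to-peak response around an event trigger.

    ``pre_peak`` / ``post_peak`` are means within ``peak_win_s`` centered
    on the local maximum of the pre-/post-trigger window; ``amplitude``
    is their difference (post − pre).
    """

    pre_peak: float
    post_peak: float
    amplitude: float

    def __post_init__(self) -> None:
        if not np.isclose(self.amplitude, self.post_peak - self.pre_peak):
            raise ValueError("amplitude must equal post_peak - pre_peak")


def detect_events(trace: Trace, cfg: RunConfig) -> EventSet:
    """Detect spontaneous events as z-scored peaks above threshold.

    The z-score uses the whole-trace mean and SD.  Candidate peaks are
    strict local maxima (plateaus resolved to the earliest frame) with
    z > ``cfg.event_z_sd``; candidates closer than ``cfg.event_min_sep_s``
    are merged greedily in descending z order (ties to the earlier frame),
    keeping the larger peak.
    """
    x = trace.values
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance trace")
    min_sep_frames = cfg.event_min_sep_s * trace.frame_rate_hz
    if x.size < 2 * min_sep_frames:
        raise ValueError("trace shorter than twice the minimum event separation")
    z = (x - x.mean()) / sd

    peaks, props = signal.find_peaks(z, height=cfg.event_z_sd, plateau_size=(1, None))
    candidates = props["left_edges"]          # plateau ties -> earliest frame
    heights = z[candidates]

    # Greedy merge: accept in descending z (ties: earlier frame first).
    order = np.lexsort((candidates, -heights))
    accepted: list[int] = []
    for idx in order:
        f = int(candidates[idx])
        if all(abs(f - a) >= min_sep_frames - 1e-9 for a in accepted):
            accepted.append(f)
    frames = np.sort(np.asarray(accepted, dtype=int))
    return EventSet(frames=frames, kind="wave", z_threshold_sd=cfg.event_z_sd,
                    min_sep_s=cfg.event_min_sep_s, frame_rate_hz=trace.frame_rate_hz,
                    z_values=z[frames])


def triggered_average(trace: Trace, events: EventSet, cfg: RunConfig) -> TriggeredAverage:
    """Average fixed windows of the trace aligned to each event.

    The window spans ``cfg.window_s`` seconds centered on the frame prior
    to each event frame.  Events whose window would run off either end of
    the trace are dropped (and counted), never padded.
    """
    fps = trace.frame_rate_hz
    n_win = int(round(cfg.window_s * fps))
    if n_win < 2:
        raise ValueError("window shorter than 2 samples")
    offset = n_win // 2
    trials = []
    dropped = 0
    for f in events.frames:
        trigger = int(f) - 1            # frame prior to the peak / puff
        start = trigger - offset
        stop = start + n_win
        if start < 0 or stop > len(trace):
            dropped += 1
            continue
        trials.append(trace.values[start:stop])
    if not trials:
        raise ValueError("no event has a full window inside the trace")
    trials_arr = np.asarray(trials)
    return TriggeredAverage(
        window_s=cfg.window_s,
        trigger_offset=offset,
        trials=trials_arr,
        mean_trace=trials_arr.mean(axis=0),
        n_events=trials_arr.shape[0],
        frame_rate_hz=fps,
        n_dropped=dropped,
    )


def _smoothed_peak(window: np.ndarray, peak_win_samples: int) -> float:
    """Mean of the samples around the window's maximum (clipped to the window)."""
    p = int(np.argmax(window))
    if peak_win_samples <= 1:
        return float(window[p])
    half = peak_win_samples // 2
    lo = max(0, p - half)
    hi = min(window.size, p + half + 1)
    return float(window[lo:hi].mean())


def response_amplitude(avg: TriggeredAverage, cfg: RunConfig) -> ResponseAmplitude:
    """Peak-difference response amplitude of a triggered average.

    In the ``cfg.prepost_win_s`` window before the trigger, find the
    maximum sample and average ``cfg.peak_win_s`` around it (clipped to
    the window) → pre peak; likewise after the trigger → post peak.
    Setting ``peak_win_s = 0`` disables the smoothing (single max sample).
    """
    if cfg.window_s < 2 * cfg.prepost_win_s:
        raise ValueError("window_s must be >= 2 * prepost_win_s")
    fps = avg.frame_rate_hz
    n_pp = int(round(cfg.prepost_win_s * fps))
    if n_pp < 1:
        raise ValueError("pre/post window shorter than one sample")
    n_pk = int(round(cfg.peak_win_s * fps))
    t = avg.trigger_offset
    pre = avg.mean_trace[max(0, t - n_pp):t]
    post = avg.mean_trace[t + 1:t + 1 + n_pp]
    if pre.size < 1 or post.size < 1:
        raise ValueError("pre/post windows do not fit inside the triggered average")
    pre_peak = _smoothed_peak(pre, n_pk)
    post_peak = _smoothed_peak(post, n_pk)
    return ResponseAmplitude(pre_peak=pre_peak, post_peak=post_peak,
                             amplitude=post_peak - pre_peak)


def puff_response_pipeline(cal: Trace, nir: Trace, puff_frames: list[int], cfg: RunConfig,
                           detrend: bool = False) -> dict[str, dict]:
    """Full stimulus-puff analysis for a calcium / near-infrared trace pair.

    Each channel is normalized (ΔF/F against the trial median), optionally
    detrended with the double-exponential model, low-pass filtered, then
    averaged over the puff triggers and reduced to a response amplitude.

    Returns ``{"cal": {...}, "nir": {...}}`` with keys ``trace``,
    ``triggered_average`` and ``amplitude`` per channel.
    """
    if cal.frame_rate_hz != nir.frame_rate_hz or len(cal) != len(nir):
        raise ValueError("channels must share frame rate and length")
    puffs = EventSet(frames=np.asarray(sorted(puff_frames), dtype=int), kind="puff",
                     z_threshold_sd=cfg.event_z_sd, min_sep_s=0.0,
                     frame_rate_hz=cal.frame_rate_hz)
    out: dict[str, dict] = {}
    for label, tr in (("cal", cal), ("nir", nir)):
        d = dff_median(tr)
        if detrend:
            d, _ = detrend_double_exp(d)
        filt = lowpass(d, cfg.lowpass_hz, cfg.lowpass_order)
        avg = triggered_average(filt, puffs, cfg)
        amp = response_amplitude(avg, cfg)
        out[label] = {"trace": filt, "triggered_average": avg, "amplitude": amp}
    return out
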