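"""Event detection, triggered averaging and response amplitudes."""

import numpy as np
import pytest

from duosensor import (EventSet, RunConfig, Trace, detect_events, puff_response_pipeline,
                       response_amplitude, triggered_average)

FPS = 1.47


def _bump_trace(centers_s, amps, duration_s, noise_sd, seed=0, sigma_s=1.5):
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * FPS))
    t = np.arange(n) / FPS
    x = np.zeros(n)
    for c, a in zip(centers_s, amps):
        x += a * np.exp(-((t - c) ** 2) / (2 * sigma_s ** 2))
    if noise_sd > 0:
        x += rng.normal(0, noise_sd, n)
    return Trace(x, FPS, kind="dff")


class TestDetectEvents:
    def test_flat_noise_has_no_events(self, cfg):
        trace = _bump_trace([], [], 200, noise_sd=0.01, seed=2)
        assert len(detect_events(trace, cfg)) == 0

    def test_three_bumps_found_at_centers(self, cfg):
        trace = _bump_trace([30, 60, 90], [1, 1, 1], 120, noise_sd=0.1, seed=5)
        events = detect_events(trace, cfg)
        assert len(events) == 3
        expected = np.round(np.array([30, 60, 90]) * FPS)
        assert np.all(np.abs(events.frames - expected) <= 1)

    def test_min_separation_keeps_taller_bump(self, cfg):
        trace = _bump_trace([60, 65], [1.0, 1.2], 130, noise_sd=0.02, seed=2, sigma_s=1.0)
        events = detect_events(trace, cfg)
        assert len(events) == 1
        assert abs(events.frames[0] - round(65 * FPS)) <= 1

    @pytest.mark.parametrize("seed", range(10))
    def test_affine_invariance(self, cfg, seed):
        """Z-scoring makes detection invariant to a·x + b for a > 0."""
        rng = np.random.default_rng(seed)
        trace = _bump_trace(rng.uniform(30, 270, 4), rng.uniform(0.8, 1.5, 4),
                            300, noise_sd=0.05, seed=seed)
        base = detect_events(trace, cfg)
        scaled = Trace(3.7 * trace.values + 11.0, FPS, kind="dff")
        np.testing.assert_array_equal(detect_events(scaled, cfg).frames, base.frames)

    @pytest.mark.parametrize("seed", range(50))
    def test_threshold_and_separation_guarantees(self, cfg, seed):
        """Every event exceeds the z threshold; all pairs respect min separation."""
        rng = np.random.default_rng(seed)
        n_bumps = rng.integers(1, 6)
        trace = _bump_trace(rng.uniform(20, 380, n_bumps), rng.uniform(0.5, 2.0, n_bumps),
                            400, noise_sd=0.08, seed=seed + 1000)
        events = detect_events(trace, cfg)
        z = (trace.values - trace.values.mean()) / trace.values.std()
        assert np.all(z[events.frames] > cfg.event_z_sd)
        min_sep_frames = cfg.event_min_sep_s * FPS
        if len(events) > 1:
            assert np.all(np.diff(events.frames) >= min_sep_frames - 1e-9)

    def test_zero_variance_rejected(self, cfg):
        with pytest.raises(ValueError, match="variance"):
            detect_events(Trace(np.full(100, 1.0), FPS, kind="dff"), cfg)


class TestTriggeredAverage:
    def test_single_event_is_identity(self, cfg, rng):
        trace = Trace(rng.normal(0, 1, 300), FPS, kind="dff")
        events = EventSet(frames=np.array([150]), min_sep_s=0, frame_rate_hz=FPS)
        avg = triggered_average(trace, events, cfg)
        n_win = int(round(cfg.window_s * FPS))
        start = 149 - n_win // 2
        np.testing.assert_array_equal(avg.mean_trace, trace.values[start:start + n_win])
        assert avg.n_events == 1

    def test_identical_trials_have_zero_variance(self, cfg):
        period = int(round(100 * FPS))
        template = np.sin(np.linspace(0, 4 * np.pi, period))
        trace = Trace(np.tile(template, 4), FPS, kind="dff")
        events = EventSet(frames=np.array([period, 2 * period]), min_sep_s=0, frame_rate_hz=FPS)
        avg = triggered_average(trace, events, cfg)
        assert avg.n_events == 2
        assert np.max(np.std(avg.trials, axis=0)) < 1e-12
        np.testing.assert_allclose(avg.mean_trace, avg.trials[0])

    def test_sqrt_n_noise_reduction(self, cfg):
        """Averaging 25 trials reduces the noise by ~sqrt(25)."""
        rng = np.random.default_rng(11)
        sigma = 0.5
        n_win = int(round(cfg.window_s * FPS))
        spacing = 2 * n_win
        n_events = 25
        n = spacing * (n_events + 2)
        t_win = np.arange(n_win) / FPS
        template = np.exp(-((t_win - 30) ** 2) / (2 * 3.0 ** 2))
        x = rng.normal(0, sigma, n)
        frames = []
        for k in range(n_events):
            trigger = spacing * (k + 1)
            start = trigger - n_win // 2
            x[start:start + n_win] += template
            frames.append(trigger + 1)  # trigger = frame prior to the event frame
        events = EventSet(frames=np.array(frames), min_sep_s=0, frame_rate_hz=FPS)
        avg = triggered_average(Trace(x, FPS, kind="dff"), events, cfg)
        rmse = np.sqrt(np.mean((avg.mean_trace - template) ** 2))
        expected = sigma / np.sqrt(n_events)
        assert expected / 1.5 < rmse < expected * 1.5

    def test_edge_events_dropped(self, cfg):
        trace = Trace(np.zeros(300) + np.arange(300) * 1e-3, FPS, kind="dff")
        events = EventSet(frames=np.array([5, 150]), min_sep_s=0, frame_rate_hz=FPS)
        avg = triggered_average(trace, events, cfg)
        assert avg.n_events == 1 and avg.n_dropped == 1

    def test_no_usable_event_rejected(self, cfg):
        trace = Trace(np.zeros(50), FPS, kind="dff")
        events = EventSet(frames=np.array([25]), min_sep_s=0, frame_rate_hz=FPS)
        with pytest.raises(ValueError, match="window"):
            triggered_average(trace, events, cfg)


def _make_avg(mean_trace, cfg):
    from duosensor.events import TriggeredAverage
    n = mean_trace.size
    return TriggeredAverage(window_s=cfg.window_s, trigger_offset=n // 2,
                            trials=mean_trace[None, :], mean_trace=mean_trace,
                            n_events=1, frame_rate_hz=FPS)


class TestResponseAmplitude:
    def test_flat_trace_zero_amplitude(self, cfg):
        n = int(round(cfg.window_s * FPS))
        amp = response_amplitude(_make_avg(np.zeros(n), cfg), cfg)
        assert amp.amplitude == 0.0

    def test_unit_step_at_trigger(self, cfg):
        n = int(round(cfg.window_s * FPS))
        x = np.zeros(n)
        x[n // 2:] = 1.0
        amp = response_amplitude(_make_avg(x, cfg), cfg)
        assert amp.pre_peak == 0.0 and amp.post_peak == 1.0 and amp.amplitude == 1.0

    def test_triangular_bump_matches_brute_force(self, cfg):
        n = int(round(cfg.window_s * FPS))
        trigger = n // 2
        x = np.zeros(n)
        apex = trigger + int(round(3 * FPS))      # peak 3 s post-trigger
        half_width = 5
        for k in range(-half_width, half_width + 1):
            x[apex + k] = 2.0 * (1 - abs(k) / half_width)
        amp = response_amplitude(_make_avg(x, cfg), cfg)
        # brute-force oracle over the constructed window
        n_pp = int(round(cfg.prepost_win_s * FPS))
        post = x[trigger + 1:trigger + 1 + n_pp]
        p = int(np.argmax(post))
        half = int(round(cfg.peak_win_s * FPS)) // 2
        expected = post[max(0, p - half):min(post.size, p + half + 1)].mean()
        assert amp.post_peak == pytest.approx(expected)
        assert amp.amplitude == pytest.approx(expected)

    def test_symmetric_negation(self, cfg):
        """A symmetric bump pair gives opposite amplitudes under negation."""
        n = int(round(cfg.window_s * FPS))
        trigger = n // 2
        t = np.arange(n)
        x = (np.exp(-((t - (trigger + 7)) ** 2) / 8.0)
             - np.exp(-((t - (trigger - 7)) ** 2) / 8.0))
        a_pos = response_amplitude(_make_avg(x, cfg), cfg)
        a_neg = response_amplitude(_make_avg(-x, cfg), cfg)
        assert a_pos.amplitude == pytest.approx(-a_neg.amplitude)


class TestPuffPipeline:
    def _puff_pair(self, scale_nir, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        n = int(round(600 * FPS))
        t = np.arange(n) / FPS
        cal = np.full(n, 100.0)
        nir = np.full(n, 100.0)
        puffs = [300, 600]
        for p in puffs:
            bump = np.exp(-((t - p / FPS - 2) ** 2) / (2 * 2.0 ** 2))
            cal += 20 * bump
            nir += 20 * scale_nir * bump
        cal += rng.normal(0, noise_sd, n)
        nir += rng.normal(0, noise_sd, n)
        return Trace(cal, FPS), Trace(nir, FPS), puffs

    def test_identical_channels_identical_amplitudes(self, cfg):
        cal, nir, puffs = self._puff_pair(1.0, 0.0)
        out = puff_response_pipeline(cal, nir, puffs, cfg)
        assert out["cal"]["amplitude"].amplitude == pytest.approx(
            out["nir"]["amplitude"].amplitude, rel=1e-9)

    def test_flat_nir_is_negative_control(self, cfg):
        cal, _, puffs = self._puff_pair(1.0, 0.05, seed=4)
        rng = np.random.default_rng(9)
        nir = Trace(100.0 + rng.normal(0, 0.05, len(cal)), FPS)
        out = puff_response_pipeline(cal, nir, puffs, cfg)
        assert out["cal"]["amplitude"].amplitude > 10 * abs(out["nir"]["amplitude"].amplitude)

    def test_coupled_scale_recovered(self, cfg):
        cal, nir, puffs = self._puff_pair(0.3, 0.01, seed=7)
        out = puff_response_pipeline(cal, nir, puffs, cfg)
        ratio = out["nir"]["amplitude"].amplitude / out["cal"]["amplitude"].amplitude
        assert ratio == pytest.approx(0.3, rel=0.1)

    def test_mismatched_channels_rejected(self, cfg):
        with pytest.raises(ValueError, match="frame rate"):
            puff_response_pipeline(Trace(np.ones(100) * 2, FPS),
                                   Trace(np.ones(100) * 2, 2 * FPS), [50], cfg)
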