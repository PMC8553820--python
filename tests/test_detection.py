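"""Detector chain: filter, envelope, threshold scan, intrinsic frequency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import oracle_detect

from ripplelearn.detection import (
    DetectionSpec,
    SWREvent,
    bandpass_filter,
    compute_envelope_z,
    detect_events,
    intrinsic_frequency,
    resample_to_target,
)

RATE = 2000.0


class TestResample:
    def test_length_ratio(self):
        x = np.random.default_rng(0).standard_normal(160_000)  # 4 s at 40 kHz
        y = resample_to_target(x, 40_000, 2_000)
        assert abs(len(y) - 8000) <= 1

    def test_tone_survives_below_new_nyquist(self):
        t = np.arange(0, 4.0, 1 / 40_000)
        x = np.sin(2 * np.pi * 300 * t)
        y = resample_to_target(x, 40_000, 2_000)
        spec = np.abs(np.fft.rfft(y[1000:-1000]))
        freqs = np.fft.rfftfreq(len(y[1000:-1000]), 1 / 2000)
        assert abs(freqs[np.argmax(spec)] - 300) < 2
        assert np.ptp(y[1000:-1000]) / 2 > 0.95  # amplitude loss < 5%

    def test_identity_and_error(self):
        x = np.arange(100.0)
        assert np.array_equal(resample_to_target(x, 2000, 2000), x)
        with pytest.raises(ValueError):
            resample_to_target(x, 1000, 2000)


class TestBandpass:
    def _gain(self, freq):
        t = np.arange(0, 4.0, 1 / RATE)
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_filter(x, RATE)
        core = y[2000:-2000]
        return np.abs(core).max()

    def test_passband_and_stopband(self):
        g150 = self._gain(150)
        assert g150 >= 0.9
        assert self._gain(10) <= 0.1
        # 50 Hz at least 20 dB below 150 Hz
        assert 20 * np.log10(self._gain(50) / g150) <= -20

    def test_zero_phase(self):
        # 150 Hz tone peaks must not be displaced (forward-backward filter)
        from scipy.signal import find_peaks

        t = np.arange(0, 2.0, 1 / RATE)
        x = np.sin(2 * np.pi * 150 * t)
        y = bandpass_filter(x, RATE)
        seg = slice(1000, 3000)
        px, _ = find_peaks(x[seg])
        py, _ = find_peaks(y[seg])
        assert np.abs(px[:20] - py[:20]).max() <= 1

    def test_linearity_zero_and_short_error(self):
        assert np.allclose(bandpass_filter(np.zeros(5000), RATE), 0.0)
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(30), RATE)


class TestEnvelope:
    def test_constant_tone_envelope_flat(self):
        # |analytic(a sin)| ~ a: away from edges the envelope is constant
        from scipy.signal import hilbert

        t = np.arange(0, 4.0, 1 / RATE)
        x = 2.5 * np.sin(2 * np.pi * 150 * t)
        env = np.abs(hilbert(x))[2000:-2000]
        assert env.std() / env.mean() < 0.05
        assert env.mean() == pytest.approx(2.5, rel=0.01)

    def test_zscore_baseline_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = bandpass_filter(rng.standard_normal(8000), RATE)
        sws = [(0.5, 3.5)]
        z = compute_envelope_z(x, RATE, sws)
        mask = np.zeros(8000, bool)
        mask[1000:7000] = True
        assert abs(z[mask].mean()) < 1e-6
        assert abs(z[mask].std() - 1) < 1e-6
        z2 = compute_envelope_z(2 * x, RATE, sws)
        assert np.allclose(z, z2, atol=1e-9)

    def test_empty_sws_errors(self):
        with pytest.raises(ValueError):
            compute_envelope_z(np.ones(4000), RATE, [])


def _bump(n_before, width, z, n_after, base=0.0):
    env = np.full(n_before + width + n_after, base)
    env[n_before : n_before + width] = z
    return env


class TestDetectEvents:
    def test_zero_envelope(self):
        assert detect_events(np.zeros(4000), RATE) == []

    def test_single_rectangular_bump(self):
        # z=6 for 50 ms: onset/offset at the 2-crossings
        env = _bump(1000, 100, 6.0, 1000)
        (ev,) = detect_events(env, RATE)
        assert ev.onset == pytest.approx(0.5)
        assert ev.offset == pytest.approx(0.55)
        assert ev.duration_ms == pytest.approx(50.0)
        assert ev.peak_z == 6.0

    def test_merge_within_20ms(self):
        # two 30 ms bumps separated by 15 ms merge into one 75 ms bout
        env = np.zeros(4000)
        env[1000:1060] = 6.0
        env[1090:1150] = 6.0
        (ev,) = detect_events(env, RATE)
        assert ev.duration_ms == pytest.approx(75.0)

    def test_discard_longer_than_100ms(self):
        env = _bump(1000, 240, 6.0, 1000)  # 120 ms
        assert detect_events(env, RATE) == []

    def test_needs_peak_threshold(self):
        env = _bump(1000, 100, 4.0, 1000)  # exceeds 2 but never 5
        assert detect_events(env, RATE) == []

    def test_matches_oracle_on_random_envelopes(self):
        rng = np.random.default_rng(7)
        spec = DetectionSpec()
        for _ in range(200):
            n = int(rng.integers(50, 2000))
            # piecewise envelope with plateaus crossing both thresholds
            env = np.abs(rng.normal(0, 1.5, n))
            for _ in range(rng.integers(0, 6)):
                i = int(rng.integers(0, n))
                w = int(rng.integers(1, 300))
                env[i : i + w] += rng.uniform(0, 7)
            got = detect_events(env, RATE, spec)
            want = oracle_detect(env, RATE, spec)
            assert len(got) == len(want)
            for ev, (i0, i1, pk) in zip(got, want):
                assert ev.onset == pytest.approx(i0 / RATE)
                assert ev.offset == pytest.approx(i1 / RATE)
                assert ev.peak_time == pytest.approx(pk / RATE)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_peak_threshold_monotonicity(self, seed):
        # On well-separated bumps (no merging) raising the peak threshold
        # can only remove events.  (With dense sub-threshold activity the
        # full merge-then-discard chain is not monotone: a lower threshold
        # can merge candidates into a bout long enough to be discarded.)
        rng = np.random.default_rng(seed)
        env = np.zeros(2000)
        pos = 100
        while pos < 1900:
            w = int(rng.integers(10, 120))
            env[pos : pos + w] = rng.uniform(3.0, 8.0)
            pos += w + int(rng.integers(60, 200))  # gaps >= 30 ms
        counts = [
            len(detect_events(env, RATE, DetectionSpec(peak_threshold=pt)))
            for pt in (3.5, 5.0, 6.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_contract_invariants_on_random_envelopes(self):
        rng = np.random.default_rng(11)
        spec = DetectionSpec()
        env = np.abs(rng.normal(0, 2.5, 50_000))
        events = detect_events(env, RATE, spec)
        assert events == sorted(events, key=lambda e: e.onset)
        for a, b in zip(events, events[1:]):
            assert (b.onset - a.offset) * 1000 >= spec.merge_gap_ms - 1e-9
        for ev in events:
            assert ev.duration_ms <= spec.max_duration_ms
            assert ev.peak_z >= spec.peak_threshold


class TestIntrinsicFrequency:
    def _clean_burst_event(self, f, dur_ms=64.0):
        from ripplelearn.synthetic import synthesize_ripple

        w = synthesize_ripple(f, dur_ms, 1.0, RATE)
        ev = SWREvent(
            onset=0.0, offset=w.size / RATE, peak_time=w.size / 2 / RATE, peak_z=6.0
        )
        return w, ev

    @pytest.mark.parametrize("f", [120.0, 150.0, 200.0])
    def test_clean_bursts(self, f):
        w, ev = self._clean_burst_event(f)
        assert intrinsic_frequency(w, ev, RATE) == pytest.approx(f, abs=2.0)

    def test_linear_chirp_mean(self):
        # 120 -> 180 Hz across the event: mean instantaneous frequency 150
        n = 256
        t = np.arange(n) / RATE
        phase = 2 * np.pi * (120 * t + 0.5 * (180 - 120) / t[-1] * t**2)
        x = np.sin(phase)
        ev = SWREvent(onset=0.0, offset=n / RATE, peak_time=n / 2 / RATE, peak_z=6.0)
        assert intrinsic_frequency(x, ev, RATE) == pytest.approx(150.0, abs=3.0)

    def test_too_short_event_errors(self):
        x = np.random.default_rng(0).standard_normal(1000)
        ev = SWREvent(onset=0.1, offset=0.1005, peak_time=0.1, peak_z=6.0)
        with pytest.raises(ValueError):
            intrinsic_frequency(x, ev, RATE)
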