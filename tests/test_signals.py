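"""Signal-processing contracts: filter responses, beat detection, HRV
statistics against brute-force oracles, windowed series arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from archepsy import (
    BeatSeries,
    ChannelSignal,
    InsufficientDataError,
    InsufficientSignalError,
    InvalidArgumentError,
    bandlimit_ecg,
    detect_beats,
    heart_rate_windows,
    hrv_frequency_domain,
    hrv_time_domain,
    respiration_rate_windows,
    scl_component,
    scr_component,
    synthesize_ecg,
    temperature_windows,
)


def sinusoid(freq, fs, duration, channel="ecg", amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return ChannelSignal(channel, fs, amp * np.sin(2 * np.pi * freq * t))


def steady_rms(x, fs, skip_s=5.0):
    """RMS away from the filter edge transients."""
    k = int(skip_s * fs)
    return np.sqrt(np.mean(x[k:-k] ** 2))


class TestECGBandlimit:
    def test_mains_hum_suppressed(self):
        sig = sinusoid(50.0, 512, 30)
        out = bandlimit_ecg(sig)
        assert steady_rms(out.values, 512) < 0.05 * steady_rms(sig.values, 512)

    def test_dc_removed(self):
        sig = ChannelSignal("ecg", 512, np.full(512 * 30, 3.0))
        out = bandlimit_ecg(sig)
        assert np.max(np.abs(out.values[512 * 5 : -512 * 5])) < 1e-3

    def test_passband_gain_near_unity(self):
        sig = sinusoid(10.0, 512, 30)
        out = bandlimit_ecg(sig)
        gain = steady_rms(out.values, 512) / steady_rms(sig.values, 512)
        assert 0.9 <= gain <= 1.1

    def test_zero_phase_preserves_peak_positions(self):
        """A train of impulses keeps its peak sample positions."""
        fs = 512
        x = 0.001 * np.ones(fs * 20)
        idx = np.arange(fs, fs * 19, fs)
        x[idx] = 1.0
        out = bandlimit_ecg(ChannelSignal("ecg", fs, x))
        for i in idx:
            local = i - 5 + np.argmax(out.values[i - 5 : i + 6])
            assert abs(local - i) <= 1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bandlimit_ecg(sinusoid(10.0, 128, 10))


class TestBeatDetection:
    def test_flatline_raises(self):
        with pytest.raises(InsufficientSignalError):
            detect_beats(ChannelSignal("ecg", 512, np.zeros(512 * 30)))

    def test_metronomic_beats_give_constant_rr(self):
        sig, _ = synthesize_ecg(60, hrv_scale=0, duration=60, seed=0, noise=0.0)
        beats = detect_beats(bandlimit_ecg(sig))
        assert np.allclose(beats.rr_ms, 1000.0, atol=1e-6)

    def test_recall_and_timing_on_known_beats(self):
        sig, truth = synthesize_ecg(75, hrv_scale=1, duration=120, seed=5)
        det = detect_beats(bandlimit_ecg(sig)).beat_times
        d = np.min(np.abs(truth[:, None] - det[None, :]), axis=1)
        assert np.mean(d <= 0.010) >= 0.99


class TestHeartRateWindows:
    @staticmethod
    def _beats_from_rr(rr_s):
        t = np.concatenate([[0.0], np.cumsum(rr_s)])
        rr_ms = np.diff(t) * 1000
        mid = (t[:-1] + t[1:]) / 2
        return BeatSeries(t, rr_ms, mid)

    def test_constant_rr(self):
        beats = self._beats_from_rr(np.ones(300))
        ws = heart_rate_windows(beats, 300)
        assert len(ws) == 30
        assert np.allclose(ws.values, 60.0)

    def test_alternating_rr(self):
        rr = np.tile([0.8, 1.0], 170)[:330]
        ws = heart_rate_windows(self._beats_from_rr(rr), 300)
        # a 10-s window holds ~11 alternating intervals, so single
        # windows can be off by one 800 vs 1000 interval
        assert np.allclose(ws.values, 60000.0 / 900.0, atol=0.75)
        assert abs(ws.values.mean() - 60000.0 / 900.0) < 0.1

    def test_empty_window_imputed_and_flagged(self):
        # beats only in the first 20 s of a 30-s epoch
        beats = self._beats_from_rr(np.full(20, 1.0))
        ws = heart_rate_windows(beats, 30)
        assert len(ws) == 3
        assert ws.imputed[2] and not ws.imputed[0]
        assert ws.values[2] == ws.values[1]


class TestHRVTimeDomain:
    def test_constant_rr_is_zero(self):
        assert hrv_time_domain(np.full(10, 800.0)) == (0.0, 0.0, 0.0)

    def test_worked_example(self):
        rr = np.array([800.0, 1000.0, 800.0, 1000.0, 800.0])
        sdnn, rmssd, sdsd = hrv_time_domain(rr)
        assert rmssd == pytest.approx(200.0, abs=1e-12)
        assert sdnn == pytest.approx(109.54451150103323, abs=1e-9)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            hrv_time_domain([800.0, 810.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(400, 1500), min_size=3, max_size=200))
    def test_matches_bruteforce_formulas(self, rr):
        """Sample-SD and successive-difference formulas written as
        explicit loops agree with the implementation to 1e-9."""
        rr = np.asarray(rr)
        sdnn, rmssd, sdsd = hrv_time_domain(rr)
        n = len(rr)
        mean = sum(rr) / n
        sdnn_ref = (sum((x - mean) ** 2 for x in rr) / (n - 1)) ** 0.5
        diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
        rmssd_ref = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
        dmean = sum(diffs) / len(diffs)
        sdsd_ref = (
            sum((d - dmean) ** 2 for d in diffs) / (len(diffs) - 1)
        ) ** 0.5 if len(diffs) > 1 else 0.0
        assert sdnn == pytest.approx(sdnn_ref, abs=1e-9)
        assert rmssd == pytest.approx(rmssd_ref, abs=1e-9)
        assert sdsd == pytest.approx(sdsd_ref, abs=1e-9)


def modulated_beats(freq, depth_ms=50.0, duration=300.0, rr0_ms=1000.0):
    """Beat series whose RR series oscillates at exactly one frequency."""
    times = [0.0]
    while times[-1] < duration:
        rr = rr0_ms + depth_ms * np.sin(2 * np.pi * freq * times[-1])
        times.append(times[-1] + rr / 1000.0)
    t = np.array(times)
    return BeatSeries(t, np.diff(t) * 1000, (t[:-1] + t[1:]) / 2)


class TestHRVFrequencyDomain:
    def test_lf_modulation_dominates(self):
        total, vlf, lf, hf, lf_hf = hrv_frequency_domain(modulated_beats(0.10))
        assert lf_hf > 5

    def test_hf_modulation_dominates(self):
        total, vlf, lf, hf, lf_hf = hrv_frequency_domain(modulated_beats(0.30))
        assert lf_hf < 0.2

    def test_constant_rr_has_negligible_power(self):
        beats = modulated_beats(0.1, depth_ms=0.0, duration=120)
        total, vlf, lf, hf, _ = hrv_frequency_domain(beats)
        assert total < 1e-12

    def test_band_partition(self):
        """Powers are non-negative and the named bands never exceed the
        total power."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            t = np.cumsum(rng.uniform(0.7, 1.2, 200))
            beats = BeatSeries(t, np.diff(t) * 1000, (t[:-1] + t[1:]) / 2)
            total, vlf, lf, hf, _ = hrv_frequency_domain(beats)
            assert min(vlf, lf, hf) >= 0
            assert vlf + lf + hf <= total * (1 + 1e-6)

    def test_short_epoch_rejected(self):
        with pytest.raises(InsufficientDataError):
            hrv_frequency_domain(modulated_beats(0.1, duration=30))


class TestEDADecomposition:
    def test_constant_input(self):
        sig = ChannelSignal("skin_conductance", 256, np.full(256 * 60, 5.0))
        scl = scl_component(sig)
        scr = scr_component(sig)
        assert np.allclose(scl.values, 5.0, atol=1e-6)
        assert np.max(np.abs(scr.values)) < 1e-6

    def test_slow_wave_is_tonic(self):
        sig = sinusoid(0.05, 256, 120, channel="skin_conductance")
        scl = scl_component(sig).values
        scr = scr_component(sig).values
        assert steady_rms(scl, 256, 20) > 0.9 * steady_rms(sig.values, 256, 20)
        assert steady_rms(scr, 256, 20) < 0.10 * steady_rms(sig.values, 256, 20)

    def test_scr_selects_fast_content(self):
        """SCR passes the 0.75 Hz wave while rejecting the 0.05 Hz one;
        SCL discriminates in the opposite direction.  (SCR is the SCL
        low-pass cascaded with a high-pass, so its absolute gain can
        never exceed SCL's at any frequency; selectivity is the
        meaningful contrast.)"""
        fast = sinusoid(0.75, 256, 120, channel="skin_conductance")
        slow = sinusoid(0.05, 256, 120, channel="skin_conductance")
        in_rms = steady_rms(fast.values, 256, 20)
        scr_fast = steady_rms(scr_component(fast).values, 256, 20)
        scr_slow = steady_rms(scr_component(slow).values, 256, 20)
        scl_fast = steady_rms(scl_component(fast).values, 256, 20)
        scl_slow = steady_rms(scl_component(slow).values, 256, 20)
        assert scr_fast > 0.5 * in_rms
        assert scr_slow < 0.05 * in_rms
        assert scr_fast / scr_slow > scl_fast / scl_slow


class TestRespirationRate:
    def test_pure_sinusoid_rate(self):
        sig = sinusoid(0.25, 32, 300, channel="respiration")
        ws = respiration_rate_windows(sig)
        assert len(ws) == 30
        assert np.allclose(ws.values, 15.0, atol=0.05)

    def test_paced_breathing_rate(self):
        sig = sinusoid(14.0 / 60.0, 32, 300, channel="respiration")
        ws = respiration_rate_windows(sig)
        assert np.allclose(ws.values, 14.0, atol=0.15)

    def test_rate_ramp_is_monotone(self):
        fs, duration = 32.0, 300.0
        t = np.arange(int(duration * fs)) / fs
        rate = 12.0 + 6.0 * t / duration  # breaths/min, 12 -> 18
        phase = 2 * np.pi * np.cumsum(rate / 60.0) / fs
        sig = ChannelSignal("respiration", fs, np.sin(phase))
        ws = respiration_rate_windows(sig)
        assert np.all(np.diff(ws.values) > -0.2)
        assert ws.values[-1] > ws.values[0] + 4

    def test_no_breaths_raises(self):
        sig = ChannelSignal("respiration", 32, np.zeros(32 * 60))
        with pytest.raises(InsufficientSignalError):
            respiration_rate_windows(sig)


class TestTemperatureWindows:
    def test_constant_trace(self):
        sig = ChannelSignal("skin_temperature", 32, np.full(32 * 300, 33.0))
        ws = temperature_windows(sig)
        assert len(ws) == 30
        assert np.allclose(ws.values, 33.0, atol=1e-6)

    def test_linear_ramp_first_window(self):
        """33 -> 34 degC over 300 s: the first 10-s mean is the integral
        of the ramp, 33 + (10/300)/2 ~= 33.0167."""
        t = np.arange(32 * 300) / 32.0
        sig = ChannelSignal("skin_temperature", 32, 33.0 + t / 300.0)
        ws = temperature_windows(sig)
        assert ws.values[0] == pytest.approx(33.0 + 10.0 / 600.0, abs=5e-3)

    @pytest.mark.parametrize("duration,expected", [(300, 30), (305, 30), (45, 4)])
    def test_window_count_floor_rule(self, duration, expected):
        sig = ChannelSignal(
            "skin_temperature", 32, np.full(int(32 * duration), 33.0)
        )
        assert len(temperature_windows(sig)) == expected
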