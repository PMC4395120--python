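"""Generator contracts: beat-process arithmetic, Poisson event counts,
SAM distribution, cohort structure and determinism."""

import numpy as np
import pytest

from archepsy import (
    ALL_CLASSES,
    CohortConfig,
    InvalidArgumentError,
    default_profiles,
    generate_cohort,
    generate_sam,
    scale_profile,
    synthesize_ecg,
    synthesize_respiration,
    synthesize_skin_conductance,
    synthesize_temperature,
)
from archepsy.profiles import ClassEffectProfile


class TestECG:
    def test_zero_variability_metronome(self):
        _, beats = synthesize_ecg(60, hrv_scale=0, duration=300, seed=0)
        assert len(beats) == 300
        assert np.allclose(np.diff(beats), 1.0, atol=1e-12)

    def test_mean_rr_closed_form(self):
        _, beats = synthesize_ecg(72, hrv_scale=0, duration=300, seed=0)
        assert abs(np.mean(np.diff(beats)) - 60.0 / 72.0) < 1e-9

    def test_variability_present(self):
        _, beats = synthesize_ecg(60, hrv_scale=1, duration=120, seed=3)
        rr = np.diff(beats) * 1000
        rmssd = np.sqrt(np.mean(np.diff(rr) ** 2))
        assert rmssd > 0

    def test_peaks_align_with_beat_times(self):
        """Ground-truth consistency: each returned beat time falls on the
        local argmax of the rendered R-peak, within one sample."""
        sig, beats = synthesize_ecg(70, hrv_scale=1, duration=60, seed=7, noise=0.0)
        fs = sig.sampling_rate
        for t in beats[1:-1]:
            c = int(round(t * fs))
            lo, hi = c - 20, c + 21
            local = lo + np.argmax(sig.values[lo:hi])
            assert abs(local - t * fs) <= 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean_hr=20, hrv_scale=0, duration=60),
            dict(mean_hr=250, hrv_scale=0, duration=60),
            dict(mean_hr=60, hrv_scale=0, duration=5),
            dict(mean_hr=60, hrv_scale=0, duration=60, fs=-1),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            synthesize_ecg(**kwargs, seed=0)


class TestSkinConductance:
    def test_tonic_only_when_no_events(self):
        sig = synthesize_skin_conductance(5.0, 0.0, 0.0, 120, seed=0)
        # constant level plus the slow 0.1-uS sinusoid, nothing else
        assert np.all(np.abs(sig.values - 5.0) <= 0.1 + 1e-9)

    def test_poisson_event_count(self):
        """rate 6/min over 300 s injects 30 events in expectation."""
        counts = [
            len(
                synthesize_skin_conductance(
                    5.0, 0.0, 6.0, 300, seed=s, return_events=True
                )[1]
            )
            for s in range(100)
        ]
        mean = np.mean(counts)
        # Poisson(30): SE of the mean over 100 draws is ~0.55
        assert abs(mean - 30.0) < 3 * np.sqrt(30.0 / 100)

    def test_deterministic_under_seed(self):
        a = synthesize_skin_conductance(5.0, 0.3, 6.0, 60, seed=9)
        b = synthesize_skin_conductance(5.0, 0.3, 6.0, 60, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_skin_conductance(5.0, 0.0, -1.0, 60, seed=0)


class TestRespirationAndTemperature:
    @pytest.mark.parametrize("rate,freq", [(15.0, 0.25), (14.0, 14.0 / 60.0)])
    def test_dominant_spectral_peak(self, rate, freq):
        sig = synthesize_respiration(rate, 300, seed=0)
        spec = np.abs(np.fft.rfft(sig.values - sig.values.mean()))
        freqs = np.fft.rfftfreq(len(sig.values), 1 / sig.sampling_rate)
        assert abs(freqs[np.argmax(spec)] - freq) < 0.01

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_respiration(0.0, 60, seed=0)

    def test_noise_free_temperature_is_constant(self):
        sig = synthesize_temperature(33.0, 0.0, 60, seed=0, noise_amp=0.0)
        assert np.allclose(sig.values, 33.0)


class TestSAM:
    def _profile(self, means, sds):
        return ClassEffectProfile(
            delta_hr=0, hrv_scale=1, scr_rate=0, scl_slope=0,
            resp_rate=14, st_slope=0, sam_means=means, sam_sds=sds,
        )

    def test_zero_sd_is_deterministic(self):
        p = self._profile((5.0, 5.0, 5.0), (0.0, 0.0, 0.0))
        for s in range(5):
            r = generate_sam(p, seed=s)
            assert (r.arousal, r.valence, r.dominance) == (5, 5, 5)

    def test_raw_draws_recover_generating_mean(self):
        """Unclipped anima arousal draws average to the published 5.320."""
        p = default_profiles()["anima"]
        rng = np.random.default_rng(0)
        draws = np.array([generate_sam(p, rng, raw=True)[0] for _ in range(100_000)])
        assert abs(draws.mean() - 5.320) < 0.05

    def test_outputs_clipped_to_scale(self):
        p = self._profile((8.9, 1.1, 5.0), (3.0, 3.0, 3.0))
        rng = np.random.default_rng(2)
        reports = [generate_sam(p, rng) for _ in range(200)]
        vals = np.array([[r.arousal, r.valence, r.dominance] for r in reports])
        assert vals.min() >= 1 and vals.max() <= 9
        assert (vals[:, 0] == 9).any() and (vals[:, 1] == 1).any()


class TestCohort:
    def test_structure(self, small_cohort):
        assert len(small_cohort) == 4
        for session in small_cohort:
            assert session.classes() == ALL_CLASSES
            for pair in session.epochs.values():
                for epoch in (pair.baseline, pair.stimulus):
                    for ch in ("ecg", "skin_conductance", "respiration",
                               "skin_temperature"):
                        assert ch in epoch
                assert pair.stimulus["ecg"].duration == 300.0
                assert pair.baseline["ecg"].duration == 40.0
                assert 1 <= pair.sam.arousal <= 9

    def test_determinism(self):
        cfg = CohortConfig(n_subjects=3, stimulus_duration=60, seed=5)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pa = a[1].epochs["hero"].stimulus
        pb = b[1].epochs["hero"].stimulus
        for ch in ("ecg", "skin_conductance"):
            assert np.array_equal(pa[ch].values, pb[ch].values)
        assert a[2].epochs["anima"].sam == b[2].epochs["anima"].sam

    def test_null_cohort_has_no_class_structure(self):
        """effect_size=0: per-class mean heart rates agree within the
        epoch-level sampling noise."""
        cfg = CohortConfig(n_subjects=6, effect_size=0.0, seed=8,
                           stimulus_duration=60)
        cohort = generate_cohort(cfg)
        class_hr = {}
        for cls in ALL_CLASSES:
            hrs = [
                60.0 / np.mean(np.diff(s.epochs[cls].true_beat_times))
                for s in cohort
            ]
            class_hr[cls] = np.mean(hrs)
        vals = np.array(list(class_hr.values()))
        # epoch HR noise sd = 2 bpm; class means over 6 subjects have
        # sd ~0.8 after subject pairing, so a 3-bpm spread is generous
        assert vals.max() - vals.min() < 3.0

    def test_scale_profile_null_collapses_classes(self):
        profs = default_profiles()
        nulls = {c: scale_profile(p, 0.0) for c, p in profs.items()}
        ref = nulls["anima"]
        for p in nulls.values():
            assert p.delta_hr == ref.delta_hr == 0.0
            assert p.resp_rate == ref.resp_rate
            assert p.scr_rate == ref.scr_rate

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CohortConfig(n_subjects=3, subject_ids=("a", "a", "b"), seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_subjects=2),
            dict(stimulus_duration=305.0),
            dict(effect_size=1.5),
            dict(classes=("anima", "anima")),
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            CohortConfig(seed=0, **kwargs)
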