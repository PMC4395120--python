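"""Seeded synthetic cohorts of autonomic recordings and SAM reports.

The generator emulates the study design end to end: ``n_subjects``
subjects each contribute one 40-s paced-breathing baseline epoch and one
300-s stimulus epoch per film-clip class, across four channels (ECG at
512 Hz, skin conductance at 256 Hz, respiration and skin temperature at
32 Hz), plus an integer SAM report per stimulus.  Class structure enters
through :class:`~archepsy.profiles.ClassEffectProfile`; a single
``effect_size`` knob interpolates between a null cohort (0, all classes
share the resting parameters) and the full shipped effects (1).

Every waveform model here is deliberately minimal: only the properties
the downstream feature extractor measures are modelled (beat timing and
its variability, tonic level/drift and phasic event rate, breathing
frequency, temperature drift).  Ground-truth annotations (true beat
times, true respiration rate) ride along for detector validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidArgumentError
from .profiles import (
    BASELINE_HR_BPM,
    BASELINE_RESP_BPM,
    BASELINE_SCL_US,
    BASELINE_SCR_RATE,
    BASELINE_TEMP_C,
    ClassEffectProfile,
    default_profiles,
    scale_profile,
)
from .types import (
    ALL_CLASSES,
    ChannelSignal,
    Epoch,
    EpochPair,
    SAMReport,
    SessionRecording,
)

#: per-channel sampling rates, Hz
ECG_FS = 512.0
EDA_FS = 256.0
RESP_FS = 32.0
TEMP_FS = 32.0

#: segment length the feature extractor uses; stimulus duration must be a
#: multiple of it
SEGMENT_S = 10.0

# RR-interval modulation: fractional amplitudes of the sympathetically
# (0.1 Hz) and parasympathetically (0.25 Hz) mediated oscillations, plus
# white beat-to-beat jitter, all scaled by hrv_scale.
_LF_FREQ, _HF_FREQ = 0.10, 0.25
_LF_AMP, _HF_AMP, _JITTER_SD = 0.03, 0.02, 0.01

_QRS_SIGMA_S = 0.012   # Gaussian R-wave width
_ECG_NOISE = 0.02      # baseline noise amplitude relative to R amplitude

_SCR_RISE_S, _SCR_DECAY_S = 1.0, 3.0
_SCR_AMP_US = 0.4      # median phasic event amplitude


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    ``effect_size`` in [0, 1] scales every class effect; 0 yields a null
    cohort with no class-dependent structure.
    """

    n_subjects: int = 25
    classes: tuple[str, ...] = ALL_CLASSES
    stimulus_duration: float = 300.0
    baseline_duration: float = 40.0
    effect_size: float = 1.0
    seed: int = 0
    subject_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise InvalidArgumentError("n_subjects must be >= 3")
        if len(set(self.classes)) != len(self.classes):
            raise InvalidArgumentError("class labels must be unique")
        if self.stimulus_duration <= 0 or (
            self.stimulus_duration % SEGMENT_S
        ) != 0:
            raise InvalidArgumentError(
                f"stimulus_duration must be a positive multiple of {SEGMENT_S} s"
            )
        if self.baseline_duration <= 0:
            raise InvalidArgumentError("baseline_duration must be positive")
        if not 0.0 <= self.effect_size <= 1.0:
            raise InvalidArgumentError("effect_size must lie in [0, 1]")
        if self.subject_ids is not None:
            if len(self.subject_ids) != self.n_subjects:
                raise InvalidArgumentError("subject_ids length != n_subjects")
            if len(set(self.subject_ids)) != len(self.subject_ids):
                raise InvalidArgumentError("duplicate subject ids")

    def resolved_subject_ids(self) -> tuple[str, ...]:
        if self.subject_ids is not None:
            return self.subject_ids
        return tuple(f"S{i + 1:02d}" for i in range(self.n_subjects))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synthesize_ecg(
    mean_hr: float,
    hrv_scale: float,
    duration: float,
    fs: float = ECG_FS,
    seed=0,
    noise: float = _ECG_NOISE,
) -> tuple[ChannelSignal, np.ndarray]:
    """Quasi-periodic ECG-like trace with a known beat process.

    Beat-to-beat intervals follow ``RR = (60/mean_hr) * (1 + m(t))``
    where ``m`` combines 0.1 Hz and 0.25 Hz sinusoids and white jitter,
    all scaled by ``hrv_scale`` (0 gives metronomic beats).  Each beat is
    rendered as a Gaussian R-like peak of unit amplitude.

    Returns the signal and the exact beat times used (seconds).
    """
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    if not 30.0 <= mean_hr <= 200.0:
        raise InvalidArgumentError("mean_hr must lie in [30, 200] beats/min")
    if duration <= 10.0:
        raise InvalidArgumentError("duration must exceed 10 s")
    rng = _as_rng(seed)

    rr0 = 60.0 / mean_hr
    # generate beats sequentially; start half an interval in so the first
    # peak is fully rendered
    beats = []
    t = rr0 / 2.0
    while t < duration - rr0 / 4.0:
        beats.append(t)
        mod = hrv_scale * (
            _LF_AMP * np.sin(2 * np.pi * _LF_FREQ * t)
            + _HF_AMP * np.sin(2 * np.pi * _HF_FREQ * t)
            + _JITTER_SD * rng.standard_normal()
        )
        t = t + rr0 * (1.0 + mod)
    beat_times = np.asarray(beats)

    n = int(round(duration * fs))
    values = noise * rng.standard_normal(n) if noise > 0 else np.zeros(n)
    # render all R peaks vectorised: identical-width index windows
    half = int(np.ceil(4 * _QRS_SIGMA_S * fs))
    offsets = np.arange(-half, half + 1)
    centers = np.round(beat_times * fs).astype(int)
    idx = centers[:, None] + offsets[None, :]
    tt = idx / fs
    vals = np.exp(-0.5 * ((tt - beat_times[:, None]) / _QRS_SIGMA_S) ** 2)
    ok = (idx >= 0) & (idx < n)
    np.add.at(values, idx[ok], vals[ok])

    return ChannelSignal("ecg", fs, values), beat_times


def _scr_kernel(fs: float) -> np.ndarray:
    """Bi-exponential phasic response, unit peak amplitude."""
    t = np.arange(0, 8 * _SCR_DECAY_S, 1.0 / fs)
    h = np.exp(-t / _SCR_DECAY_S) - np.exp(-t / _SCR_RISE_S)
    return h / h.max()


def synthesize_skin_conductance(
    scl_level: float,
    scl_slope: float,
    scr_rate: float,
    duration: float,
    fs: float = EDA_FS,
    seed=0,
    return_events: bool = False,
) -> ChannelSignal:
    """Tonic trace (level + drift + slow sinusoid) with superimposed
    bi-exponential phasic responses at Poisson-distributed onsets.

    ``scl_slope`` is in microsiemens/min, ``scr_rate`` in events/min.
    With ``return_events=True`` also returns the injected onset times.
    """
    if fs < 32:
        raise InvalidArgumentError("fs must be >= 32 Hz for skin conductance")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if scl_level <= 0:
        raise InvalidArgumentError("scl_level must be positive")
    if scr_rate < 0:
        raise InvalidArgumentError("scr_rate must be non-negative")
    rng = _as_rng(seed)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    tonic = scl_level + scl_slope * t / 60.0 + 0.1 * np.sin(
        2 * np.pi * 0.01 * t + phase
    )

    values = tonic
    n_events = rng.poisson(scr_rate * duration / 60.0)
    onsets = np.empty(0)
    if n_events > 0:
        kernel = _scr_kernel(fs)
        onsets = np.sort(rng.uniform(0, duration, n_events))
        amps = _SCR_AMP_US * rng.lognormal(mean=0.0, sigma=0.4, size=n_events)
        values = values.copy()
        for onset, amp in zip(onsets, amps):
            i0 = int(round(onset * fs))
            seg = kernel[: n - i0]
            values[i0 : i0 + len(seg)] += amp * seg
    sig = ChannelSignal("skin_conductance", fs, values)
    return (sig, onsets) if return_events else sig


def synthesize_respiration(
    rate: float,
    duration: float,
    fs: float = RESP_FS,
    seed=0,
    noise_amp: float = 0.05,
) -> ChannelSignal:
    """Sinusoidal chest-excursion trace at ``rate`` breaths/min plus
    band-limited noise (white noise low-passed at 1 Hz)."""
    if rate <= 0:
        raise InvalidArgumentError("rate must be positive")
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    rng = _as_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    values = np.sin(2 * np.pi * rate / 60.0 * t + phase)
    if noise_amp > 0:
        sos = sps.butter(2, 1.0, btype="low", fs=fs, output="sos")
        values = values + noise_amp * sps.sosfilt(sos, rng.standard_normal(n))
    return ChannelSignal("respiration", fs, values)


def synthesize_temperature(
    level: float,
    slope: float,
    duration: float,
    fs: float = TEMP_FS,
    seed=0,
    noise_amp: float = 0.01,
) -> ChannelSignal:
    """Skin-temperature trace: ``level + slope * t`` (slope in deg C/min)
    plus low-amplitude slow noise."""
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    rng = _as_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    values = level + slope * t / 60.0
    if noise_amp > 0:
        sos = sps.butter(2, 0.5, btype="low", fs=fs, output="sos")
        values = values + noise_amp * sps.sosfilt(sos, rng.standard_normal(n))
    return ChannelSignal("skin_temperature", fs, values)


def generate_sam(
    profile: ClassEffectProfile, seed=0, raw: bool = False
):
    """Draw one SAM report from the class's normal model.

    Each dimension is drawn ``N(mean, sd)``, rounded to the nearest
    integer and clipped to [1, 9].  With ``raw=True`` the unrounded,
    unclipped draws are returned (useful for checking the generating
    distribution itself).
    """
    rng = _as_rng(seed)
    draws = np.array(
        [rng.normal(m, s) for m, s in zip(profile.sam_means, profile.sam_sds)]
    )
    if raw:
        return draws
    vals = np.clip(np.rint(draws), 1, 9).astype(int)
    return SAMReport(int(vals[0]), int(vals[1]), int(vals[2]))


@dataclass
class _SubjectTraits:
    """Per-subject resting offsets, drawn once per subject."""

    resting_hr: float
    scl_level: float
    temp_level: float
    resp_offset: float
    hrv_factor: float


def _draw_traits(rng: np.random.Generator) -> _SubjectTraits:
    return _SubjectTraits(
        resting_hr=float(np.clip(rng.normal(BASELINE_HR_BPM, 7.0), 45.0, 110.0)),
        scl_level=float(max(rng.normal(BASELINE_SCL_US, 1.5), 1.0)),
        temp_level=float(rng.normal(BASELINE_TEMP_C, 0.4)),
        resp_offset=float(rng.normal(0.0, 1.0)),
        hrv_factor=float(rng.lognormal(0.0, 0.15)),
    )


def _make_epoch(
    traits: _SubjectTraits,
    profile: ClassEffectProfile,
    duration: float,
    rng: np.random.Generator,
    stimulus: bool,
) -> tuple[Epoch, np.ndarray, float]:
    """One epoch across all four channels; returns it with the true beat
    times and the true breathing rate."""
    if stimulus:
        hr = traits.resting_hr + profile.delta_hr + rng.normal(0.0, 2.0)
        hrv = traits.hrv_factor * profile.hrv_scale * rng.lognormal(0.0, 0.1)
        scr_rate = max(profile.scr_rate * rng.lognormal(0.0, 0.2), 0.0)
        scl_slope = profile.scl_slope + rng.normal(0.0, 0.08)
        resp = max(profile.resp_rate + traits.resp_offset + rng.normal(0.0, 0.7), 5.0)
        st_slope = profile.st_slope + rng.normal(0.0, 0.008)
    else:
        # paced-breathing baseline: shared resting parameters
        hr = traits.resting_hr + rng.normal(0.0, 1.0)
        hrv = traits.hrv_factor * rng.lognormal(0.0, 0.1)
        scr_rate = BASELINE_SCR_RATE
        scl_slope = rng.normal(0.0, 0.05)
        resp = BASELINE_RESP_BPM + 0.25 * traits.resp_offset
        st_slope = rng.normal(0.0, 0.005)
    hr = float(np.clip(hr, 40.0, 180.0))

    ecg, beat_times = synthesize_ecg(hr, hrv, duration, ECG_FS, rng)
    eda = synthesize_skin_conductance(
        traits.scl_level, scl_slope, scr_rate, duration, EDA_FS, rng
    )
    rsp = synthesize_respiration(resp, duration, RESP_FS, rng)
    tmp = synthesize_temperature(traits.temp_level, st_slope, duration, TEMP_FS, rng)
    epoch = Epoch(
        {
            "ecg": ecg,
            "skin_conductance": eda,
            "respiration": rsp,
            "skin_temperature": tmp,
        }
    )
    return epoch, beat_times, resp


def generate_cohort(
    config: CohortConfig,
    profiles: dict[str, ClassEffectProfile] | None = None,
) -> list[SessionRecording]:
    """Generate the full cohort: one session per subject.

    All randomness fans out from ``config.seed`` through per-subject and
    per-epoch substreams, so identical inputs give identical cohorts and
    subjects are independent of cohort size ordering.
    """
    if profiles is None:
        profiles = default_profiles()
    missing = [c for c in config.classes if c not in profiles]
    if missing:
        raise InvalidArgumentError(f"no effect profile for classes {missing}")

    scaled = {
        c: scale_profile(profiles[c], config.effect_size) for c in config.classes
    }
    subject_ids = config.resolved_subject_ids()

    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)

    sessions = []
    for sid, sseq in zip(subject_ids, subject_seqs):
        trait_seq, *class_seqs = sseq.spawn(1 + len(config.classes))
        traits = _draw_traits(np.random.default_rng(trait_seq))
        session = SessionRecording(subject_id=sid)
        for cls, cseq in zip(config.classes, class_seqs):
            b_seq, s_seq, sam_seq = cseq.spawn(3)
            baseline, base_beats, _ = _make_epoch(
                traits, scaled[cls], config.baseline_duration,
                np.random.default_rng(b_seq), stimulus=False,
            )
            stim, stim_beats, true_resp = _make_epoch(
                traits, scaled[cls], config.stimulus_duration,
                np.random.default_rng(s_seq), stimulus=True,
            )
            sam = generate_sam(scaled[cls], np.random.default_rng(sam_seq))
            session.epochs[cls] = EpochPair(
                baseline=baseline,
                stimulus=stim,
                sam=sam,
                true_beat_times=stim_beats,
                true_baseline_beat_times=base_beats,
                true_resp_rate=true_resp,
            )
        sessions.append(session)
    return sessions
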