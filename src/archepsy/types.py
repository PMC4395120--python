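"""Core domain containers shared across the pipeline.

The experiment design these mirror: each subject watches eight ~5-minute
film clips (four archetype classes, four explicit-emotion classes).  Every
clip is preceded by a 40-s paced-breathing baseline; four autonomic
channels (ECG, skin conductance, respiration, skin temperature) are
recorded throughout, and after each clip the subject files a
Self-Assessment-Manikin (SAM) report of arousal, valence and dominance on
a 1-9 integer scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, MissingChannelError

#: canonical channel names, in storage order
CHANNELS = ("ecg", "skin_conductance", "respiration", "skin_temperature")

#: the four archetype classes, then the four explicit-emotion classes
ARCHETYPE_CLASSES = ("anima", "animus", "hero", "shadow")
EMOTION_CLASSES = (
    "active-pleasant",
    "active-unpleasant",
    "passive-pleasant",
    "passive-unpleasant",
)
ALL_CLASSES = ARCHETYPE_CLASSES + EMOTION_CLASSES

#: SAM dimensions in storage order
SAM_DIMENSIONS = ("arousal", "valence", "dominance")


@dataclass(frozen=True)
class ChannelSignal:
    """One uniformly sampled physiological trace.

    Parameters
    ----------
    channel : str
        One of :data:`CHANNELS`.
    sampling_rate : float
        Samples per second, > 0.
    values : np.ndarray
        The samples; ``len(values) = duration * sampling_rate``.
    start_time : float
        Offset of the first sample on the session clock, seconds.
    """

    channel: str
    sampling_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InvalidArgumentError(f"unknown channel {self.channel!r}")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise InvalidArgumentError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("signal contains non-finite samples")

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return len(self.values) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times on the session clock, seconds."""
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate


@dataclass(frozen=True)
class SAMReport:
    """One Self-Assessment-Manikin report (integers 1-9 per dimension)."""

    arousal: int
    valence: int
    dominance: int

    def __post_init__(self) -> None:
        for dim in SAM_DIMENSIONS:
            v = getattr(self, dim)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 9):
                raise InvalidArgumentError(
                    f"SAM {dim} must be an integer in [1, 9], got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.arousal, self.valence, self.dominance], dtype=float)


@dataclass
class Epoch:
    """One recording epoch (baseline or stimulus): the four channels."""

    signals: dict[str, ChannelSignal]

    def __getitem__(self, channel: str) -> ChannelSignal:
        try:
            return self.signals[channel]
        except KeyError:
            raise MissingChannelError(channel) from None

    def __contains__(self, channel: str) -> bool:
        return channel in self.signals


@dataclass
class EpochPair:
    """Baseline + stimulus epochs for one film clip, with ground truth.

    ``true_beat_times`` (stimulus epoch, seconds from epoch start) and
    ``true_resp_rate`` (breaths/min) are generator-side annotations kept
    for validating the detectors; real recordings would not carry them.
    """

    baseline: Epoch
    stimulus: Epoch
    sam: SAMReport
    true_beat_times: np.ndarray | None = None
    true_baseline_beat_times: np.ndarray | None = None
    true_resp_rate: float | None = None


@dataclass
class SessionRecording:
    """One subject's full session: an epoch pair per class plus SAM."""

    subject_id: str
    epochs: dict[str, EpochPair] = field(default_factory=dict)

    def classes(self) -> tuple[str, ...]:
        return tuple(self.epochs)


@dataclass(frozen=True)
class BeatSeries:
    """Detected heartbeats: times (s) and cleaned RR intervals (ms).

    ``rr_times`` holds the midpoint of each retained interval so windowed
    statistics can place intervals on the epoch clock.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    rr_times: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if np.any(np.diff(bt) <= 0):
            raise InvalidArgumentError("beat times must be strictly increasing")


@dataclass(frozen=True)
class WindowedSeries:
    """Non-overlapping fixed-window means of a physiological series."""

    window_s: float
    values: np.ndarray
    units: str
    imputed: np.ndarray | None = None  # bool mask of imputed windows

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HRVSummary:
    """The eight conventional heart-rate-variability measures.

    Time domain in ms (SDNN, RMSSD, SDSD); spectral band powers in ms^2
    over VLF 0-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz; LF/HF ratio.
    """

    sdnn: float
    rmssd: float
    sdsd: float
    total_power: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sdnn, self.rmssd, self.sdsd, self.total_power,
             self.vlf, self.lf, self.hf, self.lf_hf]
        )


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validated classification run."""

    classifier: str
    classes: tuple[str, ...]
    predictions: np.ndarray  # per-row predicted class labels
    confusion: np.ndarray    # rows = actual, columns = predicted

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


@dataclass(frozen=True)
class GroupResult:
    """Accuracy of one three-subject group under stratified 3-fold CV."""

    subjects: tuple[str, str, str]
    task: str       # "archetypes" | "emotions"
    modality: str   # "physiological" | "sam"
    accuracy: float


@dataclass(frozen=True)
class TTestResult:
    """A paired-samples t-test."""

    comparison: str
    t: float
    df: int
    p: float
    mean_diff: float
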