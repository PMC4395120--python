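"""Baseline-referenced normalization and the canonical feature vector.

For each stimulus epoch, five per-channel series are reduced to a fixed
vector of 158 named features:

* 30 heart-rate segment means (10-s segments of a 300-s clip),
* the 8 conventional HRV measures, entered without normalization,
* 30 tonic skin-conductance (SCL) segment means,
* 30 phasic skin-conductance (SCR) mean-absolute-amplitude segments,
* 30 respiration-rate segment means,
* 30 skin-temperature segment means.

Segment features are baseline-referenced and min-max scaled: the mean of
the windowed series over the subject's 40-s pre-stimulus baseline is
subtracted, and the residuals are mapped to [0, 1] using the minimum and
maximum of the baseline-subtracted values pooled over that subject's
stimulus epochs for the same signal type.  The within-subject scope is
what lets recordings from different individuals be compared at all:
between-subject offsets (resting heart rate, tonic skin conductance,
skin temperature) are orders of magnitude larger than the stimulus
effects of interest.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, MissingChannelError
from .signals import (
    WINDOW_S,
    bandlimit_ecg,
    detect_beats,
    heart_rate_windows,
    hrv_summary,
    respiration_rate_windows,
    scl_component,
    scr_component,
    temperature_windows,
)
from .types import Epoch, HRVSummary, SessionRecording, WindowedSeries

logger = logging.getLogger(__name__)

N_SEGMENTS = 30
HRV_NAMES = ("sdnn", "rmssd", "sdsd", "total_power", "vlf", "lf", "hf", "lf_hf")
#: signal types carrying segment features, in canonical block order
SEGMENT_SIGNALS = ("hr", "scl", "scr", "resp", "temp")


def feature_names(n_segments: int = N_SEGMENTS) -> list[str]:
    """The canonical ordered feature-name schema (158 names at the
    default 30 segments)."""
    names = [f"hr_seg_{i + 1:02d}" for i in range(n_segments)]
    names += list(HRV_NAMES)
    for block in ("scl", "scr", "resp", "temp"):
        names += [f"{block}_seg_{i + 1:02d}" for i in range(n_segments)]
    return names


def segment_average(
    values: np.ndarray,
    duration: float,
    segment_s: float = WINDOW_S,
) -> np.ndarray:
    """Means of a uniformly sampled series over equal-length segments.

    Returns exactly ``floor(duration / segment_s)`` values; a trailing
    partial segment is discarded.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty series")
    if duration < segment_s:
        raise InvalidArgumentError("duration shorter than one segment")
    n_seg = int(duration // segment_s)
    per = x.size / (duration / segment_s)  # samples per segment
    edges = (np.arange(n_seg + 1) * per).round().astype(int)
    return np.array([x[edges[i] : edges[i + 1]].mean() for i in range(n_seg)])


def baseline_correct_and_scale(
    values: np.ndarray,
    baseline: float,
    scope_min: float,
    scope_max: float,
) -> np.ndarray:
    """Baseline-subtract then min-max scale to [0, 1].

    ``scope_min``/``scope_max`` are the extrema of the baseline-
    subtracted values over the normalization scope (the subject's pooled
    stimulus epochs for this signal).  A degenerate scope
    (``scope_max == scope_min``) maps everything to 0 with a warning.
    """
    x = np.asarray(values, dtype=float) - baseline
    span = scope_max - scope_min
    if span < 0:
        raise InvalidArgumentError("scope_max must be >= scope_min")
    if span == 0:
        warnings.warn(
            "degenerate normalization scope (max == min); features set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(x)
    return (x - scope_min) / span


def _pad_segments(vals: np.ndarray, n_segments: int) -> np.ndarray:
    """Right-pad a short segment series by holding its last value."""
    if len(vals) >= n_segments:
        return vals[:n_segments]
    logger.warning(
        "epoch yielded %d segments; padding to %d by holding the last value",
        len(vals), n_segments,
    )
    return np.concatenate([vals, np.full(n_segments - len(vals), vals[-1])])


def process_epoch_pair(
    baseline: Epoch, stimulus: Epoch, n_segments: int = N_SEGMENTS
) -> tuple[dict[str, np.ndarray], dict[str, float], HRVSummary]:
    """Run the full per-channel processing for one epoch pair.

    Returns (raw segment series per signal type, baseline scalars per
    signal type, stimulus-epoch HRV summary).  Segment values are *not*
    yet normalized; normalization needs the subject-level scope.
    """
    for ch in ("ecg", "skin_conductance", "respiration", "skin_temperature"):
        for ep, tag in ((baseline, "baseline"), (stimulus, "stimulus")):
            if ch not in ep:
                raise MissingChannelError(f"{tag} epoch lacks channel {ch!r}")

    segments: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}

    stim_beats = detect_beats(bandlimit_ecg(stimulus["ecg"]))

    def windowed(epoch: Epoch, which: str) -> WindowedSeries:
        if which == "hr":
            beats = (
                stim_beats
                if epoch is stimulus
                else detect_beats(bandlimit_ecg(epoch["ecg"]))
            )
            return heart_rate_windows(beats, epoch["ecg"].duration)
        if which == "scl":
            scl = scl_component(epoch["skin_conductance"])
            return WindowedSeries(
                WINDOW_S,
                segment_average(scl.values, scl.duration),
                "uS",
            )
        if which == "scr":
            scr = scr_component(epoch["skin_conductance"])
            return WindowedSeries(
                WINDOW_S,
                segment_average(np.abs(scr.values), scr.duration),
                "uS",
            )
        if which == "resp":
            return respiration_rate_windows(epoch["respiration"])
        return temperature_windows(epoch["skin_temperature"])

    for sig in SEGMENT_SIGNALS:
        stim_ws = windowed(stimulus, sig)
        base_ws = windowed(baseline, sig)
        segments[sig] = _pad_segments(np.asarray(stim_ws.values), n_segments)
        baselines[sig] = float(np.mean(base_ws.values))

    hrv = hrv_summary(stim_beats)
    return segments, baselines, hrv


def assemble_features(
    segments: dict[str, np.ndarray],
    hrv: HRVSummary,
    baselines: dict[str, float],
    scopes: dict[str, tuple[float, float]],
    n_segments: int = N_SEGMENTS,
) -> np.ndarray:
    """Assemble one epoch's canonical feature vector.

    ``scopes[sig] = (min, max)`` of baseline-subtracted values over the
    normalization scope for each segment signal.  HRV features enter
    unmodified.
    """
    missing = [s for s in SEGMENT_SIGNALS if s not in segments]
    if missing:
        raise MissingChannelError(f"missing segment series for {missing}")
    blocks = {
        sig: baseline_correct_and_scale(
            segments[sig], baselines[sig], *scopes[sig]
        )
        for sig in SEGMENT_SIGNALS
    }
    vec = np.concatenate(
        [blocks["hr"], hrv.as_array(), blocks["scl"], blocks["scr"],
         blocks["resp"], blocks["temp"]]
    )
    assert vec.size == 5 * n_segments + len(HRV_NAMES)
    return vec


def extract_cohort_features(
    sessions: list[SessionRecording], n_segments: int = N_SEGMENTS
) -> pd.DataFrame:
    """Feature matrix for a whole cohort.

    Rows are stimulus epochs (one per subject x class); columns are the
    canonical feature names, indexed by (subject, class).  The
    normalization scope is per subject and per signal type, pooled over
    that subject's stimulus epochs.
    """
    rows = []
    for session in sessions:
        per_class = {}
        for cls, pair in session.epochs.items():
            per_class[cls] = process_epoch_pair(
                pair.baseline, pair.stimulus, n_segments
            )
        # within-subject normalization scope per signal type
        scopes = {}
        for sig in SEGMENT_SIGNALS:
            pooled = np.concatenate(
                [seg[sig] - base[sig] for seg, base, _ in per_class.values()]
            )
            scopes[sig] = (float(pooled.min()), float(pooled.max()))
        for cls, (segments, baselines, hrv) in per_class.items():
            vec = assemble_features(segments, hrv, baselines, scopes, n_segments)
            rows.append((session.subject_id, cls, vec))

    index = pd.MultiIndex.from_tuples(
        [(s, c) for s, c, _ in rows], names=["subject", "class"]
    )
    return pd.DataFrame(
        np.vstack([v for _, _, v in rows]),
        index=index,
        columns=feature_names(n_segments),
    )


def sam_matrix(sessions: list[SessionRecording]) -> pd.DataFrame:
    """Tidy SAM report matrix: one row per stimulus epoch, columns
    arousal/valence/dominance, indexed by (subject, class)."""
    rows = [
        (s.subject_id, cls, *pair.sam.as_array())
        for s in sessions
        for cls, pair in s.epochs.items()
    ]
    df = pd.DataFrame(
        rows, columns=["subject", "class", "arousal", "valence", "dominance"]
    )
    return df.set_index(["subject", "class"])
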