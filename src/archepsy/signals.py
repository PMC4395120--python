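"""Per-channel signal conditioning and physiological measures.

The processing chain mirrors standard psychophysiological practice:

* ECG: band-limit to [0.5, 100] Hz with a 49-51 Hz mains notch, detect
  R-peaks with a Pan-Tompkins-style detector, derive 10-s windowed heart
  rate and the eight conventional HRV measures (SDNN, RMSSD, SDSD, total
  power, VLF, LF, HF, LF/HF).
* Skin conductance: tonic level (SCL) by 1 Hz low-pass; phasic response
  (SCR) by additionally high-passing at 0.5 Hz.
* Respiration: band-limit to [0.1, 10] Hz, breath-to-breath rate from
  peak intervals, averaged per 10-s window.
* Skin temperature: resample to 64 Hz, 10 Hz low-pass, 10-s window means.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so event timing is never shifted.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .exceptions import (
    InsufficientDataError,
    InsufficientSignalError,
    InvalidArgumentError,
)
from .types import BeatSeries, ChannelSignal, HRVSummary, WindowedSeries

logger = logging.getLogger(__name__)

#: default analysis window, seconds
WINDOW_S = 10.0

#: physiologically admissible RR-interval range, ms
RR_MIN_MS, RR_MAX_MS = 200.0, 3000.0

#: HRV spectral bands, Hz
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

_FILTER_ORDER = 4


def _sos(kind: str, cutoff, fs: float, order: int = _FILTER_ORDER):
    """Butterworth design in second-order sections, with cutoffs
    validated against Nyquist."""
    nyq = fs / 2.0
    cut = np.atleast_1d(cutoff).astype(float)
    if np.any(cut <= 0) or np.any(cut >= nyq):
        raise InvalidArgumentError(
            f"cutoff(s) {cut} must lie strictly inside (0, {nyq}) Hz"
        )
    wn = float(cut[0]) if cut.size == 1 else cut
    return sps.butter(order, wn, btype=kind, fs=fs, output="sos")


def _zerophase(sos, values: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, values)


def bandlimit_ecg(raw: ChannelSignal) -> ChannelSignal:
    """Condition a raw ECG trace: remove high-frequency noise (above
    100 Hz), slow components such as respiration drift (below 0.5 Hz)
    and 49-51 Hz mains hum.  Zero-phase throughout."""
    if raw.sampling_rate < 256:
        raise InvalidArgumentError("ECG sampling rate must be >= 256 Hz")
    fs = raw.sampling_rate
    x = _zerophase(_sos("high", 0.5, fs, order=2), raw.values)
    x = _zerophase(_sos("low", 100.0, fs), x)
    x = _zerophase(_sos("bandstop", (49.0, 51.0), fs, order=2), x)
    return ChannelSignal(raw.channel, fs, x, raw.start_time)


def detect_beats(ecg: ChannelSignal) -> BeatSeries:
    """Pan-Tompkins-style R-peak detection.

    Band-pass 5-20 Hz, differentiate, square, integrate over a 150-ms
    moving window, pick candidate peaks with an adaptive amplitude
    threshold and a 250-ms refractory period, then refine each candidate
    to the local maximum of the band-passed ECG.  RR intervals outside
    [200, 3000] ms are discarded as physiologically impossible.
    """
    fs = ecg.sampling_rate
    x = ecg.values
    bp = _zerophase(_sos("bandpass", (5.0, 20.0), fs, order=2), x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # adaptive threshold: a fraction of the high quantile of the
    # integrated energy; robust to isolated noise spikes
    ref = np.quantile(integ, 0.99)
    noise = np.quantile(integ, 0.50)
    if ref <= 0 or np.ptp(x) < 1e-9:
        raise InsufficientSignalError("no QRS-like energy in signal")
    height = noise + 0.25 * (ref - noise)
    cand, _ = sps.find_peaks(integ, height=height, distance=int(0.25 * fs))
    if len(cand) < 2:
        raise InsufficientSignalError("fewer than two beats detected")

    # refine to the R-wave apex on the band-passed trace
    half = int(round(0.08 * fs))
    peaks = np.empty(len(cand), dtype=int)
    for i, c in enumerate(cand):
        lo, hi = max(c - half, 0), min(c + half + 1, len(bp))
        peaks[i] = lo + int(np.argmax(bp[lo:hi]))
    peaks = np.unique(peaks)
    beat_times = ecg.start_time + peaks / fs

    rr = np.diff(beat_times) * 1000.0
    mid = (beat_times[:-1] + beat_times[1:]) / 2.0
    keep = (rr >= RR_MIN_MS) & (rr <= RR_MAX_MS)
    if not np.any(keep):
        raise InsufficientSignalError("no physiologically valid RR intervals")
    return BeatSeries(beat_times=beat_times, rr_ms=rr[keep], rr_times=mid[keep])


def heart_rate_windows(
    beats: BeatSeries, duration: float, window_s: float = WINDOW_S
) -> WindowedSeries:
    """Average heart rate (beats/min) per non-overlapping window.

    Each RR interval is assigned to the window holding its midpoint;
    the window value is ``60000 / mean(RR in window, ms)``.  Windows
    containing no interval are imputed from the nearest non-empty
    window and flagged.
    """
    if duration < window_s:
        raise InvalidArgumentError("duration must cover at least one window")
    n_win = int(duration // window_s)
    idx = (beats.rr_times // window_s).astype(int)
    vals = np.full(n_win, np.nan)
    for w in range(n_win):
        sel = idx == w
        if np.any(sel):
            vals[w] = 60000.0 / np.mean(beats.rr_ms[sel])
    imputed = np.isnan(vals)
    if np.all(imputed):
        raise InsufficientDataError("no RR intervals in any window")
    if np.any(imputed):
        logger.warning(
            "imputing %d empty heart-rate window(s) from nearest neighbour",
            int(imputed.sum()),
        )
        filled = np.flatnonzero(~imputed)
        for w in np.flatnonzero(imputed):
            vals[w] = vals[filled[np.argmin(np.abs(filled - w))]]
    return WindowedSeries(window_s, vals, "beats/min", imputed=imputed)


def hrv_time_domain(rr_ms: np.ndarray) -> tuple[float, float, float]:
    """SDNN, RMSSD and SDSD of an RR-interval series (ms).

    Standard deviations use the sample (n-1) convention; RMSSD is the
    root of the mean squared successive difference.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise InsufficientDataError("need at least 3 RR intervals")
    sdnn = float(np.std(rr, ddof=1))
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d**2)))
    sdsd = float(np.std(d, ddof=1))
    return sdnn, rmssd, sdsd


def hrv_frequency_domain(
    beats: BeatSeries, resample_hz: float = 4.0
) -> tuple[float, float, float, float, float]:
    """Band powers of the RR tachogram: total, VLF, LF, HF (ms^2) and
    the LF/HF ratio.

    The unevenly sampled tachogram is cubic-spline interpolated onto a
    uniform ``resample_hz`` grid, linearly detrended, and its Welch
    periodogram integrated over the conventional bands.
    """
    t = beats.rr_times
    rr = beats.rr_ms
    if rr.size < 8 or (t[-1] - t[0]) < 60.0:
        raise InsufficientDataError("need >= 60 s of beats for spectral HRV")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = CubicSpline(t, rr)(grid)
    tach = sps.detrend(tach, type="linear")
    nperseg = min(len(tach), int(128 * resample_hz))
    freqs, psd = sps.welch(tach, fs=resample_hz, nperseg=nperseg)

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = band_power(0.0, resample_hz / 2.0)
    lf_hf = lf / hf if hf > 0 else np.inf if lf > 0 else 0.0
    return total, vlf, lf, hf, lf_hf


def hrv_summary(beats: BeatSeries) -> HRVSummary:
    """The eight conventional HRV measures from one epoch's beats."""
    sdnn, rmssd, sdsd = hrv_time_domain(beats.rr_ms)
    total, vlf, lf, hf, lf_hf = hrv_frequency_domain(beats)
    return HRVSummary(sdnn, rmssd, sdsd, total, vlf, lf, hf, lf_hf)


def scl_component(sc: ChannelSignal) -> ChannelSignal:
    """Tonic skin-conductance level: 1 Hz low-pass, zero-phase."""
    if sc.sampling_rate < 8:
        raise InvalidArgumentError("skin-conductance sampling rate must be >= 8 Hz")
    x = _zerophase(_sos("low", 1.0, sc.sampling_rate), sc.values)
    return ChannelSignal(sc.channel, sc.sampling_rate, x, sc.start_time)


def scr_component(sc: ChannelSignal) -> ChannelSignal:
    """Phasic skin-conductance response: 1 Hz low-pass then 0.5 Hz
    high-pass, zero-phase."""
    if sc.sampling_rate < 8:
        raise InvalidArgumentError("skin-conductance sampling rate must be >= 8 Hz")
    fs = sc.sampling_rate
    x = _zerophase(_sos("low", 1.0, fs), sc.values)
    x = _zerophase(_sos("high", 0.5, fs, order=2), x)
    return ChannelSignal(sc.channel, fs, x, sc.start_time)


def respiration_rate_windows(
    resp: ChannelSignal, window_s: float = WINDOW_S
) -> WindowedSeries:
    """Breathing rate (breaths/min) per non-overlapping window.

    The trace is band-limited to [0.1, 10] Hz (or to the admissible band
    at low sampling rates), inhalation peaks are located, the
    instantaneous rate 60/interval is interpolated over the epoch and
    averaged per window.
    """
    fs = resp.sampling_rate
    duration = resp.duration
    if duration < window_s:
        raise InvalidArgumentError("epoch must cover at least one window")
    hi = min(10.0, 0.45 * fs)
    x = _zerophase(_sos("high", 0.1, fs, order=2), resp.values)
    x = _zerophase(_sos("low", hi, fs, order=2), x)
    # breaths are slower than 60/min -> peaks at least 1 s apart
    peaks, _ = sps.find_peaks(x, distance=int(fs * 1.0), prominence=0.25 * np.std(x))
    if len(peaks) < 2:
        raise InsufficientSignalError("no breaths detected in epoch")
    pt = peaks / fs
    intervals = np.diff(pt)
    rate = 60.0 / intervals
    mids = (pt[:-1] + pt[1:]) / 2.0

    n_win = int(duration // window_s)
    centers_t = np.arange(len(resp.values)) / fs
    inst = np.interp(centers_t, mids, rate)
    n_keep = int(n_win * window_s * fs)
    vals = inst[:n_keep].reshape(n_win, -1).mean(axis=1)
    return WindowedSeries(window_s, vals, "breaths/min")


def temperature_windows(
    st: ChannelSignal, window_s: float = WINDOW_S, target_fs: float = 64.0
) -> WindowedSeries:
    """Skin-temperature smoothing: resample to 64 Hz, 10 Hz low-pass,
    then non-overlapping window means (deg C)."""
    fs = st.sampling_rate
    x = st.values
    if fs != target_fs:
        up = int(round(target_fs))
        down = int(round(fs))
        from math import gcd

        g = gcd(up, down)
        x = sps.resample_poly(x, up // g, down // g, padtype="line")
        fs = target_fs
    if fs > 2 * 10.0:
        x = _zerophase(_sos("low", 10.0, fs, order=2), x)
    n_win = int(len(x) / fs // window_s)
    if n_win < 1:
        raise InvalidArgumentError("epoch must cover at least one window")
    n_keep = int(n_win * window_s * fs)
    vals = x[:n_keep].reshape(n_win, -1).mean(axis=1)
    return WindowedSeries(window_s, vals, "degC")
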