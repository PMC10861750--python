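"""ERD/ERSP, MRCP and band-power features of movement-aligned EEG epochs.

The chain mirrors standard sensorimotor-rhythm practice: trials are
epoched on [-5, +2] s around the movement onset with [-5, -2] s as the
resting baseline, band-pass filtered with a zero-phase Butterworth filter,
and analysed with a Hanning-window short-time Fourier transform. Spectral
power is expressed in dB relative to the per-frequency baseline mean
(power is averaged across trials before the log). ERD onset is the first
in-band time bin at or below a threshold (default -20 dB); the ERD peak is
the most negative in-band value. The movement-related cortical potential
(MRCP) is the 0.1-10 Hz trial average after baseline-mean subtraction,
summarised by its most negative point in [-3, +1] s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .timeseries import TimeSeries

__all__ = [
    "ALPHA_BAND", "BETA_BAND", "Epochs", "TimeFrequencyMap",
    "bandpass_butterworth", "epoch_signal", "erd_percent", "stft_ersp",
    "erd_onset", "erd_peak", "frequency_power_curve",
    "characteristic_frequency", "mrcp_extract", "baseline_power",
    "detection_features", "feature_row", "feature_table",
]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 25.0)

#: FeatureTable column order
FEATURE_COLUMNS = [
    "erd_onset_time", "erd_peak", "char_freq_alpha", "char_freq_beta",
    "alpha_peak_power", "beta_peak_power", "mrcp_peak", "mrcp_peak_time",
    "baseline_power",
]


@dataclass
class Epochs:
    """Trial-aligned windows around movement onset.

    data : (n_trials, n_samples) matrix.
    window : (tmin, tmax) seconds relative to onset; samples are the
        half-open range [tmin, tmax).
    baseline : (start, end) of the resting-state window.
    """

    data: np.ndarray
    sampling_rate: float
    window: tuple[float, float] = (-5.0, 2.0)
    baseline: tuple[float, float] = (-5.0, -2.0)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("epoch data must be trials x samples")
        w0, w1 = self.window
        b0, b1 = self.baseline
        if not (w0 < b1 <= 0 < w1) or b0 < w0:
            raise ValueError(
                "need window start < baseline end <= 0 < window end, "
                "with the baseline inside the window"
            )
        n_expected = int(round((w1 - w0) * self.sampling_rate))
        if self.data.shape[1] != n_expected:
            raise ValueError(
                f"window {self.window} at {self.sampling_rate} Hz implies "
                f"{n_expected} samples, got {self.data.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.sampling_rate

    def time_mask(self, start: float, end: float) -> np.ndarray:
        t = self.times
        return (t >= start) & (t < end)


@dataclass
class TimeFrequencyMap:
    """Baseline-relative spectral perturbation in dB on a time x freq grid."""

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n_times), dB

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ValueError("values grid inconsistent with axes")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.times >= window[0]) & (self.times <= window[1])


def _band_sos(low: float, high: float, fs: float, order: int):
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sampling rate {fs} Hz"
        )
    return butter(order, [low / nyq, high / nyq], btype="bandpass",
                  output="sos")


def _bandpass_array(x: np.ndarray, fs: float, low: float, high: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    return sosfiltfilt(_band_sos(low, high, fs, order), x, axis=-1)


def bandpass_butterworth(ts: TimeSeries, low: float, high: float,
                         order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass of a single series."""
    return ts.copy_with(_bandpass_array(ts.samples, ts.sampling_rate,
                                        low, high, order))


def epoch_signal(source, onsets=None, window=(-5.0, 2.0),
                 baseline=None) -> Epochs:
    """Cut trial-aligned epochs from a recording or a trial ensemble.

    source : TimeSeries (with explicit `onsets`, in seconds on its time
        axis) or a TrialEnsemble (each trial already aligned; onset 0).
    The epoch holds the half-open sample range [onset+tmin, onset+tmax);
    the t = 0 column is the onset sample (floor convention). The default
    baseline is the resting window [-5, -2] s, shrunk to the first half of
    the pre-onset segment for shorter windows.
    """
    w0, w1 = window
    if baseline is None:
        baseline = (w0, -2.0) if w0 <= -3.0 else (w0, w0 / 2.0)
    if hasattr(source, "trials"):  # TrialEnsemble duck-typed
        series = source.trials
        onsets = [0.0] * len(series) if onsets is None else list(onsets)
    elif isinstance(source, TimeSeries):
        if onsets is None:
            raise ValueError("onsets are required for a continuous recording")
        series = [source] * len(list(onsets))
        onsets = list(onsets)
    else:
        raise TypeError("source must be a TimeSeries or TrialEnsemble")
    if len(series) != len(onsets):
        raise ValueError("one onset per trial required")
    fs = series[0].sampling_rate
    n = int(round((w1 - w0) * fs))
    off = int(round(w0 * fs))
    rows = []
    for i, (ts, onset) in enumerate(zip(series, onsets)):
        i_on = int(np.floor((onset - ts.t0) * fs))
        start = i_on + off
        stop = start + n
        if start < 0 or stop > len(ts):
            raise ValueError(
                f"trial {i}: window {window} s around onset {onset} s falls "
                f"outside the recording"
            )
        rows.append(ts.samples[start:stop])
    return Epochs(np.stack(rows), fs, window=(w0, w1), baseline=baseline)


def erd_percent(epoch_power, baseline_powers) -> np.ndarray | float:
    """Relative band-power change (E - E_b)/E_b x 100.

    `epoch_power` is the mean squared signal of one (or many) sub-epochs;
    `baseline_powers` the per-epoch powers of the m baseline epochs, whose
    mean is the reference E_b. Negative values are desynchronization,
    positive synchronization.
    """
    eb = float(np.mean(np.asarray(baseline_powers, dtype=float)))
    if eb <= 0:
        raise ValueError("baseline power must be > 0")
    out = (np.asarray(epoch_power, dtype=float) - eb) / eb * 100.0
    return float(out) if out.ndim == 0 else out


def mean_power(x: np.ndarray, axis=-1) -> np.ndarray:
    """Mean of squared samples (the E of the ERD definition)."""
    x = np.asarray(x, dtype=float)
    return np.mean(x * x, axis=axis)


def stft_ersp(epochs: Epochs, window_length: float = 1.0,
              hop: float = 0.05, fmax: float = 45.0) -> TimeFrequencyMap:
    """Hanning-window STFT spectral perturbation in dB re. baseline.

    Power spectra of 1-s (default) windows are averaged across trials,
    referenced to the mean power of the baseline-window frames per
    frequency, and expressed as 10*log10(P/P_baseline). Frames are labelled
    by their centre time.
    """
    fs = epochs.sampling_rate
    nwin = int(round(window_length * fs))
    nhop = max(1, int(round(hop * fs)))
    if nwin > epochs.data.shape[1]:
        raise ValueError("epoch shorter than one STFT window")
    frames = np.lib.stride_tricks.sliding_window_view(
        epochs.data, nwin, axis=1)[:, ::nhop, :]
    win = hann(nwin, sym=False)
    spec = np.fft.rfft(frames * win, axis=-1)
    power = np.mean(np.abs(spec) ** 2, axis=0)  # (n_frames, n_freqs)
    starts = np.arange(frames.shape[1]) * nhop
    times = epochs.window[0] + (starts + nwin / 2.0) / fs
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    keep = freqs <= fmax
    freqs, power = freqs[keep], power[:, keep]
    b0, b1 = epochs.baseline
    base_frames = (times >= b0) & (times <= b1)
    if not np.any(base_frames):
        raise ValueError(
            "baseline window shorter than one STFT window: no baseline frame"
        )
    pb = power[base_frames].mean(axis=0)
    if np.any(pb <= 0):
        raise ValueError("zero baseline power at some frequency bin")
    values = 10.0 * np.log10(power / pb).T  # (n_freqs, n_times)
    return TimeFrequencyMap(times, freqs, values)


def erd_onset(tfmap: TimeFrequencyMap, threshold_db: float = -20.0,
              search: tuple[float, float] = (-2.0, 2.0),
              band: tuple[float, float] = (8.0, 30.0)) -> float | None:
    """Earliest in-band time bin at or below the threshold; None if absent."""
    fm = tfmap.band_mask(band)
    tm = tfmap.window_mask(search)
    if not fm.any() or not tm.any():
        return None
    sub = tfmap.values[np.ix_(fm, tm)]
    hit = np.any(sub <= threshold_db, axis=0)
    if not hit.any():
        return None
    return float(tfmap.times[tm][int(np.argmax(hit))])


def erd_peak(tfmap: TimeFrequencyMap,
             search: tuple[float, float] = (-2.0, 2.0),
             band: tuple[float, float] = (8.0, 30.0)) -> float:
    """Most negative in-band, in-window perturbation (dB)."""
    sub = tfmap.values[np.ix_(tfmap.band_mask(band),
                              tfmap.window_mask(search))]
    if sub.size == 0:
        raise ValueError("empty search region")
    return float(sub.min())


def frequency_power_curve(tfmap: TimeFrequencyMap, after: float = -2.0):
    """Mean perturbation per frequency over post-baseline times (> `after`)."""
    tm = tfmap.times >= after
    if not tm.any():
        raise ValueError("no time bins after the baseline")
    return tfmap.freqs.copy(), tfmap.values[:, tm].mean(axis=1)


def characteristic_frequency(freqs, curve, band: tuple[float, float]) -> float:
    """In-band frequency of the deepest power attenuation (ties: lowest)."""
    freqs = np.asarray(freqs, dtype=float)
    curve = np.asarray(curve, dtype=float)
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ValueError(f"band {band} not covered by the curve")
    return float(freqs[m][int(np.argmin(curve[m]))])


def mrcp_extract(epochs: Epochs, band: tuple[float, float] = (0.1, 10.0),
                 search: tuple[float, float] = (-3.0, 1.0), order: int = 4):
    """Movement-related cortical potential of an epoch ensemble.

    Returns (waveform, peak, peak_time): the baseline-corrected 0.1-10 Hz
    trial average, its most negative value in the search window and the
    time of that value (first sample on ties).
    """
    filt = _bandpass_array(epochs.data, epochs.sampling_rate, *band,
                           order=order)
    base = epochs.time_mask(*epochs.baseline)
    filt = filt - filt[:, base].mean(axis=1, keepdims=True)
    avg = filt.mean(axis=0)
    waveform = TimeSeries(avg, epochs.sampling_rate, t0=epochs.window[0])
    t = epochs.times
    m = (t >= search[0]) & (t <= search[1])
    if not m.any():
        raise ValueError("search window outside the epoch")
    idx = int(np.argmin(avg[m]))
    return waveform, float(avg[m][idx]), float(t[m][idx])


def baseline_power(epochs: Epochs, band: tuple[float, float] = (8.0, 25.0),
                   order: int = 4) -> float:
    """Mean squared band-filtered signal over the resting baseline."""
    filt = _bandpass_array(epochs.data, epochs.sampling_rate, *band,
                           order=order)
    base = epochs.time_mask(*epochs.baseline)
    return float(mean_power(filt[:, base]).mean())


def detection_features(epochs: Epochs, window: tuple[float, float],
                       order: int = 4) -> np.ndarray:
    """Per-trial feature vectors of one epoch segment for detection.

    Columns: log10 alpha power, log10 beta power, mean 0.1-10 Hz amplitude
    (signed, carries the MRCP shift) over the given window.
    """
    fs = epochs.sampling_rate
    m = epochs.time_mask(*window)
    if not m.any():
        raise ValueError("window outside the epoch")
    cols = []
    for band in (ALPHA_BAND, BETA_BAND):
        filt = _bandpass_array(epochs.data, fs, *band, order=order)
        cols.append(np.log10(mean_power(filt[:, m]) + 1e-30))
    low = _bandpass_array(epochs.data, fs, 0.1, 10.0, order=order)
    base = epochs.time_mask(*epochs.baseline)
    low = low - low[:, base].mean(axis=1, keepdims=True)
    cols.append(low[:, m].mean(axis=1))
    return np.column_stack(cols)


def feature_row(epochs: Epochs, stft_window: float = 1.0,
                stft_hop: float = 0.05) -> dict:
    """One FeatureTable row summarising an epoch ensemble."""
    tf = stft_ersp(epochs, window_length=stft_window, hop=stft_hop)
    freqs, curve = frequency_power_curve(tf, after=epochs.baseline[1])
    f_alpha = characteristic_frequency(freqs, curve, ALPHA_BAND)
    f_beta = characteristic_frequency(freqs, curve, BETA_BAND)
    onset = erd_onset(tf)
    _, peak, peak_time = mrcp_extract(epochs)
    return {
        "erd_onset_time": np.nan if onset is None else onset,
        "erd_peak": erd_peak(tf),
        "char_freq_alpha": f_alpha,
        "char_freq_beta": f_beta,
        "alpha_peak_power": float(curve[freqs == f_alpha][0]),
        "beta_peak_power": float(curve[freqs == f_beta][0]),
        "mrcp_peak": peak,
        "mrcp_peak_time": peak_time,
        "baseline_power": baseline_power(epochs),
    }


def feature_table(items, **kwargs) -> pd.DataFrame:
    """FeatureTable over named epoch ensembles.

    `items` maps a dataset label to an Epochs object (dict or iterable of
    (label, Epochs) pairs).
    """
    if hasattr(items, "items"):
        items = items.items()
    rows = {label: feature_row(ep, **kwargs) for label, ep in items}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    df.index.name = "dataset"
    return df
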