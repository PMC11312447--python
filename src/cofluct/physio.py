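"""Physiological and EEG feature extraction.

Raw recordings (PPG, respiration belt, skin conductance, pupil, EEG
channels) are reduced to slow feature time courses and standardized onto
the fMRI frame grid: clip at +/-5 SD, resample to the frame count, then
zero-phase fifth-order 0.01-0.1 Hz bandpass.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline, PchipInterpolator

from .filters import LOW_FREQ_BAND, bandpass, check_band_duration, zero_phase, butter_sos

MODALITIES = {"ppg", "respiration", "skin_conductance", "pupil", "eeg_channel"}


@dataclass
class RawPhysioSignal:
    """A uniformly sampled raw recording."""

    samples: np.ndarray
    fs_hz: float
    modality: str
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "pupil" and not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples (only pupil may contain gaps)")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class BeatSeries:
    """Systolic peak times and amplitudes."""

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray

    def __post_init__(self):
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_times_s.size and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if not np.all(np.isfinite(self.peak_amplitudes)):
            raise ValueError("peak amplitudes must be finite")


@dataclass
class FeatureSeries:
    """A feature on the fMRI frame grid, band-limited to 0.01-0.1 Hz."""

    values: np.ndarray
    tr_s: float
    name: str
    units: str = "z"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def detect_ppg_peaks(
    sig: RawPhysioSignal,
    peak_window_s: float = 0.111,
    beat_window_s: float = 0.667,
    beta: float = 0.02,
) -> BeatSeries:
    """Systolic peak detection by the two-moving-average event scheme.

    The signal is bandpassed 0.5-8 Hz (third-order Butterworth), squared
    after clipping negatives, and candidate systolic blocks are the
    regions where a short moving average (default 111 ms) exceeds a long
    moving average (default 667 ms) plus an offset ``beta * mean(squared)``.
    Blocks at least one short-window wide contribute one peak: the argmax
    of the filtered signal; amplitudes are read from the filtered signal.
    """
    if sig.modality != "ppg":
        raise ValueError("detect_ppg_peaks requires a PPG signal")
    fs = sig.fs_hz
    if sig.samples.size / fs < 5.0:
        raise ValueError("PPG segment must be at least 5 s long")
    if np.std(sig.samples) == 0:
        raise ValueError("no peaks detected: PPG signal is constant")
    filt = bandpass(sig.samples, fs, band=(0.5, 8.0), order=3)
    clipped = np.clip(filt, 0.0, None)
    squared = clipped ** 2

    def moving_average(x, width_s):
        w = max(int(round(width_s * fs)), 1)
        kernel = np.ones(w) / w
        return signal.fftconvolve(x, kernel, mode="same")

    ma_peak = moving_average(squared, peak_window_s)
    ma_beat = moving_average(squared, beat_window_s)
    alpha = beta * squared.mean()
    blocks = ma_peak > ma_beat + alpha
    w1 = max(int(round(peak_window_s * fs)), 1)

    idx = np.flatnonzero(blocks)
    if idx.size == 0:
        raise ValueError("no peaks detected in PPG signal")
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[run_breaks + 1]])
    run_stops = np.concatenate([idx[run_breaks], [idx[-1]]]) + 1
    peaks = []
    for a, b in zip(run_starts, run_stops):
        if b - a >= w1:
            peaks.append(a + int(np.argmax(filt[a:b])))
    if not peaks:
        raise ValueError("no peaks detected in PPG signal")
    peaks = np.asarray(peaks)
    return BeatSeries(
        peak_times_s=sig.start_time_s + peaks / fs,
        peak_amplitudes=filt[peaks],
    )


def _beat_interpolate(times, values, fs_hz, n_samples, start_time_s=0.0):
    """Monotone-cubic interpolation of per-beat values onto the sample grid,
    holding boundary values outside the first/last beat."""
    t = start_time_s + np.arange(n_samples) / fs_hz
    interp = PchipInterpolator(times, values, extrapolate=False)
    out = interp(t)
    out[t <= times[0]] = values[0]
    out[t >= times[-1]] = values[-1]
    # any NaN left (shouldn't be) -> nearest fill
    if np.any(np.isnan(out)):
        out = np.where(np.isnan(out), np.interp(t, times, values), out)
    return out


def heart_rate(beats: BeatSeries, fs_hz: float, n_samples: int,
               start_time_s: float = 0.0) -> np.ndarray:
    """Instantaneous heart rate (bpm) on the raw-signal sample grid.

    Rate 60/IBI is assigned at each beat (the first beat inherits the
    first interval) and monotone-cubic interpolated between beats.
    """
    if beats.peak_times_s.size < 2:
        raise ValueError("heart_rate requires at least 2 beats")
    ibi = np.diff(beats.peak_times_s)
    rate = 60.0 / ibi
    rate_at_beat = np.concatenate([[rate[0]], rate])
    return _beat_interpolate(beats.peak_times_s, rate_at_beat, fs_hz, n_samples,
                             start_time_s)


def ppg_amplitude(beats: BeatSeries, fs_hz: float, n_samples: int,
                  start_time_s: float = 0.0) -> np.ndarray:
    """Systolic peak amplitude interpolated onto the raw-signal grid."""
    if beats.peak_times_s.size < 2:
        raise ValueError("ppg_amplitude requires at least 2 beats")
    return _beat_interpolate(beats.peak_times_s, beats.peak_amplitudes,
                             fs_hz, n_samples, start_time_s)


def respiratory_volume(sig: RawPhysioSignal, lowpass_hz: float = 0.75,
                       max_iter: int = 50) -> np.ndarray:
    """Respiratory volume: instantaneous breathing rate x depth.

    Tenth-order Butterworth low-pass (< 0.75 Hz), analytic signal via the
    Hilbert transform, then an iterated linear interpolation of the
    unwrapped phase that replaces decreasing segments until the phase is
    non-decreasing. RV = dphi/dt (rad/s) times the envelope amplitude.
    """
    if sig.modality != "respiration":
        raise ValueError("respiratory_volume requires a respiration signal")
    x = sig.samples
    if np.std(x) < 1e-12:
        raise ValueError("respiration signal is degenerate (zero variance)")
    fs = sig.fs_hz
    sos = butter_sos(10, lowpass_hz, fs, "lowpass")
    filt = zero_phase(sos, x - x.mean(), 10)
    analytic = signal.hilbert(filt)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    for _ in range(max_iter):
        dec = np.diff(phase) < 0
        if not dec.any():
            break
        keep = np.concatenate([[True], ~dec])
        idx = np.flatnonzero(keep)
        phase = np.interp(np.arange(phase.size), idx, phase[idx])
    else:
        n_dec = int((np.diff(phase) < 0).sum())
        raise RuntimeError(
            f"phase monotonization did not converge in {max_iter} iterations "
            f"({n_dec} decreasing samples remain)"
        )
    rate = np.gradient(phase) * fs  # rad/s
    return rate * amplitude


def tonic_skin_conductance(sig: RawPhysioSignal) -> np.ndarray:
    """Slow (0.01-0.1 Hz) component of the skin conductance signal."""
    if sig.modality != "skin_conductance":
        raise ValueError("tonic_skin_conductance requires a skin_conductance signal")
    check_band_duration(sig.samples.size, sig.fs_hz)
    return bandpass(sig.samples, sig.fs_hz)


def default_wavelet_freqs(n: int = 19) -> np.ndarray:
    """Default Morlet filter-bank grid spanning 2-20 Hz inclusive."""
    return np.linspace(2.0, 20.0, n)


def eeg_wavelet_power(sig: RawPhysioSignal, freqs=None,
                      n_cycles: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency power via a Morlet wavelet filter bank.

    Each wavelet has ``n_cycles`` cycles (sigma_t = n_cycles / (2 pi f));
    power is the squared magnitude of the complex convolution. Returns
    ``(power, freqs)`` with power shaped samples x frequencies.
    """
    if sig.modality != "eeg_channel":
        raise ValueError("eeg_wavelet_power requires an EEG channel signal")
    if freqs is None:
        freqs = default_wavelet_freqs()
    freqs = np.asarray(freqs, dtype=float)
    fs = sig.fs_hz
    if np.any(freqs > fs / 2):
        raise ValueError("wavelet frequency above Nyquist")
    x = sig.samples - sig.samples.mean()
    out = np.empty((x.size, freqs.size))
    for j, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(5 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
        wavelet /= np.sqrt(0.5) * np.linalg.norm(wavelet)
        conv = signal.fftconvolve(x, wavelet, mode="same")
        out[:, j] = np.abs(conv) ** 2
    return out, freqs


def alpha_power(sig: RawPhysioSignal, band=(8.0, 12.0),
                numtaps: int | None = None) -> np.ndarray:
    """Alpha-band envelope: Hamming FIR bandpass then Hilbert amplitude."""
    if sig.modality != "eeg_channel":
        raise ValueError("alpha_power requires an EEG channel signal")
    fs = sig.fs_hz
    if fs < 2 * band[1]:
        raise ValueError("sampling rate too low for the alpha band")
    if numtaps is None:
        numtaps = int(round(3.3 * fs / 2.0)) | 1  # ~2 Hz transition band
    if sig.samples.size <= 3 * numtaps:
        raise ValueError("signal too short for the FIR filter order")
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs, window="hamming")
    filt = signal.filtfilt(taps, [1.0], sig.samples - sig.samples.mean())
    return np.abs(signal.hilbert(filt))


def interpolate_blinks(samples: np.ndarray) -> np.ndarray:
    """Linear interpolation across NaN gaps (for synthetic pupil traces)."""
    x = np.asarray(samples, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("all samples are missing")
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def standardize_feature(series: np.ndarray, fs_hz: float, n_frames: int,
                        tr_s: float, name: str = "feature", units: str = "a.u.",
                        clip_sd: float = 5.0, apply_bandpass: bool = True
                        ) -> FeatureSeries:
    """Clip at +/- 5 SD, resample to the fMRI frame grid, bandpass.

    Resampling is anti-aliased polyphase when fs_hz / (1/tr) is a simple
    rational ratio, and cubic-spline interpolation otherwise. Inputs that
    are already band-limited (tonic skin conductance) may skip the final
    filter via ``apply_bandpass=False``.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    expected = x.size / fs_hz / tr_s
    if abs(expected - n_frames) > max(0.02 * n_frames, 2):
        raise ValueError(
            f"n_frames={n_frames} inconsistent with a {x.size / fs_hz:.1f} s "
            f"series at tr={tr_s} s (~{expected:.0f} frames)"
        )
    mu, sd = x.mean(), x.std()
    x = np.clip(x, mu - clip_sd * sd, mu + clip_sd * sd)

    ratio = Fraction(tr_s * fs_hz).limit_denominator(1000)
    if ratio.denominator <= 64 and x.size >= 2 * ratio.numerator:
        y = signal.resample_poly(x, up=ratio.denominator, down=ratio.numerator,
                                 padtype="line")
        y = y[:n_frames]
        if y.size < n_frames:  # pad by edge value if rounding fell short
            y = np.concatenate([y, np.full(n_frames - y.size, y[-1])])
    else:
        t_in = np.arange(x.size) / fs_hz
        t_out = np.arange(n_frames) * tr_s
        y = CubicSpline(t_in, x)(np.clip(t_out, t_in[0], t_in[-1]))
    if apply_bandpass:
        check_band_duration(n_frames, 1.0 / tr_s, LOW_FREQ_BAND[0])
        y = bandpass(y, 1.0 / tr_s)
    return FeatureSeries(values=y, tr_s=tr_s, name=name, units=units)
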