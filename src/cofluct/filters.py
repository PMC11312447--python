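"""Shared zero-phase filtering primitives.

All temporal filters in the package are applied forward-backward
(zero-phase) on second-order sections, with reflect padding of
3x the filter order at each edge.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

LOW_FREQ_BAND = (0.01, 0.1)  # Hz; the analyzed low-frequency band


def butter_sos(
    order: int,
    cutoff,
    fs_hz: float,
    btype: str = "bandpass",
) -> np.ndarray:
    """Design a Butterworth filter as second-order sections."""
    return signal.butter(order, cutoff, btype=btype, fs=fs_hz, output="sos")


def zero_phase(sos: np.ndarray, x: np.ndarray, order: int, axis: int = -1) -> np.ndarray:
    """Forward-backward filtering with reflect padding of 3x the order."""
    x = np.asarray(x, dtype=float)
    padlen = min(3 * max(order, 2) * 2, x.shape[axis] - 1)
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def bandpass(
    x: np.ndarray,
    fs_hz: float,
    band=LOW_FREQ_BAND,
    order: int = 5,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default: fifth order, 0.01-0.1 Hz)."""
    sos = butter_sos(order, band, fs_hz, "bandpass")
    return zero_phase(sos, x, order, axis=axis)


def check_band_duration(n_samples: int, fs_hz: float, low_hz: float = 0.01) -> None:
    """Require at least two cycles of the lowest passband frequency."""
    duration = n_samples / fs_hz
    need = 2.0 / low_hz
    if duration < need:
        raise ValueError(
            f"signal of {duration:.1f} s is too short to resolve {low_hz} Hz "
            f"(need >= {need:.0f} s, i.e. two cycles)"
        )


def shift_series(x: np.ndarray, t_s: np.ndarray, lag_s: float) -> np.ndarray:
    """Delay a sampled series by ``lag_s`` seconds.

    The value at time t is the input at t - lag_s, obtained by linear
    interpolation with edge-value (not circular) padding.
    """
    x = np.asarray(x, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    return np.interp(t_s - lag_s, t_s, x, left=x[0], right=x[-1])
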