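"""Volume-wise monoexponential T2*/S0 fitting and cardiac-cycle
(RETROICOR-style) Fourier regressors with per-slice max-R2 selection.

The decay model is ``S(TE) = S0 * exp(-TE / T2*)``, fit frame-by-frame
by ordinary least squares of ``ln S`` on echo time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physio import BeatSeries


@dataclass
class MultiEchoSeries:
    data: np.ndarray  # frames x echoes x voxels
    echo_times_ms: np.ndarray
    tr_s: float
    slice_of_voxel: np.ndarray | None = None
    slice_timing_s: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be frames x echoes x voxels")
        if self.echo_times_ms.size < 2:
            raise ValueError("at least 2 echoes are required")
        if np.any(self.echo_times_ms <= 0) or np.any(np.diff(self.echo_times_ms) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.data.shape[1] != self.echo_times_ms.size:
            raise ValueError("echo axis does not match echo_times_ms")


@dataclass
class DecaySeries:
    t2s_ms: np.ndarray  # frames x voxels
    s0: np.ndarray  # frames x voxels
    valid: np.ndarray  # frames x voxels bool


@dataclass
class CardiacPhase:
    phase: np.ndarray  # slices x frames, radians in [0, 2pi)
    order: int
    regressors: np.ndarray  # slices x frames x 2*order


def fit_decay(me: MultiEchoSeries) -> DecaySeries:
    """Log-linear least squares fit of the monoexponential decay.

    Per frame/voxel: OLS of ln S on TE; T2* = -1/slope, S0 =
    exp(intercept). Frames/voxels with any nonpositive echo sample, or a
    nonphysical (non-negative) slope, are flagged invalid rather than
    raising.
    """
    s = me.data
    te = me.echo_times_ms
    n_frames, n_echoes, n_vox = s.shape
    valid = np.all(s > 0, axis=1)  # frames x voxels
    logs = np.log(np.where(s > 0, s, 1.0))
    te_c = te - te.mean()
    denom = float(te_c @ te_c)
    slope = np.einsum("e,fev->fv", te_c, logs) / denom
    intercept = logs.mean(axis=1) - slope * te.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        t2s = -1.0 / slope
    valid &= slope < 0
    t2s = np.where(valid, t2s, np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    return DecaySeries(t2s_ms=t2s, s0=s0, valid=valid)


def cardiac_phase(beats: BeatSeries, frame_times_per_slice: np.ndarray,
                  order: int = 2) -> CardiacPhase:
    """Cardiac phase and Fourier regressors at each slice's frame times.

    ``phi(t) = 2 pi (t - t_k) / (t_{k+1} - t_k)`` for t within the k-th
    inter-beat interval; regressors are ``cos(m phi), sin(m phi)`` for
    m = 1..order.
    """
    bt = beats.peak_times_s
    if bt.size < 2:
        raise ValueError("need at least 2 beats")
    frame_times = np.atleast_2d(np.asarray(frame_times_per_slice, dtype=float))
    if frame_times.min() < bt[0] or frame_times.max() >= bt[-1]:
        raise ValueError("frame time outside the span of detected beats")
    k = np.searchsorted(bt, frame_times, side="right") - 1
    phi = 2 * np.pi * (frame_times - bt[k]) / (bt[k + 1] - bt[k])
    phi = np.mod(phi, 2 * np.pi)
    regs = np.empty(frame_times.shape + (2 * order,))
    for m in range(1, order + 1):
        regs[..., 2 * (m - 1)] = np.cos(m * phi)
        regs[..., 2 * (m - 1) + 1] = np.sin(m * phi)
    return CardiacPhase(phase=phi, order=order, regressors=regs)


def max_slice_r2(voxel_series: np.ndarray, phase: CardiacPhase
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Max across slices of the R2 of each voxel on slice regressors.

    Each voxel's series is regressed (with intercept) on every slice's
    regressor matrix; the maximum R2 across slices is returned together
    with a flag marking constant voxels (R2 reported as 0 there).
    """
    y = np.asarray(voxel_series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_frames, n_vox = y.shape
    yc = y - y.mean(axis=0, keepdims=True)
    ss_tot = np.sum(yc ** 2, axis=0)
    degenerate = ss_tot == 0
    ss_tot_safe = np.where(degenerate, 1.0, ss_tot)
    n_slices = phase.regressors.shape[0]
    best = np.zeros(n_vox)
    for s in range(n_slices):
        x = phase.regressors[s]
        if x.shape[0] != n_frames:
            raise ValueError("regressor frame count does not match voxel series")
        xc = x - x.mean(axis=0, keepdims=True)
        beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        resid = yc - xc @ beta
        r2 = 1.0 - np.sum(resid ** 2, axis=0) / ss_tot_safe
        best = np.maximum(best, r2)
    best = np.where(degenerate, 0.0, best)
    return best, degenerate
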