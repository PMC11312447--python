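"""Lead-lag coupling: lagged cross-correlation curves and impulse
response estimation by deconvolution under a Gaussian-process prior.

Cross-correlation convention: ``r(i) = corr(x[t+i], y[t])`` with x the
global fMRI signal and y the physiological signal, so a peak at positive
lag means the global signal lags (follows) the physiological signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve

from .physio import FeatureSeries


@dataclass
class CrossCorrCurve:
    lags_s: np.ndarray
    r: np.ndarray
    level: str = "subject"  # or "group"
    pair: tuple = ("x", "y")

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)

    def at(self, lag_s: float) -> float:
        return float(np.interp(lag_s, self.lags_s, self.r))


@dataclass
class ImpulseResponse:
    lags_s: np.ndarray
    h: np.ndarray
    length_scale: float
    kernel_variance: float
    noise_variance: float


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureSeries):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance overlap segment in cross-correlation")
    return float((a @ b) / denom)


def cross_correlate(x: FeatureSeries, y: FeatureSeries, max_lag_s: float = 30.0,
                    grid_step_s: float = 1.0) -> CrossCorrCurve:
    """Product-moment correlation at every integer-frame lag, then a
    cubic-spline interpolation onto a common 1 s grid on [-30, +30] s."""
    xv, yv = _as_values(x), _as_values(y)
    tr = x.tr_s if isinstance(x, FeatureSeries) else y.tr_s
    if isinstance(x, FeatureSeries) and isinstance(y, FeatureSeries):
        if x.tr_s != y.tr_s:
            raise ValueError("x and y must share a repetition time")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    max_shift = int(np.floor(max_lag_s / tr))
    if n - max_shift < 10:
        raise ValueError("fewer than 10 overlapping samples at maximum lag")
    shifts = np.arange(-max_shift, max_shift + 1)
    r = np.empty(shifts.size)
    for k, s in enumerate(shifts):
        if s >= 0:  # pairs (x[t+s], y[t])
            r[k] = _corr(xv[s:], yv[:n - s]) if s else _corr(xv, yv)
        else:
            r[k] = _corr(xv[:n + s], yv[-s:])
    lag_grid = np.arange(-max_lag_s, max_lag_s + grid_step_s / 2, grid_step_s)
    spline = CubicSpline(shifts * tr, r)
    r_grid = np.clip(spline(np.clip(lag_grid, shifts[0] * tr, shifts[-1] * tr)),
                     -1.0, 1.0)
    name_x = x.name if isinstance(x, FeatureSeries) else "x"
    name_y = y.name if isinstance(y, FeatureSeries) else "y"
    return CrossCorrCurve(lags_s=lag_grid, r=r_grid, pair=(name_x, name_y))


def group_average(curves) -> CrossCorrCurve:
    """Pointwise mean of subject-level curves on a common lag grid."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags_s
    for c in curves[1:]:
        if c.lags_s.shape != lags.shape or not np.allclose(c.lags_s, lags):
            raise ValueError("curves must share a common lag grid")
    r = np.mean([c.r for c in curves], axis=0)
    return CrossCorrCurve(lags_s=lags, r=r, level="group", pair=curves[0].pair)


def default_irf_lags(tr_s: float, neg_s: float = 10.0, pos_s: float = 30.0
                     ) -> np.ndarray:
    """Default impulse-response lag grid: -10 s ... +30 s in frame steps."""
    return np.arange(-np.floor(neg_s / tr_s), np.floor(pos_s / tr_s) + 1) * tr_s


def _sq_exp_kernel(lags: np.ndarray, length_scale: float, variance: float
                   ) -> np.ndarray:
    if length_scale <= 0:
        return variance * np.eye(lags.size)
    d = lags[:, None] - lags[None, :]
    return variance * np.exp(-0.5 * (d / length_scale) ** 2)


def _lagged_design(p: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Columns p(t - shift) with zero padding outside the record."""
    n = p.size
    a = np.zeros((n, shifts.size))
    for j, s in enumerate(shifts):
        if s >= 0:
            a[s:, j] = p[:n - s] if s else p
        else:
            a[:n + s, j] = p[-s:]
    return a


def estimate_irf(output: FeatureSeries, input_: FeatureSeries,
                 lag_grid_s: np.ndarray | None = None,
                 length_scale: float = 3.0, kernel_variance: float = 1.0,
                 length_scale_in_seconds: bool = False,
                 noise_variance: float | None = None,
                 n_noise_grid: int = 20) -> ImpulseResponse:
    """MAP deconvolution of ``output = h * input + noise`` under a GP prior.

    ``h`` has a zero-mean Gaussian-process prior with squared-exponential
    kernel (default length scale 3 lag samples, variance 1). The MAP
    estimate is ``h = K A^T (A K A^T + sigma^2 I)^{-1} g`` with A the
    lagged design matrix of the input. The noise variance is selected by
    maximizing the marginal likelihood over a log-spaced grid unless
    given explicitly. Negative lags capture responses of the output that
    precede the input.
    """
    g = _as_values(output)
    p = _as_values(input_)
    if g.size != p.size:
        raise ValueError("series must have equal length")
    tr = output.tr_s if isinstance(output, FeatureSeries) else 1.0
    if lag_grid_s is None:
        lag_grid_s = default_irf_lags(tr)
    lag_grid_s = np.asarray(lag_grid_s, dtype=float)
    if np.any(np.diff(lag_grid_s) <= 0):
        raise ValueError("lag grid must be strictly increasing")
    shifts = np.round(lag_grid_s / tr).astype(int)
    g = g - g.mean()
    p = p - p.mean()
    a = _lagged_design(p, shifts)
    ell = length_scale if length_scale_in_seconds else length_scale * tr
    k = _sq_exp_kernel(lag_grid_s, ell, kernel_variance)
    aka = a @ k @ a.T
    n = g.size

    def _map_h(s2):
        c = aka + s2 * np.eye(n)
        cf = cho_factor(c, lower=True)
        alpha = cho_solve(cf, g)
        logdet = 2 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (g @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
        return k @ a.T @ alpha, ll

    if noise_variance is not None:
        if noise_variance <= 0:
            raise ValueError("noise variance must be > 0 (the design is "
                             "ill-conditioned at sigma^2 = 0)")
        h, _ = _map_h(noise_variance)
        s2_best = noise_variance
    else:
        var_g = g.var() if g.var() > 0 else 1.0
        grid = var_g * np.logspace(-6, 1, n_noise_grid)
        best = (-np.inf, None, None)
        for s2 in grid:
            h, ll = _map_h(s2)
            if ll > best[0]:
                best = (ll, h, s2)
        _, h, s2_best = best
    return ImpulseResponse(lags_s=lag_grid_s, h=h, length_scale=ell,
                           kernel_variance=kernel_variance,
                           noise_variance=float(s2_best))
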