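"""Multi-set canonical correlation with distributed-lag spline sets.

Each signal contributes a 'set' of three columns: linear combinations of
its 0-10 s lagged copies weighted by a natural cubic spline basis. The
first canonical component maximizes the summed pairwise correlations of
the per-set variates (SUMCOR relaxation solved as a generalized
eigenproblem: total covariance against the block-diagonal within-set
covariance). Inference is by subject-block permutation of each signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .physio import FeatureSeries


@dataclass
class LaggedPredictorSet:
    name: str
    columns: np.ndarray  # frames x n_splines
    basis: np.ndarray  # lag-grid x n_splines
    lag_grid_s: np.ndarray
    window_s: tuple = (0.0, 10.0)

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)


@dataclass
class MccaSolution:
    weights: list  # per-set weight vectors
    variates: np.ndarray  # frames x n_sets, unit variance
    pairwise_r: np.ndarray  # n_sets x n_sets
    mean_pairwise_r: float
    set_names: list = field(default_factory=list)
    null_r: np.ndarray | None = None
    p_value: float | None = None


def natural_cubic_basis(x: np.ndarray, knots=(0.0, 5.0, 10.0)) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    Uses the standard truncated-power construction: with K knots the
    basis is {1, x, d_1(x) - d_{K-1}(x), ...}, giving K functions. The
    default knots (0, 5, 10 s) yield three basis functions over 0-10 s.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    if K < 3:
        raise ValueError("need at least 3 knots")
    def d(k):
        num = (np.clip(x - knots[k], 0, None) ** 3
               - np.clip(x - knots[-1], 0, None) ** 3)
        return num / (knots[-1] - knots[k])
    cols = [np.ones_like(x), x]
    dKm1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm1)
    return np.column_stack(cols)


def build_lagged_set(feature: FeatureSeries, window_s=(0.0, 10.0),
                     n_splines: int = 3) -> LaggedPredictorSet:
    """Spline-weighted lagged copies of one signal.

    Column k at frame t is ``sum_l B_k(l) * feature(t - l)`` over the
    integer-frame lag grid covering the window, with edge padding by the
    boundary value.
    """
    if n_splines != 3:
        raise ValueError("the distributed-lag basis uses exactly 3 splines")
    v = np.asarray(feature.values, dtype=float)
    tr = feature.tr_s
    lo, hi = window_s
    lags = np.arange(int(np.floor(lo / tr)), int(np.floor(hi / tr)) + 1)
    if lags.size >= v.size:
        raise ValueError("lag window is longer than the series")
    lag_s = lags * tr
    knots = (lo, (lo + hi) / 2.0, hi)
    basis = natural_cubic_basis(lag_s, knots)
    n = v.size
    lagmat = np.empty((n, lags.size))
    for j, l in enumerate(lags):
        if l == 0:
            lagmat[:, j] = v
        else:
            lagmat[l:, j] = v[:n - l]
            lagmat[:l, j] = v[0]
    return LaggedPredictorSet(name=feature.name, columns=lagmat @ basis,
                              basis=basis, lag_grid_s=lag_s, window_s=window_s)


def _stack(sets) -> tuple[np.ndarray, list]:
    cols = [np.asarray(s.columns, dtype=float) for s in sets]
    n = cols[0].shape[0]
    for c in cols:
        if c.shape[0] != n:
            raise ValueError("all sets must have equal frame counts")
    return cols, [c.shape[1] for c in cols]


def fit_mcca(sets, ridge: float = 1e-6) -> MccaSolution:
    """First sum-of-correlations canonical component across >= 2 sets.

    Solves ``R w = lambda D w`` with R the covariance of all stacked
    columns and D its block-diagonal within-set part (each block's
    diagonal inflated by ``1 + ridge`` for conditioning). Variates are
    scaled to unit variance; the achieved statistic is the mean
    off-diagonal pairwise correlation of the variates.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("MCCA requires at least 2 sets")
    cols, widths = _stack(sets)
    x = np.hstack(cols)
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    r_full = x.T @ x / n
    d_block = np.zeros_like(r_full)
    offs = np.cumsum([0] + widths)
    for i in range(len(sets)):
        sl = slice(offs[i], offs[i + 1])
        block = r_full[sl, sl].copy()
        if ridge <= 0 and np.linalg.matrix_rank(block) < block.shape[0]:
            raise np.linalg.LinAlgError(
                f"within-set covariance of {sets[i].name!r} is rank-deficient; "
                "use ridge > 0")
        # ridge proportional to each column's variance: the solution is
        # then exactly invariant to per-column rescaling
        block[np.diag_indices_from(block)] *= 1.0 + ridge
        d_block[sl, sl] = block
    evals, evecs = eigh(r_full, d_block)
    w = evecs[:, -1]
    variates = np.empty((n, len(sets)))
    weights = []
    for i in range(len(sets)):
        sl = slice(offs[i], offs[i + 1])
        wi = w[offs[i]:offs[i + 1]]
        vi = x[:, sl] @ wi
        sd = vi.std()
        if sd == 0:
            raise np.linalg.LinAlgError(
                f"degenerate variate for set {sets[i].name!r}")
        variates[:, i] = vi / sd
        weights.append(wi / sd)
    pairwise = np.corrcoef(variates.T)
    # align signs so variates correlate positively with the first set
    for i in range(1, len(sets)):
        if pairwise[0, i] < 0:
            variates[:, i] *= -1
            weights[i] = -weights[i]
    pairwise = np.corrcoef(variates.T)
    iu = np.triu_indices(len(sets), k=1)
    mean_r = float(pairwise[iu].mean())
    return MccaSolution(weights=weights, variates=variates, pairwise_r=pairwise,
                        mean_pairwise_r=mean_r,
                        set_names=[s.name for s in sets])


def _concat_sets(per_subject_sets, order_per_signal):
    """Concatenate subjects per signal following the given subject orders."""
    n_signals = len(per_subject_sets[0])
    out = []
    for j in range(n_signals):
        template = per_subject_sets[0][j]
        cols = np.vstack([per_subject_sets[s][j].columns
                          for s in order_per_signal[j]])
        out.append(LaggedPredictorSet(name=template.name, columns=cols,
                                      basis=template.basis,
                                      lag_grid_s=template.lag_grid_s,
                                      window_s=template.window_s))
    return out


def permutation_test(per_subject_sets, n_perm: int = 1000, seed: int = 0,
                     ridge: float = 1e-6) -> MccaSolution:
    """Subject-block permutation test of the mean pairwise correlation.

    ``per_subject_sets`` is a list over subjects of lists of
    :class:`LaggedPredictorSet` (same signals, same order). For each
    permutation, the subject assignment of each signal is shuffled
    independently before temporal concatenation, the MCCA refit, and the
    mean pairwise correlation recorded; ``p = (1 + #{null >= obs}) /
    (n_perm + 1)``.
    """
    n_sub = len(per_subject_sets)
    if n_sub < 3:
        raise ValueError("permutation test requires at least 3 subjects")
    n_signals = len(per_subject_sets[0])
    rng = np.random.default_rng(seed)
    identity = [np.arange(n_sub) for _ in range(n_signals)]
    observed = fit_mcca(_concat_sets(per_subject_sets, identity), ridge=ridge)
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = [rng.permutation(n_sub) for _ in range(n_signals)]
        sol = fit_mcca(_concat_sets(per_subject_sets, order), ridge=ridge)
        null[b] = sol.mean_pairwise_r
    p = (1.0 + np.sum(null >= observed.mean_pairwise_r)) / (n_perm + 1.0)
    observed.null_r = null
    observed.p_value = float(p)
    return observed
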