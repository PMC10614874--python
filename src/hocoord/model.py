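"""Multinomial logistic GLM for marked ensemble spiking.

Each modeled mark ``m`` has a linear predictor ``x_t' w(m)`` where ``x_t`` is
the history covariate vector ``[1, n_{t-1}(1), ..., n_{t-p}(1), ...,
n_{t-1}(C), ..., n_{t-p}(C)]`` (constant first, then lags of each neuron).
With the no-event outcome as the reference category, the per-bin mark
probabilities are

    lam*(m) dt = exp(x' w(m)) / (1 + sum_j exp(x' w(j)))

and the ground (any-event) probability is their sum.  Parameters are assumed
piecewise constant over windows of ``W`` bins; time variation is tracked by
maximizing the forgetting-factor log-likelihood

    l_k^beta(w) = (1 - beta) * sum_{i<=k} beta^(k-i) l_i(w),

where ``l_i`` is the window-i multinomial log-likelihood.  Because the data
enter ``l_k^beta`` only through (a) exponentially weighted outcome-covariate
sums and (b) an exponentially weighted histogram of covariate patterns (the
covariates are binary, so distinct rows repeat heavily), both the weighted
log-likelihood and its gradient admit exact O(#unique patterns) recursive
computation; :class:`WeightedStats` maintains those accumulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .markspace import MarkSpace, MarkedSeries, SpikeRaster

_CLIP = 1e-12


def effective_window(W: int, beta: float) -> float:
    """Effective integration window N_eff = W / (1 - beta), in bins."""
    if not 0 <= beta < 1:
        raise ValueError("beta must be in [0, 1)")
    return W / (1.0 - beta)


# ---------------------------------------------------------------------------
# covariates and parameters


def build_history_design(raster: SpikeRaster, p: int) -> np.ndarray:
    """T x (1 + C*p) binary design matrix of lagged ensemble spiking.

    Row ``t`` is ``[1, n_{t-1}(1)..n_{t-p}(1), ..., n_{t-1}(C)..n_{t-p}(C)]``.
    Bins before lag ``p`` use zero-padded history.
    """
    if p < 0:
        raise ValueError("history lag p must be >= 0")
    C, T = raster.data.shape
    X = np.zeros((T, 1 + C * p), dtype=np.uint8)
    X[:, 0] = 1
    for c in range(C):
        for lag in range(1, p + 1):
            col = 1 + c * p + (lag - 1)
            X[lag:, col] = raster.data[c, :-lag]
    return X


@dataclass
class ModelParams:
    """Per-mark GLM coefficients for the reliable mark set of one window.

    ``coef`` has shape ``(M, 1 + C*p)``; column 0 is the base rate ``mu(m)``
    (log-odds of mark m versus no event) and the rest are the history
    coefficients ``theta(m)``.  A history-independent model simply has
    ``p = 0`` (``coef`` is a single column).
    """

    marks: np.ndarray
    C: int
    p: int
    coef: np.ndarray

    def __post_init__(self) -> None:
        self.marks = np.asarray(self.marks, dtype=np.int64)
        self.coef = np.asarray(self.coef, dtype=float)
        d = 1 + self.C * self.p
        if self.coef.shape != (self.marks.size, d):
            raise ValueError(
                f"coef shape {self.coef.shape} inconsistent with "
                f"{self.marks.size} marks and dimension {d}"
            )
        if not np.isfinite(self.coef).all():
            raise ValueError("non-finite coefficients")

    @property
    def mu(self) -> np.ndarray:
        return self.coef[:, 0]

    @property
    def theta(self) -> np.ndarray:
        return self.coef[:, 1:]

    @property
    def n_marks(self) -> int:
        return self.marks.size


# ---------------------------------------------------------------------------
# conditional intensities and per-bin likelihood


def _logits(coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != coef.shape[1]:
        raise ValueError(
            f"covariate dimension {x.shape[-1]} != parameter dimension {coef.shape[1]}"
        )
    return x @ coef.T


def mark_cifs(params: ModelParams, x: np.ndarray):
    """Per-mark probabilities ``lam*(m) dt``, ground probability, and no-event.

    ``x`` may be a single covariate vector or a matrix of rows; probabilities
    are computed with the log-sum-exp trick and always sum to one across the
    ``M + 1`` outcomes (M marks plus no-event).
    """
    u = _logits(params.coef, x)
    one = u.ndim == 1
    u = np.atleast_2d(u)
    z = np.concatenate([np.zeros((u.shape[0], 1)), u], axis=1)
    lse = logsumexp(z, axis=1, keepdims=True)
    probs = np.exp(z - lse)
    p_none = probs[:, 0]
    p_marks = probs[:, 1:]
    p_ground = p_marks.sum(axis=1)
    if one:
        return p_marks[0], p_ground[0], p_none[0]
    return p_marks, p_ground, p_none


def neuron_cif(params: ModelParams, x: np.ndarray, c: int) -> np.ndarray:
    """Probability that neuron ``c`` spikes: sum of CIFs of marks with bit c set."""
    if not 1 <= c <= params.C:
        raise ValueError(f"neuron index {c} out of range for C={params.C}")
    p_marks, _, _ = mark_cifs(params, x)
    has_c = ((params.marks >> (c - 1)) & 1).astype(bool)
    return np.atleast_2d(p_marks)[:, has_c].sum(axis=1).squeeze()


def event_log_likelihood(n_star: np.ndarray, params: ModelParams, x: np.ndarray) -> float:
    """Log-probability of a single-bin marked outcome under the model.

    The marked-process likelihood collapses to ``log lam*(m) dt`` if mark ``m``
    fired and ``log(1 - lam(g) dt)`` if no event occurred.
    """
    n_star = np.asarray(n_star)
    if n_star.sum() > 1:
        raise ValueError("at most one mark may fire in a bin (disjointness)")
    p_marks, _, p_none = mark_cifs(params, x)
    if n_star.sum() == 0:
        return float(np.log(np.clip(p_none, _CLIP, None)))
    m_row = int(np.nonzero(n_star)[0][0])
    return float(np.log(np.clip(p_marks[m_row], _CLIP, None)))


# ---------------------------------------------------------------------------
# window and forgetting-factor log-likelihoods (direct forms)


def _window_ll_core(coef: np.ndarray, X_win: np.ndarray, rows: np.ndarray) -> float:
    """Multinomial log-likelihood of one window.

    ``rows[t]`` is the mark row index that fired at bin t, or -1 for no event.
    """
    u = _logits(coef, X_win)
    z = np.concatenate([np.zeros((u.shape[0], 1)), u], axis=1)
    lse = logsumexp(z, axis=1)
    lin = 0.0
    ev = rows >= 0
    if ev.any():
        lin = u[np.nonzero(ev)[0], rows[ev]].sum()
    return float(lin - lse.sum())


def window_loglik(params: ModelParams, X_win: np.ndarray, rows: np.ndarray) -> float:
    """Log-likelihood ``l_i`` of one window of outcomes (row-coded, -1 = none)."""
    return _window_ll_core(params.coef, np.asarray(X_win, dtype=float),
                           np.asarray(rows, dtype=np.int64))


def weighted_loglik(params: ModelParams, windows, beta: float) -> float:
    """Direct evaluation of ``l_k^beta`` from a list of (X_win, rows) windows."""
    if not 0 <= beta < 1:
        raise ValueError("beta must be in [0, 1)")
    k = len(windows)
    total = 0.0
    for i, (X_win, rows) in enumerate(windows, start=1):
        total += beta ** (k - i) * window_loglik(params, X_win, rows)
    return (1.0 - beta) * total


def weighted_gradient(params: ModelParams, windows, beta: float) -> np.ndarray:
    """Direct gradient of ``l_k^beta`` w.r.t. ``coef`` (shape (M, d))."""
    k = len(windows)
    grad = np.zeros_like(params.coef)
    for i, (X_win, rows) in enumerate(windows, start=1):
        w = beta ** (k - i)
        X_win = np.asarray(X_win, dtype=float)
        rows = np.asarray(rows, dtype=np.int64)
        p_marks, _, _ = mark_cifs(params, X_win)
        p_marks = np.atleast_2d(p_marks)
        Y = np.zeros_like(p_marks)
        ev = rows >= 0
        Y[np.nonzero(ev)[0], rows[ev]] = 1.0
        grad += w * ((Y - p_marks).T @ X_win)
    return (1.0 - beta) * grad


# ---------------------------------------------------------------------------
# recursive sufficient statistics


@dataclass
class WeightedStats:
    """Exact recursive sufficient statistics of the forgetting-factor likelihood.

    Maintains, across windows,

    * ``S`` (M x d): exponentially weighted sums of covariate rows at event
      bins, one row per mark — the data side of the gradient;
    * a weighted histogram over *unique covariate patterns* (``U`` stacking the
      distinct binary rows seen so far, ``A`` their exponentially weighted
      occurrence counts) — enough to evaluate the weighted log-partition term
      and the model side of the gradient exactly, because ``l_k^beta``
      depends on past covariates only through pattern counts.

    ``loglik``/``gradient`` reproduce the direct sums
    :func:`weighted_loglik` / :func:`weighted_gradient` to numerical precision
    at any parameter value, at cost proportional to the number of distinct
    patterns rather than the number of past bins.
    """

    n_marks: int
    dim: int
    beta: float
    k: int = 0
    S: np.ndarray = field(init=False)
    _patterns: dict = field(init=False, default_factory=dict)
    _U: list = field(init=False, default_factory=list)
    _A: list = field(init=False, default_factory=list)
    _cache: tuple | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if not 0 <= self.beta < 1:
            raise ValueError("beta must be in [0, 1)")
        self.S = np.zeros((self.n_marks, self.dim))

    # -- update -------------------------------------------------------------

    def update(self, X_win: np.ndarray, rows: np.ndarray) -> None:
        """Fold in one window of covariates and row-coded outcomes."""
        X_win = np.ascontiguousarray(np.asarray(X_win, dtype=np.uint8))
        rows = np.asarray(rows, dtype=np.int64)
        if X_win.shape[1] != self.dim:
            raise ValueError("covariate dimension mismatch")
        self.S *= self.beta
        ev = rows >= 0
        if ev.any():
            np.add.at(self.S, rows[ev], X_win[ev].astype(float))
        A = np.asarray(self._A, dtype=float) * self.beta if self._A else np.zeros(0)
        self._A = list(A)
        for t in range(X_win.shape[0]):
            key = X_win[t].tobytes()
            idx = self._patterns.get(key)
            if idx is None:
                self._patterns[key] = len(self._U)
                self._U.append(X_win[t].astype(float))
                self._A.append(1.0)
            else:
                self._A[idx] += 1.0
        self.k += 1
        self._cache = None
        # compact the histogram: patterns whose weight has decayed below a
        # 1e-12 relative floor contribute nothing at double precision
        if self.beta and len(self._A) > 512 and self.k % 64 == 0:
            A = np.asarray(self._A)
            keep = A > A.max() * 1e-12
            if not keep.all():
                U = [u for u, k_ in zip(self._U, keep) if k_]
                self._U = U
                self._A = list(A[keep])
                self._patterns = {u.astype(np.uint8).tobytes(): i
                                  for i, u in enumerate(self._U)}

    # -- evaluation ---------------------------------------------------------

    def _UA(self):
        if self._cache is None:
            self._cache = (np.asarray(self._U, dtype=float),
                           np.asarray(self._A, dtype=float))
        return self._cache

    def loglik(self, coef: np.ndarray) -> float:
        """Forgetting-factor log-likelihood ``l_k^beta`` at ``coef``."""
        U, A = self._UA()
        lin = float(np.sum(self.S * coef))
        u = U @ coef.T
        z = np.concatenate([np.zeros((u.shape[0], 1)), u], axis=1)
        lse = logsumexp(z, axis=1)
        return (1.0 - self.beta) * (lin - float(A @ lse))

    def gradient(self, coef: np.ndarray) -> np.ndarray:
        """Gradient of ``l_k^beta`` w.r.t. ``coef`` (recursive statistics)."""
        U, A = self._UA()
        u = U @ coef.T
        z = np.concatenate([np.zeros((u.shape[0], 1)), u], axis=1)
        lse = logsumexp(z, axis=1, keepdims=True)
        P = np.exp(z[:, 1:] - lse)  # pattern x mark probabilities
        model_term = (P * A[:, None]).T @ U
        return (1.0 - self.beta) * (self.S - model_term)

    def loglik_and_gradient(self, coef: np.ndarray) -> tuple[float, np.ndarray]:
        """Fused evaluation sharing the soft-max pass (optimizer hot path)."""
        U, A = self._UA()
        u = U @ coef.T
        z = np.concatenate([np.zeros((u.shape[0], 1)), u], axis=1)
        lse = logsumexp(z, axis=1, keepdims=True)
        ll = (1.0 - self.beta) * (float(np.sum(self.S * coef)) - float(A @ lse[:, 0]))
        P = np.exp(z[:, 1:] - lse)
        grad = (1.0 - self.beta) * (self.S - (P * A[:, None]).T @ U)
        return ll, grad

    @property
    def n_patterns(self) -> int:
        return len(self._A)

    def weight_sum(self) -> float:
        """Total accumulated window weight ``sum_i beta^(k-i)``."""
        return float((1 - self.beta ** self.k) / (1 - self.beta)) if self.beta else float(self.k > 0)


def iter_windows(X: np.ndarray, rows: np.ndarray, W: int):
    """Yield (X_win, rows_win) pairs of consecutive length-W windows."""
    T = X.shape[0]
    K = T // W
    for i in range(K):
        sl = slice(i * W, (i + 1) * W)
        yield X[sl], rows[sl]


# ---------------------------------------------------------------------------
# parameter export


def params_to_table(trace, marks: np.ndarray) -> np.ndarray:
    """Flatten a per-window parameter trace to (window, mark, coef_index, value) rows."""
    rows = []
    for k, coef in enumerate(trace):
        M, d = coef.shape
        for i in range(M):
            for j in range(d):
                if coef[i, j] != 0.0 or j == 0:
                    rows.append((k + 1, int(marks[i]), j, coef[i, j]))
    return np.asarray(rows, dtype=float)
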