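"""History-independent model: forgetting-factor multinomial MLE of base rates.

With no history covariates the window log-likelihood depends on the data only
through the window-mean outcome vector ``nbar_i`` and the weighted objective is

    l_k^beta(mu) = (1 - beta) * W * sum_i beta^(k-i) (mu' nbar_i - psi(mu)),
    psi(mu) = log(1 + sum_m exp(mu(m))).

Its maximizer moment-matches: softmax probabilities equal the exponentially
weighted empirical frequencies ``mbar_k``, giving the closed form

    mu_k(m) = log(mbar_k(m) / (1 - sum_j mbar_k(j))).

The closed form is used by default; a gradient-ascent solver is kept as an
independent cross-check since the objective is concave with the same optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .markspace import MarkedSeries, MarkSpace

logger = logging.getLogger(__name__)

MU_FLOOR = -20.0


@dataclass
class BaseRateTrace:
    """Per-window base-rate estimates for the reliable marks."""

    marks: np.ndarray
    W: int
    beta: float
    mu: np.ndarray          # K x M
    mark_means: np.ndarray  # K x M weighted empirical frequencies

    @property
    def n_windows(self) -> int:
        return self.mu.shape[0]


def _window_mark_means(marked: MarkedSeries, W: int, marks: np.ndarray) -> np.ndarray:
    """K x M matrix of per-window mean outcomes ``nbar_i`` for the given marks."""
    K = marked.T // W
    rows = marked.mark_rows(marks, T=K * W)
    out = np.zeros((K, marks.size))
    ev = np.nonzero(rows >= 0)[0]
    np.add.at(out, (ev // W, rows[ev]), 1.0)
    return out / W


def weighted_mark_means(marked: MarkedSeries, W: int, beta: float,
                        k: int | None = None,
                        marks: np.ndarray | None = None) -> np.ndarray:
    """Exponentially weighted average outcome vector(s).

    Returns the full ``K x M`` trace of ``mbar_k = sum_i beta^(k-i) nbar_i /
    sum_i beta^(k-i)`` (maintained by the recursion ``s_k = beta s_{k-1} +
    nbar_k``), or row ``k`` (1-based) if ``k`` is given.
    """
    if not 0 <= beta < 1:
        raise ValueError("beta must be in [0, 1)")
    if marks is None:
        marks = np.arange(1, marked.n_marks + 1)
    nbar = _window_mark_means(marked, W, marks)
    K = nbar.shape[0]
    out = np.empty_like(nbar)
    s = np.zeros(nbar.shape[1])
    c = 0.0
    for i in range(K):
        s = beta * s + nbar[i]
        c = beta * c + 1.0
        out[i] = s / c
    if k is not None:
        if not 1 <= k <= K:
            raise ValueError(f"window {k} out of range (K={K})")
        return out[k - 1]
    return out


def mu_from_means(mbar: np.ndarray, floor: float = MU_FLOOR) -> np.ndarray:
    """Closed-form stationary MLE: ``mu(m) = log(mbar(m) / (1 - sum mbar))``.

    Marks with zero weighted frequency are capped at ``floor`` on the log-odds
    scale (keeps downstream deviances finite).
    """
    mbar = np.asarray(mbar, dtype=float)
    p_none = 1.0 - mbar.sum(axis=-1, keepdims=True)
    p_none = np.clip(p_none, 1e-12, None)
    with np.errstate(divide="ignore"):
        mu = np.log(mbar / p_none)
    n_floor = int((~np.isfinite(mu)).sum() + (mu < floor).sum())
    if n_floor:
        logger.warning("floored %d base-rate estimates at %.0f", n_floor, floor)
    return np.clip(np.nan_to_num(mu, nan=floor, neginf=floor), floor, None)


def estimate_mu(marked: MarkedSeries, W: int, beta: float,
                markspace: MarkSpace | None = None,
                floor: float = MU_FLOOR) -> BaseRateTrace:
    """Per-window base-rate MLEs over the reliable mark set (closed form)."""
    marks = markspace.reliable if markspace is not None else np.arange(1, marked.n_marks + 1)
    if marks.size == 0:
        raise ValueError("reliable mark set is empty")
    mbar = weighted_mark_means(marked, W, beta, marks=marks)
    mu = mu_from_means(mbar, floor=floor)
    return BaseRateTrace(marks=marks, W=W, beta=beta, mu=mu, mark_means=mbar)


def constrained_mu(mbar: np.ndarray, fixed: dict[int, float],
                   floor: float = MU_FLOOR) -> np.ndarray:
    """Maximize the weighted objective with some coordinates of ``mu`` fixed.

    With ``exp(mu(m))`` fixed to ``c_m`` for the constrained marks, the free
    coordinates still moment-match against the renormalized partition:
    ``exp(mu(j)) = mbar(j) * Z`` with ``Z = (1 + sum_fixed c) /
    (1 - sum_free mbar)``.
    """
    mbar = np.asarray(mbar, dtype=float)
    out = np.empty_like(mbar)
    fixed_idx = np.asarray(sorted(fixed), dtype=int)
    free = np.ones(mbar.size, dtype=bool)
    free[fixed_idx] = False
    c_sum = float(np.sum(np.exp([fixed[i] for i in fixed_idx]))) if fixed_idx.size else 0.0
    denom = 1.0 - mbar[free].sum()
    Z = (1.0 + c_sum) / np.clip(denom, 1e-12, None)
    with np.errstate(divide="ignore"):
        out[free] = np.log(mbar[free] * Z)
    out[free] = np.clip(np.nan_to_num(out[free], nan=floor, neginf=floor), floor, None)
    for i in fixed_idx:
        out[i] = fixed[i]
    return out


def hf_loglik(mu: np.ndarray, mbar: np.ndarray, W: int, weight_sum: float,
              beta: float) -> float:
    """Weighted log-likelihood ``l_k^beta(mu)`` from the weighted means.

    ``weight_sum`` is ``sum_i beta^(k-i)``; the value equals
    ``(1-beta) * W * weight_sum * (mu' mbar - psi(mu))``.
    """
    psi = logsumexp(np.concatenate([[0.0], mu]))
    return (1.0 - beta) * W * weight_sum * float(mu @ mbar - psi)


def estimate_mu_gd(mbar: np.ndarray, mu0: np.ndarray | None = None,
                   tol: float = 1e-10) -> np.ndarray:
    """Gradient-based maximizer of the window objective (oracle cross-check)."""
    mbar = np.asarray(mbar, dtype=float)

    def negobj(mu):
        psi = logsumexp(np.concatenate([[0.0], mu]))
        return -(mu @ mbar - psi)

    def grad(mu):
        z = np.concatenate([[0.0], mu])
        p = np.exp(z - logsumexp(z))[1:]
        return -(mbar - p)

    x0 = np.full(mbar.size, -3.0) if mu0 is None else np.asarray(mu0, dtype=float)
    res = minimize(negobj, x0, jac=grad, method="L-BFGS-B",
                   options={"gtol": tol, "maxiter": 2000, "ftol": 1e-16})
    mu = res.x
    # Newton polish: the Hessian of psi is diag(p) - p p' (exact, tiny system)
    for _ in range(4):
        z = np.concatenate([[0.0], mu])
        p = np.exp(z - logsumexp(z))[1:]
        g = mbar - p
        H = np.diag(p) - np.outer(p, p)
        try:
            mu = mu + np.linalg.solve(H + 1e-14 * np.eye(p.size), g)
        except np.linalg.LinAlgError:
            break
    return mu
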