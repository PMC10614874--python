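"""Adaptive Orthogonal Matching Pursuit over windowed ensemble-spiking GLMs.

Per window, the algorithm (i) folds the new data into the recursive weighted
sufficient statistics, (ii) warm-starts the parameter support from the
previous window, drops history coefficients whose refit value has collapsed to
zero, and greedily adds, per mark, the inactive coordinate with the largest
absolute gradient of the forgetting-factor log-likelihood until the per-mark
sparsity budget ``s`` is met, and (iii) refits the coefficients over the
active support by maximizing the concave weighted log-likelihood.  Base rates
are never sparsified, so the support of every mark always contains its
intercept (unless the intercept is externally pinned, as in the reduced models
used for coordination testing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .markspace import MarkedSeries, MarkSpace, SpikeRaster, reliable_marks
from .model import ModelParams, WeightedStats, build_history_design, window_loglik

logger = logging.getLogger(__name__)

REMOVAL_TOL = 1e-8
MU_BOUNDS = (-20.0, 5.0)     # base-rate log-odds; lower bound = rare-mark floor
THETA_BOUNDS = (-10.0, 10.0)  # history coefficients


# ---------------------------------------------------------------------------
# constrained concave refit


def _ascent(fun, grad, x0, gtol, max_iter=500):
    """Gradient ascent with backtracking line search on a concave objective."""
    x = x0.copy()
    f = fun(x)
    step = 1.0
    for _ in range(max_iter):
        g = grad(x)
        gnorm = np.linalg.norm(g, ord=np.inf) if g.size else 0.0
        if gnorm < gtol:
            return x, True
        step = min(step * 2.0, 1e3)
        while step > 1e-14:
            x_new = x + step * g
            f_new = fun(x_new)
            if f_new >= f + 1e-4 * step * (g @ g):
                break
            step *= 0.5
        else:
            return x, False
        x, f = x_new, f_new
    return x, False


def refit(stats: WeightedStats, coef: np.ndarray, support: np.ndarray,
          fixed_value: np.ndarray | None = None,
          optimizer: str = "lbfgs", gtol: float = 1e-6,
          ridge: float = 0.0, max_iter: int = 500) -> tuple[np.ndarray, bool]:
    """Maximize the weighted log-likelihood over the active support.

    ``support`` is an (M, d) boolean mask of *free* coordinates; coordinates
    outside it are held at ``fixed_value`` (default zero).  Off-support
    history coefficients are therefore exactly zero in the result.

    The optimization runs on the accumulated-likelihood scale (the weighted
    log-likelihood divided by ``1 - beta``) so that ``gtol`` means the same
    thing for any forgetting factor; base rates are box-bounded below at the
    rare-mark floor (a mark with no recent events has an unbounded log-odds
    MLE), and convergence is judged on the projected gradient.  ``ridge``
    adds a quadratic penalty ``ridge/2 * ||theta||^2`` on the *history*
    coefficients only (base rates are never penalized): binary covariates and
    sparse events make quasi-separation common, and an unpenalized history
    coefficient can then run away to its bound.  Returns the refit
    coefficient matrix and a convergence flag; non-convergence is logged and
    the last iterate returned.
    """
    base = np.zeros_like(coef) if fixed_value is None else fixed_value.copy()
    idx = np.nonzero(support.ravel())[0]
    if idx.size == 0:
        return base, True
    scale = 1.0 / (1.0 - stats.beta)
    d = coef.shape[1]
    is_theta = (idx % d) != 0
    lob = np.where(~is_theta, MU_BOUNDS[0], THETA_BOUNDS[0])
    upb = np.where(~is_theta, MU_BOUNDS[1], THETA_BOUNDS[1])

    def unpack(x):
        full = base.copy()
        full.ravel()[idx] = x
        return full

    def negll_grad(x):
        ll, grad = stats.loglik_and_gradient(unpack(x))
        f = -scale * ll
        g = -scale * grad.ravel()[idx]
        if ridge:
            f += 0.5 * ridge * float(np.sum(x[is_theta] ** 2))
            g = g + np.where(is_theta, ridge * x, 0.0)
        return f, g

    def negll(x):
        return negll_grad(x)[0]

    def neggrad(x):
        return negll_grad(x)[1]

    def projected_gnorm(x):
        g = -neggrad(x)  # ascent direction
        g = np.where((x <= lob + 1e-12) & (g < 0), 0.0, g)
        g = np.where((x >= upb - 1e-12) & (g > 0), 0.0, g)
        return np.linalg.norm(g, ord=np.inf)

    x0 = np.clip(coef.ravel()[idx], lob, upb)
    if optimizer == "ascent":
        x, ok = _ascent(lambda x: -negll(x), lambda x: -neggrad(x), x0, gtol)
        x = np.clip(x, lob, upb)
        ok = projected_gnorm(x) < gtol
    else:
        x = x0
        ok = False
        for _ in range(3):  # restarts reset the L-BFGS memory near flat optima
            res = minimize(negll_grad, x, jac=True, method="L-BFGS-B",
                           bounds=list(zip(lob, upb)),
                           options={"gtol": gtol, "maxiter": max_iter,
                                    "ftol": 1e-15})
            x = res.x
            ok = projected_gnorm(x) < 10 * gtol
            if ok or res.nit == 0:
                break
    if not ok:
        logger.warning("refit projected gradient above tolerance %.1e", gtol)
    return unpack(x), ok


# ---------------------------------------------------------------------------
# greedy support selection


def greedy_select(stats: WeightedStats, coef: np.ndarray, support: np.ndarray,
                  s: int, mu_free: np.ndarray,
                  fixed_value: np.ndarray | None = None,
                  optimizer: str = "lbfgs", gtol: float = 1e-6,
                  ridge: float = 0.0, max_iter: int = 500):
    """One window's support update: removal pass, then gradient-guided additions.

    ``support`` masks active *history* coordinates (columns >= 1); column 0 is
    governed by ``mu_free`` (False where the base rate is pinned by a reduced-
    model constraint).  Each mark may hold at most ``s`` history coefficients.
    Returns ``(coef, support, converged)`` after the final refit.
    """
    M, d = coef.shape
    # removal pass: drop collapsed history coefficients from the warm support
    collapsed = support.copy()
    collapsed[:, 0] = False
    drop = collapsed & (np.abs(coef) < REMOVAL_TOL)
    if drop.any():
        support = support & ~drop
        coef = np.where(drop, 0.0, coef)
    support[:, 0] = mu_free

    coef, ok = refit(stats, coef, support, fixed_value, optimizer, gtol, ridge,
                     max_iter)
    if d == 1 or s <= 0:
        return coef, support, ok
    for _ in range(s):
        hist_count = support[:, 1:].sum(axis=1)
        room = hist_count < min(s, d - 1)
        if not room.any():
            break
        g = stats.gradient(coef)
        g[:, 0] = 0.0
        g[support] = 0.0
        g[~room, :] = 0.0
        best = np.abs(g).argmax(axis=1)
        changed = False
        for m in np.nonzero(room)[0]:
            j = best[m]
            if j >= 1 and abs(g[m, j]) > 0:
                support[m, j] = True
                changed = True
        if not changed:
            break
        coef, ok = refit(stats, coef, support, fixed_value, optimizer, gtol, ridge,
                         max_iter)
    return coef, support, ok


# ---------------------------------------------------------------------------
# the adaptive filter


@dataclass
class FilterTrace:
    """Per-window output of the adaptive greedy filter."""

    marks: np.ndarray
    C: int
    p: int
    W: int
    beta: float
    s: int
    coef: np.ndarray            # K x M x d
    loglik: np.ndarray          # K: l_k^beta at the window's own estimate
    df: np.ndarray              # K: number of free parameters (bias term)
    loglik_eval: np.ndarray | None = None  # l_k^beta at externally supplied params
    support: np.ndarray | None = None      # K x M x d boolean

    @property
    def n_windows(self) -> int:
        return self.coef.shape[0]

    def params(self, k: int) -> ModelParams:
        """ModelParams of window ``k`` (1-based)."""
        return ModelParams(self.marks, self.C, self.p, self.coef[k - 1])


def adomp_filter(marked: MarkedSeries, W: int, beta: float, s: int, p: int,
                 markspace: MarkSpace | None = None,
                 raster: SpikeRaster | None = None,
                 X: np.ndarray | None = None,
                 fixed_mu: np.ndarray | None = None,
                 eval_coef: np.ndarray | None = None,
                 optimizer: str = "lbfgs", gtol: float = 1e-6,
                 ridge: float = 0.0, max_iter: int = 80,
                 support_trace: np.ndarray | None = None,
                 keep_support: bool = False) -> FilterTrace:
    """Run the adaptive greedy filter over all windows.

    Parameters
    ----------
    marked:
        Disjoint marked series of the recording.
    W, beta, s, p:
        Window length (bins), forgetting factor, per-mark history sparsity
        budget, and history lag order.
    markspace:
        Reliable mark set; defaults to the full space (no pruning).
    raster / X:
        History covariates: either a raster from which the design is built, or
        a precomputed ``T x (1 + C*p)`` design matrix.  With ``p = 0`` neither
        is needed.
    fixed_mu:
        Optional ``K x M`` array pinning base rates per window: non-NaN
        entries constrain ``mu_k(m)`` to the given value (reduced models).
    eval_coef:
        Optional ``K x M x d`` reference parameters; ``l_k^beta`` is also
        evaluated at ``eval_coef[k]`` with the same statistics (used to share
        one accumulator between full and reduced model evaluations).
    support_trace:
        Optional ``K x M x d`` boolean mask fixing the history support per
        window (no greedy selection; coefficients are refit over the given
        support).  Used by the reduced-model pass of the coordination test so
        that full and reduced fits differ only in the tested constraints, not
        in greedy selection noise.

    Each window is processed exactly once via the recursive statistics, so the
    per-window cost does not grow with the window index (it scales with the
    number of distinct covariate patterns seen).
    """
    if marked.T < W:
        raise ValueError("recording shorter than one window")
    if markspace is None:
        markspace = MarkSpace(C=marked.C, n_thr=0)
    marks = markspace.reliable
    if marks.size == 0:
        raise ValueError("reliable mark set is empty")
    if p > 0:
        if X is None:
            if raster is None:
                from .markspace import from_marked
                raster = from_marked(marked)
            X = build_history_design(raster, p)
    else:
        X = np.ones((marked.T, 1), dtype=np.uint8)
    d = 1 + marked.C * p
    if X.shape[1] != d:
        raise ValueError("design matrix dimension inconsistent with p")
    M = marks.size
    K = marked.T // W
    rows = marked.mark_rows(marks, T=K * W)

    stats = WeightedStats(n_marks=M, dim=d, beta=beta)
    coef = np.zeros((M, d))
    coef[:, 0] = -3.0  # generic low-rate start
    support = np.zeros((M, d), dtype=bool)
    support[:, 0] = True

    out_coef = np.empty((K, M, d))
    out_ll = np.empty(K)
    out_df = np.empty(K, dtype=np.int64)
    out_ll_eval = np.empty(K) if eval_coef is not None else None
    out_support = np.zeros((K, M, d), dtype=bool) if keep_support else None

    for k in range(K):
        sl = slice(k * W, (k + 1) * W)
        stats.update(X[sl], rows[sl])
        mu_free = np.ones(M, dtype=bool)
        fixed_value = None
        if fixed_mu is not None:
            pin = ~np.isnan(fixed_mu[k])
            if pin.any():
                mu_free = ~pin
                fixed_value = np.zeros((M, d))
                fixed_value[pin, 0] = fixed_mu[k][pin]
                coef = coef.copy()
                coef[pin, 0] = fixed_mu[k][pin]
        if support_trace is not None:
            support = support_trace[k].copy()
            support[:, 0] = mu_free
            coef, _ = refit(stats, np.where(support, coef, 0.0), support,
                            fixed_value, optimizer, gtol, ridge, max_iter)
        else:
            coef, support, _ = greedy_select(
                stats, coef, support, s, mu_free, fixed_value, optimizer, gtol,
                ridge, max_iter
            )
        out_coef[k] = coef
        out_ll[k] = stats.loglik(coef)
        out_df[k] = int(support.sum())
        if out_ll_eval is not None:
            out_ll_eval[k] = stats.loglik(eval_coef[k])
        if keep_support:
            out_support[k] = support

    return FilterTrace(marks=marks, C=marked.C, p=p, W=W, beta=beta, s=s,
                       coef=out_coef, loglik=out_ll, df=out_df,
                       loglik_eval=out_ll_eval, support=out_support)


# ---------------------------------------------------------------------------
# sparsity cross-validation


def cross_validate_sparsity(marked: MarkedSeries, candidates, W: int, beta: float,
                            p: int, markspace: MarkSpace | None = None,
                            raster: SpikeRaster | None = None,
                            burn_in: int | None = None) -> int:
    """Select the sparsity budget by forward-chained predictive likelihood.

    For each candidate ``s`` the filter is run once and scored prequentially:
    the window-``k`` outcomes are predicted with the window ``k-1`` estimate
    (a temporal split at every window boundary, so dependent history never
    leaks from the future).  The candidate with the largest summed one-step-
    ahead log-likelihood after ``burn_in`` windows wins; ties go to the
    smaller (sparser) budget.
    """
    candidates = sorted(set(int(s) for s in candidates))
    if len(candidates) == 1:
        return candidates[0]
    if markspace is None:
        markspace = MarkSpace(C=marked.C, n_thr=0)
    if p > 0 and raster is None:
        from .markspace import from_marked
        raster = from_marked(marked)
    X = build_history_design(raster, p) if p > 0 else np.ones((marked.T, 1), dtype=np.uint8)
    K = marked.T // W
    rows = marked.mark_rows(markspace.reliable, T=K * W)
    if burn_in is None:
        burn_in = max(1, K // 5)
    scores = {}
    for s in candidates:
        trace = adomp_filter(marked, W, beta, s, p, markspace=markspace, X=X)
        score = 0.0
        for k in range(burn_in, K):
            sl = slice(k * W, (k + 1) * W)
            score += window_loglik(trace.params(k), X[sl], rows[sl])
        scores[s] = score
        logger.info("cross-validation: s=%d predictive loglik %.2f", s, score)
    best = max(candidates, key=lambda s: (scores[s], -s))
    return best
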