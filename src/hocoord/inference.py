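"""Statistical inference of dynamic higher-order spiking coordination.

The test asks, per window, whether the r-neuron coincidence patterns (the
order-r marks) occur at the rate implied by conditionally independent neurons
given ensemble spiking history.  Writing ``u_t(m) = x_t' w_k(m)`` for the full
model's log-odds of mark ``m`` versus no event, independence implies

    u0_t(m) = sum_{c in m} log( lam_t(c) dt / (1 - lam_t(c) dt) ),

with the per-neuron intensities computed from the fitted full model.  The
window-averaged gap ``gamma_k(m) = mean_t(u_t(m) - u0_t(m))`` is the
*exogenous factor*: the part of mark m's base rate not explained by
independence plus history.  A reduced model pins the tested marks' base rates
at ``mu_k(m) - gamma~_k(m)`` (gamma~ Kalman-smoothed across windows) and
re-estimates everything else; the de-biased, forgetting-factor-scaled deviance

    D_k = (1+beta)/(1-beta) * [ 2(l^beta(full) - l^beta(reduced)) - dB_k ]

is asymptotically chi-square with ``M = |tested marks|`` degrees of freedom
under the null and non-central chi-square under the alternative.  The
non-centrality trace is smoothed over windows, and the outcome per window is
summarized by a signed Youden J statistic in ``[-(1-alpha), 1-alpha]``:
zero when the null is not rejected, near ``+-(1-alpha)`` for strongly
facilitated/suppressed coordination.

The same machinery runs with a history-independent model (``p = 0``), in which
case base rates are fitted in closed form and significant exogenous factors
mean "rates deviate from static independence" — the complementary reading
that, contrasted with the history-dependent result, attributes coordination
to ensemble history or to unobserved exogenous processes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import chi2, ncx2

from .adomp import FilterTrace, adomp_filter
from .history_free import constrained_mu, estimate_mu, hf_loglik
from .markspace import (
    MarkedSeries,
    MarkSpace,
    SpikeRaster,
    from_marked,
    order_r_marks,
    reliable_marks,
)
from .model import ModelParams, build_history_design, mark_cifs

logger = logging.getLogger(__name__)

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# log-odds under full and null models


def log_odds_full(params: ModelParams, x: np.ndarray, m: int) -> np.ndarray:
    """Linear predictor ``u_t(m) = x_t' w(m)`` of mark ``m`` (full model)."""
    row = np.nonzero(params.marks == m)[0]
    if row.size == 0:
        raise ValueError(f"mark {m} not in the reliable set")
    return np.asarray(x, dtype=float) @ params.coef[row[0]]


def null_log_odds(params: ModelParams, x: np.ndarray, m: int) -> np.ndarray:
    """Independence log-odds ``u0_t(m)``: sum of participating neurons' log-odds.

    Neuron intensities are computed from the full model (sums of mark CIFs)
    and clipped away from {0, 1} before the logit.
    """
    p_marks, _, _ = mark_cifs(params, np.atleast_2d(np.asarray(x, dtype=float)))
    return _null_log_odds_from_cifs(p_marks, params.marks, params.C, m)


def _neuron_cifs_matrix(p_marks: np.ndarray, marks: np.ndarray, C: int) -> np.ndarray:
    """T x C matrix of per-neuron intensities from the mark CIF matrix."""
    bits = ((marks[:, None] >> np.arange(C)) & 1).astype(float)  # M x C
    return p_marks @ bits


def _null_log_odds_from_cifs(p_marks: np.ndarray, marks: np.ndarray, C: int,
                             m: int) -> np.ndarray:
    lam = np.clip(_neuron_cifs_matrix(p_marks, marks, C), _PCLIP, 1 - _PCLIP)
    lo = logit(lam)  # T x C
    mbits = (int(m) >> np.arange(C)) & 1
    return (lo[:, mbits.astype(bool)]).sum(axis=1).squeeze()


def estimate_exogenous(u: np.ndarray, u0: np.ndarray) -> float:
    """Window-mean exogenous factor ``gamma_k(m) = mean(u - u0)``."""
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    if u.shape != u0.shape:
        raise ValueError("u and u0 must have equal length")
    return float(np.mean(u - u0))


# ---------------------------------------------------------------------------
# Kalman fixed-interval smoothing (scalar random walk)


def kalman_smooth(y: np.ndarray, obs_var, state_var: float) -> np.ndarray:
    """RTS fixed-interval smoother under a random-walk state model.

    ``y`` may be 1-D (one series) or 2-D ``(K, n_series)``; ``obs_var`` a
    scalar or per-step array.  Initialization is diffuse (the first state
    equals the first observation).
    """
    y = np.asarray(y, dtype=float)
    one = y.ndim == 1
    Y = y[:, None] if one else y
    K, S = Y.shape
    R = np.broadcast_to(np.asarray(obs_var, dtype=float), (K,)) if np.ndim(obs_var) <= 1 \
        else np.asarray(obs_var, dtype=float)
    if R.ndim == 0:
        R = np.full(K, float(R))
    Q = float(state_var)
    xf = np.empty((K, S))
    Pf = np.empty(K)
    x = Y[0].copy()
    P = R[0]
    xf[0], Pf[0] = x, P
    for k in range(1, K):
        Pp = P + Q
        gain = Pp / (Pp + R[k])
        x = x + gain * (Y[k] - x)
        P = (1 - gain) * Pp
        xf[k], Pf[k] = x, P
    xs = xf.copy()
    for k in range(K - 2, -1, -1):
        G = Pf[k] / (Pf[k] + Q) if (Pf[k] + Q) > 0 else 0.0
        xs[k] = xf[k] + G * (xs[k + 1] - xf[k])
    return xs[:, 0] if one else xs


def smooth_exogenous(gamma: np.ndarray, obs_var: float | None = None,
                     state_var: float | None = None) -> np.ndarray:
    """Kalman forward/backward smoothing of the exogenous-factor trace.

    Observation variance defaults to the first-difference estimate
    ``var(diff(gamma)) / 2`` (pooled over marks); state-noise variance
    defaults to a tenth of that, a mild smoother that suppresses abrupt
    window-to-window variation without erasing real transitions.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] < 2:
        return gamma.copy()
    if obs_var is None:
        dif = np.diff(gamma, axis=0)
        obs_var = float(np.var(dif) / 2.0)
    if obs_var <= 0:
        return gamma.copy()
    if state_var is None:
        state_var = obs_var / 10.0
    return kalman_smooth(gamma, obs_var, state_var)


# ---------------------------------------------------------------------------
# deviance, non-centrality, J


def deviance_difference(ll_full: float, ll_reduced: float, b_full: float,
                        b_reduced: float, beta: float) -> float:
    """Adaptive de-biased deviance difference ``D_k``."""
    scale = (1.0 + beta) / (1.0 - beta)
    return scale * (2.0 * (ll_full - ll_reduced) - (b_full - b_reduced))


def estimate_noncentrality(D: np.ndarray, M: int,
                           state_var: float = 10.0) -> np.ndarray:
    """Smoothed non-centrality trace from observed deviance differences.

    Uses the moment identity ``E[chi2(M, nu)] = M + nu``: pseudo-observations
    ``max(D - M, 0)`` enter a random-walk Kalman smoother whose observation
    variance is the chi-square variance ``2(M + 2 nu_obs)``.  Negative inputs
    are floored at zero with a warning.
    """
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        logger.warning("floored %d negative deviance values at 0", int((D < 0).sum()))
        D = np.maximum(D, 0.0)
    nu_obs = np.maximum(D - M, 0.0)
    if nu_obs.size < 2:
        return nu_obs
    obs_var = 2.0 * (M + 2.0 * nu_obs)
    return np.maximum(kalman_smooth(nu_obs, obs_var, state_var), 0.0)


def fit_reduced(marked: MarkedSeries, full_trace: FilterTrace,
                mu0: np.ndarray, tested_rows: np.ndarray,
                raster: SpikeRaster | None = None,
                X: np.ndarray | None = None,
                markspace: MarkSpace | None = None,
                ridge: float = 0.1, gtol: float = 1e-4) -> FilterTrace:
    """Constrained reduced-model pass for a nested coordination test.

    Pins the base rates of the tested marks (rows ``tested_rows`` of the
    reliable set) to ``mu0`` (K x n_tested, typically the smoothed
    null-rate trace) and re-estimates all remaining parameters over the full
    pass's selected history support, window by window.  The constrained
    optimum can never exceed the full fit's likelihood.
    """
    from .adomp import MU_BOUNDS

    if markspace is None:
        markspace = MarkSpace(C=marked.C, n_thr=0,
                              reliable=full_trace.marks)
    K = full_trace.n_windows
    fixed_mu = np.full((K, full_trace.marks.size), np.nan)
    fixed_mu[:, tested_rows] = np.clip(mu0, MU_BOUNDS[0], MU_BOUNDS[1])
    if X is None and full_trace.p > 0:
        if raster is None:
            raster = from_marked(marked)
        X = build_history_design(raster, full_trace.p)
    return adomp_filter(marked, full_trace.W, full_trace.beta, full_trace.s,
                        full_trace.p, markspace=markspace, X=X,
                        fixed_mu=fixed_mu, ridge=ridge, gtol=gtol,
                        support_trace=full_trace.support)


def benjamini_hochberg(pvalues: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """BH step-up rejection mask at false-discovery rate ``alpha``.

    Optional correction across the windows of one inference run (off by
    default everywhere: each window is ordinarily tested at level alpha).
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    reject = np.zeros(n, dtype=bool)
    if passed.any():
        k_max = np.nonzero(passed)[0].max()
        reject[order[:k_max + 1]] = True
    return reject


def j_statistic(nu: float, M: int, alpha: float, sign: float = 1.0,
                reject: bool = True) -> float:
    """Signed Youden J: ``1 - alpha - F_{chi2(M, nu)}(F^-1_{chi2(M)}(1-alpha))``.

    Zero when the window's test does not reject; multiplied by the sign of the
    net (smoothed) exogenous effect otherwise.  Bounded by ``1 - alpha`` in
    magnitude; 0 at ``nu = 0``, approaching ``1 - alpha`` as ``nu -> inf``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if nu < 0:
        raise ValueError("non-centrality must be >= 0")
    if not reject:
        return 0.0
    thr = chi2.ppf(1.0 - alpha, M)
    beta_err = ncx2.cdf(thr, M, nu) if nu > 0 else (1.0 - alpha)
    return float(np.sign(sign) * (1.0 - alpha - beta_err))


# ---------------------------------------------------------------------------
# result container


@dataclass
class InferenceResult:
    """Per-window coordination-inference trace for one tested mark set."""

    order: int | None
    tested_marks: np.ndarray
    M: int
    W: int
    beta: float
    alpha: float
    history: bool
    D: np.ndarray
    nu: np.ndarray
    h: np.ndarray
    J: np.ndarray
    gamma: np.ndarray          # K x M raw exogenous factors
    gamma_smooth: np.ndarray   # K x M smoothed
    config: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.D.size

    def pvalues(self) -> np.ndarray:
        """Per-window upper-tail p-values of D under the central chi-square."""
        return chi2.sf(np.maximum(self.D, 0.0), self.M)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window": np.arange(1, self.n_windows + 1),
            "D": self.D,
            "nu": self.nu,
            "h": self.h,
            "J": self.J,
            "sum_gamma_smooth": self.gamma_smooth.sum(axis=1),
        })

    def write_tsv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        if sidecar:
            side = str(path) + ".json"
            cfg = dict(self.config)
            cfg.update(order=self.order,
                       tested_marks=[int(m) for m in self.tested_marks],
                       M=self.M, W=self.W, beta=self.beta, alpha=self.alpha,
                       history=self.history)
            with open(side, "w") as fh:
                json.dump(cfg, fh, indent=2)


# ---------------------------------------------------------------------------
# bias strategies


def _bias_terms(df_full: np.ndarray, df_reduced: np.ndarray, M: int,
                beta: float, strategy) -> tuple[np.ndarray, np.ndarray]:
    """Per-window bias terms (B_full, B_reduced) on the weighted-loglik scale.

    The default ``"adaptive"`` strategy charges each model its free-parameter
    count, counting the reduced model's data-estimated base-rate constraints
    as spent degrees of freedom, all scaled by ``(1-beta)/(1+beta)`` (the
    effective inverse sample size of the forgetting-factor likelihood).  The
    bias difference then vanishes when the two supports otherwise coincide,
    which preserves the central chi-square(M) null calibration; any excess
    support selected by only one of the fits is corrected at one effective
    degree of freedom per coefficient.  ``"none"`` disables the correction;
    a callable ``strategy(df_full, df_reduced, M, beta)`` may supply both
    terms directly.
    """
    if callable(strategy):
        return strategy(df_full, df_reduced, M, beta)
    unit = (1.0 - beta) / (1.0 + beta)
    if strategy == "adaptive":
        return df_full * unit, (df_reduced + M) * unit
    if strategy == "none":
        z = np.zeros_like(df_full, dtype=float)
        return z, z
    raise ValueError(f"unknown bias strategy {strategy!r}")


# ---------------------------------------------------------------------------
# the full pipeline (Algorithm: full fit -> gamma -> constraint -> reduced fit
# -> deviance -> threshold test -> noncentrality smoothing -> signed J)


def run_inference(marked: MarkedSeries, r: int | None, W: int, beta: float,
                  alpha: float = 0.01, p: int = 0, s: int = 0,
                  n_thr: int = 1, history: bool | None = None,
                  raster: SpikeRaster | None = None,
                  tested_marks: np.ndarray | None = None,
                  markspace: MarkSpace | None = None,
                  nu_state_var: float = 10.0,
                  gamma_state_var: float | None = None,
                  bias: str = "adaptive",
                  ridge: float = 0.1,
                  gtol: float = 1e-4,
                  full_trace: FilterTrace | None = None) -> InferenceResult:
    """Dynamic inference of r-th order (or arbitrary-subset) coordination.

    Runs the full pipeline: adaptive full-model fit, per-window exogenous
    factors, Kalman smoothing, constrained reduced-model fit, de-biased
    deviance differences, threshold test at level ``alpha``, non-centrality
    smoothing, and signed J statistics.  ``history=False`` (or ``p == 0``)
    uses the closed-form history-independent model.

    ``tested_marks`` overrides the order-r set to test the significance of an
    arbitrary collection of simultaneous-spiking patterns; ``full_trace``
    allows reuse of a previously computed full-model fit (history case).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if history is None:
        history = p > 0
    if history and p <= 0:
        raise ValueError("history-dependent inference requires p >= 1")
    if markspace is None:
        markspace = reliable_marks(marked, n_thr)
    if tested_marks is None:
        if r is None:
            raise ValueError("either r or tested_marks must be given")
        if not 1 <= r <= marked.C:
            raise ValueError(f"order r={r} out of range for C={marked.C}")
        tested_marks = order_r_marks(marked.C, r)
    tested_marks = np.asarray(tested_marks, dtype=np.int64)
    tested = tested_marks[np.isin(tested_marks, markspace.reliable)]
    skipped = np.setdiff1d(tested_marks, tested)
    if skipped.size:
        logger.warning("tested marks %s not reliable; skipped", skipped.tolist())
    if tested.size == 0:
        raise ValueError(
            f"no tested mark of order r={r} is in the reliable set: "
            "order untestable at this pruning threshold"
        )
    M_t = tested.size
    marks = markspace.reliable
    t_rows = np.searchsorted(marks, tested)  # rows of tested marks (marks sorted)

    cfg = dict(W=W, beta=beta, alpha=alpha, p=p, s=s, n_thr=n_thr,
               bias=bias, nu_state_var=nu_state_var)

    if history:
        res = _history_dependent(marked, raster, marks, tested, t_rows, W, beta,
                                 p, s, markspace, gamma_state_var, ridge, gtol,
                                 full_trace)
    else:
        res = _history_free(marked, marks, tested, t_rows, W, beta,
                            markspace, gamma_state_var)
    ll_F, ll_R, df_F, df_R, gamma, gamma_s = res

    b_F, b_R = _bias_terms(df_F, df_R, M_t, beta, bias)
    scale = (1.0 + beta) / (1.0 - beta)
    D = scale * (2.0 * (ll_F - ll_R) - (b_F - b_R))

    thr = chi2.ppf(1.0 - alpha, M_t)
    reject = D > thr
    sign = np.sign(gamma_s.sum(axis=1))
    h = np.where(reject, sign, 0.0)

    nu = estimate_noncentrality(D, M_t, state_var=nu_state_var)
    beta_err = np.where(nu > 0, ncx2.cdf(thr, M_t, np.maximum(nu, 1e-300)),
                        1.0 - alpha)
    J = h * (1.0 - alpha - beta_err)

    return InferenceResult(order=r, tested_marks=tested, M=M_t, W=W, beta=beta,
                           alpha=alpha, history=history, D=D, nu=nu, h=h, J=J,
                           gamma=gamma, gamma_smooth=gamma_s, config=cfg)


def _history_dependent(marked, raster, marks, tested, t_rows, W, beta, p, s,
                       markspace, gamma_state_var, ridge, gtol, full_trace):
    if raster is None:
        raster = from_marked(marked)
    X = build_history_design(raster, p)
    if full_trace is None:
        full_trace = adomp_filter(marked, W, beta, s, p, markspace=markspace,
                                  X=X, ridge=ridge, gtol=gtol,
                                  keep_support=True)
    K = full_trace.n_windows
    C = marked.C
    bits = ((marks[:, None] >> np.arange(C)) & 1).astype(float)

    gamma = np.empty((K, tested.size))
    for k in range(K):
        sl = slice(k * W, (k + 1) * W)
        Xw = X[sl].astype(float)
        coef = full_trace.coef[k]
        u = Xw @ coef[t_rows].T                       # W x M_t
        params = ModelParams(marks, C, p, coef)
        p_marks, _, _ = mark_cifs(params, Xw)
        lam = np.clip(p_marks @ bits, _PCLIP, 1 - _PCLIP)   # W x C
        lo = logit(lam)
        tb = ((tested[:, None] >> np.arange(C)) & 1).astype(float)  # M_t x C
        u0 = lo @ tb.T                                # W x M_t
        gamma[k] = (u - u0).mean(axis=0)
    # Smooth the null-rate trace mu_hat - gamma_hat (rather than gamma alone):
    # the two are equivalent when mu_hat evolves smoothly, but the null rates
    # are driven by the well-estimated per-neuron intensities and stay stable
    # even when a rare tested mark's own base-rate estimate jumps between its
    # floor and a post-event value.
    mu_hat = full_trace.coef[:, t_rows, 0]
    mu0 = smooth_exogenous(mu_hat - gamma, state_var=gamma_state_var)
    gamma_s = mu_hat - mu0

    reduced = fit_reduced(marked, full_trace, mu0, t_rows, X=X,
                          markspace=markspace, ridge=ridge, gtol=gtol)
    return (full_trace.loglik, reduced.loglik,
            full_trace.df.astype(float), reduced.df.astype(float),
            gamma, gamma_s)


def _history_free(marked, marks, tested, t_rows, W, beta, markspace,
                  gamma_state_var):
    trace = estimate_mu(marked, W, beta, markspace=markspace)
    K = trace.n_windows
    C = marked.C
    M = marks.size
    bits = ((marks[:, None] >> np.arange(C)) & 1).astype(float)
    tb = ((tested[:, None] >> np.arange(C)) & 1).astype(float)

    # softmax mark probabilities per window
    z = np.concatenate([np.zeros((K, 1)), trace.mu], axis=1)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez[:, 1:] / ez.sum(axis=1, keepdims=True)
    lam = np.clip(probs @ bits, _PCLIP, 1 - _PCLIP)   # K x C
    u0 = logit(lam) @ tb.T                             # K x M_t
    gamma = trace.mu[:, t_rows] - u0
    # Constrain to the smoothed independence log-odds (see history-dependent
    # branch for why the smoother runs on the null-rate trace).
    mu0_s = smooth_exogenous(u0, state_var=gamma_state_var)
    gamma_s = trace.mu[:, t_rows] - mu0_s

    # weighted log-likelihoods of full and reduced closed-form fits
    ll_F = np.empty(K)
    ll_R = np.empty(K)
    wsum = 0.0
    for k in range(K):
        wsum = beta * wsum + 1.0
        mbar = trace.mark_means[k]
        ll_F[k] = hf_loglik(trace.mu[k], mbar, W, wsum, beta)
        fixed = {int(row): float(mu0_s[k, i]) for i, row in enumerate(t_rows)}
        mu_red = constrained_mu(mbar, fixed)
        ll_R[k] = hf_loglik(mu_red, mbar, W, wsum, beta)
    df_F = np.full(K, float(M))
    df_R = np.full(K, float(M - tested.size))
    return ll_F, ll_R, df_F, df_R, gamma, gamma_s
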