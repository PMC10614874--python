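"""Conditional intensities, likelihoods, and the recursive weighted statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hocoord.markspace import MarkSpace, reliable_marks
from hocoord.model import (
    ModelParams,
    WeightedStats,
    build_history_design,
    effective_window,
    event_log_likelihood,
    iter_windows,
    mark_cifs,
    neuron_cif,
    weighted_gradient,
    weighted_loglik,
    window_loglik,
)


def params_of(mu, C, p=0, theta=None, marks=None):
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if marks is None:
        marks = np.arange(1, mu.size + 1)
    coef = np.zeros((mu.size, 1 + C * p))
    coef[:, 0] = mu
    if theta is not None:
        coef[:, 1:] = theta
    return ModelParams(np.asarray(marks), C, p, coef)


class TestMarkCifs:
    def test_zero_parameters_uniform(self):
        # C*=3 marks with all-zero coefficients: each outcome has mass 1/4
        params = params_of([0.0, 0.0, 0.0], C=2)
        p_marks, p_ground, p_none = mark_cifs(params, np.ones(1))
        assert np.allclose(p_marks, 0.25)
        assert np.isclose(p_ground, 0.75)
        assert np.isclose(p_none, 0.25)

    def test_log2_example(self):
        # mu = (0, 0, ln 2) -> probabilities (1/5, 1/5, 2/5), ground 4/5
        params = params_of([0.0, 0.0, np.log(2)], C=2)
        p_marks, p_ground, p_none = mark_cifs(params, np.ones(1))
        assert np.allclose(p_marks, [0.2, 0.2, 0.4])
        assert np.isclose(p_ground, 0.8)
        assert np.isclose(p_none, 0.2)

    def test_all_rates_vanish(self):
        params = params_of([-200.0, -200.0, -200.0], C=2)
        _, _, p_none = mark_cifs(params, np.ones(1))
        assert np.isclose(p_none, 1.0)

    @given(st.integers(1, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_outcome_probabilities_sum_to_one(self, C, seed):
        rng = np.random.default_rng(seed)
        M = 2 ** C - 1
        params = params_of(rng.normal(0, 2, M), C=C)
        p_marks, p_ground, p_none = mark_cifs(params, np.ones(1))
        assert np.isclose(p_marks.sum() + p_none, 1.0)
        assert np.isclose(p_ground, p_marks.sum())

    def test_dimension_mismatch(self):
        params = params_of([0.0], C=1)
        with pytest.raises(ValueError):
            mark_cifs(params, np.ones(3))


class TestNeuronCif:
    def test_bitmask_sum(self):
        params = params_of([0.0, 0.0, np.log(2)], C=2)
        x = np.ones(1)
        # neuron 1 participates in marks 1 and 3: 1/5 + 2/5
        assert np.isclose(neuron_cif(params, x, 1), 0.6)
        assert np.isclose(neuron_cif(params, x, 2), 0.6)

    def test_uniform_combinatorics(self):
        C = 3
        params = params_of(np.zeros(7), C=C)
        lam_c = neuron_cif(params, np.ones(1), 1)
        p_marks, _, _ = mark_cifs(params, np.ones(1))
        assert np.isclose(lam_c, 2 ** (C - 1) * p_marks[0])

    def test_single_reliable_mark(self):
        # only the "neuron 2 alone" mark is modeled
        params = params_of([-1.0], C=2, marks=[2])
        p_marks, _, _ = mark_cifs(params, np.ones(1))
        assert np.isclose(neuron_cif(params, np.ones(1), 2), p_marks[0])
        assert np.isclose(neuron_cif(params, np.ones(1), 1), 0.0)


class TestEventLogLikelihood:
    def test_no_event(self):
        # ground probability 0.2 -> log 0.8
        mu = np.log(np.array([0.1, 0.1]) / 0.8)
        params = params_of(mu, C=2, marks=[1, 2])
        ll = event_log_likelihood(np.zeros(2), params, np.ones(1))
        assert np.isclose(ll, np.log(0.8))

    def test_mark_event(self):
        mu = np.log(np.array([0.1, 0.1, 0.4]) / 0.4)
        params = params_of(mu, C=2)
        p_marks, _, _ = mark_cifs(params, np.ones(1))
        assert np.isclose(p_marks[2], 0.4)
        ll = event_log_likelihood(np.array([0, 0, 1]), params, np.ones(1))
        assert np.isclose(ll, np.log(0.4))

    def test_normalization_over_outcomes(self, rng):
        params = params_of(rng.normal(0, 1, 3), C=2)
        total = np.exp(event_log_likelihood(np.zeros(3), params, np.ones(1)))
        for m in range(3):
            n_star = np.zeros(3)
            n_star[m] = 1
            total += np.exp(event_log_likelihood(n_star, params, np.ones(1)))
        assert np.isclose(total, 1.0)

    def test_two_marks_invalid(self):
        params = params_of([0.0, 0.0, 0.0], C=2)
        with pytest.raises(ValueError):
            event_log_likelihood(np.array([1, 1, 0]), params, np.ones(1))


class TestWindowLoglik:
    def test_all_zero_outcomes(self):
        # C*=1, omega=0, two empty bins: each bin contributes -log 2
        params = params_of([0.0], C=1)
        X = np.ones((2, 1))
        rows = np.array([-1, -1])
        assert np.isclose(window_loglik(params, X, rows), -2 * np.log(2))

    def test_equals_per_bin_sum(self, small_raster, small_marked, rng):
        p = 2
        X = build_history_design(small_raster, p)
        space = reliable_marks(small_marked, 0)
        rows = small_marked.mark_rows(space.reliable)
        M = space.reliable.size
        params = params_of(rng.normal(-2, 1, M), C=4, p=p,
                           theta=rng.normal(0, 0.3, (M, 8)),
                           marks=space.reliable)
        sl = slice(40, 60)
        total = 0.0
        for t in range(40, 60):
            n_star = np.zeros(M)
            if rows[t] >= 0:
                n_star[rows[t]] = 1
            total += event_log_likelihood(n_star, params, X[t])
        assert np.isclose(window_loglik(params, X[sl], rows[sl]), total)

    def test_history_free_reduction(self, rng):
        # with constant covariates the window log-likelihood collapses to
        # W * (mu' nbar - psi(mu))
        W, M = 10, 3
        mu = rng.normal(-1.5, 0.5, M)
        params = params_of(mu, C=2)
        rows = np.array([0, -1, 2, -1, -1, 1, -1, -1, 0, -1])
        X = np.ones((W, 1))
        nbar = np.bincount(rows[rows >= 0], minlength=M) / W
        psi = np.log(1 + np.exp(mu).sum())
        assert np.isclose(window_loglik(params, X, rows),
                          W * (mu @ nbar - psi))


def _random_problem(rng, C=3, p=1, K=6, W=8):
    data = (rng.random((C, K * W)) < 0.25).astype(np.uint8)
    from hocoord.markspace import SpikeRaster, to_marked

    raster = SpikeRaster(data)
    marked = to_marked(raster)
    X = build_history_design(raster, p)
    space = MarkSpace(C=C, n_thr=0)
    rows = marked.mark_rows(space.reliable, T=K * W)
    M = space.reliable.size
    params = params_of(rng.normal(-1.5, 0.8, M), C=C, p=p,
                       theta=rng.normal(0, 0.4, (M, C * p)),
                       marks=space.reliable)
    wins = list(iter_windows(X, rows, W))
    return params, wins


class TestWeightedLoglik:
    def test_beta_zero_is_current_window(self, rng):
        params, wins = _random_problem(rng)
        assert np.isclose(weighted_loglik(params, wins, 0.0),
                          window_loglik(params, *wins[-1]))

    def test_single_window_scaling(self, rng):
        params, wins = _random_problem(rng, K=1)
        l1 = window_loglik(params, *wins[0])
        assert np.isclose(weighted_loglik(params, wins, 0.5), 0.5 * l1)

    @pytest.mark.parametrize("beta", [0.0, 0.5, 0.9])
    def test_recursion_matches_direct(self, rng, beta):
        params, wins = _random_problem(rng, K=12)
        stats = WeightedStats(n_marks=params.n_marks, dim=params.coef.shape[1],
                              beta=beta)
        for k, (Xw, rw) in enumerate(wins, start=1):
            stats.update(Xw, rw)
            direct = weighted_loglik(params, wins[:k], beta)
            assert np.isclose(stats.loglik(params.coef), direct,
                              rtol=1e-10, atol=1e-10)


class TestWeightedGradient:
    def test_first_window_scaling(self, rng):
        params, wins = _random_problem(rng, K=1)
        g1 = weighted_gradient(params, wins, 0.0)
        g_beta = weighted_gradient(params, wins, 0.6)
        assert np.allclose(g_beta, (1 - 0.6) * g1)

    def test_recursive_equals_direct_and_finite_difference(self, rng):
        beta = 0.8
        params, wins = _random_problem(rng, K=5)
        stats = WeightedStats(n_marks=params.n_marks, dim=params.coef.shape[1],
                              beta=beta)
        for Xw, rw in wins:
            stats.update(Xw, rw)
        g_rec = stats.gradient(params.coef)
        g_dir = weighted_gradient(params, wins, beta)
        assert np.abs(g_rec - g_dir).max() <= 1e-8 * max(1.0, np.abs(g_dir).max())
        # spot-check against central finite differences
        eps = 1e-6
        for (i, j) in [(0, 0), (1, 0), (2, params.coef.shape[1] - 1)]:
            cplus = params.coef.copy()
            cplus[i, j] += eps
            cminus = params.coef.copy()
            cminus[i, j] -= eps
            fd = (stats.loglik(cplus) - stats.loglik(cminus)) / (2 * eps)
            assert np.isclose(g_rec[i, j], fd, rtol=1e-4, atol=1e-7)

    def test_gradient_vanishes_at_maximizer(self, rng):
        from hocoord.adomp import refit

        params, wins = _random_problem(rng, K=8)
        stats = WeightedStats(n_marks=params.n_marks, dim=params.coef.shape[1],
                              beta=0.7)
        for Xw, rw in wins:
            stats.update(Xw, rw)
        support = np.ones_like(params.coef, dtype=bool)
        coef, ok = refit(stats, params.coef, support, gtol=1e-7)
        assert ok
        g = stats.gradient(coef) / (1 - 0.7)
        at_bound = np.zeros_like(coef, dtype=bool)
        at_bound[:, 0] = (coef[:, 0] <= -20 + 1e-9) | (coef[:, 0] >= 5 - 1e-9)
        at_bound[:, 1:] = np.abs(coef[:, 1:]) >= 10 - 1e-9
        assert np.abs(np.where(at_bound, 0.0, g)).max() < 1e-6

    def test_concavity_same_optimum_from_two_starts(self, rng):
        from hocoord.adomp import refit

        params, wins = _random_problem(rng, K=6)
        stats = WeightedStats(n_marks=params.n_marks, dim=params.coef.shape[1],
                              beta=0.5)
        for Xw, rw in wins:
            stats.update(Xw, rw)
        support = np.ones_like(params.coef, dtype=bool)
        c1, _ = refit(stats, np.zeros_like(params.coef), support, gtol=1e-8)
        c2, _ = refit(stats, params.coef, support, gtol=1e-8)
        assert np.isclose(stats.loglik(c1), stats.loglik(c2), atol=1e-6)


class TestEffectiveWindow:
    @pytest.mark.parametrize("W,beta,expected", [(10, 0.975, 400.0),
                                                 (10, 0.95, 200.0),
                                                 (10, 0.99, 1000.0)])
    def test_values(self, W, beta, expected):
        assert np.isclose(effective_window(W, beta), expected)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            effective_window(10, 1.0)


class TestHistoryDesign:
    def test_layout_and_padding(self):
        from hocoord.markspace import SpikeRaster

        data = np.array([[1, 0, 1, 0], [0, 1, 0, 0]], dtype=np.uint8)
        X = build_history_design(SpikeRaster(data), p=2)
        assert X.shape == (4, 5)
        assert (X[:, 0] == 1).all()
        # bin 0 has zero-padded history
        assert (X[0, 1:] == 0).all()
        # bin 2: neuron 1 lag1 = data[0,1] = 0, lag2 = data[0,0] = 1;
        #        neuron 2 lag1 = data[1,1] = 1, lag2 = data[1,0] = 0
        assert X[2, 1:].tolist() == [0, 1, 1, 0]
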