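"""Nested-hypothesis machinery: exogenous factors, smoothing, deviance, J."""

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import chi2

from hocoord.inference import (
    deviance_difference,
    estimate_exogenous,
    estimate_noncentrality,
    j_statistic,
    kalman_smooth,
    log_odds_full,
    null_log_odds,
    run_inference,
    smooth_exogenous,
)
from hocoord.model import ModelParams, mark_cifs
from hocoord.simulator import (
    SimulationConfig,
    independent_mu,
    make_independent,
    simulate,
)


def static_params(rates):
    """History-free product-form model with given per-neuron rates."""
    C = len(rates)
    mu = independent_mu(np.asarray(rates))
    coef = mu[:, None]
    return ModelParams(np.arange(1, 2 ** C), C, 0, coef)


class TestLogOdds:
    def test_full_log_odds_reduces_to_mu_without_history(self):
        params = static_params([0.2, 0.3])
        x = np.ones((4, 1))
        u = log_odds_full(params, x, 3)
        assert np.allclose(u, params.coef[2, 0])

    def test_full_log_odds_matches_cif_identity(self):
        params = static_params([0.1, 0.25, 0.05])
        x = np.ones((1, 1))
        p_marks, p_ground, _ = mark_cifs(params, x)
        for m in (1, 5, 7):
            row = m - 1
            expected = np.log(p_marks[0, row] / (1 - p_ground[0]))
            assert np.isclose(log_odds_full(params, x, m)[0], expected)

    def test_null_log_odds_equal_rates_half(self):
        params = static_params([0.5, 0.5])
        u0 = null_log_odds(params, np.ones((1, 1)), 3)
        assert np.isclose(u0, 0.0, atol=1e-9)

    def test_null_log_odds_single_neuron(self):
        params = static_params([0.3, 0.2])
        u0 = null_log_odds(params, np.ones((1, 1)), 2)
        assert np.isclose(u0, logit(0.2), atol=1e-9)

    def test_null_log_odds_three_neurons(self):
        params = static_params([0.1, 0.2, 0.4])
        u0 = null_log_odds(params, np.ones((1, 1)), 7)
        expected = np.log(1 / 9) + np.log(0.25) + np.log(2 / 3)
        assert np.isclose(u0, expected, atol=1e-9)

    def test_product_form_has_zero_exogenous_factor(self):
        # under independence the full and null log-odds coincide identically
        params = static_params([0.1, 0.2, 0.4])
        x = np.ones((5, 1))
        for m in (3, 5, 7):
            u = log_odds_full(params, x, m)
            u0 = null_log_odds(params, x, m)
            assert np.isclose(estimate_exogenous(u, np.atleast_1d(u0) * np.ones(5)), 0.0,
                              atol=1e-9)

    def test_estimate_exogenous_basics(self, rng):
        u = rng.normal(size=20)
        assert np.isclose(estimate_exogenous(u, u), 0.0)
        assert np.isclose(estimate_exogenous(u + 1.3, u), 1.3)
        u0 = rng.normal(size=20)
        assert np.isclose(estimate_exogenous(u, u0), (u - u0).mean())
        with pytest.raises(ValueError):
            estimate_exogenous(u, u0[:-1])


class TestKalmanSmoothing:
    def test_constant_input_unchanged(self):
        y = np.full(30, 2.5)
        out = smooth_exogenous(y)
        assert np.allclose(out, 2.5)

    def test_huge_state_noise_returns_input(self, rng):
        y = rng.normal(size=40)
        out = kalman_smooth(y, obs_var=1.0, state_var=1e9)
        assert np.allclose(out, y, atol=1e-3)

    def test_noisy_step_has_smaller_total_variation(self, rng):
        y = np.concatenate([np.zeros(40), np.ones(40)]) + rng.normal(0, 0.5, 80)
        out = smooth_exogenous(y)
        tv = lambda a: np.abs(np.diff(a)).sum()  # noqa: E731
        assert tv(out) < tv(y)

    def test_multiseries(self, rng):
        y = rng.normal(size=(25, 3))
        out = smooth_exogenous(y)
        assert out.shape == y.shape


class TestDeviance:
    def test_zero_when_equal(self):
        assert deviance_difference(-5.0, -5.0, 1.0, 1.0, 0.9) == 0.0

    def test_scale_factor(self):
        # beta = 0.99 -> (1+beta)/(1-beta) = 199
        d = deviance_difference(1.0, 0.0, 0.0, 0.0, 0.99)
        assert np.isclose(d, 398.0)

    def test_bias_subtraction(self):
        d = deviance_difference(1.0, 0.0, 0.5, 0.0, 0.0)
        assert np.isclose(d, 1.5)


class TestNoncentrality:
    def test_central_input_gives_zero(self):
        nu = estimate_noncentrality(np.full(50, 10.0), M=10)
        assert np.allclose(nu, 0.0)

    def test_moment_matching_fixed_point(self):
        nu = estimate_noncentrality(np.full(200, 110.0), M=10)
        assert np.allclose(nu[50:], 100.0, rtol=0.05)

    def test_negative_floored(self, caplog):
        nu = estimate_noncentrality(np.array([-3.0, 5.0, 4.0]), M=10)
        assert (nu >= 0).all()


class TestJStatistic:
    def test_zero_noncentrality(self):
        assert j_statistic(0.0, M=10, alpha=0.01) == 0.0

    def test_saturates_at_one_minus_alpha(self):
        assert np.isclose(j_statistic(1e6, M=10, alpha=0.01), 0.99, atol=1e-9)
        assert np.isclose(j_statistic(1e6, M=5, alpha=0.05), 0.95, atol=1e-9)

    def test_reported_noncentrality_value(self):
        # nu = 327 with M = 10 at alpha = 0.01: essentially full power
        assert abs(j_statistic(327.0, M=10, alpha=0.01) - 0.99) < 1e-4

    def test_sign_and_rejection_gating(self):
        assert j_statistic(50.0, M=10, alpha=0.01, sign=-1.0) < 0
        assert j_statistic(50.0, M=10, alpha=0.01, reject=False) == 0.0

    def test_bounded_by_one_minus_alpha(self, rng):
        for nu in rng.uniform(0, 500, 25):
            assert abs(j_statistic(nu, M=7, alpha=0.01)) <= 0.99 + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            j_statistic(1.0, M=10, alpha=1.5)
        with pytest.raises(ValueError):
            j_statistic(-1.0, M=10, alpha=0.01)


class TestRunInference:
    def test_invalid_order(self):
        sim = make_independent(1, T=400, C=3, seed=0, rates=np.full(3, 0.2))[0]
        with pytest.raises(ValueError):
            run_inference(sim.marked, r=4, W=10, beta=0.9)
        with pytest.raises(ValueError):
            run_inference(sim.marked, r=3, W=10, beta=0.9, alpha=1.2)

    def test_untestable_order_errors(self):
        # quiet ensemble: no 3rd-order event ever occurs
        sim = make_independent(1, T=400, C=3, seed=1, rates=np.full(3, 0.02))[0]
        with pytest.raises(ValueError, match="untestable"):
            run_inference(sim.marked, r=3, W=10, beta=0.9, n_thr=5)

    def test_history_free_smoke_invariants(self):
        sim = make_independent(1, T=2000, C=3, seed=2, rates=np.full(3, 0.25))[0]
        res = run_inference(sim.marked, r=2, W=10, beta=0.95, alpha=0.01,
                            history=False)
        assert res.n_windows == 200
        assert np.all(np.abs(res.J) <= 0.99 + 1e-12)
        thr = chi2.ppf(0.99, res.M)
        # J nonzero exactly on rejected windows
        assert np.array_equal(res.J != 0, res.D > thr)
        frame = res.to_frame()
        assert list(frame.columns) == ["window", "D", "nu", "h", "J",
                                       "sum_gamma_smooth"]

    def test_arbitrary_mark_subset(self):
        # the nested test runs on any tested collection, not just full K_r
        sim = make_independent(1, T=2000, C=3, seed=3, rates=np.full(3, 0.25))[0]
        res = run_inference(sim.marked, r=None, tested_marks=np.array([3, 7]),
                            W=10, beta=0.95, history=False)
        assert res.M == 2
        assert np.all(np.abs(res.J) <= 0.99 + 1e-12)
        assert np.array_equal(res.J != 0, res.D > chi2.ppf(0.99, 2))

    def test_history_pipeline_smoke(self):
        sim = make_independent(1, T=1200, C=3, seed=4, rates=np.full(3, 0.25))[0]
        res = run_inference(sim.marked, r=2, W=10, beta=0.95, p=1, s=1,
                            history=True, raster=sim.raster)
        assert res.n_windows == 120
        assert res.history
        assert np.isfinite(res.D).all()
        assert (res.nu >= 0).all()

    def test_facilitated_pair_detected(self):
        # strong exogenous drive on one pair mark: late windows reject with +1
        C = 3
        mu = independent_mu(np.full(C, 0.15))
        drive = np.zeros(3000)
        drive[1000:] = 2.5
        cfg = SimulationConfig(C=C, T=3000, mu_true=mu, drive=drive,
                               drive_marks=np.array([3]), seed=11)
        sim = simulate(cfg)
        res = run_inference(sim.marked, r=None, tested_marks=np.array([3]),
                            W=10, beta=0.98, history=False)
        late = slice(250, 300)
        assert (res.J[late] > 0.5).mean() > 0.8
        assert res.h[late].max() == 1.0

    def test_tsv_output(self, tmp_path):
        sim = make_independent(1, T=1000, C=3, seed=5, rates=np.full(3, 0.25))[0]
        res = run_inference(sim.marked, r=2, W=10, beta=0.95, history=False)
        out = tmp_path / "trace.tsv"
        res.write_tsv(out)
        assert out.exists() and (tmp_path / "trace.tsv.json").exists()
        loaded = np.loadtxt(out, skiprows=1)
        assert loaded.shape == (res.n_windows, 6)


class TestBenjaminiHochberg:
    def test_step_up_rule(self):
        from hocoord.inference import benjamini_hochberg

        p = np.array([0.001, 0.008, 0.039, 0.041, 0.5])
        rej = benjamini_hochberg(p, alpha=0.05)
        # thresholds i/n * alpha = [.01, .02, .03, .04, .05]: largest passing
        # index is 4 (0.041 <= 0.04 fails, 0.039 <= 0.03 fails, 0.008 <= 0.02)
        assert rej.tolist() == [True, True, False, False, False]

    def test_no_rejections(self):
        from hocoord.inference import benjamini_hochberg

        assert not benjamini_hochberg(np.array([0.5, 0.9]), 0.01).any()

    def test_pvalues_accessor(self):
        from hocoord.simulator import make_independent

        sim = make_independent(1, T=800, C=3, seed=6, rates=np.full(3, 0.25))[0]
        res = run_inference(sim.marked, r=2, W=10, beta=0.95, history=False)
        p = res.pvalues()
        assert p.shape == (res.n_windows,)
        assert ((p >= 0) & (p <= 1)).all()


class TestFitReduced:
    def test_constrained_likelihood_never_exceeds_full(self):
        from hocoord.adomp import adomp_filter
        from hocoord.inference import fit_reduced
        from hocoord.markspace import reliable_marks
        from hocoord.simulator import make_independent

        sim = make_independent(1, T=1500, C=3, seed=8, rates=np.full(3, 0.2))[0]
        space = reliable_marks(sim.marked, 0)
        full = adomp_filter(sim.marked, W=10, beta=0.95, s=1, p=1,
                            raster=sim.raster, markspace=space,
                            keep_support=True)
        rows = np.array([0, 2])
        mu0 = full.coef[:, rows, 0] - 0.8  # active constraints
        red = fit_reduced(sim.marked, full, mu0, rows, raster=sim.raster,
                          markspace=space)
        assert (red.loglik <= full.loglik + 1e-9).all()
        # pinned base rates equal the constraint values exactly
        assert np.allclose(red.coef[:, rows, 0], np.clip(mu0, -20, 5))
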