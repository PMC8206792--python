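import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from mrexsurv import (
    CoxMixedFit,
    SurvivalTable,
    cox_partial_loglik,
    fit_cox,
    fit_cox_mixed,
    simulate_covariates,
    simulate_survival,
    wald_test,
)
from mrexsurv.pipeline import standardized_covariates
from conftest import correlated_block


class TestPartialLoglik:
    def test_null_loglik_hand_enumeration(self, three_subjects):
        surv, x = three_subjects
        # risk sets {1,2,3}, {2,3}, {3}: log(1/3) + log(1/2) + log(1)
        ll = cox_partial_loglik(np.zeros(1), x, surv)
        assert ll == pytest.approx(-np.log(6), abs=1e-12)

    def test_zero_covariate_constant_in_beta(self, three_subjects):
        surv, _ = three_subjects
        zeros = np.zeros((3, 1))
        lls = [cox_partial_loglik(np.array([b]), zeros, surv) for b in (-2.0, 0.0, 3.0)]
        assert max(lls) - min(lls) < 1e-12

    def test_no_events_error(self):
        surv = SurvivalTable(["a", "b"], [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            cox_partial_loglik(np.zeros(1), np.ones((2, 1)), surv)

    def test_efron_matches_lifelines_loglik(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        t = rng.integers(1, 15, n).astype(float)  # heavy ties
        e = rng.binomial(1, 0.7, n)
        e[:2] = 1
        surv = SurvivalTable([f"s{i}" for i in range(n)], t, e)
        df = pd.DataFrame(X, columns=["x1", "x2"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        beta = cph.params_.to_numpy()
        assert cox_partial_loglik(beta, X, surv) == pytest.approx(
            cph.log_likelihood_, rel=1e-9)


class TestFitCox:
    def test_closed_form_estimate(self, three_subjects):
        surv, x = three_subjects
        fit = fit_cox(surv, x)
        # score equation reduces to e^{2b} = 2
        assert fit.beta[0] == pytest.approx(np.log(2) / 2, abs=1e-6)
        assert fit.converged

    def test_monotone_likelihood_flagged(self):
        surv = SurvivalTable(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1])
        x = np.array([[1.0], [0.0], [0.0]])  # earliest event carries x = 1
        fit = fit_cox(surv, x)
        assert fit.monotone and not fit.converged

    def test_duplicated_subjects_same_estimate(self, three_subjects):
        surv, x = three_subjects
        dup = SurvivalTable([f"s{i}" for i in range(6)],
                            np.repeat(surv.time, 2), np.repeat(surv.event, 2))
        # Breslow: duplicated data shifts the loglik by a constant only
        a = fit_cox(surv, x, ties="breslow").beta[0]
        b = fit_cox(dup, np.repeat(x, 2, axis=0), ties="breslow").beta[0]
        assert b == pytest.approx(a, abs=1e-8)

    def test_matches_lifelines(self, rng):
        n = 150
        X = rng.standard_normal((n, 3))
        surv = simulate_survival(X, None, None, a=[0.4, -0.3, 0.2],
                                 baseline=("weibull", 1.5, 30.0),
                                 censor_target=0.3, rng=rng)
        Xs = standardized_covariates(surv)
        ours = fit_cox(surv, Xs)
        df = pd.DataFrame(Xs, columns=["x1", "x2", "x3"])
        df["T"], df["E"] = surv.time, surv.event
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(ours.beta, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.cov)),
                                   cph.standard_errors_.to_numpy(), atol=1e-5)


def _simulated_case(seed, n=100, p=5, b=0.4):
    rng = np.random.default_rng(seed)
    M = correlated_block(rng, n, p, 0.4)
    g = rng.standard_normal(n)
    X = simulate_covariates(n, rng)
    surv = simulate_survival(X, g, None, a=[0.3, 0.2, 0.1], b=b,
                             baseline=("exponential", 0.02),
                             censor_target=0.3, rng=rng)
    return standardized_covariates(surv), g, M, surv


class TestFitCoxMixed:
    def test_p_zero_reduces_to_plain_cox(self):
        for seed in (0, 1):
            Xs, g, _, surv = _simulated_case(seed)
            mixed = fit_cox_mixed(surv, Xs, g, None)
            plain = fit_cox(surv, np.column_stack([Xs, g]))
            assert mixed.b_hat == pytest.approx(plain.beta[-1], abs=1e-12)
            assert mixed.var_b == pytest.approx(plain.cov[-1, -1], abs=1e-12)
            assert mixed.sigma_c2 == 0.0

    def test_degenerate_prior_limit(self):
        Xs, g, M, surv = _simulated_case(3)
        tiny = fit_cox_mixed(surv, Xs, g, M, sigma_c2=1e-10)
        assert np.max(np.abs(tiny.c_hat)) < 1e-4
        plain = fit_cox(surv, np.column_stack([Xs, g]))
        assert tiny.b_hat == pytest.approx(plain.beta[-1], abs=1e-4)

    def test_marginal_loglik_finite_and_sigma_nonnegative(self):
        Xs, g, M, surv = _simulated_case(4)
        fit = fit_cox_mixed(surv, Xs, g, M)
        assert np.isfinite(fit.loglik_marginal)
        assert fit.sigma_c2 >= 0.0
        assert fit.var_b > 0.0
        assert fit.c_hat.shape == (M.shape[1],)

    def test_zero_boundary_sets_c_to_zero(self):
        # no pleiotropy simulated: the variance estimate should hit 0 often
        Xs, g, M, surv = _simulated_case(5)
        fit = fit_cox_mixed(surv, Xs, g, M)
        if fit.sigma_c2 == 0.0:
            np.testing.assert_array_equal(fit.c_hat, 0.0)

    def test_baseline_hazard_monotone(self):
        Xs, g, _, surv = _simulated_case(6)
        fit = fit_cox_mixed(surv, Xs, g, None, with_baseline=True)
        h0 = fit.baseline
        assert (np.diff(h0[:, 1]) > 0).all()
        assert (np.diff(h0[:, 0]) > 0).all()


class TestWald:
    def _fit(self, b, var):
        return CoxMixedFit(np.empty(0), b, np.empty(0), 0.0, var, 0.0, True, 10)

    def test_zero_effect(self):
        res = wald_test(self._fit(0.0, 1.0))
        assert res.z == 0.0 and res.p_value == pytest.approx(1.0)

    def test_critical_value(self):
        res = wald_test(self._fit(1.959964, 1.0))
        assert res.p_value == pytest.approx(0.05, abs=1e-6)

    def test_sign_invariance(self):
        assert wald_test(self._fit(0.7, 0.2)).p_value == \
            wald_test(self._fit(-0.7, 0.2)).p_value

    def test_degenerate_variance_error(self):
        with pytest.raises(ValueError):
            wald_test(self._fit(1.0, 0.0))
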