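"""NB-GLM engine: closed forms, oracle equivalence, inference, L1 path.

The brute-force oracle here writes its own NB2 log-likelihood and gradient
and maximises them with scipy's generic BFGS optimizer -- a route fully
independent of the package's IRLS/profile-theta implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from mirmod import nb_glm
from mirmod.errors import FitError, ValidationError

from conftest import nb_sample


def oracle_negloglik(params, y, A):
    """Joint NB2 negative log-likelihood over (beta, log theta), log link."""
    beta, theta = params[:-1], np.exp(params[-1])
    mu = np.exp(A @ beta)
    ll = np.sum(
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta)
        + y * np.log(mu)
        - (y + theta) * np.log(theta + mu)
    )
    return -ll


def oracle_grad(params, y, A):
    beta, theta = params[:-1], np.exp(params[-1])
    mu = np.exp(A @ beta)
    dbeta = A.T @ (y - (y + theta) * mu / (theta + mu))
    dtheta = np.sum(
        special.digamma(y + theta)
        - special.digamma(theta)
        + np.log(theta)
        + 1
        - np.log(theta + mu)
        - (y + theta) / (theta + mu)
    )
    return -np.concatenate([dbeta, [theta * dtheta]])


def brute_force_fit(y, A):
    """Independent joint maximiser; returns (beta, theta)."""
    start = np.zeros(A.shape[1] + 1)
    start[0] = np.log(np.mean(y) + 0.5)
    res = optimize.minimize(
        oracle_negloglik, start, args=(y, A), jac=oracle_grad,
        method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
    )
    res = optimize.minimize(
        oracle_negloglik, res.x, args=(y, A), jac=oracle_grad,
        method="BFGS", options={"gtol": 1e-12, "maxiter": 500},
    )
    return res.x[:-1], np.exp(res.x[-1])


def simulate(seed, n=500, theta=2.0, beta=(3.0, 0.3, -0.2)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        }
    )
    mu = np.exp(X.to_numpy() @ np.asarray(beta))
    y = nb_sample(rng, mu, theta)
    return y, X


class TestFitNB:
    def test_constant_outcome_intercept_only(self):
        y = np.full(50, 7)
        X = pd.DataFrame({"intercept": np.ones(50)})
        fit = nb_glm.fit_nb(y, X)
        assert fit.params["intercept"] == pytest.approx(np.log(7), abs=1e-8)
        assert fit.theta_capped  # variance <= mean: Poisson limit

    def test_oracle_equivalence(self):
        y, X = simulate(11)
        fit = nb_glm.fit_nb(y, X)
        beta_o, theta_o = brute_force_fit(y.astype(float), X.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta_o, rtol=1e-5)
        assert fit.theta == pytest.approx(theta_o, rel=1e-4)

    def test_parameter_recovery_within_2se(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        truth = np.array([3.0, 0.2])
        y = nb_sample(rng, np.exp(X.to_numpy() @ truth), 2.0)
        fit = nb_glm.fit_nb(y, X)
        assert np.all(np.abs(fit.params.to_numpy() - truth) < 2 * fit.se.to_numpy())

    def test_local_optimum_probe(self):
        y, X = simulate(5, n=300)
        fit = nb_glm.fit_nb(y, X)
        A = X.to_numpy()
        ll_hat = nb_glm.nb_loglik(y, np.exp(A @ fit.params.to_numpy()), fit.theta)
        for j in range(A.shape[1]):
            for sign in (-1, 1):
                beta = fit.params.to_numpy().copy()
                beta[j] += sign * 0.01
                assert nb_glm.nb_loglik(y, np.exp(A @ beta), fit.theta) <= ll_hat + 1e-9

    def test_poisson_limit_matches_poisson_glm(self):
        rng = np.random.default_rng(8)
        n = 1500
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        y = rng.poisson(np.exp(2.0 + 0.3 * X["x"].to_numpy()))
        fit = nb_glm.fit_nb(y, X)
        # equidispersed data drives theta far above the mean scale ...
        assert fit.theta > 100
        import statsmodels.api as sm

        # ... and the coefficients collapse onto the Poisson-GLM solution
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), pois.params, atol=1e-4)

    def test_statsmodels_cross_check(self):
        import statsmodels.discrete.discrete_model as dm

        y, X = simulate(3)
        fit = nb_glm.fit_nb(y, X)
        ref = dm.NegativeBinomial(y, X.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params[:-1], rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_rank_deficient_names_columns(self):
        y, X = simulate(1, n=100)
        X = X.assign(dup=X["x1"] * 2.0)
        with pytest.raises(ValidationError, match="dup|x1"):
            nb_glm.fit_nb(y, X)

    def test_loglik_nested_poisson_bound(self):
        # NB loglik at the ML theta is >= the Poisson limit on the same data
        y, X = simulate(17, theta=1.0)
        fit = nb_glm.fit_nb(y, X)
        mu = np.exp(X.to_numpy() @ fit.params.to_numpy())
        assert fit.loglik >= nb_glm.nb_loglik(y, mu, nb_glm.THETA_CAP) - 1e-6

    def test_identity_link_nonpositive_mean_error(self):
        # the ML line crosses zero inside the covariate range
        rng = np.random.default_rng(2)
        n = 200
        x = rng.uniform(0, 2, size=n)
        y = nb_sample(rng, np.maximum(10 - 5 * x, 0.05), 5.0)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        with pytest.raises(FitError, match="log link"):
            nb_glm.fit_nb(y, X, link="identity")

    def test_identity_link_recovers_additive_mean(self):
        rng = np.random.default_rng(2)
        n = 1200
        x = rng.uniform(0, 1, size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        y = nb_sample(rng, 20.0 + 10.0 * x, 5.0)
        fit = nb_glm.fit_nb(y, X, link="identity")
        assert fit.params["intercept"] == pytest.approx(20.0, abs=1.5)
        assert fit.params["x"] == pytest.approx(10.0, abs=3.0)


class TestWald:
    def test_closed_forms(self):
        idx = ["intercept", "t"]
        fit = nb_glm.NBFitResult(
            params=pd.Series([0.0, 0.4], index=idx),
            cov=pd.DataFrame(np.diag([1.0, 0.04]), index=idx, columns=idx),
            theta=1.0, loglik=0.0, converged=True, iterations=1, n_used=10, link="log",
        )
        z, p = nb_glm.wald_test(fit, "t")
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.04550026, abs=1e-6)
        fit.params["t"] = 0.0
        assert nb_glm.wald_test(fit, "t") == (0.0, 1.0)
        fit.params["t"] = -0.4
        assert nb_glm.wald_test(fit, "t")[1] == pytest.approx(0.04550026, abs=1e-6)

    def test_missing_term_rejected(self):
        y, X = simulate(1, n=100)
        fit = nb_glm.fit_nb(y, X)
        with pytest.raises(ValidationError):
            nb_glm.wald_test(fit, "nope")


class TestGroupTest:
    def test_identical_models_give_null_stat(self):
        y, X = simulate(4, n=300)
        full = nb_glm.fit_nb(y, X)
        reduced = nb_glm.fit_nb(y, X[["intercept", "x1"]])
        stat, df, p = nb_glm.group_test(full, reduced)
        assert df == 1 and stat >= 0
        # identical predictor sets are rejected as non-nested
        with pytest.raises(ValidationError):
            nb_glm.group_test(full, full)

    def test_lrt_matches_squared_wald_asymptotically(self):
        rng = np.random.default_rng(9)
        n = 5000
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        y = nb_sample(rng, np.exp(3.0 + 0.0 * X["x"].to_numpy()), 2.0)
        full = nb_glm.fit_nb(y, X)
        reduced = nb_glm.fit_nb(y, X[["intercept"]])
        stat, _, _ = nb_glm.group_test(full, reduced)
        z, _ = nb_glm.wald_test(full, "x")
        assert stat == pytest.approx(z**2, abs=0.05 + 0.02 * z**2)

    def test_power_against_planted_effect(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
            y = nb_sample(rng, np.exp(3.0 + 0.5 * X["x"].to_numpy()), 2.0)
            full = nb_glm.fit_nb(y, X)
            reduced = nb_glm.fit_nb(y, X[["intercept"]])
            _, _, p = nb_glm.group_test(full, reduced)
            hits += p < 0.01
        assert hits >= 38  # >= 95% power


class TestL1:
    def test_zero_lambda_matches_unpenalised(self):
        y, X = simulate(6, n=400)
        free = nb_glm.fit_nb(y, X)
        pen = nb_glm.fit_nb_l1(y, X, lam=0.0)
        np.testing.assert_allclose(
            pen.params.to_numpy(), free.params.to_numpy(), atol=1e-4
        )
        assert pen.cov is None
        with pytest.raises(ValidationError):
            _ = pen.se

    def test_full_shrinkage_limit(self):
        y, X = simulate(7, n=400)
        pen = nb_glm.fit_nb_l1(y, X, lam=1e7)
        assert pen.params["x1"] == pytest.approx(0.0, abs=1e-8)
        assert pen.params["x2"] == pytest.approx(0.0, abs=1e-8)
        assert pen.params["intercept"] == pytest.approx(np.log(np.mean(y)), abs=1e-4)

    def test_null_coefficients_zero_first_along_path(self):
        rng = np.random.default_rng(13)
        n = 500
        cols = {"intercept": np.ones(n)}
        for j in range(10):
            cols[f"x{j}"] = rng.normal(size=n)
        X = pd.DataFrame(cols)
        beta = np.zeros(11)
        beta[0] = 3.0
        beta[1], beta[2] = 0.5, -0.5  # x0, x1 are the true predictors
        y = nb_sample(rng, np.exp(X.to_numpy() @ beta), 2.0)
        first_null_death = None
        true_alive_at_death = None
        for lam in [0.5, 2, 8, 32, 128, 512]:
            pen = nb_glm.fit_nb_l1(y, X, lam=lam)
            nulls = pen.params[[f"x{j}" for j in range(2, 10)]].abs()
            trues = pen.params[["x0", "x1"]].abs()
            if first_null_death is None and (nulls < 1e-8).all():
                first_null_death = lam
                true_alive_at_death = (trues > 1e-3).all()
        assert first_null_death is not None
        assert true_alive_at_death
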