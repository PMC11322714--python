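"""IRLS Poisson core: closed forms, independent Newton oracle, sandwich
variance identities, and the day-aggregation equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walletrdd import glm
from walletrdd.glm import DesignMatrix, fit_poisson, sandwich_cov, wald


def _design(X, names):
    return DesignMatrix(np.asarray(X, dtype=float), tuple(names))


def newton_poisson(X, y, offset=None, tol=1e-12, max_iter=200):
    """Independent Newton-Raphson oracle on the raw score/Hessian."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() / np.exp(off).mean())
    for _ in range(max_iter):
        mu = np.exp(X @ beta + off)
        score = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestFitPoisson:
    def test_intercept_only_closed_form(self, rng):
        y = (rng.random(400) < 0.25).astype(float)
        d = _design(np.ones((400, 1)), ["intercept"])
        fit = fit_poisson(d, y)
        assert fit.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-10)

    def test_two_group_closed_form(self):
        # rates 10/1000 vs 5/1000: group coefficient is exactly ln 2
        y = np.r_[np.repeat([1.0, 0.0], [10, 990]), np.repeat([1.0, 0.0], [5, 995])]
        g = np.r_[np.ones(1000), np.zeros(1000)]
        d = _design(np.column_stack([np.ones(2000), g]), ["intercept", "group"])
        fit = fit_poisson(d, y)
        assert fit.beta[1] == pytest.approx(np.log(2.0), abs=1e-9)
        assert fit.beta[0] == pytest.approx(np.log(0.005), abs=1e-9)

    def test_matches_newton_oracle(self, rng):
        X = np.column_stack([np.ones(200), rng.normal(size=200), rng.normal(size=200)])
        eta = -2.0 + 0.3 * X[:, 1] - 0.2 * X[:, 2]
        y = rng.poisson(np.exp(eta)).astype(float)
        d = _design(X, ["intercept", "x1", "x2"])
        fit = fit_poisson(d, y)
        beta_oracle = newton_poisson(X, y)
        assert np.max(np.abs(fit.beta - beta_oracle)) < 1e-8

    def test_score_equations_hold_at_convergence(self, small_sim):
        _, panels, _ = small_sim
        p = panels["saving"]
        counts = p.daily_counts().astype(float)
        t = np.arange(p.study_days, dtype=float) - p.cutoff_day
        lock = (np.arange(p.study_days) >= p.cutoff_day).astype(float)
        d = _design(
            np.column_stack([np.ones(p.study_days), t, lock, t * lock]),
            ["intercept", "time_c", "lockdown", "time_c:lockdown"],
        )
        fit = fit_poisson(d, counts, offset=np.full(p.study_days, np.log(p.n_users)))
        score = d.X.T @ (counts - fit.mu)
        scale = np.abs(d.X.T @ counts) + 1.0
        assert np.max(np.abs(score) / scale) < 1e-8

    def test_aggregation_equivalence(self, rng):
        """Person-day binaries and day counts with log-exposure offset give
        identical coefficients: the Poisson likelihood factorizes over
        day-level covariates."""
        n_users, days = 300, 60
        t = np.arange(days, dtype=float)
        p = 0.01 * np.exp(0.01 * t)
        y = (rng.random((n_users, days)) < p).astype(float)
        Xd = np.column_stack([np.ones(days), t])
        d_day = _design(Xd, ["intercept", "t"])
        fit_day = fit_poisson(d_day, y.sum(axis=0), offset=np.full(days, np.log(n_users)))
        d_pd = _design(np.repeat(Xd, n_users, axis=0), ["intercept", "t"])
        fit_pd = fit_poisson(d_pd, y.T.ravel())
        assert np.max(np.abs(fit_day.beta - fit_pd.beta)) < 1e-8

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            _design(X, ["intercept", "a", "b"])

    def test_no_events_rejected(self):
        d = _design(np.ones((20, 1)), ["intercept"])
        with pytest.raises(ValueError, match="no events"):
            fit_poisson(d, np.zeros(20))

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = np.column_stack([np.ones(500), rng.normal(size=500)])
        y = rng.poisson(np.exp(-1.5 + 0.4 * X[:, 1])).astype(float)
        fit = fit_poisson(_design(X, ["intercept", "x"]), y)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        assert np.max(np.abs(fit.beta - ref.params)) < 1e-8
        assert np.max(np.abs(fit.se() - ref.bse)) < 1e-8


class TestSandwich:
    def test_intercept_only_closed_form(self, rng):
        # robust var of b0 at the MLE is (1 - ybar) / (n * ybar)
        n = 1000
        y = np.zeros(n)
        y[:10] = 1.0  # ybar = 0.01
        fit = fit_poisson(_design(np.ones((n, 1)), ["intercept"]), y)
        var = fit.cov_robust[0, 0]
        assert var == pytest.approx(0.99 / (n * 0.01), rel=1e-10)
        assert np.sqrt(var) == pytest.approx(0.31464, abs=5e-6)

    def test_zero_residuals_give_zero_meat(self):
        # y exactly equal to mu: fit constant data with intercept only
        y = np.full(50, 3.0)
        fit = fit_poisson(_design(np.ones((50, 1)), ["intercept"]), y)
        assert fit.cov_robust[0, 0] == pytest.approx(0.0, abs=1e-14)

    def test_robust_cov_psd_and_hc1_inflation(self, rng):
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = rng.poisson(np.exp(-1.0 + 0.2 * X[:, 1])).astype(float)
        d = _design(X, ["intercept", "x"])
        fit = fit_poisson(d, y)
        eigs = np.linalg.eigvalsh(fit.cov_robust)
        assert np.all(eigs >= -1e-14)
        hc1 = sandwich_cov(fit, d, y, flavor="HC1")
        assert np.allclose(hc1, fit.cov_robust * 200 / 198)

    def test_robust_se_tracks_empirical_sd(self):
        """Mean sandwich SE matches the Monte Carlo SD of the slope within 10%."""
        rng = np.random.default_rng(777)
        days = 120
        t = (np.arange(days) - 60) / 30.0
        X = np.column_stack([np.ones(days), t])
        d = _design(X, ["intercept", "t"])
        p = 0.02 * np.exp(0.3 * t)
        n_users = 400
        slopes, ses = [], []
        for _ in range(400):
            counts = rng.binomial(n_users, p).astype(float)
            if counts.sum() == 0:
                continue
            fit = fit_poisson(d, counts, offset=np.full(days, np.log(n_users)))
            # person-day robust variance from day-level binary identity
            pr = fit.mu / n_users
            w = counts * (1 - 2 * pr) + n_users * pr**2
            bread = X.T @ (X * fit.mu[:, None])
            meat = X.T @ (X * w[:, None])
            bi = np.linalg.inv(bread)
            cov = bi @ meat @ bi
            slopes.append(fit.beta[1])
            ses.append(np.sqrt(cov[1, 1]))
        ratio = np.mean(ses) / np.std(slopes, ddof=1)
        assert 0.9 < ratio < 1.1

    def test_cluster_cov_exceeds_hc0_under_correlation(self, rng):
        # shared user frailty induces within-user correlation
        n_users, days = 150, 40
        frail = rng.lognormal(0, 0.8, size=n_users)
        p = np.clip(0.03 * frail, 0, 0.5)
        y = (rng.random((n_users, days)) < p[:, None]).astype(float)
        X = np.ones((n_users * days, 1))
        d = _design(X, ["intercept"])
        fit = fit_poisson(d, y.ravel(), clusters=np.repeat(np.arange(n_users), days))
        assert fit.cov_cluster[0, 0] > fit.cov_robust[0, 0]


class TestWald:
    def test_null_estimate_gives_p_one(self, rng):
        y = (rng.random(500) < 0.2).astype(float)
        fit = fit_poisson(_design(np.ones((500, 1)), ["intercept"]), y)
        w = wald(fit, "intercept", null_value=fit.beta[0])
        assert w.p == pytest.approx(1.0)
        assert w.z == pytest.approx(0.0)

    def test_two_sided_p_from_normal_quantile(self):
        from scipy import stats

        # estimate = 1.2816 SE -> one-sided tail 0.10, two-sided p ~ 0.20
        z = 1.2815515655446004
        assert 2 * stats.norm.sf(z) == pytest.approx(0.20, abs=1e-10)

    def test_ci_geometric_symmetry_on_irr_scale(self):
        """The published jump CI must be geometrically symmetric about the
        IRR: sqrt(lo * hi) ~ point, since CI = exp(est +/- 1.96 SE)."""
        irr, lo, hi = 0.4152, 0.3589, 0.4802
        assert np.sqrt(lo * hi) == pytest.approx(irr, abs=2e-3)

    def test_unknown_coefficient_rejected(self, rng):
        y = (rng.random(100) < 0.3).astype(float)
        fit = fit_poisson(_design(np.ones((100, 1)), ["intercept"]), y)
        with pytest.raises(KeyError):
            wald(fit, "slope")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(shift=st.floats(min_value=-50, max_value=50))
def test_recentering_invariance(shift):
    """Shifting the time regressor moves only the intercept, by exactly
    -slope * shift; the slope estimate is unchanged to 1e-8."""
    rng = np.random.default_rng(99)
    t = np.arange(80, dtype=float)
    y = rng.poisson(np.exp(-2.0 + 0.02 * t)).astype(float)
    if y.sum() == 0:
        return
    d0 = _design(np.column_stack([np.ones(80), t]), ["intercept", "t"])
    d1 = _design(np.column_stack([np.ones(80), t - shift]), ["intercept", "t"])
    f0 = fit_poisson(d0, y)
    f1 = fit_poisson(d1, y)
    assert f1.beta[1] == pytest.approx(f0.beta[1], abs=1e-8)
    assert f1.beta[0] == pytest.approx(f0.beta[0] + f0.beta[1] * shift, abs=1e-7)
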