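"""The three likelihoods, cluster sandwich, and GxE contrasts/profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from statsmodels.tools import numdiff

from prefgxe.regression import (
    GxeSpec,
    SeparationError,
    build_gxe_design,
    cluster_vcov,
    fit_gxe,
    fit_interval,
    fit_logit,
    fit_ologit,
    implied_effect,
    ologit_probs,
    predict_profile,
    prop_odds_test,
)


def _interval_data(rng, n=2000, beta=(1.0, -0.5, 0.8), sigma=1.2, grid=0.75):
    X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.binomial(1, 0.5, n)])
    y = X @ np.asarray(beta) + rng.normal(0, sigma, n)
    lower = np.floor(y / grid) * grid
    upper = lower + grid
    return X, y, lower, upper


# ------------------------------------------------------------------ interval

def test_interval_point_rows_reduce_to_ols():
    rng = np.random.default_rng(10)
    X, y, *_ = _interval_data(rng, n=400)
    fit = fit_interval(y, y, X)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.params[:3], beta_ols, rtol=1e-6)
    rss = np.sum((y - X @ beta_ols) ** 2)
    assert fit.sigma[0] ** 2 == pytest.approx(rss / len(y), rel=1e-5)
    # exact normal-regression log-likelihood at the MLE
    llf_ols = -0.5 * len(y) * (np.log(2 * np.pi * rss / len(y)) + 1)
    assert fit.llf == pytest.approx(llf_ols, rel=1e-10)


def test_interval_recovers_simulated_parameters():
    rng = np.random.default_rng(11)
    beta, sigma = (1.0, -0.5, 0.8), 1.2
    X, y, lower, upper = _interval_data(rng, n=2000, beta=beta, sigma=sigma)
    fit = fit_interval(lower, upper, X)
    for j, b in enumerate(beta):
        assert abs(fit.params[j] - b) < 3 * fit.se[j]
    assert abs(fit.sigma[0] - sigma) < 3 * sigma / np.sqrt(len(y))


def test_interval_likelihood_matches_quadrature_row_by_row():
    from scipy.integrate import quad

    rng = np.random.default_rng(12)
    X, y, lower, upper = _interval_data(rng, n=30)
    fit = fit_interval(lower, upper, X)
    beta, sig = fit.params[:3], fit.sigma[0]
    mu = X @ beta
    for i in range(len(y)):
        direct, _ = quad(lambda v: stats.norm.pdf(v, mu[i], sig), lower[i], upper[i])
        via_cdf = stats.norm.cdf(upper[i], mu[i], sig) - stats.norm.cdf(lower[i], mu[i], sig)
        assert direct == pytest.approx(via_cdf, abs=1e-10)
    # total log-likelihood equals the sum of quadrature row masses
    total = sum(
        np.log(quad(lambda v: stats.norm.pdf(v, mu[i], sig), lower[i], upper[i])[0])
        for i in range(len(y))
    )
    assert fit.llf == pytest.approx(total, abs=1e-6)


def test_interval_handles_half_infinite_rows():
    rng = np.random.default_rng(13)
    X, y, lower, upper = _interval_data(rng, n=1500)
    hi = y > np.quantile(y, 0.9)
    lo = y < np.quantile(y, 0.1)
    lower2, upper2 = lower.copy(), upper.copy()
    upper2[hi] = np.inf  # right-censored tail
    lower2[lo] = -np.inf
    fit = fit_interval(lower2, upper2, X)
    assert abs(fit.params[1] - (-0.5)) < 4 * fit.se[1]
    with pytest.raises(ValueError, match="finite"):
        fit_interval(np.full(5, -np.inf), np.full(5, np.inf), np.ones((5, 1)))
    with pytest.raises(ValueError, match="exceed"):
        fit_interval(np.ones(3), np.zeros(3), np.ones((3, 1)))


def test_gradient_vanishes_at_optimum_all_families(golden_fixture):
    d = golden_fixture
    X = d[["group", "pgs", "pgs_group", "female", "female_group"]]
    Xc = X.copy()
    Xc.insert(0, "const", 1.0)
    fits = [
        fit_interval(d.crra_lower, d.crra_upper, Xc),
        fit_logit(d.la_binary, Xc),
        fit_ologit(d.risk_la, X),
    ]
    for fit in fits:
        assert fit.grad_norm < 1e-5


# ------------------------------------------------------------------ logit

def test_logit_intercept_only_is_sample_logit():
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    fit = fit_logit(y, np.ones((10, 1)))
    assert fit.params[0] == pytest.approx(special.logit(0.3), abs=1e-8)


def test_logit_symmetric_data_zero_slope():
    # outcome pattern invariant under x -> -x forces a zero slope
    x = np.array([-2.0, -1.0, 1.0, 2.0])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    X = np.column_stack([np.ones(4), x])
    fit = fit_logit(y, X)
    assert fit.params[1] == pytest.approx(0.0, abs=1e-8)


def test_logit_recovery_and_separation():
    rng = np.random.default_rng(14)
    n = 4000
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    beta = np.array([0.4, -0.9])
    y = (rng.random(n) < special.expit(X @ beta)).astype(float)
    fit = fit_logit(y, X)
    for j in range(2):
        assert abs(fit.params[j] - beta[j]) < 3 * fit.se[j]
    x = np.linspace(-1, 1, 40)
    y_sep = (x > 0).astype(float)
    with pytest.raises(SeparationError):
        fit_logit(y_sep, np.column_stack([np.ones(40), x]))


# ------------------------------------------------------------------ ologit

def test_two_category_ordered_equals_binary_logit():
    rng = np.random.default_rng(15)
    n = 500
    x = rng.standard_normal((n, 2))
    y = (rng.random(n) < special.expit(0.5 * x[:, 0] - 0.7 * x[:, 1])).astype(int)
    fo = fit_ologit(y, x)
    fl = fit_logit(y, np.column_stack([np.ones(n), x]))
    np.testing.assert_allclose(fo.params[:2], fl.params[1:], atol=1e-7)
    np.testing.assert_allclose(fo.thresholds, [-fl.params[0]], atol=1e-7)
    np.testing.assert_allclose(fo.llf, fl.llf, atol=1e-8)


def test_ologit_recovery_six_levels():
    rng = np.random.default_rng(16)
    n = 4000
    x = rng.standard_normal((n, 2))
    beta = np.array([0.8, -0.5])
    cuts = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    lat = x @ beta + rng.logistic(size=n)
    y = np.digitize(lat, cuts)
    fit = fit_ologit(y, x)
    for j in range(2):
        assert abs(fit.params[j] - beta[j]) < 3 * fit.se[j]
    np.testing.assert_allclose(fit.thresholds, cuts, atol=0.2)
    probs = ologit_probs(fit, x[:5])
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(probs >= 0)


def test_ologit_rejects_constant_column():
    with pytest.raises(ValueError, match="constant"):
        fit_ologit(np.array([0, 1, 2, 1]), np.ones((4, 1)))


# ---------------------------------------------------------- proportional odds

def test_prop_odds_two_levels_undefined():
    rng = np.random.default_rng(17)
    x = rng.standard_normal((100, 1))
    y = (x[:, 0] + rng.logistic(size=100) > 0).astype(int)
    res = prop_odds_test(y, x)
    assert res["df"] == 0 and res["stat"] is None


def test_prop_odds_detects_slope_heterogeneity():
    rng = np.random.default_rng(18)
    n = 3000
    x = rng.standard_normal(n)
    # category-specific slopes: the low split responds to x, the high one inversely
    y = np.zeros(n, dtype=int)
    u1 = special.expit(1.0 + 1.5 * x) > rng.random(n)  # P(y >= 1)
    u2 = special.expit(-1.0 - 1.5 * x) > rng.random(n)  # P(y >= 2), opposite sign
    y = u1.astype(int) + (u1 & u2).astype(int)
    res = prop_odds_test(y, x[:, None])
    assert res["p"] is not None and res["p"] < 1e-4


def test_prop_odds_size_under_null():
    rng = np.random.default_rng(19)
    reps, n = 300, 400
    rejections = 0
    skipped = 0
    for _ in range(reps):
        x = rng.standard_normal((n, 2))
        lat = 0.6 * x[:, 0] - 0.4 * x[:, 1] + rng.logistic(size=n)
        y = np.digitize(lat, [-1.0, 0.0, 1.0])
        res = prop_odds_test(y, x)
        if res["p"] is None:
            skipped += 1
        elif res["p"] < 0.05:
            rejections += 1
    rate = rejections / (reps - skipped)
    # approximate test: size should sit near the nominal 5%
    assert 0.01 <= rate <= 0.11


# ---------------------------------------------------------------- clustering

def test_singleton_clusters_reduce_to_hc_sandwich():
    rng = np.random.default_rng(20)
    n = 300
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = (rng.random(n) < special.expit(X @ np.array([0.2, 0.5]))).astype(float)
    fit = fit_logit(y, X)
    cv = cluster_vcov(fit, np.arange(n))
    s = fit.scores
    hc0 = fit.cov @ (s.T @ s) @ fit.cov
    np.testing.assert_allclose(cv, hc0 * n / (n - 1), rtol=1e-10)
    with pytest.raises(ValueError, match="two clusters"):
        cluster_vcov(fit, np.zeros(n))


def test_duplicated_rows_in_shared_clusters_do_not_shrink_se():
    rng = np.random.default_rng(21)
    n = 250
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = (rng.random(n) < special.expit(X @ np.array([0.1, 0.7]))).astype(float)
    base = fit_logit(y, X)
    se_base = np.sqrt(np.diag(cluster_vcov(base, np.arange(n))))
    X2 = np.vstack([X, X])
    y2 = np.concatenate([y, y])
    dup = fit_logit(y2, X2)
    se_dup = np.sqrt(np.diag(cluster_vcov(dup, np.concatenate([np.arange(n)] * 2))))
    np.testing.assert_allclose(se_dup, se_base, rtol=0.01)
    # while the naive (model-based) SE wrongly shrinks by sqrt(2)
    assert np.all(dup.se[:2] < 0.8 * base.se[:2])


def test_cluster_ci_coverage_with_person_wave_correlation():
    rng = np.random.default_rng(22)
    reps, persons = 150, 250
    beta1 = 0.5
    target = _marginal_slope(beta1)
    hits_cluster = 0
    for _ in range(reps):
        x_p = rng.standard_normal(persons)
        eff = rng.normal(0, 1.0, persons)  # person random intercept
        idx = np.repeat(np.arange(persons), 2)  # two waves each
        eta = 0.2 + beta1 * x_p[idx] + eff[idx]
        y = (rng.random(len(idx)) < special.expit(eta)).astype(float)
        X = np.column_stack([np.ones(len(idx)), x_p[idx]])
        fit = fit_logit(y, X)
        se_c = np.sqrt(cluster_vcov(fit, idx)[1, 1])
        # the marginal (population-averaged) slope is attenuated relative to
        # the conditional one; compare against its large-sample value
        hits_cluster += abs(fit.params[1] - target) < 1.96 * se_c
    assert hits_cluster / reps > 0.90


def _marginal_slope(beta1, intercept=0.2, sd=1.0):
    """Large-sample population-averaged logit slope under a normal random intercept."""
    rng = np.random.default_rng(99)
    x = rng.standard_normal(400_000)
    e = rng.normal(0, sd, 400_000)
    p = special.expit(intercept + beta1 * x + e)
    y = (rng.random(400_000) < p).astype(float)
    return fit_logit(y, np.column_stack([np.ones_like(x), x])).params[1]


# ------------------------------------------------------------------ GxE layer

def _gxe_frame(rng, n=800):
    df = pd.DataFrame(
        {
            "pgs": rng.standard_normal(n),
            "disadvantage": rng.binomial(1, 0.35, n),
            "age_c": rng.uniform(-1, 1, n),
            "female": rng.binomial(1, 0.5, n),
        }
    )
    eta = 0.5 - 0.4 * df.pgs + 0.8 * df.pgs * df.disadvantage - 0.2 * df.disadvantage
    y = eta + 0.1 * df.age_c + rng.normal(0, 1.0, n)
    df["lower"], df["upper"] = np.floor(y * 2) / 2, np.floor(y * 2) / 2 + 0.5
    df["binary"] = (y > y.median()).astype(int)
    return df


def test_design_columns_and_order():
    rng = np.random.default_rng(23)
    df = _gxe_frame(rng, n=50)
    spec = GxeSpec(outcome="binary", family="logit", covariates=("age_c", "female"))
    X = build_gxe_design(df, spec)
    assert list(X.columns) == [
        "const", "disadvantage", "pgs", "pgs:disadvantage",
        "age_c", "age_c:disadvantage", "female", "female:disadvantage",
    ]
    assert X.shape[1] == 8
    sub = X[df.disadvantage == 0]
    assert (sub["pgs:disadvantage"] == 0).all()
    df2 = df.assign(disadvantage=0)
    with pytest.raises(ValueError, match="constant"):
        build_gxe_design(df2, spec)
    df3 = df.copy()
    df3.loc[0, "age_c"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        build_gxe_design(df3, spec)


def test_full_interaction_fit_equals_groupwise_fits():
    rng = np.random.default_rng(24)
    df = _gxe_frame(rng)
    spec = GxeSpec(outcome=("lower", "upper"), family="interval", covariates=("age_c",))
    res = fit_gxe(df, spec)  # group-specific sigma by default
    llf_groups = 0.0
    for g in (0, 1):
        sub = df[df.disadvantage == g]
        Xg = pd.DataFrame({"const": 1.0, "pgs": sub.pgs, "age_c": sub.age_c})
        fg = fit_interval(sub.lower, sub.upper, Xg)
        llf_groups += fg.llf
        # group-g parameters from the interacted fit
        if g == 0:
            np.testing.assert_allclose(res.fit["pgs"], fg["pgs"], atol=1e-5)
        else:
            np.testing.assert_allclose(
                res.fit["pgs"] + res.fit["pgs:disadvantage"], fg["pgs"], atol=1e-5
            )
    assert res.fit.llf == pytest.approx(llf_groups, abs=1e-6)
    # with a shared sigma the equivalence is broken by construction
    res_shared = fit_gxe(df, GxeSpec(outcome=("lower", "upper"), family="interval",
                                     covariates=("age_c",), shared_sigma=True))
    assert res_shared.fit.llf < llf_groups


def test_implied_effect_identity_and_reparameterization():
    rng = np.random.default_rng(25)
    df = _gxe_frame(rng)
    spec = GxeSpec(outcome="binary", family="logit", covariates=("age_c",))
    res = fit_gxe(df, spec)
    eff = res.implied_effect()
    assert eff.estimate == pytest.approx(
        res.fit["pgs"] + res.fit["pgs:disadvantage"], abs=1e-12
    )
    # oracle: recode the moderator baseline; the main effect of the recoded
    # fit IS the implied effect, with the same SE
    df2 = df.assign(disadvantage=1 - df.disadvantage)
    res2 = fit_gxe(df2, spec)
    eff2 = res2.main_effect()
    assert eff.estimate == pytest.approx(eff2.estimate, abs=1e-6)
    assert eff.se == pytest.approx(eff2.se, abs=1e-6)
    assert eff.odds_ratio == pytest.approx(np.exp(eff.estimate))


def test_implied_effect_is_exact_coefficient_sum():
    rng = np.random.default_rng(28)
    n = 60
    X = pd.DataFrame(
        {"const": 1.0, "a": rng.binomial(1, 0.5, n), "b": rng.standard_normal(n)}
    )
    y = rng.binomial(1, 0.5, n).astype(float)
    fit = fit_logit(y, X)
    eff = implied_effect(fit, "a", "b")
    assert eff.estimate == pytest.approx(fit["a"] + fit["b"])
    with pytest.raises(KeyError):
        implied_effect(fit, "a", "nope")


def test_predict_profile_interval_is_linear_arithmetic():
    rng = np.random.default_rng(26)
    df = _gxe_frame(rng)
    spec = GxeSpec(outcome=("lower", "upper"), family="interval", covariates=("age_c",))
    res = fit_gxe(df, spec)
    prof = predict_profile(res, pgs_grid=np.array([-2.0, 0.0, 2.0]))
    f = res.fit
    for _, row in prof.iterrows():
        expected = (
            f["const"]
            + f["disadvantage"] * row.group
            + f["pgs"] * row.pgs
            + f["pgs:disadvantage"] * row.pgs * row.group
            + f["age_c"] * res.design_means["age_c"]
            + f["age_c:disadvantage"] * res.design_means["age_c"] * row.group
        )
        assert row.prediction == pytest.approx(expected, abs=1e-10)
    # opposing slopes: group profiles must cross
    g0 = prof[prof.group == 0].prediction.to_numpy()
    g1 = prof[prof.group == 1].prediction.to_numpy()
    assert (g0[0] - g1[0]) * (g0[-1] - g1[-1]) < 0


def test_predict_profile_probabilities_bounded():
    rng = np.random.default_rng(27)
    df = _gxe_frame(rng)
    for fam, outcome in (("logit", "binary"), ("ologit", "binary")):
        res = fit_gxe(df, GxeSpec(outcome=outcome, family=fam, covariates=("age_c",)))
        prof = predict_profile(res, pgs_grid=np.linspace(-3, 3, 13))
        assert ((prof.prediction >= 0) & (prof.prediction <= 1)).all()
        if fam == "logit":  # bands from the linear predictor stay inside (0, 1)
            assert ((prof.ci_low >= 0) & (prof.ci_high <= 1)).all()
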