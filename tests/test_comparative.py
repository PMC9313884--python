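"""Regression machinery, phylogenetic signal, garden pooling, ANOVA.

GLS/PGLS expected values are frozen from independent R fits on the oracle
tree: nlme::gls with a corPagel correlation structure (fixed lambda) and
phytools::phylosig (Blomberg's K, Pagel's lambda).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xylophen as xp
from xylophen.comparative import InteractionError, _compact_letters

from conftest import ORACLE_TAXA


# --------------------------------------------------------------------- OLS


def test_ols_matches_normal_equations(rng):
    n = 30
    X = rng.normal(size=(n, 3))
    y = rng.normal(size=n)
    fit = xp.ols_fit(y, X)
    Xd = np.column_stack([np.ones(n), X])
    beta = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
    np.testing.assert_allclose(fit.params, beta, atol=1e-10)


def test_ols_exact_line_r2_one():
    x = np.arange(10.0)
    fit = xp.ols_fit(3.0 + 2.0 * x, x)
    assert fit.r2 == pytest.approx(1.0)
    np.testing.assert_allclose(fit.params, [3.0, 2.0], atol=1e-10)


def test_ols_order_invariance(rng):
    n = 25
    X = rng.normal(size=(n, 2))
    y = X @ [1.0, -2.0] + rng.normal(size=n)
    perm = rng.permutation(n)
    f1 = xp.ols_fit(y, X)
    f2 = xp.ols_fit(y[perm], X[perm])
    np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)
    assert f1.aic == pytest.approx(f2.aic)


def test_ols_rejects_rank_deficiency(rng):
    x = rng.normal(size=20)
    with pytest.raises(np.linalg.LinAlgError):
        xp.ols_fit(rng.normal(size=20), np.column_stack([x, 2 * x]))


def test_select_model_penalty_and_guards(rng):
    x = np.linspace(0, 1, 40)
    y = 1.0 + 2.0 * x + rng.normal(scale=0.1, size=40)
    small = xp.ols_fit(y, x, names=["x"], response="y")
    noise = rng.normal(size=40)
    big = xp.ols_fit(y, np.column_stack([x, noise]), names=["x", "z"], response="y")
    best, table = xp.select_model([small, big])
    assert set(table.columns) >= {"model", "aic", "delta_aic", "tied"}
    # identical logLik -> smaller model must win on the penalty alone
    if abs(small.loglik - big.loglik) < 1e-12:
        assert best is small
    other = xp.ols_fit(noise, x, names=["x"], response="other")
    with pytest.raises(ValueError, match="different responses"):
        xp.select_model([small, other])


def test_select_model_flags_ties(rng):
    x = rng.normal(size=20)
    y = x + rng.normal(size=20)
    f = xp.ols_fit(y, x)
    best, table = xp.select_model([f, f])
    assert table["tied"].sum() == 2


def test_log_variant_shifts_intercept_only(rng):
    # under x -> c x, the log-model slope is unchanged, intercept absorbs ln c
    x = np.exp(rng.normal(size=50))
    y = 2.0 + 3.0 * np.log(x)
    f1 = xp.log_variant(y, x, names=["x"])
    f2 = xp.log_variant(y, 5.0 * x, names=["x"])
    assert f1.coef("log_x") == pytest.approx(f2.coef("log_x"), abs=1e-8)
    assert f2.params[0] == pytest.approx(f1.params[0] - 3.0 * np.log(5.0), abs=1e-8)


def test_log_variant_rejects_nonpositive():
    with pytest.raises(ValueError, match="rows"):
        xp.log_variant(np.ones(5), np.array([1.0, 2.0, -1.0, 3.0, 4.0]))


# --------------------------------------------------------------------- PGLS


def test_pgls_fixed_lambda_matches_gls_oracle(oracle_tree, oracle_data):
    # nlme::gls(y ~ x, correlation = corPagel(0.3, fixed = TRUE), method = "ML")
    taxa, x, y = oracle_data
    fit = xp.pgls_fit(y, x, oracle_tree, taxa, lam=0.3)
    np.testing.assert_allclose(fit.params, [-60.99007857, 14.97678568], rtol=1e-7)
    np.testing.assert_allclose(fit.bse, [11.0195737146, 0.4354307347], rtol=1e-7)
    assert fit.loglik == pytest.approx(-26.74601, abs=2e-5)


def test_pgls_lambda_zero_equals_ols(oracle_tree, oracle_data):
    taxa, x, y = oracle_data
    fit = xp.pgls_fit(y, x, oracle_tree, taxa, lam=0.0)
    ols = xp.ols_fit(y, x)
    np.testing.assert_allclose(fit.params, ols.params, atol=1e-8)
    assert fit.loglik == pytest.approx(-26.10517, abs=2e-5)  # nlme logLik


def test_pgls_star_tree_equals_ols_any_lambda(star_tree, rng):
    taxa = ["a", "b", "c", "d", "e", "f"]
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    ols = xp.ols_fit(y, x)
    for lam in (0.0, 0.4, 1.0):
        fit = xp.pgls_fit(y, x, star_tree, taxa, lam=lam)
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-8)


def test_pgls_matches_explicit_gls_formula(oracle_tree, oracle_data):
    taxa, x, y = oracle_data
    lam = 0.62
    V = xp.pagel_transform(xp.vcv_matrix(oracle_tree, order=taxa)[0], lam)
    Xd = np.column_stack([np.ones(8), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.inv(Xd.T @ Vi @ Xd) @ Xd.T @ Vi @ y
    fit = xp.pgls_fit(y, x, oracle_tree, taxa, lam=lam)
    np.testing.assert_allclose(fit.params, beta, atol=1e-8)


def test_pgls_estimator_sklearn_protocol(oracle_tree, oracle_data):
    taxa, x, y = oracle_data
    est = xp.PGLSRegression(tree=oracle_tree, taxa=taxa, lam=0.3)
    est.fit(x, y)
    assert est.get_params()["lam"] == 0.3
    assert hasattr(est, "coef_") and hasattr(est, "lambda_")
    pred = est.predict(x)
    assert pred.shape == y.shape
    # predictions reproduce the linear part
    np.testing.assert_allclose(pred, est.intercept_ + est.coef_[0] * x)


def test_lrt_lambda_zero_basics(oracle_tree, oracle_data):
    taxa, x, y = oracle_data
    full = xp.pgls_fit(y, x, oracle_tree, taxa, lam="ml")
    restricted = xp.pgls_fit(y, x, oracle_tree, taxa, lam=0.0)
    stat, p = xp.lrt_lambda_zero(full, restricted)
    assert stat >= 0.0
    assert 0.0 < p <= 1.0
    # identical fits -> statistic 0, p = 1
    stat0, p0 = xp.lrt_lambda_zero(restricted, restricted)
    assert stat0 == 0.0 and p0 == 1.0


# ------------------------------------------------------------------- signal


def test_blomberg_k_matches_phytools(oracle_tree, oracle_data):
    taxa, x, _ = oracle_data
    res = xp.blomberg_k(dict(zip(taxa, x)), oracle_tree, n_rand=199,
                        rng=np.random.default_rng(0))
    assert res.statistic == pytest.approx(0.7784723, abs=1e-6)
    assert 0.0 < res.pvalue <= 1.0


def test_blomberg_k_rejects_constant_trait(oracle_tree):
    with pytest.raises(ValueError, match="zero variance"):
        xp.blomberg_k({t: 1.0 for t in ORACLE_TAXA}, oracle_tree, n_rand=9)


def test_pagel_lambda_signal_matches_phytools(oracle_tree, oracle_data):
    # phytools::phylosig(..., method="lambda", test=TRUE)
    taxa, x, _ = oracle_data
    res = xp.pagel_lambda_signal(dict(zip(taxa, x)), oracle_tree)
    assert res.statistic == pytest.approx(0.8884307, abs=1e-4)
    assert res.loglik == pytest.approx(-25.7005, abs=2e-4)
    assert res.loglik0 == pytest.approx(-26.36151, abs=2e-5)
    assert res.pvalue == pytest.approx(0.2502312, abs=1e-3)


def test_pagel_lambda_affine_invariance(oracle_tree, oracle_data):
    taxa, x, _ = oracle_data
    r1 = xp.pagel_lambda_signal(dict(zip(taxa, x)), oracle_tree)
    r2 = xp.pagel_lambda_signal(dict(zip(taxa, 3.0 * x + 100.0)), oracle_tree)
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-5)


def test_randomization_p_never_zero(oracle_tree, oracle_data):
    taxa, x, _ = oracle_data
    res = xp.blomberg_k(dict(zip(taxa, x)), oracle_tree, n_rand=9,
                        rng=np.random.default_rng(1))
    assert res.pvalue >= 1.0 / 10.0


# -------------------------------------------------------- pooling & nonlinear


def test_combine_identical_datasets_shift_zero(rng):
    x = rng.uniform(10, 50, size=20)
    df = pd.DataFrame({"diam": x, "gdd": 50 + 9 * x + rng.normal(size=20)})
    combined, diag = xp.combine_gardens(df, df, "gdd", "diam")
    assert diag["shift_applied_to_a"] == pytest.approx(0.0, abs=1e-10)
    assert len(combined) == 40


def test_combine_parallel_lines_exact():
    x = np.linspace(10, 40, 12)
    a = pd.DataFrame({"diam": x, "gdd": 100 + 9.0 * x})
    b = pd.DataFrame({"diam": x + 1.3, "gdd": 250 + 9.0 * (x + 1.3)})
    combined, diag = xp.combine_gardens(a, b, "gdd", "diam")
    assert diag["shift_applied_to_a"] == pytest.approx(150.0, abs=1e-8)
    pooled = xp.ols_fit(combined["gdd"], combined["diam"], names=["diam"])
    assert pooled.coef("diam") == pytest.approx(9.0, abs=1e-8)
    # after the shift both lines coincide: pooled RSS is exactly 0
    resid = combined["gdd"] - pooled.params[0] - pooled.coef("diam") * combined["diam"]
    assert float((resid ** 2).sum()) == pytest.approx(0.0, abs=1e-14)


def test_combine_refuses_different_slopes(rng):
    x = np.linspace(10, 40, 30)
    a = pd.DataFrame({"diam": x, "gdd": 100 + 2.0 * x + rng.normal(scale=0.1, size=30)})
    b = pd.DataFrame({"diam": x, "gdd": 100 + 9.0 * x + rng.normal(scale=0.1, size=30)})
    with pytest.raises(InteractionError) as err:
        xp.combine_gardens(a, b, "gdd", "diam")
    assert err.value.interaction_p < 0.05


def test_exponential_exact_recovery():
    x = np.linspace(10, 40, 25)
    y = 180.0 + 0.5 * np.exp(0.2 * x)
    fit = xp.fit_exponential(x, y)
    assert fit["converged"]
    assert fit["y0"] == pytest.approx(180.0, rel=1e-6)
    assert fit["a"] == pytest.approx(0.5, rel=1e-6)
    assert fit["b"] == pytest.approx(0.2, rel=1e-6)


def test_exponential_degenerate_constant():
    x = np.linspace(0, 10, 20)
    y = np.full(20, 7.0)
    fit = xp.fit_exponential(x, y)
    pred = fit["y0"] + fit["a"] * np.exp(fit["b"] * x)
    np.testing.assert_allclose(pred, y, atol=1e-6)


# -------------------------------------------------------------------- ANOVA


def _toy_groups():
    return pd.DataFrame({
        "g": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
        "v": [10.0, 11, 9, 10, 20, 21, 19, 20, 30, 29, 31, 30],
    })


def test_anova_f_matches_hand_sums():
    df = _toy_groups()
    res = xp.anova_tukey(df, "v", "g", alpha=0.05)
    means = df.groupby("g")["v"].mean()
    grand = df["v"].mean()
    ssb = sum(4 * (m - grand) ** 2 for m in means)
    ssw = sum((df.loc[df.g == g, "v"] - means[g]).pow(2).sum() for g in means.index)
    f_hand = (ssb / 2) / (ssw / 9)
    assert res.fstat == pytest.approx(f_hand, rel=1e-10)
    # clearly separated groups get three distinct letters
    assert len({res.letters[g] for g in "abc"}) == 3


def test_anova_identical_groups_share_letter(rng):
    vals = rng.normal(size=6)
    df = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6, "v": np.r_[vals, vals]})
    res = xp.anova_tukey(df, "v", "g", alpha=0.05)
    assert res.fstat == pytest.approx(0.0, abs=1e-12)
    assert res.letters["a"] == res.letters["b"] == "a"


def test_tukey_two_groups_equals_pooled_t(rng):
    a = rng.normal(0, 1, size=8)
    b = rng.normal(1, 1, size=8)
    df = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8, "v": np.r_[a, b]})
    res = xp.anova_tukey(df, "v", "g", alpha=0.05)
    t_p = stats.ttest_ind(a, b).pvalue
    assert float(res.pairwise["p-adj"].iloc[0]) == pytest.approx(t_p, abs=1e-4)


def test_anova_rejects_tiny_group():
    df = pd.DataFrame({"g": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        xp.anova_tukey(df, "v", "g")


def test_compact_letters_chain():
    # a > b > c with only a-c significant: a="a", b="ab" overlap, c="b"
    means = {"a": 3.0, "b": 2.0, "c": 1.0}
    sig = {("a", "c"): True, ("a", "b"): False, ("b", "c"): False}
    letters = _compact_letters(["a", "b", "c"], means, sig)
    assert set(letters["b"]) == set(letters["a"]) | set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
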