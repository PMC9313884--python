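"""Cross-species statistics for trait–phenology analysis.

Implements ordinary least squares with AIC model selection, phylogenetic
generalized least squares (PGLS) with Pagel's lambda estimated by maximum
likelihood, the chi-square likelihood-ratio test against lambda = 0,
Blomberg's K and Pagel's lambda phylogenetic-signal tests, the two-garden
intercept adjustment for pooling common gardens, an exponential leaf-out
model, and one-way ANOVA with Tukey HSD compact letter display.

The regression estimators follow the scikit-learn protocol (``fit``,
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes); the module-level ``*_fit`` functions are thin wrappers that
return a :class:`FitResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .phylo import independent_contrasts, pagel_transform, vcv_matrix

__all__ = [
    "FitResult",
    "SignalResult",
    "PGLSRegression",
    "ExponentialLeafOutModel",
    "ols_fit",
    "pgls_fit",
    "log_variant",
    "select_model",
    "lrt_lambda_zero",
    "blomberg_k",
    "pagel_lambda_signal",
    "combine_gardens",
    "fit_exponential",
    "anova_tukey",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class FitResult:
    """Summary of a fitted linear model (OLS or PGLS)."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    fstat: float
    df_num: int
    df_den: int
    f_pvalue: float
    r2: float
    loglik: float
    aic: float
    n: int
    k: int                      # parameters counted by AIC (incl. error variance)
    response: str = "y"
    method: str = "ols"
    lambda_hat: float | None = None

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues},
            index=self.names,
        )


@dataclass
class SignalResult:
    """A phylogenetic-signal test outcome (Blomberg's K or Pagel's lambda)."""

    statistic: float
    pvalue: float
    method: str
    n_randomizations: int = 0
    loglik: float | None = None
    loglik0: float | None = None


@dataclass
class TukeyResult:
    fstat: float
    df_num: int
    df_den: int
    pvalue: float
    alpha: float
    letters: dict[str, str]
    pairwise: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# GLS core


def _as_design(X, names: Sequence[str] | None, add_intercept: bool):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


def _gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates and Gaussian log-likelihoods under cov = sigma^2 * V.

    Returns dict with beta, cov_beta (unbiased sigma^2), rss (whitened),
    loglik (ML, sigma^2 profiled out), loglik_reml.
    """
    n, p = X.shape
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance matrix not positive definite") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX = Xw.T @ Xw
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_V + n)
    if n > p:
        sigma2_u = rss / (n - p)
        sign, logdet_XtX = np.linalg.slogdet(XtX)
        loglik_reml = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2_u)
            + logdet_V
            + logdet_XtX
            + (n - p)
        )
        cov_beta = sigma2_u * np.linalg.inv(XtX)
    else:
        sigma2_u = np.nan
        loglik_reml = np.nan
        cov_beta = np.full((p, p), np.nan)
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "rss": rss,
        "sigma2": sigma2_u,
        "loglik": loglik,
        "loglik_reml": loglik_reml,
        "yw": yw,
        "Xw": Xw,
    }


def _fit_summary(y, X, V, names, response, method_label, lam, k_extra):
    n, p = X.shape
    sol = _gls_solve(y, X, V)
    beta, cov = sol["beta"], sol["cov_beta"]
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    df_den = n - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df_den)
    # GLS R^2 and F against the intercept-only model under the same V
    ones = np.ones((n, 1))
    sol0 = _gls_solve(y, ones, V)
    tss = sol0["rss"]
    rss = sol["rss"]
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    df_num = p - 1
    if df_num > 0 and rss > 0:
        fstat = ((tss - rss) / df_num) / (rss / df_den)
        f_p = float(stats.f.sf(fstat, df_num, df_den))
    elif df_num > 0:
        fstat, f_p = np.inf, 0.0
    else:
        fstat, f_p = np.nan, np.nan
    k = p + 1 + k_extra  # + error variance (+ lambda when estimated)
    loglik = sol["loglik"]
    return FitResult(
        names=list(names),
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        fstat=float(fstat),
        df_num=df_num,
        df_den=df_den,
        f_pvalue=f_p,
        r2=float(r2),
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * k),
        n=n,
        k=k,
        response=response,
        method=method_label,
        lambda_hat=lam,
    )


# ---------------------------------------------------------------------------
# estimators


class PGLSRegression(BaseEstimator, RegressorMixin):
    """Phylogenetic generalized least squares with Pagel's lambda residuals.

    The error covariance is ``sigma^2 * V(lambda)`` where ``V`` is the
    phylogenetic variance–covariance matrix of the tree and ``V(lambda)``
    multiplies its off-diagonal elements by ``lambda``.  ``lambda`` is either
    fixed or estimated on [0, 1] by bounded scalar optimization of the
    profile (ML or REML) log-likelihood.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted phylogeny whose tips cover the modeled species.
    taxa : sequence of str
        Species label of each row of ``X``/``y``, in order.
    lam : "ml" or float in [0, 1], default "ml"
        Estimate lambda by maximum likelihood, or hold it fixed.
    method : {"ml", "reml"}, default "ml"
        Likelihood used both for the lambda profile and for ``loglik_``.
    fit_intercept : bool, default True
    tol : float, default 1e-6
        Absolute tolerance of the bounded lambda search.

    Attributes
    ----------
    coef_, intercept_ : fitted regression parameters
    lambda_ : estimated (or fixed) Pagel's lambda
    loglik_, aic_ : profile log-likelihood and AIC (error variance and, when
        estimated, lambda are counted as parameters)
    result_ : :class:`FitResult` with SEs, t, F, R^2
    """

    def __init__(self, tree=None, taxa=None, lam="ml", method="ml",
                 fit_intercept=True, tol=1e-6):
        self.tree = tree
        self.taxa = taxa
        self.lam = lam
        self.method = method
        self.fit_intercept = fit_intercept
        self.tol = tol

    def fit(self, X, y, feature_names: Sequence[str] | None = None,
            response: str = "y"):
        if self.tree is None or self.taxa is None:
            raise ValueError("PGLSRegression requires tree= and taxa=")
        y = np.asarray(y, dtype=float).ravel()
        X, names = _as_design(X, feature_names, self.fit_intercept)
        if X.shape[0] != len(self.taxa) or len(y) != len(self.taxa):
            raise ValueError("X, y and taxa must have matching length")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values in y or X")
        V, _ = vcv_matrix(self.tree, order=list(self.taxa))

        crit = "loglik" if self.method == "ml" else "loglik_reml"

        def negll(lam: float) -> float:
            return -_gls_solve(y, X, pagel_transform(V, lam))[crit]

        if self.lam == "ml":
            res = optimize.minimize_scalar(
                negll, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": self.tol},
            )
            # the bounded search can stall short of a boundary optimum
            lam_hat = float(res.x)
            for cand in (0.0, 1.0):
                if negll(cand) < res.fun:
                    lam_hat = cand
            k_extra = 1
        else:
            lam_hat = float(self.lam)
            if not 0.0 <= lam_hat <= 1.0:
                raise ValueError("fixed lambda must be in [0, 1]")
            k_extra = 0

        result = _fit_summary(
            y, X, pagel_transform(V, lam_hat), names, response,
            "pgls-" + self.method, lam_hat, k_extra,
        )
        if self.method == "reml":
            sol = _gls_solve(y, X, pagel_transform(V, lam_hat))
            result.loglik = float(sol["loglik_reml"])
            result.aic = float(-2 * result.loglik + 2 * result.k)
        self.result_ = result
        self.lambda_ = lam_hat
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        if self.fit_intercept:
            self.intercept_ = float(result.params[0])
            self.coef_ = result.params[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = result.params.copy()
        self.n_features_in_ = self.coef_.size
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


class ExponentialLeafOutModel(BaseEstimator, RegressorMixin):
    """Exponential trait–phenology model ``y = y0 + a * exp(b * x)``.

    Fitted by nonlinear least squares from a grid of starting rates ``b``
    (multi-start) to avoid the flat-valley local optima typical of
    exponential fits; the best converged attempt is kept.

    Attributes
    ----------
    y0_, a_, b_ : fitted parameters
    converged_ : whether any start converged
    rss_ : residual sum of squares of the kept fit
    """

    def __init__(self, b_grid: Sequence[float] = (-0.3, -0.1, 0.01, 0.05, 0.1, 0.2, 0.4),
                 maxfev: int = 5000):
        self.b_grid = b_grid
        self.maxfev = maxfev

    @staticmethod
    def _model(x, y0, a, b):
        return y0 + a * np.exp(b * x)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 4:
            raise ValueError("exponential fit needs at least 4 points")
        best = None
        yspan = np.ptp(y) or 1.0
        for b0 in self.b_grid:
            scale = np.exp(b0 * np.median(x))
            p0 = (float(np.min(y)), yspan / scale if scale > 0 else 1.0, b0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        self._model, x, y, p0=p0, maxfev=self.maxfev
                    )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((y - self._model(x, *popt)) ** 2))
            if np.isfinite(rss) and (best is None or rss < best[0]):
                best = (rss, popt)
        if best is None:
            self.converged_ = False
            self.y0_ = self.a_ = self.b_ = np.nan
            self.rss_ = np.inf
            return self
        self.converged_ = True
        self.rss_, (self.y0_, self.a_, self.b_) = best[0], tuple(best[1])
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return self._model(x, self.y0_, self.a_, self.b_)


# ---------------------------------------------------------------------------
# functional wrappers


def ols_fit(y, X, names: Sequence[str] | None = None, response: str = "y") -> FitResult:
    """Ordinary least squares (intercept added) returning a :class:`FitResult`.

    AIC counts the error variance as a parameter: ``AIC = -2 logL + 2(p + 1)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, names = _as_design(X, names, add_intercept=True)
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in y or X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    model = sm.OLS(y, X).fit()
    k = X.shape[1] + 1
    return FitResult(
        names=list(names),
        params=np.asarray(model.params),
        bse=np.asarray(model.bse),
        tvalues=np.asarray(model.tvalues),
        pvalues=np.asarray(model.pvalues),
        fstat=float(model.fvalue) if X.shape[1] > 1 else np.nan,
        df_num=X.shape[1] - 1,
        df_den=int(model.df_resid),
        f_pvalue=float(model.f_pvalue) if X.shape[1] > 1 else np.nan,
        r2=float(model.rsquared),
        loglik=float(model.llf),
        aic=float(-2 * model.llf + 2 * k),
        n=len(y),
        k=k,
        response=response,
        method="ols",
    )


def pgls_fit(y, X, tree: dendropy.Tree, taxa: Sequence[str],
             lam="ml", method: str = "ml",
             names: Sequence[str] | None = None, response: str = "y") -> FitResult:
    """PGLS under Pagel's-lambda residual covariance (see :class:`PGLSRegression`)."""
    est = PGLSRegression(tree=tree, taxa=taxa, lam=lam, method=method)
    est.fit(X, y, feature_names=names, response=response)
    return est.result_


def log_variant(y, X, tree=None, taxa=None,
                log_columns: Sequence[int] | None = None,
                names: Sequence[str] | None = None,
                response: str = "y", **kwargs) -> FitResult:
    """Refit with natural-log-transformed covariates (all columns by default).

    Used for the multiplicative-error robustness check on vessel diameter and
    height.  Raises on nonpositive values, naming the offending rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = list(log_columns) if log_columns is not None else list(range(X.shape[1]))
    Xl = X.copy()
    for c in cols:
        bad = np.nonzero(X[:, c] <= 0)[0]
        if bad.size:
            raise ValueError(
                f"log transform of column {c} undefined at rows {bad.tolist()}"
            )
        Xl[:, c] = np.log(X[:, c])
    if names is not None:
        names = [f"log_{nm}" if i in cols else nm for i, nm in enumerate(names)]
    if tree is None:
        return ols_fit(y, Xl, names=names, response=response)
    return pgls_fit(y, Xl, tree, taxa, names=names, response=response, **kwargs)


def select_model(fits: Sequence[FitResult]) -> tuple[FitResult, pd.DataFrame]:
    """Pick the fit with the lowest AIC; returns (best, full AIC table).

    All candidates must model the same response on the same n.  Ties (AIC
    within 1e-9) are flagged in the table's ``tied`` column; the first of the
    tied set is returned.
    """
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    resp = {(f.response, f.n) for f in fits}
    if len(resp) > 1:
        raise ValueError(f"candidates model different responses: {resp}")
    aics = np.array([f.aic for f in fits])
    best_idx = int(np.argmin(aics))
    table = pd.DataFrame(
        {
            "model": [" + ".join(nm for nm in f.names if nm != "intercept") or "1"
                      for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": aics,
            "delta_aic": aics - aics[best_idx],
            "r2": [f.r2 for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    table["tied"] = np.isclose(table["aic"], aics[best_idx], atol=1e-9)
    return fits[best_idx], table


def lrt_lambda_zero(full: FitResult, restricted: FitResult) -> tuple[float, float]:
    """Chi-square LRT of a lambda-estimating PGLS against the lambda = 0 fit.

    The statistic ``2 (logL_full - logL_0)`` is floored at zero (the boundary
    case lambda_hat = 0) and referred to chi-square with 1 df, which is
    conservative at the boundary.
    """
    if full.n != restricted.n or full.response != restricted.response:
        raise ValueError("fits are not on the same data")
    if len(full.names) != len(restricted.names):
        raise ValueError("fits are not nested: designs differ")
    stat = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# phylogenetic signal


def _phylo_mean(x: np.ndarray, Vinv_ones: np.ndarray, ones_Vinv_ones: float) -> float:
    return float(Vinv_ones @ x / ones_Vinv_ones)


def blomberg_k(trait: Mapping[str, float], tree: dendropy.Tree,
               n_rand: int = 999, rng: np.random.Generator | None = None) -> SignalResult:
    """Blomberg's K with a tip-randomization significance test.

    K compares the observed ratio of trait variance to phylogenetically
    corrected variance with its Brownian-motion expectation on the same tree;
    K = 1 under Brownian motion, K -> 0 with no signal.  The p-value shuffles
    trait values across tips and asks how often the variance of standardized
    independent contrasts is <= the observed one, with the add-one rule
    ``p = (r + 1) / (n_rand + 1)`` so p is never zero.
    """
    rng = rng or np.random.default_rng()
    V, labels = vcv_matrix(tree)
    x = np.array([trait[lab] for lab in labels], dtype=float)
    n = len(x)
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    Vinv_ones = Vinv @ ones
    denom = float(ones @ Vinv_ones)
    a_hat = _phylo_mean(x, Vinv_ones, denom)
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ Vinv @ dev) / (n - 1)
    expected = (np.trace(V) - n / denom) / (n - 1)
    K = (mse0 / mse) / expected

    # contrasts are linear in the trait vector: build the weight matrix once
    # from unit-vector traits, then score all tip shuffles by matrix product
    W = np.column_stack([
        independent_contrasts(tree, dict(zip(labels, e)))
        for e in np.eye(n)
    ])
    obs = float(np.var(W @ x, ddof=1))
    if n_rand > 0:
        perms = np.array([rng.permutation(x) for _ in range(n_rand)])
        null_vars = np.var(perms @ W.T, axis=1, ddof=1)
        count = int(np.count_nonzero(null_vars <= obs))
        p = (count + 1) / (n_rand + 1)
    else:
        p = np.nan
    return SignalResult(statistic=float(K), pvalue=p, method="blomberg_k",
                        n_randomizations=n_rand)


def pagel_lambda_signal(trait: Mapping[str, float], tree: dendropy.Tree,
                        mode: str = "lrt", n_rand: int = 999,
                        rng: np.random.Generator | None = None) -> SignalResult:
    """Pagel's lambda signal test on a single trait.

    lambda is estimated by ML on the intercept-only PGLS model.  With
    ``mode="lrt"`` (default, the phylosig convention) the p-value is a
    chi-square LRT against lambda = 0; with ``mode="randomization"`` trait
    values are shuffled across tips and the LRT statistic compared with its
    permutation distribution using ``(r + 1) / (n_rand + 1)``.
    """
    V, labels = vcv_matrix(tree)
    x = np.array([trait[lab] for lab in labels], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("trait has zero variance")
    n = len(x)
    ones = np.ones((n, 1))

    def ml_lambda(vals: np.ndarray):
        def negll(lam):
            return -_gls_solve(vals, ones, pagel_transform(V, lam))["loglik"]
        res = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        lam_hat, best = float(res.x), res.fun
        for cand in (0.0, 1.0):
            f = negll(cand)
            if f < best:
                lam_hat, best = cand, f
        return lam_hat, -best

    lam_hat, ll = ml_lambda(x)
    ll0 = _gls_solve(x, ones, pagel_transform(V, 0.0))["loglik"]
    stat = max(0.0, 2.0 * (ll - ll0))
    if mode == "lrt":
        p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
        n_used = 0
    elif mode == "randomization":
        rng = rng or np.random.default_rng()
        count = 0
        for _ in range(n_rand):
            xp = rng.permutation(x)
            _, ll_p = ml_lambda(xp)
            ll0_p = _gls_solve(xp, ones, pagel_transform(V, 0.0))["loglik"]
            if 2.0 * (ll_p - ll0_p) >= stat:
                count += 1
        p = (count + 1) / (n_rand + 1)
        n_used = n_rand
    else:
        raise ValueError("mode must be 'lrt' or 'randomization'")
    return SignalResult(statistic=lam_hat, pvalue=p, method="pagel_lambda",
                        n_randomizations=n_used, loglik=float(ll), loglik0=float(ll0))


# ---------------------------------------------------------------------------
# garden pooling, exponential fit, ANOVA


class InteractionError(ValueError):
    """Raised when gardens cannot be pooled because their slopes differ."""

    def __init__(self, message, interaction_p=None, fit=None):
        super().__init__(message)
        self.interaction_p = interaction_p
        self.fit = fit


def combine_gardens(data_a: pd.DataFrame, data_b: pd.DataFrame,
                    response: str, covariate: str,
                    alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Pool two common-garden datasets onto a shared intercept.

    First verifies the garden-by-covariate interaction is not significant
    (the slopes are statistically indistinguishable); then fits the
    parallel-slopes model and shifts garden A's response by
    ``intercept_B - intercept_A`` so both gardens lie on garden B's line.
    Raises :class:`InteractionError` when the slopes differ at ``alpha``.

    Returns the combined table (with a ``garden`` column) and a diagnostics
    dict (interaction p, common slope, the applied shift).
    """
    for df in (data_a, data_b):
        if response not in df or covariate not in df:
            raise ValueError(f"tables need columns {response!r} and {covariate!r}")
    x = np.concatenate([data_a[covariate].to_numpy(float),
                        data_b[covariate].to_numpy(float)])
    y = np.concatenate([data_a[response].to_numpy(float),
                        data_b[response].to_numpy(float)])
    g = np.concatenate([np.zeros(len(data_a)), np.ones(len(data_b))])
    parallel = ols_fit(y, np.column_stack([x, g]),
                       names=[covariate, "garden"], response=response)
    if parallel.r2 >= 1.0 - 1e-12:
        # the parallel-slopes model is exact: the slopes cannot differ, and
        # the interaction t-test would divide rounding error by rounding error
        p_int = 1.0
    else:
        inter = ols_fit(y, np.column_stack([x, g, x * g]),
                        names=[covariate, "garden", f"garden_x_{covariate}"],
                        response=response)
        p_int = float(inter.pvalues[inter.names.index(f"garden_x_{covariate}")])
        if p_int < alpha:
            raise InteractionError(
                f"garden-by-{covariate} interaction significant "
                f"(p = {p_int:.4g}); slopes differ, refusing to pool",
                interaction_p=p_int, fit=inter,
            )
    # garden coefficient = intercept_B - intercept_A under parallel slopes
    shift = parallel.coef("garden")
    out_a = data_a.copy()
    out_b = data_b.copy()
    out_a[response] = out_a[response] + shift
    out_a["garden"] = "A"
    out_b["garden"] = "B"
    combined = pd.concat([out_a, out_b], ignore_index=True)
    diag = {
        "interaction_p": p_int,
        "common_slope": parallel.coef(covariate),
        "shift_applied_to_a": shift,
    }
    return combined, diag


def fit_exponential(x, y, b_grid=None) -> dict:
    """Nonlinear least squares for ``y = y0 + a * exp(b * x)`` (multi-start).

    Returns a dict with ``y0``, ``a``, ``b``, ``rss`` and ``converged``; a
    non-converged fit is returned flagged invalid rather than raised.
    """
    kwargs = {} if b_grid is None else {"b_grid": b_grid}
    est = ExponentialLeafOutModel(**kwargs).fit(x, y)
    return {"y0": est.y0_, "a": est.a_, "b": est.b_,
            "rss": est.rss_, "converged": est.converged_}


def _compact_letters(groups: Sequence[str], means: Mapping[str, float],
                     sig: Mapping[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups that are *not* significantly different share at least one letter.
    Ties at the alpha boundary are treated as non-significant upstream.
    """
    order = sorted(groups, key=lambda g: -means[g])
    sets: list[set[str]] = [set(order)]
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            if not sig.get((gi, gj), sig.get((gj, gi), False)):
                continue
            new_sets: list[set[str]] = []
            for s in sets:
                if gi in s and gj in s:
                    new_sets.extend([s - {gi}, s - {gj}])
                else:
                    new_sets.append(s)
            # absorb subsets
            sets = [s for s in new_sets
                    if not any(s < t for t in new_sets) and s]
            # deduplicate
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return letters


def anova_tukey(data: pd.DataFrame, value: str, group: str,
                alpha: float = 0.01) -> TukeyResult:
    """One-way ANOVA with Tukey HSD multiple comparisons and letter display.

    Pairs whose Tukey p-value is below ``alpha`` get different letters;
    groups sharing any letter are statistically indistinguishable at
    ``alpha``.  Every group needs at least two observations.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if data[group].nunique() < 2:
        raise ValueError("need at least two groups")
    sizes = data.groupby(group)[value].size()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 observations: {list(small.index)}")
    samples = [sub[value].to_numpy(float) for _, sub in data.groupby(group)]
    f, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(data[value].to_numpy(float),
                           data[group].to_numpy(str), alpha=alpha)
    pairwise = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    means = data.groupby(group)[value].mean().to_dict()
    sig = {}
    for (g1, g2), pval in zip(zip(pairwise["group1"], pairwise["group2"]),
                              pairwise["p-adj"]):
        sig[(str(g1), str(g2))] = float(pval) < alpha
    letters = _compact_letters(list(sizes.index.astype(str)), means, sig)
    k = len(samples)
    n = len(data)
    return TukeyResult(fstat=float(f), df_num=k - 1, df_den=n - k,
                       pvalue=float(p), alpha=alpha, letters=letters,
                       pairwise=pairwise)
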