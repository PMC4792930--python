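"""Group-level statistics relating connectivity parameters to age and
cognition: multiple regression, canonical correlation analysis with
structure correlations and permutation inference, moderation analysis,
and false-discovery-rate control.

The same machinery runs on effective-connectivity parameters (posterior
means after Bayesian model averaging) and on Fisher-z functional
connectivity values; :func:`fc_reanalysis` is a thin relabelling of the
shared pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "CCAResult",
    "ModerationResult",
    "age_regression",
    "cca",
    "structure_correlations",
    "cca_significance",
    "moderation",
    "fdr_correct",
    "brain_behaviour_analysis",
    "fc_reanalysis",
]

logger = logging.getLogger(__name__)

LOADING_THRESHOLD = 0.3  # |structure correlation| below which a variable is flagged


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


@dataclass
class RegressionResult:
    r: float  # multiple correlation
    table: pd.DataFrame  # per-coefficient estimates with 95% CIs
    n: int


@dataclass
class CCAResult:
    correlations: np.ndarray       # non-increasing, in [0, 1]
    x_weights: np.ndarray          # (p, n_pairs)
    y_weights: np.ndarray          # (q, n_pairs)
    x_scores: np.ndarray           # canonical variates, unit variance
    y_scores: np.ndarray
    x_loadings: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    p_first: float | None = None


@dataclass
class ModerationResult:
    table: pd.DataFrame            # standardized coefficients with p-values
    r: float                       # multiple correlation of the full model
    simple_slopes: np.ndarray      # per age-tertile slope of W1 on V1
    tertile_edges: np.ndarray
    n: int


def age_regression(params: np.ndarray, age: np.ndarray,
                   covariates: np.ndarray | None = None,
                   param_names: list[str] | None = None,
                   covariate_names: list[str] | None = None
                   ) -> RegressionResult:
    """Standardized multiple regression of age on parameters (+ covariates).

    Returns the multiple correlation R, per-coefficient standardized
    estimates with analytic 95% confidence intervals, and a flag for
    coefficients whose interval excludes zero.
    """
    params = np.atleast_2d(np.asarray(params, float))
    if params.shape[0] == 1 and np.asarray(age).size > 1:
        params = params.T
    age = np.asarray(age, float)
    n, p = params.shape
    ncov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if n <= p + ncov + 2:
        raise ValueError("not enough subjects for the requested design")
    X = _zscore(params)
    names = list(param_names or [f"param_{j}" for j in range(p)])
    if covariates is not None:
        C = np.asarray(covariates, float)
        C = C.reshape(n, -1)
        X = np.hstack([X, _zscore(C)])
        names += list(covariate_names or [f"cov_{j}" for j in range(C.shape[1])])
    y = _zscore(age)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "name": names,
        "beta": fit.params[1:],
        "se": fit.bse[1:],
        "ci_low": ci[1:, 0],
        "ci_high": ci[1:, 1],
        "pvalue": fit.pvalues[1:],
    })
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return RegressionResult(r=float(np.sqrt(max(fit.rsquared, 0.0))),
                            table=table, n=n)


def _inv_sqrt_psd(S: np.ndarray, label: str) -> np.ndarray:
    """Inverse symmetric square root with ridge fallback on rank deficiency."""
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    if w.min() < 1e-10 * max(w.max(), 1e-300):
        ridge = 1e-8 * float(np.trace(S))
        warnings.warn(f"rank-deficient {label} covariance; applying ridge "
                      f"{ridge:.3g}", stacklevel=3)
        w = w + ridge
    return (V / np.sqrt(w)) @ V.T


def cca(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Canonical correlation analysis by SVD of the whitened cross-covariance.

    Columns are standardized internally; canonical variates have unit
    variance and each weight vector's largest-magnitude element is made
    positive (a deterministic sign convention — canonical signs are
    otherwise arbitrary).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    n = X.shape[0]
    p, q = X.shape[1], Y.shape[1]
    if n <= p + q + 2:
        raise ValueError("not enough observations for CCA")
    Xz, Yz = _zscore(X), _zscore(Y)
    Sxx = Xz.T @ Xz / (n - 1)
    Syy = Yz.T @ Yz / (n - 1)
    Sxy = Xz.T @ Yz / (n - 1)
    Kx = _inv_sqrt_psd(Sxx, "X")
    Ky = _inv_sqrt_psd(Syy, "Y")
    U, s, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    npair = min(p, q)
    A = Kx @ U[:, :npair]
    B = Ky @ Vt.T[:, :npair]
    for W in (A, B):
        for j in range(npair):
            if W[np.argmax(np.abs(W[:, j])), j] < 0:
                W[:, j] = -W[:, j]
    xs = Xz @ A
    ys = Yz @ B
    xs = xs / xs.std(axis=0, ddof=1)
    ys = ys / ys.std(axis=0, ddof=1)
    return CCAResult(correlations=np.clip(s[:npair], 0.0, 1.0),
                     x_weights=A, y_weights=B, x_scores=xs, y_scores=ys)


def structure_correlations(result: CCAResult, X: np.ndarray, Y: np.ndarray
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of each original variable with its own set's first
    canonical variate ("loadings"); |r| < 0.3 is flagged low-contribution."""
    Xz, Yz = _zscore(X), _zscore(Y)
    n = Xz.shape[0]
    xl = Xz.T @ result.x_scores[:, 0] / (n - 1)
    yl = Yz.T @ result.y_scores[:, 0] / (n - 1)
    result.x_loadings, result.y_loadings = xl, yl
    fx = pd.DataFrame({"loading": xl, "low_contribution": np.abs(xl) < LOADING_THRESHOLD})
    fy = pd.DataFrame({"loading": yl, "low_contribution": np.abs(yl) < LOADING_THRESHOLD})
    return fx, fy


def cca_significance(X: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                     rng: np.random.Generator | int | None = None
                     ) -> dict[str, float]:
    """Permutation p-value for the first canonical correlation.

    Rows of Y are permuted and the CCA refitted; p = (1 + #{r_perm >=
    r_obs}) / (1 + n_perm).  Bartlett's chi-square approximation is also
    reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(rng)
    res = cca(X, Y)
    r_obs = float(res.correlations[0])
    n = X.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = float(cca(X, Y[perm]).correlations[0])
        if r_perm >= r_obs:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    p_, q_ = X.shape[1], Y.shape[1]
    lam = float(np.sum(np.log(np.clip(1.0 - res.correlations ** 2, 1e-300, None))))
    chi2 = -(n - 1 - (p_ + q_ + 1) / 2.0) * lam
    p_bartlett = float(stats.chi2.sf(chi2, df=p_ * q_))
    return {"r": r_obs, "p_perm": float(p_perm), "p_bartlett": p_bartlett,
            "chi2": chi2, "n_perm": n_perm}


def moderation(W1: np.ndarray, V1: np.ndarray, age: np.ndarray,
               covariates: np.ndarray | None = None,
               covariate_names: list[str] | None = None,
               orient: bool = True) -> ModerationResult:
    """Does age moderate the profile-cognition relationship?

    OLS of the cognitive profile W1 on [age, connectivity profile V1,
    age x V1, covariates], all standardized; the interaction product is
    formed from the standardized age and V1.  Because canonical-variate
    signs are arbitrary, ``orient=True`` flips V1 so that corr(V1, W1)
    is non-negative before fitting, making the interaction sign
    interpretable.  Per-tertile simple slopes of W1 on V1 are returned
    for plotting.
    """
    W1 = np.asarray(W1, float).ravel()
    V1 = np.asarray(V1, float).ravel()
    age = np.asarray(age, float).ravel()
    n = W1.size
    if V1.size != n or age.size != n:
        raise ValueError("W1, V1 and age must have the same length")
    if orient and np.corrcoef(V1, W1)[0, 1] < 0:
        V1 = -V1
    zw, zv, za = (_zscore(W1), _zscore(V1), _zscore(age))
    inter = za * zv
    cols = [za, zv, inter]
    names = ["age", "profile", "age_x_profile"]
    if covariates is not None:
        C = np.asarray(covariates, float).reshape(n, -1)
        for j in range(C.shape[1]):
            cols.append(_zscore(C[:, j]))
        names += list(covariate_names or [f"cov_{j}" for j in range(C.shape[1])])
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("moderation design matrix is rank deficient")
    fit = sm.OLS(zw, X).fit()
    table = pd.DataFrame({"name": names, "beta": fit.params[1:],
                          "se": fit.bse[1:], "pvalue": fit.pvalues[1:]})
    edges = np.quantile(age, [1 / 3, 2 / 3])
    groups = np.digitize(age, edges)
    slopes = np.full(3, np.nan)
    for gidx in range(3):
        m = groups == gidx
        if m.sum() >= 3 and np.std(zv[m]) > 0:
            slopes[gidx] = float(np.polyfit(zv[m], zw[m], 1)[0])
    return ModerationResult(table=table,
                            r=float(np.sqrt(max(fit.rsquared, 0.0))),
                            simple_slopes=slopes, tertile_edges=edges, n=n)


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection flags)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def brain_behaviour_analysis(param_matrix: np.ndarray, cognition: np.ndarray,
                             age: np.ndarray,
                             covariates: np.ndarray | None = None,
                             param_names: list[str] | None = None,
                             covariate_names: list[str] | None = None,
                             n_perm: int = 1000,
                             rng: np.random.Generator | int | None = None,
                             label: str = "EC") -> dict:
    """The full group pipeline on one set of connectivity measures:
    age regression, CCA against cognition with structure correlations
    and permutation inference, and the age-moderation model.

    Rows with missing values are dropped (complete-case analysis; the
    exclusion count is logged).
    """
    P = np.atleast_2d(np.asarray(param_matrix, float))
    Cg = np.atleast_2d(np.asarray(cognition, float))
    age = np.asarray(age, float)
    blocks = [P, Cg, age[:, None]]
    if covariates is not None:
        covariates = np.asarray(covariates, float).reshape(age.size, -1)
        blocks.append(covariates)
    complete = np.all([np.all(np.isfinite(b), axis=1) for b in blocks], axis=0)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("%s analysis: dropped %d incomplete rows", label, dropped)
    P, Cg, age = P[complete], Cg[complete], age[complete]
    cov = covariates[complete] if covariates is not None else None

    reg = age_regression(P, age, covariates=cov, param_names=param_names,
                         covariate_names=covariate_names)
    c = cca(P, Cg)
    fx, fy = structure_correlations(c, P, Cg)
    sig = cca_significance(P, Cg, n_perm=n_perm, rng=rng)
    c.p_first = sig["p_perm"]
    mod = moderation(c.y_scores[:, 0], c.x_scores[:, 0], age, covariates=cov,
                     covariate_names=covariate_names)
    return {"label": label, "n": int(complete.sum()), "dropped": dropped,
            "age_regression": reg, "cca": c, "x_loadings": fx,
            "y_loadings": fy, "cca_significance": sig, "moderation": mod}


def fc_reanalysis(fc_matrix: np.ndarray, cognition: np.ndarray,
                  age: np.ndarray, covariates: np.ndarray | None = None,
                  **kwargs) -> dict:
    """Identical statistical machinery applied to Fisher-z functional
    connectivity values; outputs are labelled FC."""
    kwargs.setdefault("label", "FC")
    return brain_behaviour_analysis(fc_matrix, cognition, age,
                                    covariates=covariates, **kwargs)
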