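"""Robust brain-behavior coupling.

Ratings are regressed on signature responses (controlling for study via
dummy covariates) with iteratively reweighted least squares under a
Tukey bisquare loss, which down-weights gross outliers; the final IRLS
weights are reused for a weighted correlation between the two variables
after residualizing both against the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["RobustFit", "robust_regress", "weighted_correlation", "RobustRatingRegression"]


@dataclass
class RobustFit:
    coef: float  # slope: rating units per score unit
    se: float
    t: float
    p: float  # two-tailed, t reference with df = n - n_params
    df: int
    weights: np.ndarray  # final IRLS weights, in (0, 1]
    r_weighted: float
    params: np.ndarray  # intercept, slope, covariate coefficients
    converged: bool


def _cov_matrix(n: int, covariates) -> np.ndarray:
    """Intercept plus optional covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(n), cov])


def _design(x: np.ndarray, covariates) -> np.ndarray:
    Z = _cov_matrix(len(x), covariates)
    return np.column_stack([Z[:, :1], x, Z[:, 1:]])


def robust_regress(
    y,
    x,
    covariates=None,
    tuning_constant: float = 4.685,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RobustFit:
    """IRLS robust regression of ratings ``y`` on scores ``x``.

    Tukey bisquare loss (tuning constant 4.685 by default, the 95%-
    efficiency value), residual scale = MAD/0.6745, convergence on the
    coefficients. Inference on the slope uses the robust-fit covariance
    with a two-tailed t reference. Non-convergence is flagged on the
    returned fit, which carries the last iterate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = _design(x, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than regressors")
    # Exact linear relation: zero residual scale makes the IRLS weights
    # ill-defined, so return the (exact) least-squares fit with unit weights.
    ols_params, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ols_params
    if np.max(np.abs(resid)) <= 1e-10 * (1.0 + np.max(np.abs(y))):
        weights = np.ones(n)
        return RobustFit(
            coef=float(ols_params[1]),
            se=0.0,
            t=float("inf"),
            p=0.0,
            df=n - p,
            weights=weights,
            r_weighted=weighted_correlation(x, y, weights, covariates=covariates),
            params=np.asarray(ols_params, dtype=float),
            converged=True,
        )
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
    res = model.fit(conv="coefs", tol=tol, maxiter=max_iter, scale_est="mad")
    n_iter = len(res.fit_history.get("params", [])) if hasattr(res, "fit_history") else 0
    converged = n_iter < max_iter
    slope, se = float(res.params[1]), float(res.bse[1])
    df = n - p
    t = slope / se
    pval = float(2 * stats.t.sf(abs(t), df))
    weights = np.asarray(res.weights, dtype=float)
    r_w = weighted_correlation(x, y, weights, covariates=covariates)
    return RobustFit(
        coef=slope,
        se=se,
        t=float(t),
        p=pval,
        df=df,
        weights=weights,
        r_weighted=r_w,
        params=np.asarray(res.params, dtype=float),
        converged=converged,
    )


def weighted_correlation(x, y, weights, covariates=None) -> float:
    """Weighted Pearson correlation after weighted residualization.

    Both variables are residualized against an intercept plus the
    covariates by weighted least squares with the given weights, then
    r_w = sum w ex ey / sqrt(sum w ex^2 * sum w ey^2). With equal
    weights and no covariates this is the ordinary Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    Z = _cov_matrix(len(x), covariates)

    def residualize(v: np.ndarray) -> np.ndarray:
        zw = Z.T * w
        beta = np.linalg.solve(zw @ Z, zw @ v)
        return v - Z @ beta

    ex, ey = residualize(x), residualize(y)
    vx, vy = float(w @ ex**2), float(w @ ey**2)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance: correlation undefined")
    return float((w @ (ex * ey)) / np.sqrt(vx * vy))


class RobustRatingRegression(BaseEstimator, RegressorMixin):
    """Estimator form of the robust rating-on-score regression.

    ``fit(X, y)`` takes X with the signature score in column 0 and study
    dummy covariates in the remaining columns, y the VAS-style rating
    contrast per subject. Fitted attributes: ``coef_`` (slope), ``se_``,
    ``pvalue_``, ``weights_``, ``r_weighted_``, ``params_``,
    ``converged_``.
    """

    def __init__(self, tuning_constant: float = 4.685, tol: float = 1e-8, max_iter: int = 50):
        self.tuning_constant = tuning_constant
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cov = X[:, 1:] if X.shape[1] > 1 else None
        fit = robust_regress(
            y,
            X[:, 0],
            covariates=cov,
            tuning_constant=self.tuning_constant,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.coef_ = fit.coef
        self.se_ = fit.se
        self.pvalue_ = fit.p
        self.weights_ = fit.weights
        self.r_weighted_ = fit.r_weighted
        self.params_ = fit.params
        self.converged_ = fit.converged
        self.fit_ = fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xd = np.column_stack([np.ones(len(X)), X])
        return Xd @ self.params_[: Xd.shape[1]]
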