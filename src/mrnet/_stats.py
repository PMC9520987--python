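"""Small shared numerical routines: OLS, partial correlation, Fisher-z tests.

These are deliberately thin wrappers around numpy/scipy linear algebra; every
estimator that carries scientific meaning lives in the public modules.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    """Column-stack an intercept with an optional design matrix."""
    one = np.ones((n, 1))
    if X is None or X.size == 0:
        return one
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return np.hstack([one, X])


def ols(y: np.ndarray, X: np.ndarray):
    """Least squares of y on X (X already includes any intercept).

    Returns (coef, se, resid, sigma2, XtX_inv). Standard errors use the
    classical homoskedastic estimator with n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    return coef, se, resid, sigma2, XtX_inv


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of each column of ``values`` on covariates plus an intercept.

    With no covariates this is plain column centering.
    """
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    V = values.reshape(-1, 1) if one_d else values
    Z = add_intercept(covariates, V.shape[0])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("covariate matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(Z, V, rcond=None)
    R = V - Z @ coef
    return R.ravel() if one_d else R


def partial_correlation(corr: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    """Partial correlation of variables i and j given ``cond``.

    ``corr`` is a full correlation (or covariance) matrix; the result is
    obtained from the inverse of the sub-matrix on (i, j, cond).
    """
    if not cond:
        c = corr[np.ix_([i, j], [i, j])]
        denom = np.sqrt(c[0, 0] * c[1, 1])
        return float(c[0, 1] / denom) if denom > 0 else 0.0
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom <= 0:
        return 0.0
    r = -prec[0, 1] / denom
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_pvalue(r: float, n: int, n_cond: int) -> float:
    """Two-sided p-value for a (partial) correlation via the Fisher transform."""
    dof = n - n_cond - 3
    if dof <= 0:
        return 1.0
    r = float(np.clip(r, -0.999999999, 0.999999999))
    z = np.sqrt(dof) * np.arctanh(r)
    return float(2.0 * stats.norm.sf(abs(z)))
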