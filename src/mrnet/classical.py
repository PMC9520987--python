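"""Classical Mendelian-randomization estimators.

Implements the standard instrumental-variable toolkit on individual-level and
summary data:

* first-stage prediction of an exposure from one or more uncorrelated
  instruments, X_hat = alpha_1 IV_1 + ... + alpha_k IV_k;
* multivariable MR: regress the response on the predicted exposures, the
  coefficients being the causal effects (two-stage least squares);
* the Wald ratio beta_gy / beta_gx with a delta-method standard error;
* two-step MR mediation: tau (exposure -> mediator), gamma (mediator ->
  response), total effect beta, and the direct effect phi = beta - tau*gamma;
* two-sample MR prediction X_hat = sum_i beta_i(sample 1) * IV_i(sample 2);
* first-stage strength diagnostics (F statistic against a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import add_intercept, ols, residualize
from .errors import (
    CollinearityError,
    DataError,
    VariantLookupError,
    WeakInstrumentError,
)
from .synthetic import GenotypeMatrix

__all__ = [
    "FirstStageFit",
    "MREstimate",
    "MediationEstimate",
    "first_stage_predict",
    "multivariable_mr",
    "wald_ratio",
    "two_step_mediation",
    "two_sample_predict",
    "instrument_strength",
    "validate_summary_stats",
]

Z_95 = float(stats.norm.ppf(0.975))


@dataclass
class FirstStageFit:
    """Least-squares fit of one exposure on its instruments."""

    entity: str
    instrument_ids: list[str]
    alpha: np.ndarray  # per-instrument first-stage effects
    predicted: np.ndarray  # X_hat, fitted values from instruments only
    r_squared: float
    f_statistic: float
    exposure_values: np.ndarray | None = None  # residualized exposure (for 2SLS se)
    instrument_values: np.ndarray | None = None  # residualized instruments (bootstrap)

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DataError("r_squared outside [0, 1]")


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty."""

    exposure: str
    response: str
    beta: float
    se: float
    ci: tuple[float, float]
    method: str  # wald_ratio | multivariable_2sls | two_sample_ratio

    def __post_init__(self):
        if self.se < 0:
            raise DataError("standard error must be non-negative")
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.beta <= hi + 1e-12):
            raise DataError("confidence interval must contain the point estimate")


@dataclass
class MediationEstimate:
    """Two-step MR decomposition; phi = beta_total - tau*gamma by construction."""

    tau: float
    gamma: float
    beta_total: float
    phi: float
    ses: dict[str, float] = field(default_factory=dict)


def _check_full_rank(X: np.ndarray, names: list[str], context: str) -> None:
    if X.size == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column set via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[i] for i in sorted(piv[rank:])]
        raise CollinearityError(bad, context)


def first_stage_predict(
    exposure_values: np.ndarray,
    instruments: np.ndarray,
    covariates: np.ndarray | None = None,
    entity: str = "exposure",
    instrument_ids: list[str] | None = None,
) -> FirstStageFit:
    """Regress an exposure on its instruments (after covariate residualization).

    ``alpha`` are the joint least-squares coefficients; ``predicted`` are the
    fitted values from the instruments alone; the F statistic tests the joint
    significance of the instruments.
    """
    x = np.asarray(exposure_values, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(instruments, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    if Z.shape[0] != x.size:
        raise DataError("exposure and instrument row counts disagree")
    n, k = Z.shape
    ids = instrument_ids or [f"iv{i}" for i in range(k)]
    if covariates is not None and np.asarray(covariates).size:
        x = residualize(x, covariates)
        Z = residualize(Z, covariates)
    _check_full_rank(Z - Z.mean(axis=0), ids, "first stage")
    X = add_intercept(Z, n)
    coef, _, resid, _, _ = ols(x, X)
    predicted = X @ coef
    tss = float(((x - x.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    dof = n - k - 1
    if rss <= 1e-12 * max(tss, 1.0):
        f_stat = np.inf
    elif dof > 0 and r2 < 1.0:
        f_stat = (r2 / k) / ((1.0 - r2) / dof)
    else:
        f_stat = np.inf
    return FirstStageFit(
        entity=entity,
        instrument_ids=ids,
        alpha=coef[1:],
        predicted=predicted,
        r_squared=min(r2, 1.0),
        f_statistic=float(f_stat),
        exposure_values=x,
        instrument_values=Z,
    )


def multivariable_mr(
    response_values: np.ndarray,
    first_stages: list[FirstStageFit],
    covariates: np.ndarray | None = None,
    se_method: str = "sandwich",
    n_boot: int = 500,
    seed: int = 0,
) -> list[MREstimate]:
    """Two-stage least squares with several instrumented exposures.

    The response is regressed jointly on all predicted exposures X_hat; those
    coefficients are the causal effects. Standard errors use the 2SLS sandwich
    sigma^2 (X_hat' X_hat)^-1 with residuals evaluated at the *observed*
    exposures, or a seeded nonparametric bootstrap (``se_method="bootstrap"``).
    """
    if not first_stages:
        raise DataError("at least one first stage is required")
    y = np.asarray(response_values, dtype=float).ravel()
    if covariates is not None and np.asarray(covariates).size:
        y = residualize(y, covariates)
    Xhat = np.column_stack([f.predicted for f in first_stages])
    if Xhat.shape[0] != y.size:
        raise DataError("response length does not match first-stage samples")
    names = [f.entity for f in first_stages]
    _check_full_rank(Xhat - Xhat.mean(axis=0), names, "predicted exposures")
    D = add_intercept(Xhat, y.size)
    coef, _, _, _, DtD_inv = ols(y, D)
    betas = coef[1:]

    if all(f.exposure_values is not None for f in first_stages):
        Xobs = np.column_stack([f.exposure_values for f in first_stages])
        u = y - coef[0] - Xobs @ betas
        sigma2 = float(u @ u) / (y.size - D.shape[1])
    else:  # fall back to residuals at X_hat
        u = y - D @ coef
        sigma2 = float(u @ u) / (y.size - D.shape[1])
    se = np.sqrt(np.maximum(sigma2 * np.diag(DtD_inv)[1:], 0.0))

    if se_method == "bootstrap":
        se = _mvmr_bootstrap_se(y, first_stages, n_boot, seed)
    elif se_method != "sandwich":
        raise ValueError(f"unknown se_method {se_method!r}")

    out = []
    for name, b, s in zip(names, betas, se):
        out.append(
            MREstimate(
                exposure=name,
                response="response",
                beta=float(b),
                se=float(s),
                ci=(float(b - Z_95 * s), float(b + Z_95 * s)),
                method="multivariable_2sls",
            )
        )
    return out


def _mvmr_bootstrap_se(y, first_stages, n_boot, seed) -> np.ndarray:
    if any(f.instrument_values is None or f.exposure_values is None for f in first_stages):
        raise DataError("bootstrap requires stored exposure and instrument values")
    rng = np.random.default_rng(seed)
    n = y.size
    draws = np.empty((n_boot, len(first_stages)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        refits = [
            first_stage_predict(
                f.exposure_values[idx], f.instrument_values[idx], entity=f.entity
            )
            for f in first_stages
        ]
        Xh = np.column_stack([f.predicted for f in refits])
        D = add_intercept(Xh, n)
        coef, _, _, _ = np.linalg.lstsq(D, y[idx], rcond=None)
        draws[b] = coef[1:]
    return draws.std(axis=0, ddof=1)


def wald_ratio(
    beta_gy: float,
    se_gy: float,
    beta_gx: float,
    se_gx: float,
    weak_floor: float = 2.0,
    exposure: str = "exposure",
    response: str = "response",
) -> MREstimate:
    """Ratio estimate beta_gy / beta_gx with a first-order delta-method se.

    The denominator must clear a weak-instrument floor |beta_gx| / se_gx >=
    ``weak_floor`` (with se_gx == 0 only beta_gx != 0 is required).
    """
    if beta_gx == 0:
        raise WeakInstrumentError("variant has zero effect on the exposure")
    if se_gx > 0 and abs(beta_gx) / se_gx < weak_floor:
        raise WeakInstrumentError(
            f"|beta_gx|/se_gx = {abs(beta_gx) / se_gx:.2f} below floor {weak_floor}"
        )
    beta = beta_gy / beta_gx
    var = se_gy**2 / beta_gx**2 + beta_gy**2 * se_gx**2 / beta_gx**4
    se = float(np.sqrt(var))
    return MREstimate(
        exposure=exposure,
        response=response,
        beta=float(beta),
        se=se,
        ci=(beta - Z_95 * se, beta + Z_95 * se),
        method="wald_ratio",
    )


def _iv_slope(y: np.ndarray, fs: FirstStageFit, f_floor: float, label: str):
    """Second-stage slope of y on one predicted exposure, with 2SLS se."""
    if fs.f_statistic < f_floor:
        raise WeakInstrumentError(
            f"first stage for {label} has F = {fs.f_statistic:.2f} < {f_floor}"
        )
    D = add_intercept(fs.predicted.reshape(-1, 1), y.size)
    coef, _, _, _, DtD_inv = ols(y, D)
    if fs.exposure_values is not None:
        u = y - coef[0] - fs.exposure_values * coef[1]
    else:
        u = y - D @ coef
    sigma2 = float(u @ u) / (y.size - 2)
    se = float(np.sqrt(max(sigma2 * DtD_inv[1, 1], 0.0)))
    return float(coef[1]), se


def two_step_mediation(
    exposure: np.ndarray,
    mediator: np.ndarray,
    response: np.ndarray,
    iv1: np.ndarray,
    iv2: np.ndarray,
    f_floor: float = 10.0,
) -> MediationEstimate:
    """Two-step MR mediation decomposition.

    tau: effect of the exposure on the mediator (exposure instrumented by
    iv1); gamma: effect of the mediator on the response (instrumented by
    iv2); beta_total: effect of the exposure on the response (iv1). The
    direct effect is phi = beta_total - tau * gamma. The standard error of
    phi propagates the three (independent-stage) uncertainties:
    Var(phi) ~= Var(beta) + gamma^2 Var(tau) + tau^2 Var(gamma).
    """
    x = np.asarray(exposure, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    y = np.asarray(response, dtype=float).ravel()
    if not (x.size == m.size == y.size):
        raise DataError("exposure, mediator and response lengths differ")
    fs_x = first_stage_predict(x, np.asarray(iv1, dtype=float), entity="exposure")
    fs_m = first_stage_predict(m, np.asarray(iv2, dtype=float), entity="mediator")
    tau, se_tau = _iv_slope(m, fs_x, f_floor, "exposure (iv1)")
    gamma, se_gamma = _iv_slope(y, fs_m, f_floor, "mediator (iv2)")
    beta, se_beta = _iv_slope(y, fs_x, f_floor, "exposure (iv1)")
    phi = beta - tau * gamma
    se_phi = float(
        np.sqrt(se_beta**2 + gamma**2 * se_tau**2 + tau**2 * se_gamma**2)
    )
    return MediationEstimate(
        tau=tau,
        gamma=gamma,
        beta_total=beta,
        phi=phi,
        ses={"tau": se_tau, "gamma": se_gamma, "beta_total": se_beta, "phi": se_phi},
    )


def validate_summary_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory columns, id uniqueness and non-negative ses."""
    required = {"variant_id", "beta", "se"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"summary table missing columns: {sorted(missing)}")
    if table["variant_id"].duplicated().any():
        dup = table.loc[table["variant_id"].duplicated(), "variant_id"].tolist()
        raise DataError(f"duplicate variant ids in summary table: {dup}")
    if (table["se"] < 0).any():
        raise DataError("summary table contains negative standard errors")
    return table


def two_sample_predict(
    summary_sample1: pd.DataFrame,
    genotypes_sample2: GenotypeMatrix,
    corr_warn_threshold: float = 0.2,
) -> np.ndarray:
    """Predicted exposure for cohort 2: X_hat = sum_i beta_i(sample 1) * IV_i(sample 2).

    Variants should be mutually uncorrelated; a warning is emitted when any
    pairwise dosage correlation in cohort 2 exceeds ``corr_warn_threshold``.
    """
    table = validate_summary_stats(summary_sample1)
    missing = [v for v in table["variant_id"] if v not in genotypes_sample2.variant_ids]
    if missing:
        raise VariantLookupError(missing)
    G = np.column_stack([genotypes_sample2.column(v) for v in table["variant_id"]])
    if G.shape[1] > 1:
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(G, rowvar=False)
        np.fill_diagonal(C, 0.0)
        if np.nanmax(np.abs(C)) > corr_warn_threshold:
            warnings.warn(
                "summary variants are correlated in cohort 2; the two-sample "
                "prediction assumes mutually uncorrelated instruments",
                stacklevel=2,
            )
    return G @ table["beta"].to_numpy(dtype=float)


def instrument_strength(fit: FirstStageFit, threshold: float = 10.0):
    """Pass/fail of the first IV assumption via the first-stage F statistic."""
    n = fit.predicted.size
    k = len(fit.instrument_ids)
    report = {
        "entity": fit.entity,
        "f_statistic": fit.f_statistic,
        "r_squared": fit.r_squared,
        "df_num": k,
        "df_den": n - k - 1,
        "threshold": threshold,
    }
    return fit.f_statistic >= threshold, report
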