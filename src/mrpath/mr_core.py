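"""Univariable two-sample MR estimators and sensitivity statistics.

Implements the Wald ratio (single SNP), the inverse-variance-weighted (IVW)
estimator — algebraically a weighted regression of outcome betas on exposure
betas through the origin — MR-Egger regression with a free intercept as a
directional-pleiotropy test, Cochran's Q heterogeneity statistic over
per-SNP ratio estimates, and the log-odds → OR/CI conversion used in all
reporting.

Default IVW inference is multiplicative random effects: the fixed-effect
standard error is inflated by sqrt(Q/(J−1)) whenever that exceeds one, and
never shrunk below it. Egger slope and intercept use t inference with J−2
degrees of freedom; IVW uses the normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EstimationError, InsufficientInstrumentsError
from .summary_io import HarmonizedPair

Z95 = float(sps.norm.ppf(0.975))

#: fixed column order of the tidy results table
RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "pvalue",
    "or_value",
    "ci_low",
    "ci_high",
    "egger_intercept",
    "egger_intercept_p",
    "q_statistic",
    "q_pvalue",
]


@dataclass
class MREstimate:
    """One causal effect estimate (beta on the outcome's log-odds or SD scale)."""

    exposure_name: str
    outcome_name: str
    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_value: float
    ci_low: float
    ci_high: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    q_statistic: float | None = None
    q_pvalue: float | None = None


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI low, 95% CI high) from a log-odds beta and its SE."""
    if se <= 0:
        raise EstimationError("se must be positive")
    with np.errstate(over="ignore"):  # extreme betas legitimately map to inf OR
        return (
            float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)),
        )


def _make_estimate(
    exposure: str,
    outcome: str,
    method: str,
    n_snp: int,
    beta: float,
    se: float,
    pvalue: float | None = None,
    **extra,
) -> MREstimate:
    if pvalue is None:
        pvalue = float(2 * sps.norm.sf(abs(beta) / se))
    or_value, ci_low, ci_high = to_odds_scale(beta, se)
    return MREstimate(
        exposure_name=exposure,
        outcome_name=outcome,
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        pvalue=pvalue,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        **extra,
    )


def estimate_from_summary(
    beta: float,
    se: float,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    method: str = "ivw",
    n_snp: int = 1,
) -> MREstimate:
    """Package an externally reported (beta, se) as an MREstimate."""
    return _make_estimate(exposure_name, outcome_name, method, n_snp, beta, se)


def _kept_arrays(pair: HarmonizedPair):
    k = pair.kept
    bx = k["beta_exp"].to_numpy(float)
    sx = k["se_exp"].to_numpy(float)
    by = k["beta_out"].to_numpy(float)
    sy = k["se_out"].to_numpy(float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise EstimationError("standard errors must be positive")
    return bx, sx, by, sy


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    The default SE is the first-order delta method se_out/|beta_exp|;
    ``second_order=True`` adds the exposure-uncertainty term
    beta_out²·se_exp²/beta_exp⁴ under the square root.
    """
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined: exposure beta is zero")
    if se_exp <= 0 or se_out <= 0:
        raise EstimationError("standard errors must be positive")
    beta = beta_out / beta_exp
    var = se_out**2 / beta_exp**2
    if second_order:
        var += beta_out**2 * se_exp**2 / beta_exp**4
    return _make_estimate(exposure_name, outcome_name, "wald_ratio", 1, beta, float(np.sqrt(var)))


def cochran_q(pair: HarmonizedPair, pooled_beta: float) -> tuple[float, float]:
    """Cochran's Q over per-SNP Wald ratios, weights 1/se(ratio)².

    Computed in the numerically equivalent form
    Q = Σ_j (beta_out_j − pooled·beta_exp_j)² / se_out_j², which avoids
    dividing by small exposure betas; p from chi-square with J−1 df.
    """
    bx, _, by, sy = _kept_arrays(pair)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 SNPs")
    q = float(np.sum((by - pooled_beta * bx) ** 2 / sy**2))
    return q, float(sps.chi2.sf(q, j - 1))


def ivw(pair: HarmonizedPair, *, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate over the kept SNPs of a pair.

    beta = Σ w_j β_xj β_yj / Σ w_j β_xj² with w_j = 1/se_yj² — weighted
    least squares through the origin. With ``random_effects`` (default) the
    fixed-effect SE is multiplied by sqrt(Q/(J−1)) when that ratio exceeds
    one (multiplicative random effects with a floor at the fixed-effect SE).
    """
    bx, _, by, sy = _kept_arrays(pair)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError(
            "IVW needs at least 2 SNPs; use wald_ratio for a single instrument"
        )
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise EstimationError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    q, q_p = cochran_q(pair, beta)
    if random_effects:
        se *= float(np.sqrt(max(1.0, q / (j - 1))))
    return _make_estimate(
        pair.exposure_name,
        pair.outcome_name,
        "ivw",
        j,
        beta,
        se,
        q_statistic=q,
        q_pvalue=q_p,
    )


def mr_egger(pair: HarmonizedPair, *, constrain_intercept: bool = False) -> MREstimate:
    """MR-Egger regression: weighted fit of β_yj = α + β·β_xj.

    Exposure betas are oriented non-negative first (each SNP's beta pair is
    sign-flipped so β_xj ≥ 0); weights are 1/se_yj². Slope and intercept
    p-values use t with J−2 df and the estimated residual variance, the
    conventional Egger inference. A non-null intercept indicates
    directional horizontal pleiotropy. ``constrain_intercept=True`` forces
    α = 0, an internal-consistency mode whose slope must agree with IVW.
    """
    bx, _, by, sy = _kept_arrays(pair)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    if constrain_intercept:
        x = bx[:, None]
    else:
        x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    try:
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise EstimationError("degenerate Egger design (constant exposure betas)") from None
    coef = cov_unit @ (x.T @ (w * by))
    resid = by - x @ coef
    dof = j - x.shape[1]
    sigma2 = float(np.sum(w * resid**2)) / dof
    cov = cov_unit * sigma2
    if constrain_intercept:
        beta = float(coef[0])
        se_beta = float(np.sqrt(cov[0, 0]))
        alpha, se_alpha = 0.0, float("nan")
    else:
        alpha, beta = float(coef[0]), float(coef[1])
        se_alpha, se_beta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_beta = float(2 * sps.t.sf(abs(beta) / se_beta, dof))
    p_alpha = (
        float("nan")
        if constrain_intercept
        else float(2 * sps.t.sf(abs(alpha) / se_alpha, dof))
    )
    # Rücker's Q': heterogeneity about the Egger fit, chi-square with J-2 df
    q = float(np.sum(w * resid**2))
    q_p = float(sps.chi2.sf(q, dof))
    return _make_estimate(
        pair.exposure_name,
        pair.outcome_name,
        "mr_egger",
        j,
        beta,
        se_beta,
        pvalue=p_beta,
        egger_intercept=alpha,
        egger_intercept_p=p_alpha,
        q_statistic=q,
        q_pvalue=q_p,
    )


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tidy results table, one row per estimate, fixed column order."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "exposure": e.exposure_name,
                "outcome": e.outcome_name,
                "method": e.method,
                "n_snp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "pvalue": e.pvalue,
                "or_value": e.or_value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "egger_intercept": e.egger_intercept,
                "egger_intercept_p": e.egger_intercept_p,
                "q_statistic": e.q_statistic,
                "q_pvalue": e.q_pvalue,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
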