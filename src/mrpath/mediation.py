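"""Two-step mediation MR and multivariable MR (MVMR).

Two-step mediation combines three univariable MR legs — exposure→outcome
(total effect β_EO), exposure→mediator (β_EM) and mediator→outcome (β_MO) —
by the product of coefficients: the indirect effect is β_EM·β_MO and the
proportion mediated is (β_EM·β_MO)/β_EO. The no-interaction assumption of
two-step MR (exposure and mediator do not interact on the outcome) is not
testable from summary data and is simply assumed.

MVMR regresses outcome betas jointly on several exposures' betas (weighted,
no intercept) to estimate each exposure's direct effect conditional on the
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    EstimationError,
    InsufficientInstrumentsError,
)
from .mr_core import MREstimate, to_odds_scale
from .summary_io import HarmonizedPair

logger = logging.getLogger("mrpath")


@dataclass
class MediationResult:
    """Decomposition of a total effect into mediated and direct components."""

    exposure_name: str
    mediator_name: str
    outcome_name: str
    beta_EO: float
    beta_EM: float
    beta_MO: float
    indirect: float
    direct: float
    proportion_mediated: float
    se_proportion: float | None = None
    flags: list[str] = field(default_factory=list)
    component_estimates: dict[str, MREstimate] | None = None

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percentage (the reporting scale)."""
        return 100.0 * self.proportion_mediated


def two_step_mediation(
    est_EO: MREstimate,
    est_EM: MREstimate,
    est_MO: MREstimate,
) -> MediationResult:
    """Product-of-coefficients mediation from three MR legs.

    ``se_proportion`` uses the first-order delta method treating the three
    betas as independent, which is customary for non-overlapping two-sample
    designs. A proportion outside [0, 1] (sign-discordant chain) is returned
    with a ``proportion_outside_unit_interval`` flag, not raised.
    """
    if est_EO.beta == 0:
        raise EstimationError("total effect beta_EO is zero: proportion mediated undefined")
    names_ok = (
        est_EO.exposure_name == est_EM.exposure_name
        and est_EM.outcome_name == est_MO.exposure_name
        and est_MO.outcome_name == est_EO.outcome_name
    )
    if not names_ok:
        logger.warning(
            "mediation chain names look inconsistent: E->O %s->%s, E->M %s->%s, M->O %s->%s",
            est_EO.exposure_name,
            est_EO.outcome_name,
            est_EM.exposure_name,
            est_EM.outcome_name,
            est_MO.exposure_name,
            est_MO.outcome_name,
        )

    b_eo, b_em, b_mo = est_EO.beta, est_EM.beta, est_MO.beta
    indirect = b_em * b_mo
    direct = b_eo - indirect
    proportion = indirect / b_eo

    # delta method on p = b_em * b_mo / b_eo with independent components
    grad = np.array([b_mo / b_eo, b_em / b_eo, -indirect / b_eo**2])
    ses = np.array([est_EM.se, est_MO.se, est_EO.se])
    se_p = float(np.sqrt(np.sum(grad**2 * ses**2)))

    flags = []
    if est_EM.outcome_name == est_EO.exposure_name:
        flags.append("mediator_equals_exposure")
    if not 0.0 <= proportion <= 1.0:
        flags.append("proportion_outside_unit_interval")
        logger.info(
            "%s -> %s -> %s: proportion mediated %.3f outside [0, 1]",
            est_EO.exposure_name,
            est_EM.outcome_name,
            est_EO.outcome_name,
            proportion,
        )
    return MediationResult(
        exposure_name=est_EO.exposure_name,
        mediator_name=est_EM.outcome_name,
        outcome_name=est_EO.outcome_name,
        beta_EO=b_eo,
        beta_EM=b_em,
        beta_MO=b_mo,
        indirect=indirect,
        direct=direct,
        proportion_mediated=proportion,
        se_proportion=se_p,
        flags=flags,
        component_estimates={"EO": est_EO, "EM": est_EM, "MO": est_MO},
    )


def mediation_to_frame(results) -> pd.DataFrame:
    """Tidy mediation report: one row per chain, proportion in percent."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure_name,
                "mediator": r.mediator_name,
                "outcome": r.outcome_name,
                "beta_EO": r.beta_EO,
                "beta_EM": r.beta_EM,
                "beta_MO": r.beta_MO,
                "indirect": r.indirect,
                "direct": r.direct,
                "proportion_pct": r.proportion_pct,
                "se_proportion": r.se_proportion,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MvmrEstimate:
    """Joint (direct) effects of several exposures on one outcome."""

    exposure_names: list[str]
    outcome_name: str
    table: pd.DataFrame = field(repr=False)  # exposure, beta, se, pvalue, or_value, ci_low, ci_high
    n_snp: int = 0


def _align_pairs(pairs: list[HarmonizedPair]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inner-join kept rows of all pairs on snp_id, aligned to the first
    pair's outcome orientation (pairs harmonized to different exposure
    alleles can carry opposite outcome signs for the same SNP)."""
    frames = []
    for i, p in enumerate(pairs):
        k = p.kept[["snp_id", "beta_exp", "beta_out", "se_out"]].copy()
        k.columns = ["snp_id", f"bx{i}", f"by{i}", f"sy{i}"]
        frames.append(k)
    merged = frames[0]
    for k in frames[1:]:
        merged = merged.merge(k, on="snp_id", how="inner")
    merged = merged.sort_values("snp_id").reset_index(drop=True)

    drop = np.zeros(len(merged), dtype=bool)
    for i in range(1, len(pairs)):
        same = np.isclose(merged[f"by{i}"], merged["by0"], rtol=1e-6, atol=1e-12)
        flipped = np.isclose(merged[f"by{i}"], -merged["by0"], rtol=1e-6, atol=1e-12)
        merged.loc[flipped & ~same, f"bx{i}"] *= -1.0
        bad = ~(same | flipped)
        if bad.any():
            logger.warning(
                "mvmr: %d SNP(s) with irreconcilable outcome betas dropped", int(bad.sum())
            )
            drop |= bad.to_numpy()
    merged = merged.loc[~drop].reset_index(drop=True)

    x = merged[[f"bx{i}" for i in range(len(pairs))]].to_numpy(float)
    y = merged["by0"].to_numpy(float)
    sy = merged["sy0"].to_numpy(float)
    return merged, np.column_stack([x]), (y, sy)  # type: ignore[return-value]


def mvmr(pairs, *, random_effects: bool = True) -> MvmrEstimate:
    """Multivariable MR: weighted regression of outcome betas on the matrix
    of exposure betas, no intercept, weights 1/se_out².

    ``pairs`` is one HarmonizedPair per exposure against the same outcome;
    SNPs are inner-joined. Exposures whose betas are exactly zero at every
    SNP are reported with beta 0 and NaN se (they carry no information);
    rank deficiency among the remaining exposures raises
    :class:`CollinearityError` naming the offending exposures. SEs come
    from the weighted-least-squares covariance with the residual variance
    floored at 1; p-values are two-sided normal.
    """
    pairs = list(pairs.values()) if isinstance(pairs, dict) else list(pairs)
    if len(pairs) < 2:
        raise EstimationError("MVMR needs at least 2 exposures")
    outcome = pairs[0].outcome_name
    if any(p.outcome_name != outcome for p in pairs):
        raise EstimationError("all pairs must share the same outcome")
    names = [p.exposure_name for p in pairs]

    merged, x, (y, sy) = _align_pairs(pairs)
    j, k = x.shape
    if j < k + 1:
        raise InsufficientInstrumentsError(
            f"MVMR needs at least {k + 1} shared SNPs, found {j}"
        )

    nonzero = [i for i in range(k) if np.any(x[:, i] != 0)]
    x_fit = x[:, nonzero]
    if np.linalg.matrix_rank(x_fit) < len(nonzero):
        corr = np.corrcoef(x_fit, rowvar=False)
        offenders = sorted(
            {
                names[nonzero[a]]
                for a in range(len(nonzero))
                for b in range(a + 1, len(nonzero))
                if abs(corr[a, b]) > 0.999
            }
            | {
                names[nonzero[b]]
                for a in range(len(nonzero))
                for b in range(a + 1, len(nonzero))
                if abs(corr[a, b]) > 0.999
            }
        )
        raise CollinearityError(
            f"rank-deficient exposure matrix; collinear exposures: {offenders or names}"
        )

    w = 1.0 / sy**2
    xtwx = x_fit.T @ (w[:, None] * x_fit)
    cov_unit = np.linalg.inv(xtwx)
    coef = cov_unit @ (x_fit.T @ (w * y))
    resid = y - x_fit @ coef
    dof = j - len(nonzero)
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / dof) if random_effects else 1.0
    cov = cov_unit * sigma2

    beta = np.full(k, 0.0)
    se = np.full(k, np.nan)
    beta[nonzero] = coef
    se[nonzero] = np.sqrt(np.diag(cov))

    rows = []
    for i, name in enumerate(names):
        if np.isnan(se[i]):
            rows.append(
                {
                    "exposure": name,
                    "beta": 0.0,
                    "se": np.nan,
                    "pvalue": np.nan,
                    "or_value": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            continue
        p = float(2 * sps.norm.sf(abs(beta[i]) / se[i]))
        or_value, ci_low, ci_high = to_odds_scale(beta[i], se[i])
        rows.append(
            {
                "exposure": name,
                "beta": float(beta[i]),
                "se": float(se[i]),
                "pvalue": p,
                "or_value": or_value,
                "ci_low": ci_low,
                "ci_high": ci_high,
            }
        )
    return MvmrEstimate(
        exposure_names=names,
        outcome_name=outcome,
        table=pd.DataFrame(rows),
        n_snp=j,
    )
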