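"""Bayesian colocalization of two traits at a locus.

Per-SNP approximate Bayes factors (normal-normal marginal likelihood
ratios) feed a five-hypothesis posterior model: H0 neither trait has a
causal variant in the window; H1/H2 only trait 1/2 does; H3 both do but
distinct variants; H4 both share a single causal variant. Each hypothesis
assumes at most one causal variant per trait. All sums run in log space
(log-sum-exp), so z-scores of 50 and beyond remain finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConfigError, DataError, EstimationError
from .summary_io import SummaryStats

#: conventional single-variant priors: P(causal for trait 1), trait 2, both
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: conventional prior SDs for the causal effect size, by trait type
PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    locus_id: str
    n_snp: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: tuple[float, float, float]
    decision: bool

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def abf(beta, se, prior_sd):
    """Log approximate Bayes factor for association at one SNP.

    With V = se², W = prior_sd² and z = beta/se:
    log-ABF = 0.5·[log(V/(V+W)) + z²·W/(V+W)] — the log ratio of the
    marginal likelihood of the observed beta under effect ~ N(0, W) to its
    likelihood under no effect. Positive values favor association.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise EstimationError("se must be positive")
    if prior_sd <= 0:
        raise EstimationError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    out = 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b, -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def window(stats: SummaryStats, chromosome: str, anchor_pos: int, window_kb: int = 500) -> SummaryStats:
    """Restrict to SNPs within ±window_kb of an anchor position."""
    rec = stats.records
    keep = (
        rec["chromosome"].astype(str) == str(chromosome)
    ) & (np.abs(rec["position"] - anchor_pos) <= window_kb * 1000)
    return SummaryStats(
        trait_name=stats.trait_name,
        records=rec.loc[keep].reset_index(drop=True),
        trait_type=stats.trait_type,
        n_cases=stats.n_cases,
        n_controls=stats.n_controls,
    )


def colocalize(
    trait1: SummaryStats,
    trait2: SummaryStats,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    *,
    locus_id: str = "locus",
    pph4_threshold: float = 0.75,
) -> ColocResult:
    """Five-hypothesis colocalization over the shared SNPs of a window.

    Prior effect SDs default by trait type (0.15 quantitative, 0.2 binary
    log-odds). The decision flag is PPH4 > ``pph4_threshold`` (default
    0.75); all five posteriors are reported regardless.
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise ConfigError("priors must be positive and sum below 1")
    sd1 = PRIOR_SD[trait1.trait_type] if prior_sd1 is None else prior_sd1
    sd2 = PRIOR_SD[trait2.trait_type] if prior_sd2 is None else prior_sd2

    r1 = trait1.records.set_index("snp_id")
    r2 = trait2.records.set_index("snp_id")
    shared = sorted(set(r1.index) & set(r2.index))
    if len(shared) < 2:
        raise DataError(
            f"colocalization needs at least 2 shared SNPs at {locus_id}, found {len(shared)}"
        )
    l1 = abf(r1.loc[shared, "beta"].to_numpy(), r1.loc[shared, "se"].to_numpy(), sd1)
    l2 = abf(r2.loc[shared, "beta"].to_numpy(), r2.loc[shared, "se"].to_numpy(), sd2)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)  # same causal SNP in both traits

    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12),
            np.log(p12) + s12,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocResult(
        locus_id=locus_id,
        n_snp=len(shared),
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        priors=(p1, p2, p12),
        decision=bool(post[4] > pph4_threshold),
    )
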