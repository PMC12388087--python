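"""Synthetic GWAS summary statistics with a known causal structure.

The generator emulates the statistical shape of the consortium data the
pipeline is designed for: a 16S microbiome-scale exposure GWAS
(n ≈ 18,340), a plasma-metabolite GWAS (n ≈ 7,824) and a rare binary
outcome on the log-odds scale (n ≈ 408,241 with ~0.27% cases). Effects
follow an exposure→mediator→outcome chain with an optional direct path and
optional pleiotropy; per-SNP sampling noise is scaled by allele frequency
and sample size, LD acts block-wise on the noise z-scores, and allele
labels/orientations are randomized with the ground truth recorded — every
downstream oracle test reads its expected values from that record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError
from .instruments import LdMatrix
from .mr_core import MREstimate, estimate_from_summary
from .summary_io import CANONICAL_COLUMNS, SummaryStats

ALLELES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generator settings; the defaults mirror the cohort scales and
    instrument strengths of consortium-scale microbiome/metabolite GWAS.

    ``gamma_sd`` (per-instrument effect SD on the exposure, 0.08 by default)
    yields median single-SNP F-statistics of a few tens at n_exp = 18,340 —
    the range reported for metabolite and microbiome instruments. The rare
    binary outcome uses the effective-sample-size scaling
    se = 1/sqrt(2p(1−p)·n·φ(1−φ)).
    """

    seed: int = 0
    n_snp: int = 60
    n_instruments: int = 20
    n_med_instruments: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 18_340
    n_med: int = 7_824
    n_out: int = 408_241
    outcome_case_fraction: float = 1086 / 408_241
    gamma_sd: float = 0.08
    delta_sd: float = 0.12
    beta_EM_true: float = 0.4
    beta_MO_true: float = 0.5
    beta_direct_true: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_block_size: int = 1
    ld_within_block_r: float = 0.0
    randomize_orientation: bool = True

    def validate(self) -> None:
        if self.n_instruments + self.n_med_instruments > self.n_snp:
            raise ConfigError("n_instruments + n_med_instruments must not exceed n_snp")
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise ConfigError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 < self.outcome_case_fraction < 1:
            raise ConfigError("outcome_case_fraction must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.ld_block_size < 1 or not 0 <= self.ld_within_block_r < 1:
            raise ConfigError("invalid LD block settings")
        if self.gamma_sd < 0 or self.delta_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigError("effect SDs must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    snp_ids: list[str]
    gamma: np.ndarray  # true per-SNP effects on the exposure
    delta: np.ndarray  # mediator-specific instrument effects
    alpha_med: np.ndarray  # pleiotropic effects on the mediator
    alpha_out: np.ndarray  # pleiotropic effects on the outcome
    true_exp_eff: np.ndarray
    true_med_eff: np.ndarray
    true_out_eff: np.ndarray
    # canonical-orientation *observed* betas, before label randomization
    canonical_beta_exp: np.ndarray
    canonical_beta_med: np.ndarray
    canonical_beta_out: np.ndarray
    orientation_med: np.ndarray  # +1 canonical, -1 alleles swapped in the mediator file
    orientation_out: np.ndarray
    instrument_ids: list[str]
    med_instrument_ids: list[str]
    total_effect: float
    indirect_effect: float
    direct_effect: float
    proportion_mediated: float

    def to_json(self, path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class Simulation(NamedTuple):
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LdMatrix
    truth: GroundTruth


def _block_noise(rng: np.random.Generator, n_snp: int, block: int, r: float) -> np.ndarray:
    """Standard-normal z noise with compound-symmetric correlation r inside
    consecutive blocks of the given size."""
    z = rng.standard_normal(n_snp)
    if block <= 1 or r == 0:
        return z
    out = np.empty(n_snp)
    for start in range(0, n_snp, block):
        stop = min(start + block, n_snp)
        shared = rng.standard_normal()
        out[start:stop] = np.sqrt(r) * shared + np.sqrt(1 - r) * z[start:stop]
    return out


def _records(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    p = 2 * sps.norm.sf(np.abs(beta) / se)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": n,
        }
    )
    return df[CANONICAL_COLUMNS]


def simulate(config: SimConfig) -> Simulation:
    """Generate exposure/mediator/outcome summary statistics, the LD matrix
    and the ground-truth record. Deterministic given ``config.seed``.

    Per SNP j with minor-allele frequency p_j ~ U(maf_range):
    instrument effect γ_j ~ N(0, gamma_sd²) for the first ``n_instruments``
    SNPs; mediator-specific instrument effect δ_j ~ N(0, delta_sd²) for the
    next ``n_med_instruments``. True effects:
    exposure γ_j; mediator β_EM·γ_j + δ_j + s_j·α_med,j; outcome (log-odds)
    (β_direct + β_EM·β_MO)·γ_j + β_MO·δ_j + s_j·α_out,j, where s_j aligns
    directional pleiotropy with the exposure-increasing allele. Observed
    beta = true + z·se with se = 1/sqrt(2p(1−p)n) (quantitative) or
    1/sqrt(2p(1−p)·n·φ(1−φ)) (binary outcome, φ the case fraction); noise
    z-scores share the within-block LD correlation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snp

    snp_ids = [f"rs{j:06d}" for j in range(1, m + 1)]
    chrom = np.repeat("1", m)
    # blocks laid out contiguously, 5 kb spacing inside, 20 Mb between blocks
    block = config.ld_block_size
    block_idx = np.arange(m) // block
    within = np.arange(m) % block
    pos = (block_idx * 20_000_000 + within * 5_000 + 1_000_000).astype(int)

    maf = rng.uniform(*config.maf_range, size=m)
    gamma = np.zeros(m)
    gamma[: config.n_instruments] = rng.normal(0, config.gamma_sd, config.n_instruments)
    delta = np.zeros(m)
    med_slice = slice(config.n_instruments, config.n_instruments + config.n_med_instruments)
    delta[med_slice] = rng.normal(0, config.delta_sd, config.n_med_instruments)

    sign = np.sign(gamma)
    sign[sign == 0] = 1.0
    alpha_med = np.zeros(m)
    alpha_out = np.zeros(m)
    if config.pleiotropy_mode != "none":
        loc = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        ins = slice(0, config.n_instruments)
        alpha_med[ins] = rng.normal(loc, config.pleiotropy_sd, config.n_instruments)
        alpha_out[ins] = rng.normal(loc, config.pleiotropy_sd, config.n_instruments)
        # directional pleiotropy is defined relative to the exposure-increasing allele
        alpha_med[ins] *= sign[ins] if config.pleiotropy_mode == "directional" else 1.0
        alpha_out[ins] *= sign[ins] if config.pleiotropy_mode == "directional" else 1.0

    total = config.beta_direct_true + config.beta_EM_true * config.beta_MO_true
    true_exp = gamma
    true_med = config.beta_EM_true * gamma + delta + alpha_med
    true_out = total * gamma + config.beta_MO_true * delta + alpha_out

    het = 2 * maf * (1 - maf)
    phi = config.outcome_case_fraction
    se_exp = 1 / np.sqrt(het * config.n_exp)
    se_med = 1 / np.sqrt(het * config.n_med)
    se_out = 1 / np.sqrt(het * config.n_out * phi * (1 - phi))

    r = config.ld_within_block_r
    obs_exp = true_exp + _block_noise(rng, m, block, r) * se_exp
    obs_med = true_med + _block_noise(rng, m, block, r) * se_med
    obs_out = true_out + _block_noise(rng, m, block, r) * se_out

    # allele pair per SNP (may be palindromic); canonical effect allele first
    ea = rng.choice(ALLELES, size=m)
    oa = np.array([rng.choice([a for a in "ACGT" if a != e]) for e in ea])

    def _trait_frame(beta, se, n, flips, strand):
        ea_t = ea.copy()
        oa_t = oa.copy()
        beta_t = beta.copy()
        eaf_t = maf.copy()
        ea_t[flips], oa_t[flips] = oa_t[flips].copy(), ea_t[flips].copy()
        beta_t[flips] *= -1
        eaf_t[flips] = 1 - eaf_t[flips]
        if strand is not None:
            ea_t = np.array([_COMP[a] if s else a for a, s in zip(ea_t, strand)])
            oa_t = np.array([_COMP[a] if s else a for a, s in zip(oa_t, strand)])
        return _records(snp_ids, chrom, pos, ea_t, oa_t, eaf_t, beta_t, se, n)

    no_flip = np.zeros(m, dtype=bool)
    if config.randomize_orientation:
        flips_med = rng.random(m) < 0.5
        flips_out = rng.random(m) < 0.5
        # strand relabeling only for non-palindromic pairs (harmonization
        # resolves it); palindromic strand flips are left to the frequency rule
        pal = np.array([_COMP[a] == b for a, b in zip(ea, oa)])
        strand_med = (rng.random(m) < 0.5) & ~pal
        strand_out = (rng.random(m) < 0.5) & ~pal
    else:
        flips_med = flips_out = no_flip
        strand_med = strand_out = None

    exposure = SummaryStats(
        "exposure",
        _records(snp_ids, chrom, pos, ea, oa, maf, obs_exp, se_exp, config.n_exp),
        "quantitative",
    )
    mediator = SummaryStats(
        "mediator",
        _trait_frame(obs_med, se_med, config.n_med, flips_med, strand_med),
        "quantitative",
    )
    n_cases = int(round(config.n_out * phi))
    outcome = SummaryStats(
        "outcome",
        _trait_frame(obs_out, se_out, config.n_out, flips_out, strand_out),
        "binary",
        n_cases=n_cases,
        n_controls=config.n_out - n_cases,
    )

    n_blocks = int(np.ceil(m / block))
    ld_r = np.zeros((m, m))
    for b in range(n_blocks):
        lo, hi = b * block, min((b + 1) * block, m)
        ld_r[lo:hi, lo:hi] = r
    np.fill_diagonal(ld_r, 1.0)
    ld = LdMatrix(snp_ids, ld_r)

    truth = GroundTruth(
        snp_ids=snp_ids,
        gamma=gamma,
        delta=delta,
        alpha_med=alpha_med,
        alpha_out=alpha_out,
        true_exp_eff=true_exp,
        true_med_eff=true_med,
        true_out_eff=true_out,
        canonical_beta_exp=obs_exp,
        canonical_beta_med=obs_med,
        canonical_beta_out=obs_out,
        orientation_med=np.where(flips_med, -1, 1),
        orientation_out=np.where(flips_out, -1, 1),
        instrument_ids=snp_ids[: config.n_instruments],
        med_instrument_ids=snp_ids[med_slice],
        total_effect=total,
        indirect_effect=config.beta_EM_true * config.beta_MO_true,
        direct_effect=config.beta_direct_true,
        proportion_mediated=(
            config.beta_EM_true * config.beta_MO_true / total if total != 0 else float("nan")
        ),
    )
    return Simulation(exposure, mediator, outcome, ld, truth)


@dataclass
class MvmrSimulation:
    """Per-SNP exposure/outcome betas for a joint (multi-exposure) fit."""

    exposure_betas: pd.DataFrame  # snp_id + one column per exposure
    exposure_ses: pd.DataFrame
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    true_effects: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def to_pairs(self, outcome_name: str = "outcome") -> list:
        """One already-harmonized exposure/outcome pair per exposure."""
        from .summary_io import HarmonizedPair

        pairs = []
        for col in self.exposure_betas.columns:
            if col == "snp_id":
                continue
            rows = pd.DataFrame(
                {
                    "snp_id": self.snp_ids,
                    "beta_exp": self.exposure_betas[col].to_numpy(),
                    "se_exp": self.exposure_ses[col].to_numpy(),
                    "beta_out": self.outcome_beta,
                    "se_out": self.outcome_se,
                    "eaf_exp": np.nan,
                    "eaf_out": np.nan,
                    "action": "kept",
                }
            )
            pairs.append(HarmonizedPair(col, outcome_name, rows))
        return pairs


def simulate_mvmr(
    true_effects,
    *,
    n_snp_per_exposure: int = 15,
    n_exposure: int = 7_824,
    n_out: int = 408_241,
    case_fraction: float = 1086 / 408_241,
    effect_sd: float = 0.125,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> MvmrSimulation:
    """Summary statistics for several exposures acting jointly on one
    binary outcome; each exposure gets its own block of instruments, and
    every SNP carries (small, zero-mean) effects on the other exposures so
    the joint design is non-degenerate.
    """
    theta = np.asarray(true_effects, dtype=float)
    k = len(theta)
    rng = np.random.default_rng(seed)
    m = n_snp_per_exposure * k
    snp_ids = [f"rs{j:06d}" for j in range(1, m + 1)]

    maf = rng.uniform(*maf_range, size=m)
    het = 2 * maf * (1 - maf)
    se_x = 1 / np.sqrt(het * n_exposure)
    se_y = 1 / np.sqrt(het * n_out * case_fraction * (1 - case_fraction))

    true_x = np.zeros((m, k))
    for i in range(k):
        block = slice(i * n_snp_per_exposure, (i + 1) * n_snp_per_exposure)
        true_x[block, i] = rng.normal(0, effect_sd, n_snp_per_exposure)
        for other in range(k):
            if other != i:
                true_x[block, other] = rng.normal(0, effect_sd / 4, n_snp_per_exposure)

    obs_x = true_x + rng.standard_normal((m, k)) * se_x[:, None]
    true_y = true_x @ theta
    obs_y = true_y + rng.standard_normal(m) * se_y

    cols = [f"exposure_{i + 1}" for i in range(k)]
    return MvmrSimulation(
        exposure_betas=pd.DataFrame(obs_x, columns=cols).assign(snp_id=snp_ids),
        exposure_ses=pd.DataFrame(np.tile(se_x[:, None], (1, k)), columns=cols).assign(
            snp_id=snp_ids
        ),
        outcome_beta=obs_y,
        outcome_se=se_y,
        true_effects=theta,
        snp_ids=snp_ids,
    )


class MpnFixture(NamedTuple):
    """Worked-example constants for the Eubacterium xylanophilum group →
    {succinylcarnitine, lysine} → myeloproliferative-neoplasm pathway."""

    est_EO: MREstimate
    est_EM_succinylcarnitine: MREstimate
    est_MO_succinylcarnitine: MREstimate
    est_EM_lysine: MREstimate
    est_MO_lysine: MREstimate
    mvmr_succinylcarnitine: tuple[float, float]  # (beta, se)
    mvmr_lysine: tuple[float, float]


def make_mpn_fixture() -> MpnFixture:
    """Published worked-example estimates, exactly as printed.

    The total effect of the taxon on MPN is given as OR 0.49 (95% CI
    0.24–1.00); its beta is ln 0.49 and its SE is recovered from the CI
    width, ln(1.00/0.24)/(2·1.96). The taxon→metabolite legs (IVW) and the
    metabolite→MPN legs (univariate) carry printed betas and SEs; the
    instrument counts of the taxon→metabolite legs (4 SNPs) follow from
    the printed heterogeneity degrees of freedom.
    """
    from .mr_core import Z95

    taxon = "Eubacterium xylanophilum group"
    outcome = "MPN"
    se_eo = float(np.log(1.00 / 0.24) / (2 * Z95))
    est_eo = estimate_from_summary(
        float(np.log(0.49)), se_eo, exposure_name=taxon, outcome_name=outcome, method="ivw", n_snp=2
    )
    est_em_succ = estimate_from_summary(
        0.046, 0.019, exposure_name=taxon, outcome_name="succinylcarnitine", method="ivw", n_snp=4
    )
    est_mo_succ = estimate_from_summary(
        -2.244, 1.076, exposure_name="succinylcarnitine", outcome_name=outcome, method="ivw", n_snp=2
    )
    est_em_lys = estimate_from_summary(
        -0.029, 0.014, exposure_name=taxon, outcome_name="lysine", method="ivw", n_snp=4
    )
    est_mo_lys = estimate_from_summary(
        6.868, 3.138, exposure_name="lysine", outcome_name=outcome, method="ivw", n_snp=2
    )
    return MpnFixture(
        est_EO=est_eo,
        est_EM_succinylcarnitine=est_em_succ,
        est_MO_succinylcarnitine=est_mo_succ,
        est_EM_lysine=est_em_lys,
        est_MO_lysine=est_mo_lys,
        mvmr_succinylcarnitine=(-2.342, 0.823),
        mvmr_lysine=(5.714, 2.780),
    )
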