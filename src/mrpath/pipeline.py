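"""Orchestration: forward/reverse screens, mediation chains, MVMR wiring,
multiple-testing annotation and tidy reports.

Method routing follows the instrument count: one SNP → Wald ratio, two or
more → IVW, three or more additionally runs MR-Egger as a sensitivity
analysis. Per-pair failures (no instruments, no shared SNPs) become NA rows
in the screen report rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .exceptions import EstimationError, MrpathError
from .instruments import InstrumentSet, LdMatrix, select_instruments
from .mediation import MediationResult, two_step_mediation
from .mr_core import RESULT_COLUMNS, MREstimate, ivw, mr_egger, wald_ratio
from .summary_io import SummaryStats, harmonize, read_summary_stats

logger = logging.getLogger("mrpath")


@dataclass
class PipelineConfig:
    """Datasets and thresholds for a full screen/mediation run.

    Significance thresholds default to the conventions for these data
    sources: suggestive 1e-5 for microbial exposures, genome-wide 5e-8 for
    metabolite and outcome instruments. Screening significance is the raw
    IVW/Wald p < ``alpha``; Benjamini–Hochberg q-values are annotated
    alongside for transparency but do not drive the flags.
    """

    exposures: list[SummaryStats] = field(default_factory=list)
    mediators: list[SummaryStats] = field(default_factory=list)
    outcome: SummaryStats | None = None
    exposure_p_threshold: float = 1e-5
    mediator_p_threshold: float = 5e-8
    outcome_p_threshold: float = 5e-8
    eaf_min: float = 0.01
    f_min: float = 10.0
    ld: LdMatrix | None = None
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    palindromic_eaf_limit: float = 0.42
    alpha: float = 0.05
    random_effects: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a declarative run config.

        Keys: ``exposures``/``mediators`` (lists of {path, name, type}),
        ``outcome`` ({path, name, type, cases, controls}), ``ld_matrix``
        (path), plus any scalar field of this class.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def _load(entry) -> SummaryStats:
            if isinstance(entry, str):
                entry = {"path": entry}
            return read_summary_stats(
                entry["path"],
                dialect=entry.get("dialect"),
                trait_name=entry.get("name"),
                trait_type=entry.get("type", "quantitative"),
                n_cases=entry.get("cases"),
                n_controls=entry.get("controls"),
            )

        cfg = cls(
            exposures=[_load(e) for e in raw.get("exposures", [])],
            mediators=[_load(e) for e in raw.get("mediators", [])],
            outcome=_load(raw["outcome"]) if "outcome" in raw else None,
        )
        if "ld_matrix" in raw:
            cfg.ld = LdMatrix.read(raw["ld_matrix"])
        for key in (
            "exposure_p_threshold",
            "mediator_p_threshold",
            "outcome_p_threshold",
            "eaf_min",
            "f_min",
            "clump_r2",
            "clump_window_kb",
            "palindromic_eaf_limit",
            "alpha",
            "random_effects",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def _na_row(exposure: str, outcome: str, note: str) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update({"exposure": exposure, "outcome": outcome, "n_snp": 0, "error": note})
    return row


def estimate_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: PipelineConfig,
    p_threshold: float,
) -> tuple[MREstimate | None, MREstimate | None, InstrumentSet]:
    """Instruments → harmonize → routed estimate for one trait pair.

    Returns (primary estimate, Egger sensitivity estimate or None, the
    instrument set). The primary is the Wald ratio for a single instrument
    and IVW otherwise; Egger is added from 3 instruments up.
    """
    inst = select_instruments(
        exposure,
        p_threshold=p_threshold,
        eaf_min=config.eaf_min,
        f_min=config.f_min,
        ld=config.ld,
        clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
    )
    if inst.n_snp == 0:
        raise EstimationError(f"no instruments for {exposure.trait_name}")
    pair = harmonize(
        exposure.subset(inst.snp_ids), outcome, config.palindromic_eaf_limit
    )
    n = pair.n_kept
    if n == 0:
        raise EstimationError(
            f"no harmonizable instruments for {exposure.trait_name} vs {outcome.trait_name}"
        )
    if n == 1:
        row = pair.kept.iloc[0]
        primary = wald_ratio(
            row["beta_exp"],
            row["se_exp"],
            row["beta_out"],
            row["se_out"],
            exposure_name=exposure.trait_name,
            outcome_name=outcome.trait_name,
        )
    else:
        primary = ivw(pair, random_effects=config.random_effects)
    egger = mr_egger(pair) if n >= 3 else None
    return primary, egger, inst


def run_screen(config: PipelineConfig, direction: str = "forward") -> pd.DataFrame:
    """One MR estimate per (exposure, outcome) pair, NA rows on failure.

    ``forward`` screens every configured exposure against the outcome at
    the exposure-category threshold; ``reverse`` instruments the outcome at
    its own (genome-wide) threshold and screens it against each exposure.
    """
    if direction not in ("forward", "reverse"):
        raise MrpathError(f"unknown direction {direction!r}")
    if config.outcome is None:
        raise MrpathError("config has no outcome dataset")
    rows = []
    for exp in config.exposures:
        if direction == "forward":
            e, o, thr = exp, config.outcome, config.exposure_p_threshold
        else:
            e, o, thr = config.outcome, exp, config.outcome_p_threshold
        try:
            primary, egger, _ = estimate_pair(e, o, config, thr)
        except MrpathError as err:
            logger.warning("screen %s vs %s failed: %s", e.trait_name, o.trait_name, err)
            rows.append(_na_row(e.trait_name, o.trait_name, str(err)))
            continue
        row = {
            "exposure": primary.exposure_name,
            "outcome": primary.outcome_name,
            "method": primary.method,
            "n_snp": primary.n_snp,
            "beta": primary.beta,
            "se": primary.se,
            "pvalue": primary.pvalue,
            "or_value": primary.or_value,
            "ci_low": primary.ci_low,
            "ci_high": primary.ci_high,
            "q_statistic": primary.q_statistic,
            "q_pvalue": primary.q_pvalue,
            "egger_intercept": egger.egger_intercept if egger else np.nan,
            "egger_intercept_p": egger.egger_intercept_p if egger else np.nan,
            "error": "",
        }
        rows.append(row)
    report = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["error"])
    report = annotate_multiplicity(report)
    report["significant"] = report["pvalue"] < config.alpha
    return report


def annotate_multiplicity(report: pd.DataFrame, p_column: str = "pvalue") -> pd.DataFrame:
    """Append Benjamini–Hochberg q-values for one screening family.

    NA p-values (failed pairs) keep NA q-values; raw-p flags remain the
    primary significance criterion elsewhere.
    """
    report = report.copy()
    p = report[p_column].to_numpy(float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    report["q_value"] = q
    return report


def run_mediation_chain(
    config: PipelineConfig,
    exposure: SummaryStats,
    mediator: SummaryStats,
) -> MediationResult:
    """Two-step mediation for one exposure→mediator→outcome chain.

    Estimates the three legs — total E→O and E→M with the exposure's
    instruments, M→O with the mediator's own instruments at the mediator
    threshold — then applies the product-of-coefficients decomposition.
    Each leg's heterogeneity and Egger-intercept sensitivity statistics
    travel with the component estimates.
    """
    if config.outcome is None:
        raise MrpathError("config has no outcome dataset")
    legs = {}
    specs = [
        ("EO", exposure, config.outcome, config.exposure_p_threshold),
        ("EM", exposure, mediator, config.exposure_p_threshold),
        ("MO", mediator, config.outcome, config.mediator_p_threshold),
    ]
    for leg, e, o, thr in specs:
        try:
            primary, egger, _ = estimate_pair(e, o, config, thr)
        except MrpathError as err:
            raise EstimationError(
                f"mediation chain incomplete: leg {leg} "
                f"({e.trait_name} -> {o.trait_name}) failed: {err}"
            ) from err
        if egger is not None:
            primary.egger_intercept = egger.egger_intercept
            primary.egger_intercept_p = egger.egger_intercept_p
        legs[leg] = primary
    return two_step_mediation(legs["EO"], legs["EM"], legs["MO"])
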