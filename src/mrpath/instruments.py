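"""Instrument selection: significance, allele-frequency and strength filters
plus greedy LD clumping.

Filters are applied in a fixed order — p-value threshold, EAF, F-statistic,
clumping — and each stage's removals are recorded in ``selection_log``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .summary_io import SummaryStats

logger = logging.getLogger("mrpath")


@dataclass
class LdMatrix:
    """Pairwise LD correlations (r, not r²) for an ordered SNP panel."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise DataError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise DataError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise DataError("LD correlations must lie in [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float | None:
        """Squared correlation between two SNPs, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def read(cls, path) -> "LdMatrix":
        """First line: whitespace-separated snp_ids; then rows of r values."""
        with open(path) as fh:
            ids = fh.readline().split()
            r = np.loadtxt(fh, ndmin=2)
        return cls(ids, r)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.snp_ids) + "\n")
            np.savetxt(fh, self.r, fmt="%.10g")


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure, with per-SNP F and a stage log."""

    exposure_name: str
    table: pd.DataFrame = field(repr=False)  # snp_id, chromosome, position, pvalue, f_stat
    selection_log: dict = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def median_f(self) -> float:
        return float(self.table["f_stat"].median()) if self.n_snp else float("nan")


def compute_f_statistic(beta, se):
    """Single-SNP instrument-strength approximation F = (beta/se)²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ConfigError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def greedy_clump(
    df: pd.DataFrame,
    ld: LdMatrix,
    clump_r2: float,
    clump_window_kb: int,
) -> pd.DataFrame:
    """Greedy p-ordered clumping.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by snp_id) and discard all remaining SNPs on the same chromosome within
    ``clump_window_kb`` whose r² with it is at least ``clump_r2``. SNPs
    absent from the LD matrix are treated as independent (warned).
    """
    order = df.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(drop=True)
    missing = [s for s in order["snp_id"] if s not in ld._index]
    if missing:
        logger.warning(
            "clumping: %d SNP(s) absent from LD matrix treated as independent", len(missing)
        )
    active = order.to_dict("records")
    kept: list[dict] = []
    while active:
        lead = active.pop(0)
        kept.append(lead)
        survivors = []
        for row in active:
            same_chrom = (
                pd.notna(lead["chromosome"])
                and pd.notna(row["chromosome"])
                and str(lead["chromosome"]) == str(row["chromosome"])
            )
            within = (
                same_chrom
                and pd.notna(lead["position"])
                and pd.notna(row["position"])
                and abs(float(lead["position"]) - float(row["position"]))
                <= clump_window_kb * 1000
            )
            r2 = ld.r2(lead["snp_id"], row["snp_id"]) if within else None
            if r2 is not None and r2 >= clump_r2:
                continue  # clumped away
            survivors.append(row)
        active = survivors
    return pd.DataFrame(kept)


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 1e-5,
    eaf_min: float = 0.01,
    f_min: float = 10.0,
    ld: LdMatrix | None = None,
    clump_r2: float = 0.001,
    clump_window_kb: int = 10_000,
) -> InstrumentSet:
    """Select instrumental variables for one exposure.

    Fixed filter order: p < ``p_threshold``; minor-allele-side EAF above
    ``eaf_min`` (SNPs with missing EAF pass, warned); F = (beta/se)² ≥
    ``f_min``; greedy LD clumping when an LD matrix is supplied (otherwise
    SNPs are assumed pre-clumped, with a logged notice). An empty survivor
    set is returned as an empty InstrumentSet with a warning, not an error.
    """
    if not (0 < p_threshold <= 1) or not (0 <= eaf_min < 0.5) or f_min < 0:
        raise ConfigError("invalid selection thresholds")
    df = stats.records.copy()
    log = {"input": len(df)}

    surv = df[df["pvalue"] < p_threshold]
    log["below_p"] = len(df) - len(surv)

    has_eaf = surv["eaf"].notna()
    if (~has_eaf).any():
        logger.warning(
            "%s: %d SNP(s) lack EAF; frequency filter not applied to them",
            stats.trait_name,
            int((~has_eaf).sum()),
        )
    maf = np.minimum(surv["eaf"], 1 - surv["eaf"])
    ok_eaf = ~has_eaf | (maf > eaf_min)
    n_before = len(surv)
    surv = surv[ok_eaf]
    log["low_eaf"] = n_before - len(surv)

    surv = surv.assign(f_stat=compute_f_statistic(surv["beta"], surv["se"]))
    n_before = len(surv)
    surv = surv[surv["f_stat"] >= f_min]
    log["low_F"] = n_before - len(surv)

    if ld is not None and len(surv) > 1:
        n_before = len(surv)
        surv = greedy_clump(surv, ld, clump_r2, clump_window_kb)
        log["clumped"] = n_before - len(surv)
    else:
        if ld is None:
            logger.info("%s: no LD matrix supplied; SNPs assumed pre-clumped", stats.trait_name)
        log["clumped"] = 0

    log["retained"] = len(surv)
    if not len(surv):
        logger.warning("%s: no SNP survives instrument selection", stats.trait_name)
        surv = df.head(0).assign(f_stat=pd.Series(dtype=float))
    surv = surv.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(drop=True)
    return InstrumentSet(
        exposure_name=stats.trait_name,
        table=surv[["snp_id", "chromosome", "position", "pvalue", "f_stat"]],
        selection_log=log,
    )
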