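"""GWAS summary statistics: data model, delimited-text I/O, allele harmonization.

A :class:`SummaryStats` holds per-SNP association records for one trait.
:func:`harmonize` aligns the effect alleles of an exposure/outcome pair so
that both betas refer to the same allele — the preprocessing every
two-sample MR estimator requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError, DataError

logger = logging.getLogger("mrpath")

#: internal column name -> default header in summary-statistics files
DEFAULT_DIALECT = {
    "snp_id": "SNP",
    "chromosome": "CHR",
    "position": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

#: canonical column order used by :func:`write_summary_stats`
CANONICAL_COLUMNS = list(DEFAULT_DIALECT)

REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization row actions
KEPT_ACTIONS = frozenset({"kept", "flipped", "palindromic_kept"})


@dataclass(eq=False)
class SummaryStats:
    """Per-SNP association records for a single trait.

    ``records`` uses the internal column names of :data:`DEFAULT_DIALECT`;
    ``beta`` is on the log-odds scale for binary traits and in standardized
    units for quantitative traits.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "quantitative"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.records["snp_id"].duplicated().any():
            dups = self.records.loc[self.records["snp_id"].duplicated(), "snp_id"]
            raise DataError(
                f"duplicate snp_id in {self.trait_name!r}: {sorted(set(dups))[:5]}"
            )

    @property
    def n_snp(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records["snp_id"])

    def subset(self, snp_ids) -> "SummaryStats":
        """Restrict to the given SNP ids (order of ``records`` preserved)."""
        keep = self.records["snp_id"].isin(set(snp_ids))
        return SummaryStats(
            trait_name=self.trait_name,
            records=self.records.loc[keep].reset_index(drop=True),
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )

    def equals(self, other: "SummaryStats", rtol: float = 1e-9) -> bool:
        """Value equality: same trait metadata and numerically equal records."""
        if (
            self.trait_name != other.trait_name
            or self.trait_type != other.trait_type
            or self.n_snp != other.n_snp
        ):
            return False
        a = self.records.sort_values("snp_id").reset_index(drop=True)
        b = other.records.sort_values("snp_id").reset_index(drop=True)
        for col in CANONICAL_COLUMNS:
            if col not in a.columns or col not in b.columns:
                return False
            if a[col].dtype.kind in "fc" or b[col].dtype.kind in "fc":
                if not np.allclose(
                    a[col].astype(float), b[col].astype(float), rtol=rtol, equal_nan=True
                ):
                    return False
            elif not (a[col].fillna("") == b[col].fillna("")).all():
                return False
        return True


def _validate_records(df: pd.DataFrame, trait_name: str) -> pd.DataFrame:
    """Drop rows violating per-SNP invariants; log drop count; warn on z/p mismatch."""
    n_in = len(df)
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    ok = (
        df["snp_id"].notna()
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
    )
    has_eaf = df["eaf"].notna()
    ok &= ~has_eaf | ((df["eaf"] > 0) & (df["eaf"] < 1))
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.info("%s: dropped %d invalid record(s) of %d", trait_name, dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)

    # warn-only consistency check: p should match the two-sided normal tail of |beta|/se
    with np.errstate(divide="ignore"):
        p_exp = 2.0 * sps.norm.sf(np.abs(df["beta"]) / df["se"])
        mismatch = (
            (p_exp > 1e-300)
            & (df["pvalue"] > 1e-300)
            & (np.abs(np.log10(p_exp) - np.log10(df["pvalue"])) > 1.0)
        )
    if mismatch.any():
        logger.warning(
            "%s: %d record(s) have p-values inconsistent with |beta|/se "
            "(two-sided normal tail); using the stated p-values",
            trait_name,
            int(mismatch.sum()),
        )
    return df


def read_summary_stats(
    path,
    dialect: dict | None = None,
    *,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics file (gzip transparently supported).

    ``dialect`` maps internal names (keys of :data:`DEFAULT_DIALECT`) to the
    column headers used in the file; unspecified names fall back to the
    defaults, unknown extra columns are ignored. Rows violating the per-SNP
    invariants are dropped with a logged count.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
        mapping.update(dialect)

    try:
        raw = pd.read_csv(path, sep=sep, compression="infer")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty summary-statistics file: {path}") from None

    missing = [mapping[c] for c in REQUIRED_COLUMNS if mapping[c] not in raw.columns]
    if missing:
        raise ConfigError(
            f"{path}: required column(s) {missing} not found "
            f"(headers present: {list(raw.columns)})"
        )

    df = pd.DataFrame()
    for internal, header in mapping.items():
        if header in raw.columns:
            df[internal] = raw[header]
        else:
            df[internal] = np.nan
    df["snp_id"] = df["snp_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype("string").astype(object)
    for col in ("eaf", "beta", "se", "pvalue", "position", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    name = trait_name if trait_name is not None else str(path)
    df = _validate_records(df, name)
    return SummaryStats(
        trait_name=name,
        records=df[CANONICAL_COLUMNS],
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write tab-separated text in canonical column order.

    Floats use 12 significant digits so that a write→read→write cycle is
    byte-identical and round-trips are lossless at reading precision.
    """
    out = stats.records.reindex(columns=CANONICAL_COLUMNS).copy()
    out.columns = [DEFAULT_DIALECT[c] for c in CANONICAL_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


@dataclass
class HarmonizedPair:
    """Exposure and outcome records joined on SNP with effect alleles aligned.

    ``rows`` columns: snp_id, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    eaf_out, action. Only rows whose ``action`` is in :data:`KEPT_ACTIONS`
    enter MR estimation.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame = field(repr=False)

    @property
    def kept(self) -> pd.DataFrame:
        return self.rows[self.rows["action"].isin(KEPT_ACTIONS)]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def restrict(self, snp_ids) -> "HarmonizedPair":
        keep = self.rows["snp_id"].isin(set(snp_ids))
        return HarmonizedPair(
            self.exposure_name, self.outcome_name, self.rows.loc[keep].reset_index(drop=True)
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_eaf_limit: float = 0.42,
) -> HarmonizedPair:
    """Align outcome effect alleles to the exposure's.

    Per shared SNP: same allele pair and orientation → ``kept``; swapped
    orientation → outcome beta negated and eaf complemented (``flipped``);
    strand-complement pairs are complemented first and the same two rules
    applied. Palindromic pairs (A/T, C/G) are label-aligned the same way but
    kept only when both allele frequencies are informative: present, on the
    same side of 0.5 after alignment, and both outside
    ``[palindromic_eaf_limit, 1 − palindromic_eaf_limit]``; otherwise
    ``dropped_palindromic``. Irreconcilable allele pairs →
    ``dropped_allele_mismatch``. Rows are sorted by snp_id.
    """
    if not 0 < palindromic_eaf_limit < 0.5:
        raise ConfigError("palindromic_eaf_limit must be in (0, 0.5)")
    exp = exposure.records.set_index("snp_id")
    out = outcome.records.set_index("snp_id")
    shared = sorted(set(exp.index) & set(out.index))
    if not shared:
        raise DataError(
            f"no shared SNPs between exposure {exposure.trait_name!r} "
            f"and outcome {outcome.trait_name!r}"
        )

    rows = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        beta_y, eaf_y = float(o["beta"]), o["eaf"]

        def _orient(a1, a2):
            """same orientation -> +1, swapped -> -1, no match -> 0"""
            if (a1, a2) == (ea_x, oa_x):
                return 1
            if (a1, a2) == (oa_x, ea_x):
                return -1
            return 0

        orient = _orient(ea_y, oa_y)
        if orient == 0 and not _is_palindromic(ea_x, oa_x):
            # try the opposite strand
            orient = _orient(COMPLEMENT.get(ea_y, "?"), COMPLEMENT.get(oa_y, "?"))

        if orient == 0:
            action = "dropped_allele_mismatch"
        elif _is_palindromic(ea_x, oa_x):
            if orient == -1:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else np.nan
            eaf_x = e["eaf"]
            lim = palindromic_eaf_limit
            informative = (
                pd.notna(eaf_x)
                and pd.notna(eaf_y)
                and (eaf_x < lim or eaf_x > 1 - lim)
                and (eaf_y < lim or eaf_y > 1 - lim)
                and ((eaf_x - 0.5) * (eaf_y - 0.5) > 0)
            )
            action = "palindromic_kept" if informative else "dropped_palindromic"
        elif orient == 1:
            action = "kept"
        else:
            action = "flipped"
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else np.nan

        rows.append(
            {
                "snp_id": snp,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "beta_out": beta_y,
                "se_out": float(o["se"]),
                "eaf_exp": e["eaf"],
                "eaf_out": eaf_y,
                "action": action,
            }
        )

    frame = pd.DataFrame(rows)
    n_dropped = int((~frame["action"].isin(KEPT_ACTIONS)).sum())
    if n_dropped:
        logger.info(
            "harmonize %s vs %s: %d of %d shared SNP(s) dropped",
            exposure.trait_name,
            outcome.trait_name,
            n_dropped,
            len(frame),
        )
    return HarmonizedPair(exposure.trait_name, outcome.trait_name, frame)
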