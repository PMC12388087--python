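"""Shared fixtures: hand-built summary statistics and a vectorized
multi-exposure panel generator for screen-calibration tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrpath import SummaryStats
from mrpath.summary_io import CANONICAL_COLUMNS

# cohort scales shared with the simulator defaults
N_EXP = 18_340
N_OUT = 408_241
CASE_FRACTION = 1086 / 408_241


def make_stats(name, rows, trait_type="quantitative", **kwargs) -> SummaryStats:
    """Build a SummaryStats from a list of per-SNP dicts, filling defaults
    and deriving the p-value from |beta|/se when absent."""
    filled = []
    for i, row in enumerate(rows):
        r = {
            "snp_id": f"rs{i + 1:04d}",
            "chromosome": "1",
            "position": 1_000_000 + i * 50_000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "n": 10_000,
        }
        r.update(row)
        if "pvalue" not in r:
            r["pvalue"] = float(2 * sps.norm.sf(abs(r["beta"]) / r["se"]))
        filled.append(r)
    return SummaryStats(name, pd.DataFrame(filled)[CANONICAL_COLUMNS], trait_type, **kwargs)


NON_PALINDROMIC_PAIRS = [
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
]


def panel(
    seed: int,
    n_exposures: int = 20,
    n_per_exposure: int = 20,
    effects=None,
    gamma_sd: float = 0.15,
):
    """A screening panel: ``n_exposures`` exposure GWAS plus one shared rare
    binary outcome on a common SNP grid. Exposure k has instruments only in
    its own SNP block; ``effects[k]`` is its true causal effect on the
    outcome (all zero → a null screen). Allele pairs are non-palindromic so
    harmonization keeps every SNP; orientation is canonical throughout —
    the panel calibrates estimators, not harmonization."""
    rng = np.random.default_rng(seed)
    k = n_exposures
    m = k * n_per_exposure
    effects = np.zeros(k) if effects is None else np.asarray(effects, float)

    maf = rng.uniform(0.05, 0.5, m)
    het = 2 * maf * (1 - maf)
    se_x = 1 / np.sqrt(het * N_EXP)
    se_y = 1 / np.sqrt(het * N_OUT * CASE_FRACTION * (1 - CASE_FRACTION))

    gamma = np.zeros((k, m))
    for i in range(k):
        block = slice(i * n_per_exposure, (i + 1) * n_per_exposure)
        gamma[i, block] = rng.normal(0, gamma_sd, n_per_exposure)

    snp_ids = [f"rs{j:06d}" for j in range(1, m + 1)]
    pos = 1_000_000 + np.arange(m) * 1_000_000
    pair_idx = rng.integers(0, len(NON_PALINDROMIC_PAIRS), m)
    ea = np.array([NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx])

    def _frame(beta, se, n):
        p = np.clip(2 * sps.norm.sf(np.abs(beta) / se), np.nextafter(0, 1), 1.0)
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chromosome": "1",
                "position": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pvalue": p,
                "n": n,
            }
        )[CANONICAL_COLUMNS]

    exposures = []
    for i in range(k):
        beta_x = gamma[i] + rng.standard_normal(m) * se_x
        exposures.append(SummaryStats(f"exposure_{i + 1}", _frame(beta_x, se_x, N_EXP)))
    beta_y = effects @ gamma + rng.standard_normal(m) * se_y
    n_cases = int(round(N_OUT * CASE_FRACTION))
    outcome = SummaryStats(
        "outcome",
        _frame(beta_y, se_y, N_OUT),
        "binary",
        n_cases=n_cases,
        n_controls=N_OUT - n_cases,
    )
    return exposures, outcome


@pytest.fixture
def small_stats():
    """Three well-formed SNPs for one quantitative trait."""
    return make_stats(
        "trait_a",
        [
            {"snp_id": "rs0001", "beta": 0.10, "se": 0.02},
            {"snp_id": "rs0002", "beta": -0.05, "se": 0.01, "effect_allele": "T", "other_allele": "C"},
            {"snp_id": "rs0003", "beta": 0.20, "se": 0.04, "eaf": 0.12},
        ],
    )
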