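"""Instrument selection: filters, F-statistics, greedy LD clumping."""

import numpy as np
import pytest

from mrpath import (
    ConfigError,
    DataError,
    LdMatrix,
    compute_f_statistic,
    select_instruments,
    simulate,
)
from mrpath.summary_io import SummaryStats
from mrpath.synthetic import SimConfig

from conftest import make_stats


class TestFStatistic:
    def test_arithmetic(self):
        assert compute_f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert compute_f_statistic(0.0, 0.1) == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ConfigError):
            compute_f_statistic(0.1, 0.0)

    def test_median_f_matches_analytic_expectation(self):
        """Per-SNP F = (beta/se)² is noncentral chi-square with mean
        n·2p(1−p)γ² + 1; the observed mean over many instruments must sit
        within 3 SE of the mean analytic expectation, and the median within
        10% of the analytic median (the chi-square skew shifts the median a
        little below the mean)."""
        cfg = SimConfig(seed=5, n_snp=3000, n_instruments=3000, n_med_instruments=0)
        sim = simulate(cfg)
        rec = sim.exposure.records
        f_obs = compute_f_statistic(rec["beta"].to_numpy(), rec["se"].to_numpy())
        het = 2 * rec["eaf"] * (1 - rec["eaf"])
        lam = (het * cfg.n_exp * sim.truth.gamma**2).to_numpy()
        expected = lam + 1
        # mean: exact expectation, variance of noncentral chi2 is 2 + 4*lam
        se_mean = np.sqrt(np.mean(2 + 4 * lam) / len(lam))
        assert np.mean(f_obs) == pytest.approx(np.mean(expected), abs=3 * se_mean)
        assert np.median(f_obs) == pytest.approx(np.median(expected), rel=0.10)


def _block_stats(n=5, r=0.95):
    rows = [
        {
            "snp_id": f"rs{i + 1:04d}",
            "beta": 0.1,
            "se": 0.01,
            "pvalue": 1e-8 * (i + 1),
            "position": 1_000_000 + i * 10_000,
        }
        for i in range(n)
    ]
    stats = make_stats("trait", rows)
    ids = stats.snp_ids
    m = np.full((n, n), r)
    np.fill_diagonal(m, 1.0)
    return stats, LdMatrix(ids, m)


class TestClumping:
    def test_single_clump_keeps_smallest_p(self):
        stats, ld = _block_stats()
        inst = select_instruments(stats, ld=ld, clump_r2=0.001)
        assert inst.snp_ids == ["rs0001"]  # smallest p of the block
        assert inst.selection_log["clumped"] == 4

    def test_identity_ld_removes_nothing(self):
        stats, _ = _block_stats()
        ld = LdMatrix(stats.snp_ids, np.eye(5))
        inst = select_instruments(stats, ld=ld, clump_r2=0.001)
        assert inst.n_snp == 5

    def test_matches_bruteforce_enumeration(self):
        """200 SNPs in LD blocks: the greedy result must equal an
        independent brute-force pass, and every clumped-away SNP must have
        r² ≥ threshold with a retained SNP of smaller-or-equal p."""
        cfg = SimConfig(
            seed=13,
            n_snp=200,
            n_instruments=200,
            n_med_instruments=0,
            gamma_sd=0.15,
            ld_block_size=10,
            ld_within_block_r=0.6,
        )
        sim = simulate(cfg)
        clump_r2 = 0.1
        inst = select_instruments(
            sim.exposure, p_threshold=1.0, f_min=0.0, ld=sim.ld, clump_r2=clump_r2
        )

        # brute force: walk SNPs in (p, id) order, keep unless correlated
        # with an already kept SNP within the window
        rec = sim.exposure.records.sort_values(["pvalue", "snp_id"])
        kept = []
        for _, row in rec.iterrows():
            conflict = any(
                abs(row["position"] - k["position"]) <= 10_000 * 1000
                and str(row["chromosome"]) == str(k["chromosome"])
                and sim.ld.r2(row["snp_id"], k["snp_id"]) >= clump_r2
                for k in kept
            )
            if not conflict:
                kept.append(row)
        assert set(inst.snp_ids) == {k["snp_id"] for k in kept}

        p_by_id = dict(zip(rec["snp_id"], rec["pvalue"]))
        retained = set(inst.snp_ids)
        for snp in set(rec["snp_id"]) - retained:
            assert any(
                sim.ld.r2(snp, r) >= clump_r2 and p_by_id[r] <= p_by_id[snp]
                for r in retained
            )

    def test_missing_ld_snp_treated_independent(self, caplog):
        stats, ld = _block_stats()
        partial = LdMatrix(ld.snp_ids[:3], ld.r[:3, :3])
        with caplog.at_level("WARNING", logger="mrpath"):
            inst = select_instruments(stats, ld=partial, clump_r2=0.001)
        assert {"rs0004", "rs0005"} <= set(inst.snp_ids)
        assert any("absent from LD matrix" in m for m in caplog.messages)


class TestSelection:
    def test_filters_and_log(self):
        stats = make_stats(
            "trait",
            [
                {"snp_id": "rs1", "beta": 0.10, "se": 0.01},          # retained
                {"snp_id": "rs2", "beta": 0.01, "se": 0.01, "pvalue": 0.5},  # fails p
                {"snp_id": "rs3", "beta": 0.10, "se": 0.01, "eaf": 0.005},   # fails eaf
                {"snp_id": "rs4", "beta": 0.10, "se": 0.01, "eaf": 0.997},   # minor side
                {"snp_id": "rs5", "beta": 0.025, "se": 0.01},                # F = 6.25
            ],
        )
        inst = select_instruments(stats, p_threshold=0.05)
        assert inst.snp_ids == ["rs1"]
        assert inst.selection_log == {
            "input": 5,
            "below_p": 1,
            "low_eaf": 2,
            "low_F": 1,
            "clumped": 0,
            "retained": 1,
        }
        assert (inst.table["f_stat"] >= 10).all()

    def test_retained_set_independent_of_row_order(self):
        stats, ld = _block_stats()
        shuffled = SummaryStats(
            "trait", stats.records.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        a = select_instruments(stats, ld=ld, clump_r2=0.001)
        b = select_instruments(shuffled, ld=ld, clump_r2=0.001)
        assert a.snp_ids == b.snp_ids

    def test_lowering_p_threshold_never_gains_snps(self):
        sim = simulate(SimConfig(seed=3, n_snp=100, n_instruments=50, n_med_instruments=0))
        counts = [
            select_instruments(sim.exposure, p_threshold=p, f_min=0).n_snp
            for p in (1e-2, 1e-5, 5e-8, 1e-12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_survivor_returns_empty_set_with_warning(self, caplog):
        stats = make_stats("trait", [{"beta": 0.0001, "se": 0.01, "pvalue": 0.9}])
        with caplog.at_level("WARNING", logger="mrpath"):
            inst = select_instruments(stats)
        assert inst.n_snp == 0
        assert np.isnan(inst.median_f)
        assert any("no SNP survives" in m for m in caplog.messages)


class TestLdMatrixIO:
    def test_roundtrip(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        r = np.array([[1, 0.5, 0], [0.5, 1, 0.2], [0, 0.2, 1.0]])
        path = tmp_path / "ld.txt"
        LdMatrix(ids, r).write(path)
        back = LdMatrix.read(path)
        assert back.snp_ids == ids
        assert np.allclose(back.r, r)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[1, 0.5], [0.4, 1]]),      # asymmetric
            np.array([[0.9, 0.5], [0.5, 1]]),    # diagonal not 1
            np.array([[1, 1.5], [1.5, 1]]),      # out of range
        ],
    )
    def test_validation(self, bad):
        with pytest.raises(DataError):
            LdMatrix(["rs1", "rs2"], bad)
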