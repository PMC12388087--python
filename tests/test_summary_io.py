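"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrpath import (
    ConfigError,
    DataError,
    SummaryStats,
    harmonize,
    read_summary_stats,
    simulate,
    write_summary_stats,
)
from mrpath.summary_io import CANONICAL_COLUMNS, KEPT_ACTIONS
from mrpath.synthetic import SimConfig

from conftest import make_stats


class TestReadWrite:
    def test_well_formed_tsv_round_trips(self, tmp_path, small_stats):
        path = tmp_path / "trait.tsv"
        write_summary_stats(small_stats, path)
        back = read_summary_stats(path, trait_name="trait_a")
        assert back.n_snp == 3
        assert back.equals(small_stats)

    def test_write_read_write_is_byte_identical(self, tmp_path):
        sim = simulate(SimConfig(seed=11, n_snp=30, n_instruments=10, n_med_instruments=10))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_summary_stats(sim.exposure, p1)
        back = read_summary_stats(p1, trait_name="exposure")
        write_summary_stats(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gzip_transparent(self, tmp_path, small_stats):
        path = tmp_path / "trait.tsv.gz"
        write_summary_stats(small_stats, path)
        assert read_summary_stats(path, trait_name="trait_a").equals(small_stats)

    def test_printed_beta_written_verbatim(self, tmp_path):
        stats = make_stats("succinylcarnitine", [{"beta": -2.244, "se": 1.076}])
        path = tmp_path / "t.tsv"
        write_summary_stats(stats, path)
        assert "-2.244\t" in path.read_text()

    def test_empty_record_set_writes_header_only(self, tmp_path):
        stats = SummaryStats("empty", pd.DataFrame(columns=CANONICAL_COLUMNS))
        path = tmp_path / "t.tsv"
        write_summary_stats(stats, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("SNP\t")

    def test_invalid_rows_dropped_and_logged(self, tmp_path, caplog):
        stats = make_stats(
            "trait",
            [
                {"snp_id": "rs1", "beta": 0.1, "se": 0.02},
                {"snp_id": "rs2", "beta": 0.1, "se": 0.02},
            ],
        )
        stats.records.loc[1, "se"] = 0.0  # violates se > 0
        path = tmp_path / "t.tsv"
        stats.records.to_csv(path, sep="\t", index=False, header=list(CANONICAL_COLUMNS))
        # header names must match the dialect, re-write properly
        write_summary_stats(SummaryStats("trait", stats.records), path)
        with caplog.at_level("INFO", logger="mrpath"):
            back = read_summary_stats(path, trait_name="trait")
        assert back.n_snp == 1
        assert any("dropped 1" in m for m in caplog.messages)

    def test_missing_required_column_names_it(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tA1\tA2\tBETA\tP\nrs1\tA\tG\t0.1\t0.5\n")
        with pytest.raises(ConfigError, match="SE"):
            read_summary_stats(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("")
        with pytest.raises(DataError):
            read_summary_stats(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "rsid\tea\tnea\teffect\tstderr\tpval\textra\n"
            "rs1\ta\tg\t0.1\t0.02\t1e-6\tjunk\n"
        )
        stats = read_summary_stats(
            path,
            dialect={
                "snp_id": "rsid",
                "effect_allele": "ea",
                "other_allele": "nea",
                "beta": "effect",
                "se": "stderr",
                "pvalue": "pval",
            },
        )
        assert stats.n_snp == 1
        assert stats.records.loc[0, "effect_allele"] == "A"  # upper-cased

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            make_stats("t", [{"snp_id": "rs1", "beta": 0, "se": 1}, {"snp_id": "rs1", "beta": 0, "se": 1}])


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        exp = make_stats("exp", [dict(snp_id="rs1", **exp_row)])
        out = make_stats("out", [dict(snp_id="rs1", **out_row)])
        return harmonize(exp, out)

    def test_swapped_orientation_flips_beta(self):
        pair = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "se": 0.02, "eaf": 0.3},
            {"effect_allele": "G", "other_allele": "A", "beta": 0.3, "se": 0.05, "eaf": 0.7},
        )
        row = pair.rows.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_out"] == pytest.approx(-0.3)
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        # A/G on one strand is T/C on the other: same variant, kept as-is
        pair = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "se": 0.02},
            {"effect_allele": "T", "other_allele": "C", "beta": 0.3, "se": 0.05},
        )
        assert pair.rows.iloc[0]["action"] == "kept"
        assert pair.rows.iloc[0]["beta_out"] == pytest.approx(0.3)

    @pytest.mark.parametrize(
        ("eaf_exp", "eaf_out", "expected"),
        [
            (0.50, 0.50, "dropped_palindromic"),  # frequency uninformative
            (0.20, 0.25, "palindromic_kept"),
            (0.20, 0.80, "dropped_palindromic"),  # opposite sides of 0.5
            (0.45, 0.45, "dropped_palindromic"),  # inside the ambiguity band
            (np.nan, 0.20, "dropped_palindromic"),  # missing frequency -> conservative drop
        ],
    )
    def test_palindromic_frequency_rule(self, eaf_exp, eaf_out, expected):
        pair = self._pair(
            {"effect_allele": "A", "other_allele": "T", "beta": 0.1, "se": 0.02, "eaf": eaf_exp},
            {"effect_allele": "A", "other_allele": "T", "beta": 0.3, "se": 0.05, "eaf": eaf_out},
        )
        assert pair.rows.iloc[0]["action"] == expected

    def test_irreconcilable_alleles_dropped(self):
        pair = self._pair(
            {"effect_allele": "A", "other_allele": "G", "beta": 0.1, "se": 0.02},
            {"effect_allele": "A", "other_allele": "C", "beta": 0.3, "se": 0.05},
        )
        assert pair.rows.iloc[0]["action"] == "dropped_allele_mismatch"

    def test_empty_intersection_names_both_traits(self):
        exp = make_stats("taxon", [{"snp_id": "rs1", "beta": 0.1, "se": 0.02}])
        out = make_stats("mpn", [{"snp_id": "rs2", "beta": 0.1, "se": 0.02}])
        with pytest.raises(DataError, match="taxon.*mpn"):
            harmonize(exp, out)

    def test_recovers_generator_ground_truth_orientation(self):
        """Randomized allele/strand permutations of a 50-SNP simulated pair
        harmonize back to the generator's canonical-orientation betas."""
        sim = simulate(SimConfig(seed=7, n_snp=50, n_instruments=25, n_med_instruments=25))
        pair = harmonize(sim.exposure, sim.outcome)
        canonical = dict(zip(sim.truth.snp_ids, sim.truth.canonical_beta_out))
        kept = pair.kept
        assert len(kept) >= 20  # palindromic ambiguity prunes some
        for _, row in kept.iterrows():
            assert row["beta_out"] == pytest.approx(canonical[row["snp_id"]], abs=1e-12)
        # no kept row ever has mismatched alleles: mismatches are all labelled
        assert set(pair.rows["action"]) <= KEPT_ACTIONS | {
            "dropped_palindromic",
            "dropped_allele_mismatch",
        }

    def _as_stats(self, pair, name, which):
        """Rebuild SummaryStats from harmonized kept rows (exposure alleles)."""
        kept = pair.kept
        df = pd.DataFrame(
            {
                "snp_id": kept["snp_id"],
                "chromosome": "1",
                "position": np.arange(len(kept)) * 10_000 + 1,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": kept[f"eaf_{which}"].fillna(0.3),
                "beta": kept[f"beta_{which}"],
                "se": kept[f"se_{which}"],
                "pvalue": 0.5,
                "n": 10_000,
            }
        )[CANONICAL_COLUMNS]
        return SummaryStats(name, df.reset_index(drop=True))

    def test_idempotent_on_already_harmonized_pair(self):
        sim = simulate(SimConfig(seed=19, n_snp=40, n_instruments=20, n_med_instruments=20))
        first = harmonize(sim.exposure, sim.outcome)
        again = harmonize(
            self._as_stats(first, "exp", "exp"), self._as_stats(first, "out", "out")
        )
        assert (again.rows["action"] == "kept").all()
        merged = first.kept.merge(again.rows, on="snp_id", suffixes=("_1", "_2"))
        assert np.allclose(merged["beta_out_1"], merged["beta_out_2"])

    def test_double_flip_is_identity(self):
        """Negating outcome betas and swapping outcome alleles leaves every
        kept (beta_exp, beta_out) pair unchanged."""
        sim = simulate(SimConfig(seed=23, n_snp=40, n_instruments=20, n_med_instruments=20))
        base = harmonize(sim.exposure, sim.outcome)
        rec = sim.outcome.records.copy()
        rec["beta"] = -rec["beta"]
        rec["eaf"] = 1 - rec["eaf"]
        rec[["effect_allele", "other_allele"]] = rec[["other_allele", "effect_allele"]].to_numpy()
        flipped_outcome = SummaryStats("outcome", rec, "binary")
        twice = harmonize(sim.exposure, flipped_outcome)
        a = base.kept.set_index("snp_id")
        b = twice.kept.set_index("snp_id")
        assert set(a.index) == set(b.index)
        assert np.allclose(a["beta_exp"], b.loc[a.index, "beta_exp"])
        assert np.allclose(a["beta_out"], b.loc[a.index, "beta_out"])
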