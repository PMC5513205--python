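"""Relative-abundance tables: aggregation, filtering, subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_records
from metaratio.abundance import (
    DEFAULT_FILTER_THRESHOLD,
    AbundanceTable,
    DepthError,
    filter_features,
    read_table,
    relative_abundance,
    subsample_units,
    write_table,
)


class TestRelativeAbundance:
    def test_direct_division_at_genus(self, small_tree):
        rec = make_records(
            [
                ("S01", "MG", "g__Faecalibacterium", "K1", 50),
                ("S01", "MG", "g__Ruminococcus", "K1", 30),
                ("S01", "MG", "g__Bacteroides", "K1", 20),
            ]
        )
        table = relative_abundance(rec, "genus", tree=small_tree)
        np.testing.assert_allclose(
            table.data["S01"].loc[
                ["g__Faecalibacterium", "g__Ruminococcus", "g__Bacteroides"]
            ],
            [0.5, 0.3, 0.2],
        )

    def test_genus_counts_pool_at_phylum(self, small_tree):
        rec = make_records(
            [
                ("S01", "MG", "g__Faecalibacterium", "K1", 30),
                ("S01", "MG", "g__Ruminococcus", "K1", 30),
                ("S01", "MG", "g__Bacteroides", "K1", 40),
            ]
        )
        table = relative_abundance(rec, "phylum", tree=small_tree)
        assert table.data.loc["p__Firmicutes", "S01"] == pytest.approx(0.6)
        assert table.data.loc["p__Bacteroidetes", "S01"] == pytest.approx(0.4)

    def test_records_above_rank_excluded(self, small_tree):
        """A family-level assignment cannot contribute to a genus table."""
        rec = make_records(
            [
                ("S01", "MG", "f__Ruminococcaceae", "K1", 50),
                ("S01", "MG", "g__Bacteroides", "K1", 50),
            ]
        )
        table = relative_abundance(rec, "genus", tree=small_tree)
        assert list(table.data.index) == ["g__Bacteroides"]
        assert table.data.loc["g__Bacteroides", "S01"] == 1.0

    def test_ko_level_skips_unannotated(self, small_tree):
        rec = make_records(
            [
                ("S01", "MG", "g__Bacteroides", "K1", 60),
                ("S01", "MG", "g__Bacteroides", "unannotated", 40),
            ]
        )
        annotated = relative_abundance(rec, "KO", tree=small_tree)
        assert annotated.data.loc["K1", "S01"] == 1.0
        all_denom = relative_abundance(
            rec, "KO", tree=small_tree, denominator="all"
        )
        assert all_denom.data.loc["K1", "S01"] == pytest.approx(0.6)

    def test_ko_cross_genus_keys(self, small_tree):
        rec = make_records(
            [
                ("S01", "MP", "g__Faecalibacterium", "K1", 25),
                ("S01", "MP", "g__Bacteroides", "K1", 25),
                ("S01", "MP", "g__Bacteroides", "K2", 50),
            ]
        )
        table = relative_abundance(rec, "KO×genus", tree=small_tree)
        assert table.data.loc["K1|g__Faecalibacterium", "S01"] == pytest.approx(0.25)
        assert table.data.loc["K2|g__Bacteroides", "S01"] == pytest.approx(0.5)

    def test_mixed_layers_require_explicit_layer(self, small_tree):
        rec = make_records(
            [
                ("S01", "MG", "g__Bacteroides", "K1", 10),
                ("S01", "MP", "g__Bacteroides", "K1", 10),
            ]
        )
        with pytest.raises(ValueError, match="multiple layers"):
            relative_abundance(rec, "genus", tree=small_tree)

    @pytest.mark.parametrize("level", ["genus", "phylum", "KO", "KO×phylum"])
    def test_columns_sum_to_one(self, small_cohort, gut_tree, level):
        records, _ = small_cohort
        table = relative_abundance(records, level, tree=gut_tree, layer="MG")
        np.testing.assert_allclose(table.data.sum(axis=0), 1.0, atol=1e-9)

    def test_genus_to_phylum_aggregation_commutes(self, small_cohort, gut_tree):
        records, _ = small_cohort
        genus = relative_abundance(records, "genus", tree=gut_tree, layer="MG")
        phylum = relative_abundance(records, "phylum", tree=gut_tree, layer="MG")
        pooled = genus.data.groupby(
            genus.data.index.map(lambda g: gut_tree.ancestor_at_rank(g, "phylum"))
        ).sum()
        pd.testing.assert_frame_equal(
            pooled.sort_index(), phylum.data.sort_index(), check_names=False
        )


class TestFilterFeatures:
    def make_table(self, rows, subjects):
        df = pd.DataFrame(rows, columns=subjects)
        df.index = [f"f{i}" for i in range(len(rows))]
        return AbundanceTable(data=df, layer="MG", level="KO")

    def test_strict_threshold_boundary(self):
        table = self.make_table(
            [[1e-4, 1e-4], [2e-2, 2e-2], [0.0, 0.0]], ["S01", "S02"]
        )
        kept = filter_features(table, DEFAULT_FILTER_THRESHOLD)
        # mean exactly 1e-4 removed (strict >), 0.02 retained, all-zero removed
        assert list(kept.data.index) == ["f1"]
        assert kept.filtered

    def test_no_renormalization_after_filter(self):
        table = self.make_table([[0.9, 0.8], [0.1, 0.2]], ["S01", "S02"])
        kept = filter_features(table, threshold=0.2)
        assert kept.data.loc["f0", "S01"] == 0.9


class TestSubsample:
    def test_full_sample_is_identity(self, small_cohort):
        records, spec = small_cohort
        out = subsample_units(records, spec.mg_depth, seed=1)
        mg_before = records[records.layer == "MG"].reset_index(drop=True)
        mg_after = out[out.layer == "MG"].reset_index(drop=True)
        pd.testing.assert_frame_equal(mg_before, mg_after)

    def test_zero_sample_empties_layer(self, small_cohort):
        records, _ = small_cohort
        out = subsample_units(records, 0, seed=1)
        assert out[out.layer == "MG"].empty
        assert len(out[out.layer == "MP"]) == len(records[records.layer == "MP"])

    def test_oversampling_names_subject(self, small_cohort):
        records, spec = small_cohort
        with pytest.raises(DepthError, match="S01"):
            subsample_units(records, spec.mg_depth + 1, seed=1)

    def test_deterministic_given_seed(self, small_cohort):
        records, _ = small_cohort
        a = subsample_units(records, 5000, seed=9)
        b = subsample_units(records, 5000, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_retention_follows_hypergeometric(self):
        """Retained count of a k-of-N feature matches Hypergeom(N, k, n)."""
        rec = make_records(
            [
                ("S01", "MG", "g__A", "K1", 300),
                ("S01", "MG", "g__A", "K2", 700),
            ]
        )
        N, k, n = 1000, 300, 250
        draws = []
        for seed in range(100):
            out = subsample_units(rec, n, seed=seed)
            kept = out[out.function == "K1"]["weight"].sum()
            draws.append(kept)
        expected = stats.hypergeom(N, k, n).mean()
        se = stats.hypergeom(N, k, n).std() / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected) < 3 * se


class TestTableIO:
    def test_tsv_round_trip_with_metadata(self, small_cohort, gut_tree, tmp_path):
        records, _ = small_cohort
        table = relative_abundance(records, "genus", tree=gut_tree, layer="MP")
        table = filter_features(table)
        path = tmp_path / "table.tsv"
        write_table(table, path)
        back = read_table(path)
        assert back.layer == "MP"
        assert back.level == "genus"
        assert back.filtered
        pd.testing.assert_frame_equal(back.data, table.data)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_random_record_sets_conserve_mass(seed):
    """Columns sum to 1 at every level for arbitrary random record sets."""
    rng = np.random.default_rng(seed)
    taxa = ["g__Faecalibacterium", "g__Ruminococcus", "g__Coprococcus",
            "g__Bacteroides"]
    rows = []
    for s in range(rng.integers(1, 4)):
        for _ in range(rng.integers(1, 8)):
            rows.append(
                (f"S{s:02d}", "MG", taxa[rng.integers(0, len(taxa))],
                 f"K{rng.integers(1, 4)}", int(rng.integers(1, 50)))
            )
    rec = make_records(rows)
    from metaratio.taxonomy import build_taxonomy

    tree = build_taxonomy(
        [
            ("p__Firmicutes", "root", "phylum", "Firmicutes"),
            ("p__Bacteroidetes", "root", "phylum", "Bacteroidetes"),
            ("g__Faecalibacterium", "p__Firmicutes", "genus", "F"),
            ("g__Ruminococcus", "p__Firmicutes", "genus", "R"),
            ("g__Coprococcus", "p__Firmicutes", "genus", "C"),
            ("g__Bacteroides", "p__Bacteroidetes", "genus", "B"),
        ]
    )
    for level in ("genus", "phylum", "KO"):
        table = relative_abundance(rec, level, tree=tree, layer="MG")
        np.testing.assert_allclose(table.data.sum(axis=0), 1.0, atol=1e-9)
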