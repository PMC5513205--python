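"""Attribution matrix: prevalence rules, conservation, shares."""

import numpy as np
import pytest

from conftest import make_records
from metaratio.attribution import (
    TOTAL_COL,
    TOTAL_ROW,
    PathwayConfig,
    build_attribution,
    default_pathways,
    pathway_shares,
    taxon_shares,
    write_matrix,
)


@pytest.fixture
def two_pathway_config():
    return PathwayConfig.from_items(
        [("PathX", ["K1", "K2"]), ("PathY", ["K3"])]
    )


def cohort_records(n_subjects, ko_by_genus):
    """Records where every listed (genus, KO, weight) appears in each subject."""
    rows = []
    for i in range(n_subjects):
        for genus, ko, w in ko_by_genus:
            rows.append((f"S{i:02d}", "MP", genus, ko, w))
    return make_records(rows)


class TestPathwayConfig:
    def test_duplicate_ko_rejected(self):
        with pytest.raises(ValueError, match="exactly one pathway"):
            PathwayConfig.from_items([("A", ["K1"]), ("B", ["K1"])])

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PathwayConfig(())

    def test_file_round_trip(self, tmp_path, two_pathway_config):
        path = tmp_path / "pathways.tsv"
        two_pathway_config.to_file(path)
        back = PathwayConfig.from_file(path)
        assert back == two_pathway_config

    def test_default_config_is_valid(self):
        config = default_pathways()
        assert "Glycolysis" in [p for p, _ in config.pathways]
        assert len(config.kos) == len(set(config.kos))


class TestPrevalenceRules:
    def test_ko_below_half_cohort_dropped_but_counted_in_pathway(
        self, small_tree, two_pathway_config
    ):
        """A KO in 7 of 15 subjects loses its row (needs >= 8) yet still
        contributes to its pathway total."""
        rows = []
        for i in range(15):
            rows.append((f"S{i:02d}", "MP", "g__Bacteroides", "K1", 50))
            if i < 7:  # K2 detected in only 7 subjects
                rows.append((f"S{i:02d}", "MP", "g__Bacteroides", "K2", 30))
            rows.append((f"S{i:02d}", "MP", "g__Faecalibacterium", "K3", 20))
        matrix = build_attribution(
            make_records(rows), two_pathway_config, small_tree, n_subjects=15
        )
        assert "K2" not in matrix.values.index
        assert "K1" in matrix.values.index
        # pathway total includes the dropped K2 abundance
        assert matrix.values.loc["PathX", TOTAL_COL] > matrix.values.loc[
            "K1", TOTAL_COL
        ]

    def test_ko_at_exactly_half_retained_for_even_cohort(
        self, small_tree, two_pathway_config
    ):
        rows = []
        for i in range(10):
            rows.append((f"S{i:02d}", "MP", "g__Bacteroides", "K1", 10))
            if i < 5:
                rows.append((f"S{i:02d}", "MP", "g__Bacteroides", "K3", 10))
        matrix = build_attribution(
            make_records(rows), two_pathway_config, small_tree, n_subjects=10
        )
        assert "K3" in matrix.values.index  # 5 of 10 = ceil(10/2)

    def test_genus_two_subject_rule(self, small_tree, two_pathway_config):
        rows = []
        for i in range(15):
            rows.append((f"S{i:02d}", "MP", "g__Bacteroides", "K1", 50))
        # Faecalibacterium expresses K1 in exactly 2 subjects -> retained
        rows += [("S00", "MP", "g__Faecalibacterium", "K1", 5),
                 ("S01", "MP", "g__Faecalibacterium", "K1", 5)]
        # Ruminococcus in exactly 1 subject -> dropped as a column
        rows += [("S00", "MP", "g__Ruminococcus", "K1", 5)]
        matrix = build_attribution(
            make_records(rows), two_pathway_config, small_tree, n_subjects=15
        )
        assert "g__Faecalibacterium" in matrix.values.columns
        assert "g__Ruminococcus" not in matrix.values.columns
        # but the dropped genus still contributes to its phylum total
        firmicutes = matrix.values.loc[TOTAL_ROW, "p__Firmicutes"]
        faecali = matrix.values.loc[TOTAL_ROW, "g__Faecalibacterium"]
        assert firmicutes > faecali

    def test_single_contributor_phylum_equals_genus(
        self, small_tree, two_pathway_config
    ):
        records = cohort_records(
            4,
            [("g__Faecalibacterium", "K3", 30), ("g__Bacteroides", "K1", 70)],
        )
        matrix = build_attribution(
            records, two_pathway_config, small_tree, n_subjects=4
        )
        np.testing.assert_allclose(
            matrix.values["p__Firmicutes"], matrix.values["g__Faecalibacterium"]
        )

    def test_row_and_column_conservation(self, small_tree, two_pathway_config):
        rng = np.random.default_rng(4)
        genera = ["g__Faecalibacterium", "g__Ruminococcus", "g__Bacteroides"]
        rows = []
        for i in range(6):
            for g in genera:
                for k in ["K1", "K2", "K3"]:
                    if rng.random() < 0.7:
                        rows.append((f"S{i:02d}", "MP", g, k, int(rng.integers(1, 99))))
        matrix = build_attribution(
            make_records(rows), two_pathway_config, small_tree, n_subjects=6
        )
        v = matrix.values
        # grand total row = sum of pathway rows; grand total col = sum of phyla
        np.testing.assert_allclose(
            v.loc[TOTAL_ROW], v.loc[["PathX", "PathY"]].sum(axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            v[TOTAL_COL], v[matrix.phylum_cols].sum(axis=1), atol=1e-12
        )
        # pathway rows dominate every member KO row (pre-log abundances)
        for k in matrix.retained_kos:
            pw = matrix.config.ko_to_pathway[k]
            assert (v.loc[pw] >= v.loc[k] - 1e-15).all()

    def test_monotone_in_added_records(self, small_tree, two_pathway_config):
        """Adding records never removes a retained row or column."""
        base = cohort_records(6, [("g__Bacteroides", "K1", 10)])
        extra = cohort_records(
            6, [("g__Bacteroides", "K1", 10), ("g__Faecalibacterium", "K3", 10)]
        )
        m1 = build_attribution(base, two_pathway_config, small_tree, n_subjects=6)
        m2 = build_attribution(extra, two_pathway_config, small_tree, n_subjects=6)
        assert set(m1.retained_kos) <= set(m2.retained_kos)
        assert set(m1.retained_genera) <= set(m2.retained_genera)

    def test_log_values_finite_everywhere(self, small_tree, two_pathway_config):
        records = cohort_records(4, [("g__Bacteroides", "K1", 10)])
        matrix = build_attribution(
            records, two_pathway_config, small_tree, n_subjects=4
        )
        assert np.isfinite(matrix.log_values.values).all()

    def test_empty_layer_rejected(self, small_tree, two_pathway_config):
        records = cohort_records(3, [("g__Bacteroides", "K9", 10)])  # no config KO
        with pytest.raises(ValueError, match="no records"):
            build_attribution(records, two_pathway_config, small_tree)


class TestShares:
    def test_single_pathway_share_is_one(self, small_tree):
        config = PathwayConfig.from_items([("Only", ["K1"])])
        records = cohort_records(3, [("g__Bacteroides", "K1", 10)])
        matrix = build_attribution(records, config, small_tree, n_subjects=3)
        assert pathway_shares(matrix) == {"Only": pytest.approx(1.0)}
        assert taxon_shares(matrix)["p__Bacteroidetes"] == pytest.approx(1.0)

    def test_three_to_one_abundance_ratio(self, small_tree, two_pathway_config):
        records = cohort_records(
            3, [("g__Bacteroides", "K1", 75), ("g__Bacteroides", "K3", 25)]
        )
        matrix = build_attribution(
            records, two_pathway_config, small_tree, n_subjects=3
        )
        shares = pathway_shares(matrix)
        assert shares["PathX"] == pytest.approx(0.75)
        assert shares["PathY"] == pytest.approx(0.25)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_shares_invariant_under_depth_rescaling(
        self, small_tree, two_pathway_config
    ):
        r1 = cohort_records(
            3, [("g__Bacteroides", "K1", 30), ("g__Faecalibacterium", "K3", 10)]
        )
        r2 = cohort_records(
            3, [("g__Bacteroides", "K1", 300), ("g__Faecalibacterium", "K3", 100)]
        )
        m1 = build_attribution(r1, two_pathway_config, small_tree, n_subjects=3)
        m2 = build_attribution(r2, two_pathway_config, small_tree, n_subjects=3)
        for key, val in pathway_shares(m1).items():
            assert pathway_shares(m2)[key] == pytest.approx(val)
        for key, val in taxon_shares(m1).items():
            assert taxon_shares(m2)[key] == pytest.approx(val)

    def test_matrix_tsv_written_with_prevalence_sidecar(
        self, small_tree, two_pathway_config, tmp_path
    ):
        records = cohort_records(3, [("g__Bacteroides", "K1", 10)])
        matrix = build_attribution(
            records, two_pathway_config, small_tree, n_subjects=3
        )
        path = tmp_path / "attribution.tsv"
        write_matrix(matrix, path)
        assert path.exists()
        assert (tmp_path / "attribution.tsv.prevalence").exists()
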