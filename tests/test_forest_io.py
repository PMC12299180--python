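"""Input readers/writers, tiling arithmetic, stages and community matrices."""

import numpy as np
import pandas as pd
import pytest

import phylograin as pg
from phylograin.forest_io import (
    LifeStage,
    QuadratGrid,
    StemTableError,
    build_community_matrix,
    classify_life_stage,
    read_ascii_grid,
    write_ascii_grid,
)


def _stems(rows):
    return pd.DataFrame(rows, columns=["stem_id", "x", "y", "species", "dbh_cm"])


class TestStemTable:
    def test_round_trip(self, small_forest, tmp_path):
        _tree, _dem, stems = small_forest
        path = tmp_path / "stems.csv"
        pg.write_stem_table(stems, path)
        back = pg.read_stem_table(path, plot_side=50)
        pd.testing.assert_frame_equal(stems, back)

    def test_census_floor_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        _stems([("a", 1, 1, "A", 0.5)]).to_csv(path, index=False)
        with pytest.raises(StemTableError, match="census floor"):
            pg.read_stem_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"stem_id": ["a"], "x": [1]}).to_csv(path, index=False)
        with pytest.raises(StemTableError, match="missing columns"):
            pg.read_stem_table(path)

    def test_out_of_plot_coordinate_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        _stems([("a", 55.0, 1, "A", 4.0)]).to_csv(path, index=False)
        with pytest.raises(StemTableError, match="outside"):
            pg.read_stem_table(path, plot_side=50)


class TestLifeStage:
    @pytest.mark.parametrize(
        "dbh,stage",
        [(4.99, LifeStage.SAPLING), (5.0, LifeStage.JUVENILE),
         (14.99, LifeStage.JUVENILE), (15.0, LifeStage.ADULT), (1.01, LifeStage.SAPLING)],
    )
    def test_bin_boundaries(self, dbh, stage):
        assert classify_life_stage(dbh) is stage

    def test_census_floor_is_error(self):
        with pytest.raises(ValueError):
            classify_life_stage(1.0)


class TestQuadratGrid:
    def test_published_plot_tiling(self):
        assert QuadratGrid(340, 20).n_quadrats == 289
        assert QuadratGrid(340, 5).n_quadrats == 4624

    def test_half_open_convention(self):
        grid = QuadratGrid(340, 5)
        assert grid.assign([0.0], [0.0])[0] == 0
        assert grid.assign([5.0], [0.0])[0] == 1
        # far boundary folds into the last cell
        assert grid.assign([340.0], [340.0])[0] == grid.n_quadrats - 1

    def test_indivisible_scale_rejected(self):
        with pytest.raises(ValueError):
            QuadratGrid(340, 3)

    def test_nesting_conservation(self, small_forest):
        # four 2.5 m children sum to their 5 m parent; likewise 5 -> 10 m
        _tree, _dem, stems = small_forest
        for child_s, parent_s in [(2.5, 5.0), (5.0, 10.0)]:
            child = QuadratGrid(50, child_s)
            parent = QuadratGrid(50, parent_s)
            cm_child = build_community_matrix(stems, child).counts
            cm_parent = build_community_matrix(stems, parent).counts
            rolled = cm_child.groupby(child.parent_ids(parent)).sum()
            rolled = rolled.reindex(range(parent.n_quadrats), fill_value=0)
            rolled = rolled.reindex(columns=cm_parent.columns, fill_value=0)
            assert np.array_equal(rolled.to_numpy(), cm_parent.to_numpy())


class TestCommunityMatrix:
    def test_counts_and_richness(self):
        stems = _stems([("a", 1, 1, "A", 4), ("b", 2, 2, "A", 4), ("c", 30, 30, "B", 4)])
        cm = build_community_matrix(stems, QuadratGrid(40, 10))
        assert cm.counts.loc[0, "A"] == 2
        assert cm.richness[0] == 1
        assert cm.counts.to_numpy().sum() == 3

    def test_stage_partition_sums_to_whole(self, small_forest):
        _tree, _dem, stems = small_forest
        grid = QuadratGrid(50, 5)
        whole = build_community_matrix(stems, grid).counts
        parts = sum(
            build_community_matrix(stems, grid, stage=s).counts
            .reindex(columns=whole.columns, fill_value=0)
            for s in ("sapling", "juvenile", "adult")
        )
        assert np.array_equal(parts.to_numpy(), whole.to_numpy())

    def test_stage_filter_drops_other_stages(self):
        stems = _stems([("a", 1, 1, "A", 20), ("b", 2, 2, "B", 4)])
        cm = build_community_matrix(stems, QuadratGrid(40, 10), stage="adult")
        assert list(cm.counts.columns) == ["A"]
        assert cm.counts.to_numpy().sum() == 1

    def test_empty_quadrats_flagged_not_dropped(self):
        stems = _stems([("a", 1, 1, "A", 4)])
        cm = build_community_matrix(stems, QuadratGrid(40, 10))
        assert len(cm.counts) == 16
        assert len(cm.empty_quadrats) == 15


class TestNewick:
    def test_prune_preserves_paths(self, three_taxon_tree):
        pruned = pg.prune_to_species(three_taxon_tree, {"A", "C"})
        d, labels = pg.cophenetic_distances(pruned)
        assert labels == ["A", "C"]
        assert d[0, 1] == pytest.approx(4.0)

    def test_prune_to_all_is_identity(self, three_taxon_tree):
        pruned = pg.prune_to_species(three_taxon_tree, {"A", "B", "C"})
        d0, _ = pg.cophenetic_distances(three_taxon_tree)
        d1, _ = pg.cophenetic_distances(pruned)
        assert np.allclose(d0, d1)

    def test_prune_missing_species_named(self, three_taxon_tree):
        with pytest.raises(ValueError, match="Z"):
            pg.prune_to_species(three_taxon_tree, {"A", "B", "Z"})

    def test_newick_round_trip(self, tmp_path, small_forest):
        tree, _dem, _stems = small_forest
        path = tmp_path / "t.nwk"
        pg.write_newick(tree, path)
        back = pg.read_newick(path)
        d0, l0 = pg.cophenetic_distances(tree)
        d1, l1 = pg.cophenetic_distances(back)
        assert l0 == l1
        assert np.allclose(d0, d1)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        dem = pg.simulate_dem(40, 5, 6.0, seed=2)
        path = tmp_path / "dem.asc"
        write_ascii_grid(dem, path)
        back = read_ascii_grid(path)
        assert np.allclose(back.values, dem.values)
        assert back.cellsize == dem.cellsize

    def test_header_orientation(self, tmp_path):
        # first body row of the file is the northern (max-y) edge
        dem = pg.DemGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 5.0)
        path = tmp_path / "d.asc"
        write_ascii_grid(dem, path)
        body = path.read_text().strip().splitlines()[6:]
        assert body[0].split() == ["3", "4"]
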