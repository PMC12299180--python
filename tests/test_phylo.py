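"""Phylogenetic metrics against hand sums and brute-force path oracles."""

import numpy as np
import pandas as pd
import pytest

import phylograin as pg
from phylograin.forest_io import QuadratGrid, build_community_matrix
from phylograin.phylo import (
    NullModelConfig,
    cophenetic_distances,
    faith_pd,
    mntd,
    mpd,
    ses_metrics,
    stage_summary,
)


def path_sum_distance(tree, lab_a, lab_b):
    """Independent oracle: sum of edge lengths along the tip-to-tip path."""
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}

    def root_path(leaf):
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa, pb = root_path(leaves[lab_a]), root_path(leaves[lab_b])
    ids_a = {id(n): i for i, n in enumerate(pa)}
    mrca = next(n for n in pb if id(n) in ids_a)
    total = 0.0
    for path in (pa, pb):
        for node in path:
            if node is mrca:
                break
            total += node.edge.length
    return total


class TestCopheneticDistances:
    def test_hand_example(self, three_taxon_tree):
        d, labels = cophenetic_distances(three_taxon_tree)
        assert labels == ["A", "B", "C"]
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 2] == pytest.approx(4.0)
        assert d[1, 2] == pytest.approx(4.0)

    def test_ultrametric_bound(self):
        tree = pg.simulate_phylogeny(12, seed=5)
        d, _ = cophenetic_distances(tree)
        assert d.max() <= 2.0 + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_sum_oracle(self, seed):
        tree = pg.simulate_phylogeny(8, seed=seed)
        d, labels = cophenetic_distances(tree)
        for i in range(8):
            for j in range(i + 1, 8):
                assert d[i, j] == pytest.approx(
                    path_sum_distance(tree, labels[i], labels[j])
                )


class TestFaithPD:
    def test_star_tree(self):
        star = pg.read_newick("(A:1,B:1,C:1);")
        assert faith_pd({"A", "B"}, star) == pytest.approx(2.0)

    def test_all_tips_recover_total_length(self, three_taxon_tree):
        total = sum(
            e.length for e in three_taxon_tree.preorder_edge_iter()
            if e.length is not None
        )
        assert faith_pd({"A", "B", "C"}, three_taxon_tree) == pytest.approx(total)

    def test_root_inclusive_pair(self, three_taxon_tree):
        # two tip branches plus the stem back to the root
        assert faith_pd({"A", "B"}, three_taxon_tree) == pytest.approx(3.0)

    def test_empty_community(self, three_taxon_tree):
        assert faith_pd(set(), three_taxon_tree) == 0.0

    def test_monotone_in_species(self):
        tree = pg.simulate_phylogeny(10, seed=2)
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(1, 9)
            comm = set(rng.choice(labels, size=k, replace=False))
            extra = comm | {rng.choice([s for s in labels if s not in comm])}
            assert faith_pd(extra, tree) >= faith_pd(comm, tree) - 1e-12


class TestMpdMntd:
    def test_two_species(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        both = np.array([True, True])
        assert mpd(d, both) == pytest.approx(2.0)
        assert mntd(d, both) == pytest.approx(2.0)

    def test_hand_example(self, three_taxon_tree):
        d, _ = cophenetic_distances(three_taxon_tree)
        allsp = np.array([True] * 3)
        assert mpd(d, allsp) == pytest.approx(10 / 3)
        assert mntd(d, allsp) == pytest.approx(8 / 3)

    def test_undefined_below_two_species(self):
        d = np.zeros((3, 3))
        assert np.isnan(mpd(d, np.array([True, False, False])))
        assert np.isnan(mntd(d, np.array([False] * 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_bound(self, seed):
        tree = pg.simulate_phylogeny(8, seed=100 + seed)
        d, _ = cophenetic_distances(tree)
        rng = np.random.default_rng(seed)
        idx = rng.choice(8, size=5, replace=False)
        pairs = [(i, j) for a, i in enumerate(idx) for j in idx[a + 1:]]
        brute_mpd = np.mean([d[i, j] for i, j in pairs])
        brute_mntd = np.mean([min(d[i, j] for j in idx if j != i) for i in idx])
        assert mpd(d, idx) == pytest.approx(brute_mpd)
        assert mntd(d, idx) == pytest.approx(brute_mntd)
        assert mntd(d, idx) <= d[np.ix_(idx, idx)].max() + 1e-12

    def test_relabel_invariance(self):
        tree = pg.simulate_phylogeny(8, seed=3)
        d, _ = cophenetic_distances(tree)
        idx = np.array([0, 2, 5])
        perm = np.random.default_rng(1).permutation(8)
        dp = d[np.ix_(perm, perm)]
        mapped = np.array([int(np.flatnonzero(perm == i)[0]) for i in idx])
        assert mpd(dp, mapped) == pytest.approx(mpd(d, idx))
        assert mntd(dp, mapped) == pytest.approx(mntd(d, idx))


@pytest.fixture(scope="module")
def ses_run(small_forest):
    tree, _dem, stems = small_forest
    cm = build_community_matrix(stems, QuadratGrid(50, 5))
    cfg = NullModelConfig(n_rand=199, seed=42)
    return cm, tree, ses_metrics(cm, tree, cfg)


class TestSesMetrics:
    def test_seed_reproducibility(self, ses_run):
        cm, tree, rows = ses_run
        again = ses_metrics(cm, tree, NullModelConfig(n_rand=199, seed=42))
        pd.testing.assert_frame_equal(rows, again)

    def test_whole_pool_community_flagged_undefined(self):
        tree = pg.simulate_phylogeny(5, seed=1)
        labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        counts = pd.DataFrame([[1] * 5], columns=labels)
        cm = pg.forest_io.CommunityMatrix(counts=counts, scale=5.0)
        rows = ses_metrics(cm, tree, NullModelConfig(n_rand=99, seed=0))
        assert not rows.loc[0, "valid"]
        assert np.isnan(rows.loc[0, "NRI"])

    def test_branch_length_scale_invariance(self, small_forest):
        tree, _dem, stems = small_forest
        cm = build_community_matrix(stems, QuadratGrid(50, 10))
        cfg = NullModelConfig(n_rand=99, seed=7)
        base = ses_metrics(cm, tree, cfg)
        scaled_tree = tree.clone(depth=1)
        for e in scaled_tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 3.7
        scaled = ses_metrics(cm, scaled_tree, cfg)
        v = base["valid"]
        assert np.allclose(base.loc[v, "NRI"], scaled.loc[v, "NRI"], atol=1e-9)
        assert np.allclose(base.loc[v, "NTI"], scaled.loc[v, "NTI"], atol=1e-9)
        assert np.allclose(scaled.loc[v, "PD"], 3.7 * base.loc[v, "PD"])

    def test_sr_pd_columns_consistent(self, ses_run):
        _cm, _tree, rows = ses_run
        assert (rows["SR"] >= 0).all()
        assert (rows["PD"] >= 0).all()
        assert (rows.loc[rows["SR"] == 0, "PD"] == 0).all()
        # NRI defined exactly where valid
        assert rows["NRI"].notna().equals(rows["valid"])


class TestStageSummary:
    def _rows(self, nri):
        n = len(nri)
        return pd.DataFrame(
            {"scale": 5.0, "stage": "community", "NRI": nri, "NTI": nri,
             "valid": [True] * n}
        )

    def test_zero_signal_not_significant(self):
        rng = np.random.default_rng(0)
        out = stage_summary(self._rows(rng.normal(0, 1, 200)))
        assert (out["p"] > 0.05).all()

    def test_shifted_signal_detected(self):
        rng = np.random.default_rng(0)
        out = stage_summary(self._rows(rng.normal(0.5, 1, 200)))
        assert (out["p"] < 0.01).all()
        assert (out["mean"] > 0).all()

    def test_panel_layout(self):
        frames = []
        rng = np.random.default_rng(1)
        for scale in (2.5, 5.0, 10.0):
            for stage in ("community", "sapling", "juvenile", "adult"):
                f = self._rows(rng.normal(0, 1, 20))
                f["scale"], f["stage"] = scale, stage
                frames.append(f)
        out = stage_summary(pd.concat(frames, ignore_index=True))
        # 3 scales x 4 stage groupings per metric
        assert len(out[out["metric"] == "NRI"]) == 12
        assert len(out) == 24

    def test_too_few_quadrats_flagged(self):
        out = stage_summary(self._rows(np.array([0.1, 0.2])))
        assert not out["ok"].any()
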