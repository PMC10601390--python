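"""Hot-node clade enrichment: counts, permutation null, annotation."""

import numpy as np
import pytest
from scipy import stats

from ethnophylo._treemath import tree_arrays
from ethnophylo.hotnodes import (
    annotate_tree,
    clade_counts,
    hot_node_scan,
    read_annotations,
    results_frame,
)
from ethnophylo.phylo_io import Phylogeny
from ethnophylo.synthetic_data import simulate_tree

from .conftest import clade_counts_oracle

SIX_TIP = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);"


def _trait(phy, positives):
    return {lab: int(lab in positives) for lab in phy.tip_labels}


class TestCladeCounts:
    def test_root_count_is_total(self):
        phy = Phylogeny.from_newick(SIX_TIP)
        df = clade_counts(phy, _trait(phy, {"A", "B", "E"}))
        root = df[df.clade_size == 6]
        assert root.focal_count.iloc[0] == 3

    def test_counts_match_descendant_enumeration(self):
        phy = Phylogeny.from_newick(SIX_TIP)
        trait = _trait(phy, {"A", "B", "E"})
        df = clade_counts(phy, trait)
        arrays = tree_arrays(phy)
        oracle = clade_counts_oracle(phy, trait)
        for node_id in df.index:
            tips = frozenset(
                arrays.tip_labels[i] for i in np.flatnonzero(arrays.clade[node_id])
            )
            size, count = oracle[tips]
            assert df.loc[node_id, "clade_size"] == size
            assert df.loc[node_id, "focal_count"] == count

    def test_parent_counts_dominate_children(self):
        phy = simulate_tree(50, seed=1)
        rng = np.random.default_rng(2)
        trait = dict(zip(phy.tip_labels, (int(v) for v in rng.integers(0, 2, 50))))
        arrays = tree_arrays(phy)
        df = clade_counts(phy, trait)
        for i in range(arrays.n_nodes):
            p = arrays.parent[i]
            if p >= 0:
                assert df.loc[p, "focal_count"] >= df.loc[i, "focal_count"]


class TestHotNodeScan:
    def test_min_clade_floor_filters_output(self):
        phy = simulate_tree(80, seed=3)
        trait = dict(
            zip(phy.tip_labels,
                (int(v) for v in np.random.default_rng(4).integers(0, 2, 80)))
        )
        results = hot_node_scan(phy, trait, min_clade=10, n_perm=99, seed=5)
        assert results
        assert all(r.clade_size >= 10 for r in results)

    def test_null_moments_match_hypergeometric(self):
        """Shuffling k positives over n tips makes each clade's count
        hypergeometric(n, k, m); permutation moments must agree."""
        phy = simulate_tree(100, seed=6)
        n, k = 100, 30
        trait = dict(
            zip(phy.tip_labels, (int(i < k) for i in range(n)))
        )
        results = hot_node_scan(phy, trait, min_clade=10, n_perm=999, seed=7)
        for r in results:
            m = r.clade_size
            want_mean = stats.hypergeom.mean(n, k, m)
            want_sd = stats.hypergeom.std(n, k, m)
            # Monte-Carlo error at 999 draws
            assert r.null_mean == pytest.approx(
                want_mean, abs=4 * want_sd / np.sqrt(999) + 1e-9
            )
            assert r.null_sd == pytest.approx(want_sd, rel=0.15)

    def test_planted_clade_flagged_hot(self):
        phy = simulate_tree(300, seed=8)
        arrays = tree_arrays(phy)
        sizes = arrays.clade_sizes
        node = int(np.flatnonzero((~arrays.is_tip) & (sizes >= 25) & (sizes <= 35))[0])
        positives = {
            arrays.tip_labels[i] for i in np.flatnonzero(arrays.clade[node])
        }
        results = hot_node_scan(phy, _trait(phy, positives), n_perm=999, seed=9)
        hot_hashes = {r.node_id for r in results if r.is_hot}
        assert node in hot_hashes

    def test_constant_trait_degenerate_warns(self):
        phy = simulate_tree(30, seed=10)
        results = hot_node_scan(phy, dict.fromkeys(phy.tip_labels, 1),
                                n_perm=49, seed=11)
        assert results
        assert all(np.isnan(r.ses) and not r.is_hot for r in results)

    def test_tip_order_invariance(self):
        """Scan results depend on the labeled tree, not the Newick tip order."""
        phy = simulate_tree(40, seed=12)
        # rotate children at the root to change the written tip order
        rotated_tree = phy.copy().tree
        root = rotated_tree.seed_node
        kids = root.child_nodes()
        root.set_child_nodes(kids[::-1])
        rotated = Phylogeny(rotated_tree)
        trait = _trait(phy, set(list(phy.tip_labels)[:12]))
        res_a = hot_node_scan(phy, trait, n_perm=199, seed=13)
        res_b = hot_node_scan(rotated, trait, n_perm=199, seed=13)
        by_hash_a = {r.tip_hash: r.ses for r in res_a}
        by_hash_b = {r.tip_hash: r.ses for r in res_b}
        assert set(by_hash_a) == set(by_hash_b)
        for h in by_hash_a:
            assert by_hash_a[h] == pytest.approx(by_hash_b[h], abs=1e-12, nan_ok=True)

    def test_maximal_only_collapses_nested_hot_clades(self):
        phy = simulate_tree(300, seed=8)
        arrays = tree_arrays(phy)
        sizes = arrays.clade_sizes
        node = int(np.flatnonzero((~arrays.is_tip) & (sizes >= 25) & (sizes <= 35))[0])
        positives = {
            arrays.tip_labels[i] for i in np.flatnonzero(arrays.clade[node])
        }
        full = hot_node_scan(phy, _trait(phy, positives), n_perm=499, seed=14)
        collapsed = hot_node_scan(
            phy, _trait(phy, positives), n_perm=499, seed=14, maximal_only=True
        )
        hot_full = {r.node_id for r in full if r.is_hot}
        hot_max = {r.node_id for r in collapsed if r.is_hot}
        assert hot_max <= hot_full
        # no kept hot node is the ancestor of another kept hot node
        for a in hot_max:
            for b in hot_max:
                if a != b:
                    assert not arrays.clade[a][arrays.clade[b]].all()


class TestAnnotateTree:
    def test_no_hot_nodes_label_free(self):
        phy = simulate_tree(40, seed=15)
        trait = dict(
            zip(phy.tip_labels,
                (int(v) for v in np.random.default_rng(16).integers(0, 2, 40)))
        )
        results = hot_node_scan(phy, trait, n_perm=99, seed=17)
        out = annotate_tree(phy, results)
        n_hot = sum(r.is_hot for r in results)
        assert len(read_annotations(out)) == n_hot

    def test_round_trip_ses_values(self):
        phy = simulate_tree(300, seed=8)
        arrays = tree_arrays(phy)
        sizes = arrays.clade_sizes
        node = int(np.flatnonzero((~arrays.is_tip) & (sizes >= 25) & (sizes <= 35))[0])
        positives = {
            arrays.tip_labels[i] for i in np.flatnonzero(arrays.clade[node])
        }
        results = hot_node_scan(phy, _trait(phy, positives), n_perm=499, seed=18)
        out = annotate_tree(phy, results)
        reparsed = Phylogeny.from_newick(out.to_newick())
        labels = read_annotations(reparsed)
        hot = {r.node_id: r.ses for r in results if r.is_hot}
        assert len(labels) == len(hot)
        assert sorted(labels.values()) == pytest.approx(
            sorted(round(v, 4) for v in hot.values()), abs=1e-4
        )

    def test_stale_results_rejected(self):
        phy = simulate_tree(40, seed=19)
        other = simulate_tree(40, seed=20)
        trait = _trait(phy, set(list(phy.tip_labels)[:15]))
        results = hot_node_scan(phy, trait, n_perm=99, seed=21)
        from ethnophylo.hotnodes import HotNodeError

        with pytest.raises(HotNodeError):
            annotate_tree(other, results)

    def test_frame_has_expected_columns(self):
        phy = simulate_tree(40, seed=22)
        trait = _trait(phy, set(list(phy.tip_labels)[:10]))
        df = results_frame(hot_node_scan(phy, trait, n_perm=99, seed=23))
        assert list(df.columns) == [
            "node_id", "clade_size", "focal_count", "null_mean",
            "null_sd", "ses", "is_hot", "example_tips",
        ]
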