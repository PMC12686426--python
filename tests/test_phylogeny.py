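"""NJ correctness, bootstrap supports, permutation calibration, Newick I/O."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from mtclone.clones import CloneLabels, HeteroplasmyMatrix
from mtclone.io_formats import write_newick
from mtclone.phylogeny import (
    SupportCalibration,
    _canonical,
    annotate_significant_edges,
    bipartitions,
    bootstrap_support,
    cluster_distance_matrix,
    neighbor_joining,
    permutation_null_threshold,
)
import pandas as pd


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_taxa):
    """Random binary topology with branch lengths in [0.1, 1]; returns
    (ids, additive distance matrix, bipartition keys of the true tree)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]  # j > i
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.extend([b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(0.1, 1.0))
    root.extend(nodes)
    dm = root.tip_tip_distances()
    d = np.array([[dm[a, b] for b in ids] for a in ids])
    return ids, d, set(bipartitions(root, ids))


def four_taxon_ls_topology(d, ids):
    """Exhaustive least-squares over the 3 unrooted 4-taxon topologies.

    Returns the bipartition (as a frozenset pair member) of the best fit.
    """
    best_key, best_rss = None, np.inf
    pairs = list(itertools.combinations(range(4), 2))
    for split in ([(0, 1), (2, 3)], [(0, 2), (1, 3)], [(0, 3), (1, 2)]):
        (a, b), (c, e) = split
        # params: external x4 + internal branch
        rows, y = [], []
        for i, j in pairs:
            row = np.zeros(5)
            row[i] += 1
            row[j] += 1
            same_cherry = {i, j} in ({a, b}, {c, e})
            if not same_cherry:
                row[4] = 1
            rows.append(row)
            y.append(d[i, j])
        beta, rss, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = np.array(y) - np.array(rows) @ beta
        rss = float((resid**2).sum())
        if rss < best_rss:
            best_rss = rss
            best_key = frozenset({ids[a], ids[b]})
    return _canonical(best_key, ids)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _h(af):
    af = np.asarray(af, dtype=float)
    return HeteroplasmyMatrix(
        [f"c{i}" for i in range(af.shape[0])],
        [f"{100 + 7 * j}G>A" for j in range(af.shape[1])],
        af,
        np.zeros_like(af, dtype=bool),
    )


def _labels(assignment):
    return CloneLabels(
        labels=pd.Series(assignment, index=[f"c{i}" for i in range(len(assignment))])
    )


class TestClusterDistances:
    def test_identical_and_orthogonal_centroids(self):
        af = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 0], [1, 0]], dtype=float)
        ids, d = cluster_distance_matrix(_h(af), _labels([0, 0, 1, 1, 2, 2]))
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)  # clusters 0 and 2 identical
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)  # orthogonal
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_matches_direct_cosine_formula(self, rng):
        af = rng.random((9, 4))
        ids, d = cluster_distance_matrix(_h(af), _labels([0] * 3 + [1] * 3 + [2] * 3))
        cents = [af[i * 3 : (i + 1) * 3].mean(axis=0) for i in range(3)]
        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else 1 - np.dot(cents[i], cents[j]) / (
                    np.linalg.norm(cents[i]) * np.linalg.norm(cents[j])
                )
                assert d[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_norm_centroid_rejected(self):
        af = np.array([[1, 0], [0, 0], [0, 0], [0, 1], [1, 1], [1, 1]], dtype=float)
        with pytest.raises(ValueError, match="zero-norm"):
            cluster_distance_matrix(_h(af), _labels([0, 1, 1, 2, 3, 3]))

    def test_needs_three_clusters(self):
        af = np.ones((4, 2))
        with pytest.raises(ValueError, match="at least 3"):
            cluster_distance_matrix(_h(af), _labels([0, 0, 1, 1]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_recovery_and_ls_oracle(self, rng):
        for _ in range(20):
            ids, d, true_bip = random_additive_tree(rng, 4)
            tree = neighbor_joining(d, ids)
            got = set(tree.bipartition_keys())
            assert got == true_bip
            assert four_taxon_ls_topology(d, ids) in got

    @pytest.mark.parametrize("n_taxa", [5, 6])
    def test_additive_recovery(self, rng, n_taxa):
        for _ in range(10):
            ids, d, true_bip = random_additive_tree(rng, n_taxa)
            assert set(neighbor_joining(d, ids).bipartition_keys()) == true_bip

    def test_agrees_with_skbio_nj(self, rng):
        """Independent cross-check: identical bipartition sets to skbio's NJ
        on random (noisy, non-additive) matrices."""
        for _ in range(10):
            n = 6
            base = rng.random((n, n))
            d = base + base.T
            np.fill_diagonal(d, 0)
            ids = [f"t{i}" for i in range(n)]
            mine = set(neighbor_joining(d, ids).bipartition_keys())
            ref = skbio_nj(DistanceMatrix(d, ids))
            assert mine == set(bipartitions(ref, ids))

    def test_taxon_order_invariance(self, rng):
        ids, d, _ = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assert set(neighbor_joining(d, ids).bipartition_keys()) == set(
            neighbor_joining(d2, ids2).bipartition_keys()
        )

    def test_negative_lengths_clamped_with_raw_kept(self):
        d = np.array(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0.0]]
        )
        tree = neighbor_joining(d, list("ABCD"))
        for node in tree.tree.traverse(include_self=False):
            assert node.length >= 0
            assert hasattr(node, "raw_length")

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("ABC"))

    def test_reverse_bipartition_equivalence(self):
        leaves = list("ABCD")
        assert _canonical(frozenset("AB"), leaves) == _canonical(frozenset("CD"), leaves)


# ---------------------------------------------------------------------------
# bootstrap + calibration
# ---------------------------------------------------------------------------


def _four_clone_h(rng, n_per=40, sep=True):
    """Hierarchical 4-clone heteroplasmy: (A,B) share v0, (C,D) share v3."""
    af = np.zeros((4 * n_per, 6))
    blocks = [(0, [0, 1]), (1, [0, 2]), (2, [3, 4]), (3, [3, 5])]
    for ci, cols in blocks:
        rows = slice(ci * n_per, (ci + 1) * n_per)
        for c in cols:
            af[rows, c] = rng.beta(18, 2, size=n_per) if sep else rng.random(n_per)
    h = HeteroplasmyMatrix(
        [f"c{i}" for i in range(4 * n_per)],
        [f"{100 + 7 * j}G>A" for j in range(6)],
        af,
        np.zeros_like(af, dtype=bool),
    )
    labels = CloneLabels(
        labels=pd.Series(np.repeat(np.arange(4), n_per), index=h.cell_ids)
    )
    return h, labels


class TestBootstrap:
    def test_zero_variance_clusters_full_support(self):
        """Clusters of identical cells bootstrap to the same tree: support 1."""
        af = np.repeat(np.array([[0.9, 0, 0], [0, 0.9, 0], [0, 0, 0.9], [0.3, 0.3, 0.3]]), 5, axis=0)
        h = HeteroplasmyMatrix(
            [f"c{i}" for i in range(20)], [f"{100+7*j}G>A" for j in range(3)],
            af, np.zeros_like(af, dtype=bool),
        )
        labels = CloneLabels(labels=pd.Series(np.repeat(np.arange(4), 5), index=h.cell_ids))
        tree = bootstrap_support(h, labels, n_bootstrap=50, seed=0)
        assert all(v == 1.0 for v in tree.supports.values())

    def test_separated_clones_high_support(self, rng):
        h, labels = _four_clone_h(rng)
        tree = bootstrap_support(h, labels, n_bootstrap=200, seed=0)
        key = _canonical(frozenset({"0", "1"}), tree.leaf_names)
        assert tree.supports[key] >= 0.95

    def test_supports_in_unit_interval_and_deterministic(self, rng):
        h, labels = _four_clone_h(rng)
        a = bootstrap_support(h, labels, n_bootstrap=50, seed=5)
        b = bootstrap_support(h, labels, n_bootstrap=50, seed=5)
        assert a.supports == b.supports
        assert all(0 <= v <= 1 for v in a.supports.values())


class TestPermutationNull:
    def test_single_permutation_threshold(self, rng):
        h, labels = _four_clone_h(rng)
        calib = permutation_null_threshold(h, labels, n_permutations=1, n_bootstrap=20, seed=0)
        assert calib.threshold == calib.null_max_supports[0]

    def test_threshold_in_unit_interval(self, rng):
        h, labels = _four_clone_h(rng)
        calib = permutation_null_threshold(h, labels, n_permutations=5, n_bootstrap=20, seed=0)
        assert 0.0 <= calib.threshold <= 1.0
        assert len(calib.null_max_supports) == 5

    def test_real_structure_beats_null(self, rng):
        """Clonal data: the true cherry support exceeds the permutation
        threshold; permuted labels do not produce flagged edges."""
        h, labels = _four_clone_h(rng)
        tree = bootstrap_support(h, labels, n_bootstrap=100, seed=0)
        calib = permutation_null_threshold(h, labels, n_permutations=20, n_bootstrap=100, seed=0)
        tree = annotate_significant_edges(tree, calib)
        assert len(tree.significant_edges()) >= 1
        # permuted labels: rebuild under a shuffled assignment
        perm = labels.labels.copy()
        perm[:] = perm.sample(frac=1.0, random_state=0).to_numpy()
        ptree = bootstrap_support(h, CloneLabels(labels=perm), n_bootstrap=100, seed=1)
        ptree = annotate_significant_edges(ptree, calib)
        assert ptree.significant_edges() == []


class TestAnnotation:
    def _caterpillar_tree(self):
        # (((A,B),C),D,E) with a long E branch so the midpoint root lands on
        # it: the {A,B} cherry's parent edge is then the {A,B,C} split
        ids = list("ABCDE")
        base = TreeNode.read(["(((A:1,B:1):1,C:2):1,D:3,E:8);"])
        dm = base.tip_tip_distances()
        d = np.array([[dm[a, b] for b in ids] for a in ids])
        return neighbor_joining(d, ids)

    def test_all_supported_all_significant(self):
        tree = self._caterpillar_tree()
        tree.supports = {k: 1.0 for k in tree.bipartition_keys()}
        calib = SupportCalibration(10, 1, [0.6], 0.6)
        out = annotate_significant_edges(tree, calib)
        assert len(out.significant_edges()) == len(tree.bipartition_keys())

    def test_weak_parent_blocks_child(self):
        """Support 0.9 on a cherry under a 0.5-support parent edge is not
        flagged at threshold 0.6 (edge and parent must both exceed it)."""
        tree = self._caterpillar_tree()
        parent = _canonical(frozenset("ABC"), tree.leaf_names)
        cherry = _canonical(frozenset("AB"), tree.leaf_names)
        tree.supports = {parent: 0.5, cherry: 0.9}
        calib = SupportCalibration(10, 1, [0.6], 0.6)
        out = annotate_significant_edges(tree, calib)
        assert cherry not in out.significant_edges()
        # raising the parent support rescues the cherry
        tree.supports = {parent: 0.95, cherry: 0.9}
        out2 = annotate_significant_edges(tree, calib)
        assert cherry in out2.significant_edges()

    def test_star_tree_no_internal_edges(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]])
        tree = neighbor_joining(d, list("ABC"))
        assert tree.bipartition_keys() == []
        calib = SupportCalibration(10, 1, [0.5], 0.5)
        assert annotate_significant_edges(tree, calib).significant_edges() == []

    def test_unknown_root_policy(self):
        tree = self._caterpillar_tree()
        calib = SupportCalibration(10, 1, [0.5], 0.5)
        with pytest.raises(ValueError, match="root policy"):
            annotate_significant_edges(tree, calib, root_policy="nonsense")


class TestNewick:
    def test_three_leaf_star_shape(self, tmp_path):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        tree = neighbor_joining(d, list("ABC"))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        for leaf in "ABC":
            assert leaf in text

    def test_round_trip_preserves_topology(self, tmp_path, rng):
        """Writing then parsing with an independent Newick parser keeps the
        bipartition set (and supports as internal labels)."""
        ids, d, true_bip = random_additive_tree(rng, 6)
        tree = neighbor_joining(d, ids)
        tree.supports = {k: 0.75 for k in tree.bipartition_keys()}
        for node in tree.tree.non_tips(include_self=False):
            node.support = 0.75
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = TreeNode.read([path.read_text()])
        assert set(bipartitions(back, ids)) == true_bip
        text = path.read_text()
        assert "0.750" in text
        assert "'" not in text  # supports are plain labels, never quoted pairs

    def test_empty_tree_rejected(self, tmp_path):
        from mtclone.phylogeny import CloneTree

        with pytest.raises(ValueError, match="empty"):
            write_newick(CloneTree(tree=TreeNode(), leaf_names=[]), tmp_path / "t.nwk")

    def test_unlabeled_leaf_rejected(self, tmp_path):
        from mtclone.phylogeny import CloneTree

        t = TreeNode()
        t.extend([TreeNode(name="A"), TreeNode()])
        with pytest.raises(ValueError, match="unlabeled"):
            write_newick(CloneTree(tree=t, leaf_names=["A"]), tmp_path / "t.nwk")
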