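import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

from equisea.beta import (
    DistanceMatrix,
    distance_matrix,
    pcoa,
    permanova,
    unweighted_unifrac,
)
from equisea.trees import PhyloTree, tree_from_newick

from .conftest import random_bifurcating_newick, small_table, star_tree


def oracle_unifrac(newick: str, set_a: set, set_b: set) -> float:
    """Brute-force oracle: walk every branch of a freshly parsed tree,
    collect its tip set by direct traversal, and accumulate unique and
    observed branch length."""
    tree = TreeNode.read([newick])
    unique = observed = 0.0
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        in_a = bool(tips & set_a)
        in_b = bool(tips & set_b)
        if in_a or in_b:
            observed += node.length
            if in_a != in_b:
                unique += node.length
    return unique / observed


class TestUnifrac:
    def test_identical_sets(self, balanced_tree):
        assert unweighted_unifrac({"A", "C"}, {"A", "C"}, balanced_tree) == 0.0

    def test_disjoint_on_star_tree(self):
        tree = star_tree(4)
        assert unweighted_unifrac({"t0", "t1"}, {"t2", "t3"}, tree) == 1.0

    def test_hand_case_three_fifths(self, balanced_tree):
        d = unweighted_unifrac({"A", "B"}, {"A", "C"}, balanced_tree)
        assert d == pytest.approx(0.6, abs=1e-12)

    def test_both_empty_is_error(self, balanced_tree):
        with pytest.raises(ValueError):
            unweighted_unifrac(set(), set(), balanced_tree)

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            newick = random_bifurcating_newick(rng, n)
            tree = tree_from_newick(newick)
            tips = list(tree.tip_names)
            a = {t for t in tips if rng.random() < 0.5} or {tips[0]}
            b = {t for t in tips if rng.random() < 0.5} or {tips[-1]}
            want = oracle_unifrac(newick, a, b)
            assert unweighted_unifrac(a, b, tree) == pytest.approx(want, abs=1e-12)

    def test_matches_reference_library(self):
        """Cross-check against scikit-bio's unweighted UniFrac on random
        presence tables."""
        rng = np.random.default_rng(5)
        newick = random_bifurcating_newick(rng, 10)
        tree = tree_from_newick(newick)
        counts = rng.integers(0, 3, size=(6, 10))
        counts[:, 0] = 1  # no empty samples
        table = small_table(counts, feature_prefix="")
        table = table.__class__(
            table.kingdom, table.sample_ids, tree.tip_names, counts
        )
        ours = distance_matrix(table, tree)
        ref = beta_diversity(
            "unweighted_unifrac",
            counts,
            ids=list(table.sample_ids),
            taxa=list(tree.tip_names),
            tree=TreeNode.read([newick]),
        )
        assert np.allclose(ours.values, ref.data, atol=1e-10)

    def test_absent_tip_does_not_change_distance(self, balanced_tree):
        # same tree plus a basal tip E observed by neither sample
        bigger = PhyloTree(TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,E:2);"]))
        a, b = {"A", "B"}, {"A", "C"}
        assert unweighted_unifrac(a, b, bigger) == pytest.approx(
            unweighted_unifrac(a, b, balanced_tree)
        )


class TestDistanceMatrix:
    def test_identical_rows_zero_distance(self, balanced_tree):
        counts = np.array([[1, 2, 0, 0], [3, 9, 0, 0], [0, 0, 1, 1]])
        t = small_table(counts)
        t = t.__class__(t.kingdom, t.sample_ids, ("A", "B", "C", "D"), counts)
        dm = distance_matrix(t, balanced_tree)
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0  # disjoint clades

    def test_entries_match_pairwise_oracle(self, balanced_tree):
        counts = np.array([[1, 0, 1, 0], [1, 1, 1, 0], [1, 1, 1, 1]])
        t = small_table(counts)
        t = t.__class__(t.kingdom, t.sample_ids, ("A", "B", "C", "D"), counts)
        dm = distance_matrix(t, balanced_tree)
        for i, j in itertools.combinations(range(3), 2):
            a = t.presence_set(t.sample_ids[i])
            b = t.presence_set(t.sample_ids[j])
            assert dm.values[i, j] == pytest.approx(
                unweighted_unifrac(a, b, balanced_tree)
            )

    def test_sample_permutation_consistency(self, balanced_tree):
        counts = np.array([[1, 0, 1, 0], [1, 1, 0, 0], [0, 1, 1, 1]])
        ids = ("A", "B", "C", "D")
        t1 = small_table(counts)
        t1 = t1.__class__(t1.kingdom, t1.sample_ids, ids, counts)
        t2 = t1.select_samples(["s2", "s0", "s1"])
        d1 = distance_matrix(t1, balanced_tree)
        d2 = distance_matrix(t2, balanced_tree)
        assert d2["s2", "s0"] == d1["s0", "s2"]
        assert d2["s0", "s1"] == d1["s0", "s1"]


class TestPcoa:
    def test_collinear_points_recovered(self):
        pos = np.array([0.0, 1.0, 2.0])
        d = np.abs(pos[:, None] - pos[None, :])
        res = pcoa(DistanceMatrix(("a", "b", "c"), d))
        assert res.coordinates.shape[1] == 1
        got = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
        assert np.allclose(got, d, atol=1e-10)
        assert abs(res.coordinates[:, 0].mean()) < 1e-9

    def test_equilateral_tie_eigenvalues(self):
        """All-equal off-diagonal distance d among 3 samples: the
        centered matrix is (d^2/2) J whose nonzero eigenvalues are
        d^2/2 twice (closed form)."""
        d = 0.8
        m = np.full((3, 3), d) - d * np.eye(3)
        res = pcoa(DistanceMatrix(("a", "b", "c"), m))
        top_two = res.eigenvalues[:2]
        assert np.allclose(top_two, d**2 / 2, atol=1e-10)
        assert res.coordinates.shape[1] == 2

    def test_euclidean_configuration_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = tuple(f"s{i}" for i in range(7))
        res = pcoa(DistanceMatrix(ids, d))
        emb = res.coordinates
        got = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        assert np.allclose(got, d, atol=1e-8)

    def test_truncated_embedding_distances_never_exceed_input(self, balanced_tree):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 4, size=(6, 4))
        counts[:, 0] = 1
        t = small_table(counts)
        t = t.__class__(t.kingdom, t.sample_ids, ("A", "B", "C", "D"), counts)
        dm = distance_matrix(t, balanced_tree)
        res = pcoa(dm)
        for k in range(1, res.coordinates.shape[1] + 1):
            emb = res.coordinates[:, :k]
            got = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
            assert (got <= dm.values + 1e-8).all()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [1, 0, 1], [0, 1, 0.0]]))


def oracle_permanova_f(d: np.ndarray, labels: list) -> float:
    """Textbook sum-of-squares partition computed with explicit loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(
            d[i, j] ** 2
            for i in members
            for j in members
            if i < j
        ) / len(members)
    ss_among = ss_total - ss_within
    a = len(groups)
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_fully_symmetric_case(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(tuple("abcd"), d)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], exhaustive=True)
        assert res.pseudo_f == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_separated_clusters_attain_permutation_floor(self):
        """Two tight, widely separated 3-sample clusters. Of the 20
        distinct 3-vs-3 relabelings only the identity and the full swap
        reproduce the partition, so the attainable floor is exactly
        2/20 = 0.1 — and the Monte-Carlo p must sit near it."""
        pts = np.array([0.0, 0.01, 0.02, 5.0, 5.01, 5.02])
        d = np.abs(pts[:, None] - pts[None, :])
        dm = DistanceMatrix(tuple("abcdef"), d)
        labels = ["x"] * 3 + ["y"] * 3
        res = permanova(dm, labels, exhaustive=True)
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        mc = permanova(dm, labels, n_perm=999, seed=4)
        assert abs(mc.p_value - 0.1) < 0.05

    def test_exhaustive_matches_independent_enumeration(self):
        """At N=6 (3 vs 3) the permutation null has 20 distinct splits;
        the package's exhaustive p must equal a from-scratch oracle
        enumeration over those splits."""
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = ["x", "x", "x", "y", "y", "y"]
        dm = DistanceMatrix(tuple("abcdef"), d)
        res = permanova(dm, labels, exhaustive=True)
        f_obs = oracle_permanova_f(d, labels)
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-12)
        splits = list(itertools.combinations(range(6), 3))
        assert len(splits) == 20
        fs = []
        for split in splits:
            lab = ["x" if i in split else "y" for i in range(6)]
            fs.append(oracle_permanova_f(d, lab))
        want_p = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value == pytest.approx(want_p, abs=1e-12)

    def test_pseudo_f_matches_reference_library(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        pts[:6] += 1.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(10)]
        labels = ["g1"] * 6 + ["g2"] * 4
        ours = permanova(DistanceMatrix(tuple(ids), d), labels, n_perm=99, seed=0)
        ref = skbio_permanova(SkbioDM(d, ids), labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_group_too_small_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(tuple("abc"), d)
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "y"])
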