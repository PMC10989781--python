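"""Diversity, UniFrac (against brute-force oracles), ordination, PERMANOVA
and CAP."""

import io

import numpy as np
import pytest

from rhizoecol import (AsvTable, bray_curtis, cap, pcoa, permanova, shannon,
                       simulate_phylogeny, unweighted_unifrac,
                       weighted_unifrac)
from rhizoecol.core_io import ValidationError, as_distance_matrix

from conftest import (oracle_unweighted_unifrac, oracle_weighted_unifrac)


def _newick(tree) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


class TestShannon:
    @pytest.mark.parametrize("row,expected", [
        ([1, 1, 1, 1], np.log(4)),
        ([5, 0, 0], 0.0),
        ([1, 1, 2], 1.0397207708399179),
    ])
    def test_known_values(self, row, expected):
        assert shannon(row) == pytest.approx(expected, abs=1e-12)

    def test_empty_row_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = AsvTable(["a", "b", "c"], ["x", "y"],
                     np.array([[3, 1], [3, 1], [0, 5]]))
        bc = bray_curtis(t)
        assert bc["a", "b"] == 0.0
        # c shares only taxon y with a/b -> not disjoint; check formula
        assert bc["a", "c"] == pytest.approx(1 - 2 * 1 / 9)

    def test_disjoint_supports_give_one(self):
        t = AsvTable(["a", "b"], ["x", "y"], np.array([[4, 0], [0, 7]]))
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_hand_value(self):
        t = AsvTable(["a", "b"], ["x", "y", "z"],
                     np.array([[6, 0, 2], [2, 2, 0]]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(2 / 3)


class TestUniFracWorkedExamples:
    def test_unweighted_single_tips(self, three_tip_tree):
        t = AsvTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[1, 0, 0], [0, 0, 1]]))
        assert unweighted_unifrac(t, three_tip_tree)["s1", "s2"] == 1.0

    def test_unweighted_nested_sets(self, three_tip_tree):
        t = AsvTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[1, 1, 0], [1, 0, 0]]))
        assert unweighted_unifrac(t, three_tip_tree)["s1", "s2"] == \
            pytest.approx(1 / 3)

    def test_weighted_raw_opposite_tips(self, three_tip_tree):
        t = AsvTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[3, 0, 0], [0, 0, 7]]))
        d = weighted_unifrac(t, three_tip_tree, normalized=False)
        assert d["s1", "s2"] == pytest.approx(4.0)

    def test_weighted_depth_invariance(self, three_tip_tree):
        t1 = AsvTable(["s1", "s2"], ["A", "B", "C"],
                      np.array([[2, 1, 1], [1, 0, 3]]))
        t2 = AsvTable(["s1", "s2"], ["A", "B", "C"],
                      np.array([[20, 10, 10], [10, 0, 30]]))
        for norm in (True, False):
            assert weighted_unifrac(t1, three_tip_tree, norm)["s1", "s2"] == \
                pytest.approx(
                    weighted_unifrac(t2, three_tip_tree, norm)["s1", "s2"])

    def test_identical_samples_zero(self, three_tip_tree):
        t = AsvTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[2, 1, 1], [2, 1, 1]]))
        assert unweighted_unifrac(t, three_tip_tree)["s1", "s2"] == 0.0
        assert weighted_unifrac(t, three_tip_tree)["s1", "s2"] == 0.0


class TestUniFracOracle:
    """Exhaustive small-instance equivalence with the dendropy oracle."""

    @pytest.mark.parametrize("n_tips,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_unweighted_all_presence_patterns(self, n_tips, seed):
        tree = simulate_phylogeny(n_tips, seed=seed)
        nwk = _newick(tree)
        taxa = sorted(t.name for t in tree.tips())
        subsets = [[int(b) for b in np.binary_repr(k, n_tips)]
                   for k in range(1, 2 ** n_tips)]
        table = AsvTable([f"p{k}" for k in range(len(subsets))], taxa,
                         np.array(subsets))
        dm = unweighted_unifrac(table, tree)
        rng = np.random.default_rng(seed)
        # all pairs among a random subset of patterns (exhaustive at n<=4)
        idx = (range(len(subsets)) if len(subsets) <= 16
               else rng.choice(len(subsets), 16, replace=False))
        for a in idx:
            for b in idx:
                present_a = [t for t, z in zip(taxa, subsets[a]) if z]
                present_b = [t for t, z in zip(taxa, subsets[b]) if z]
                expected = oracle_unweighted_unifrac(nwk, present_a,
                                                     present_b)
                assert dm[f"p{a}", f"p{b}"] == pytest.approx(expected,
                                                             abs=1e-10)

    @pytest.mark.parametrize("n_tips,seed", [(4, 5), (6, 6)])
    @pytest.mark.parametrize("normalized", [True, False])
    def test_weighted_random_abundances(self, n_tips, seed, normalized):
        tree = simulate_phylogeny(n_tips, seed=seed)
        nwk = _newick(tree)
        taxa = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(12, n_tips))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = AsvTable([f"s{k}" for k in range(12)], taxa, counts)
        dm = weighted_unifrac(table, tree, normalized=normalized)
        for a in range(12):
            for b in range(a + 1, 12):
                expected = oracle_weighted_unifrac(
                    nwk, dict(zip(taxa, counts[a].astype(float))),
                    dict(zip(taxa, counts[b].astype(float))), normalized)
                assert dm[f"s{a}", f"s{b}"] == pytest.approx(expected,
                                                             abs=1e-10)

    def test_unifrac_triangle_inequality(self):
        tree = simulate_phylogeny(6, seed=9)
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 5, size=(8, 6)) + \
            (rng.random((8, 6)) < 0.3)
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = AsvTable([f"s{k}" for k in range(8)],
                         sorted(t.name for t in tree.tips()),
                         counts.astype(int))
        d = np.asarray(unweighted_unifrac(table, tree).data)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-10


class TestPcoa:
    def test_all_zero_distances(self):
        dm = as_distance_matrix(np.zeros((4, 4)), list("abcd"))
        res = pcoa(dm)
        assert np.abs(res.coordinates).max() < 1e-8

    def test_collinear_points_recovered_on_axis_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        dm = as_distance_matrix(np.abs(np.subtract.outer(x, x)),
                                list("abcd"))
        res = pcoa(dm)
        axis1 = res.coordinates[:, 0]
        spacing = np.diff(np.sort(axis1))
        assert spacing == pytest.approx([1, 1, 1], abs=1e-8)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-8)

    def test_euclidean_eigenvalue_identity(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(as_distance_matrix(d, [str(i) for i in range(10)]))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        centered = pts - pts.mean(axis=0)
        assert pos.sum() == pytest.approx((centered ** 2).sum(), rel=1e-8)

    def test_proportions_over_positive_eigenvalues(self):
        # non-Euclidean input: negative eigenvalues excluded from denom
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1],
                      [1, 1, 1, 0]], float)
        d[0, 1] = d[1, 0] = 1.9  # break Euclidean embeddability
        res = pcoa(as_distance_matrix(d, list("abcd")))
        pos = res.proportion_explained[res.eigenvalues > 1e-12]
        assert pos.sum() == pytest.approx(1.0, abs=1e-9)


class TestPermanova:
    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(0)
        counts = np.vstack([rng.poisson(5, (10, 30)),
                            rng.poisson(60, (10, 30))]) + 1
        t = AsvTable([f"s{i}" for i in range(20)],
                     [f"t{j}" for j in range(30)], counts)
        res = permanova(bray_curtis(t), ["a"] * 10 + ["b"] * 10,
                        n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(0.001)
        assert res.R2 > 0.5

    def test_r2_scale_invariance_under_duplication(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, (8, 15))
        labels = ["a"] * 4 + ["b"] * 4
        t1 = AsvTable([f"s{i}" for i in range(8)],
                      [f"t{j}" for j in range(15)], counts)
        t2 = AsvTable([f"s{i}" for i in range(16)],
                      [f"t{j}" for j in range(15)],
                      np.vstack([counts, counts]))
        r1 = permanova(bray_curtis(t1), labels, 99, seed=0).R2
        r2 = permanova(bray_curtis(t2), labels * 2, 99, seed=0).R2
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_group_of_one_rejected(self, small_table):
        with pytest.raises(ValidationError):
            permanova(bray_curtis(small_table), ["a", "a", "b"], 99, 0)

    def test_fixed_seed_reproducible_and_label_name_invariant(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 30, (10, 12))
        t = AsvTable([f"s{i}" for i in range(10)],
                     [f"t{j}" for j in range(12)], counts)
        dm = bray_curtis(t)
        a = permanova(dm, ["x"] * 5 + ["y"] * 5, 199, seed=7)
        b = permanova(dm, ["x"] * 5 + ["y"] * 5, 199, seed=7)
        c = permanova(dm, ["foo"] * 5 + ["bar"] * 5, 199, seed=7)
        assert a.p_value == b.p_value == c.p_value
        assert a.pseudo_F == pytest.approx(c.pseudo_F)


class TestCap:
    def test_full_separation_scores_100(self):
        rng = np.random.default_rng(1)
        counts = np.vstack([rng.poisson(5, (8, 25)),
                            rng.poisson(80, (8, 25))]) + 1
        t = AsvTable([f"s{i}" for i in range(16)],
                     [f"t{j}" for j in range(25)], counts)
        res = cap(bray_curtis(t), ["a"] * 8 + ["b"] * 8)
        assert res.classification_success == 100.0
        assert res.constrained_inertia_fraction > 0.5

    def test_structureless_labels_near_chance(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 40, (30, 20))
        t = AsvTable([f"s{i}" for i in range(30)],
                     [f"t{j}" for j in range(20)], counts)
        labels = rng.permutation(["a"] * 15 + ["b"] * 15)
        res = cap(bray_curtis(t), labels, m_axes=3)
        assert 20.0 <= res.classification_success <= 80.0

    def test_too_many_axes_rejected(self, small_table):
        with pytest.raises(ValidationError):
            cap(bray_curtis(small_table), ["a", "a", "b"], m_axes=5)
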