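"""Cophenetic distances, CCC, PCoA, PACo and tanglegram checks."""

import numpy as np
import pytest

from pipolin_scout import cophylogeny as cp
from pipolin_scout.synthetic import TreePairConfig, generate_tree_pair

from oracles import (
    crossing_count_bruteforce,
    patristic_distances,
    procrustes_m2_closed_form,
)


class TestNewickRoundTrip:
    def test_two_leaf_tree(self):
        t = cp.parse_newick("(A:1,B:2);")
        dm = cp.cophenetic_matrix(t)
        assert sorted(dm.labels) == ["A", "B"]
        assert dm.data[0, 1] == pytest.approx(3.0)

    def test_roundtrip_many_random_trees(self):
        for seed in range(100):
            host, _, _ = generate_tree_pair(TreePairConfig(n_leaves=7, seed=seed))
            reparsed = cp.write_newick(cp.parse_newick(host))
            d1 = cp.cophenetic_matrix(host)
            d2 = cp.cophenetic_matrix(reparsed)
            idx = [d2.labels.index(l) for l in d1.labels]
            assert np.allclose(d1.data, d2.data[np.ix_(idx, idx)], atol=1e-9)

    def test_unbalanced_parentheses(self):
        with pytest.raises(cp.NewickParseError):
            cp.parse_newick("(A:1,(B:2);")

    def test_duplicate_labels(self):
        with pytest.raises(cp.NewickParseError):
            cp.parse_newick("(A:1,A:2);")


class TestCopheneticMatrix:
    def test_hand_computed_four_leaves(self):
        dm = cp.cophenetic_matrix("((A:1,B:1):1,(C:1,D:1):1);")
        d = lambda a, b: dm.data[dm.labels.index(a), dm.labels.index(b)]
        assert d("A", "B") == pytest.approx(2.0)
        assert d("A", "C") == pytest.approx(4.0)
        assert d("C", "D") == pytest.approx(2.0)

    def test_missing_branch_length_errors(self):
        with pytest.raises(ValueError):
            cp.cophenetic_matrix("((A:1,B:1),C:2);")

    def test_matches_independent_path_sums(self):
        """Patristic distances equal an independent recursive Newick walk."""
        for seed in (3, 17, 99):
            host, _, _ = generate_tree_pair(TreePairConfig(n_leaves=9, seed=seed))
            dm = cp.cophenetic_matrix(host)
            expected = patristic_distances(host)
            for i, a in enumerate(dm.labels):
                for j in range(i + 1, len(dm.labels)):
                    b = dm.labels[j]
                    assert dm.data[i, j] == pytest.approx(
                        expected[frozenset((a, b))], abs=1e-6)

    def test_four_point_condition(self):
        """Additive-tree distances satisfy the four-point condition."""
        for seed in range(20):
            host, _, _ = generate_tree_pair(TreePairConfig(n_leaves=6, seed=seed))
            dm = cp.cophenetic_matrix(host)
            D = dm.data
            n = D.shape[0]
            rng = np.random.default_rng(seed)
            i, j, k, l = rng.choice(n, size=4, replace=False)
            sums = sorted([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
            assert sums[1] == pytest.approx(sums[2], abs=1e-6)


class TestCcc:
    def test_identical_trees(self):
        host, elem, assoc = generate_tree_pair(TreePairConfig(n_leaves=9, seed=1))
        assert cp.ccc(host, elem, assoc) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        host, _, _ = generate_tree_pair(TreePairConfig(n_leaves=9, seed=2))
        tree = cp.parse_newick(host)
        doubled = cp.parse_newick(host)
        for node in doubled.traverse(include_self=False):
            node.length = node.length * 2
        assert cp.ccc(tree, doubled) == pytest.approx(1.0, abs=1e-12)

    def test_five_leaf_swap_equals_direct_computation(self):
        """CCC of a fixed 5-leaf pair with one leaf swap equals Pearson
        correlation computed directly from independently derived distance
        matrices."""
        host = "((A:1,B:2):1,((C:1,D:3):2,E:1):1);"
        elem = host.replace("A:", "X:").replace("D:", "A:").replace("X:", "D:")
        got = cp.ccc(host, elem, {l: l for l in "ABCDE"})
        dh = patristic_distances(host)
        de = patristic_distances(elem)
        labels = list("ABCDE")
        va, vb = [], []
        for i in range(5):
            for j in range(i + 1, 5):
                key = frozenset((labels[i], labels[j]))
                va.append(dh[key])
                vb.append(de[key])
        expected = np.corrcoef(va, vb)[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        star = "(A:1,B:1,C:1);"
        with pytest.raises(cp.UndefinedStatisticError):
            cp.ccc(star, star)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        dm = cp.DistanceMatrix(["a", "b", "c"], D)
        coords = cp.pcoa(dm)
        assert coords.shape[1] == 1
        rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        assert np.allclose(rec, D, atol=1e-8)

    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(10, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = cp.DistanceMatrix([f"p{i}" for i in range(10)], D)
        coords = cp.pcoa(dm)
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(rec, D, atol=1e-8)

    def test_all_zero_matrix_errors(self):
        dm = cp.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            cp.pcoa(dm)


class TestPaco:
    def _dists(self, seed, n_leaves=10, n_swaps=0):
        host, elem, assoc = generate_tree_pair(
            TreePairConfig(n_leaves=n_leaves, n_swaps=n_swaps, seed=seed))
        return cp.cophenetic_matrix(host), cp.cophenetic_matrix(elem), assoc

    def test_m2_equals_residual_sum_and_closed_form(self):
        hd, ed, assoc = self._dists(5, n_swaps=3)
        res = cp.paco_fit(hd, ed, assoc, n_permutations=0)
        assert res.m2_global == pytest.approx(
            sum(res.per_link_sq_residuals.values()), abs=1e-9)
        links, X, Y = cp._link_coordinates(hd, ed, assoc)
        assert res.m2_global == pytest.approx(
            procrustes_m2_closed_form(X, Y), abs=1e-9)

    def test_no_permutations_leaves_p_undefined(self):
        hd, ed, assoc = self._dists(6)
        res = cp.paco_fit(hd, ed, assoc, n_permutations=0)
        assert res.p_value is None

    def test_relabeling_invariance(self):
        hd, ed, assoc = self._dists(7, n_swaps=2)
        m2 = cp.paco_fit(hd, ed, assoc, n_permutations=0).m2_global
        renamed_h = cp.DistanceMatrix([f"h_{l}" for l in hd.labels], hd.data)
        renamed_e = cp.DistanceMatrix([f"e_{l}" for l in ed.labels], ed.data)
        renamed_assoc = {f"h_{h}": f"e_{e}" for h, e in assoc.items()}
        m2_renamed = cp.paco_fit(renamed_h, renamed_e, renamed_assoc,
                                 n_permutations=0).m2_global
        assert m2_renamed == pytest.approx(m2, rel=1e-9)

    def test_m2_monotone_in_swaps(self):
        """Mean m2 over 100 seeded replicates is non-decreasing in the
        number of leaf-label swaps (0, 2, 8)."""
        means = []
        for n_swaps in (0, 2, 8):
            vals = [
                cp.paco_fit(*self._dists(seed, n_leaves=10, n_swaps=n_swaps),
                            n_permutations=0).m2_global
                for seed in range(100)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_non_one_to_one_association_rejected(self):
        hd, ed, _ = self._dists(8)
        bad = {h: ed.labels[0] for h in hd.labels}
        with pytest.raises(ValueError):
            cp.paco_fit(hd, ed, bad, n_permutations=0)

    def test_jackknife_zero_for_identical_trees(self):
        hd, ed, assoc = self._dists(9)
        jack = cp.paco_jackknife(hd, ed, assoc)
        for mean, _upper in jack.values():
            assert abs(mean) < 1e-9

    def test_jackknife_requires_five_links(self):
        hd, ed, assoc = self._dists(10, n_leaves=4)
        with pytest.raises(ValueError):
            cp.paco_jackknife(hd, ed, assoc)


class TestTanglegram:
    def test_identical_trees_no_crossings(self):
        host, elem, assoc = generate_tree_pair(TreePairConfig(n_leaves=8, seed=4))
        t = cp.tanglegram_export(host, elem, assoc)
        assert t.n_crossings == 0

    def test_two_swapped_links_one_crossing(self):
        host = "((A:1,B:1):1,(C:1,D:1):1);"
        elem = "((a:1,b:1):1,(c:1,d:1):1);"
        assoc = {"A": "b", "B": "a", "C": "c", "D": "d"}  # adjacent pair swapped
        t = cp.tanglegram_export(host, elem, assoc, untangle=False)
        assert t.n_crossings == 1

    def test_crossing_count_matches_bruteforce(self, rng):
        """Crossing counter equals O(L^2) pair enumeration on random
        10-leaf instances."""
        for _ in range(50):
            left = rng.permutation(10)
            right = rng.permutation(10)
            links = list(zip(left.tolist(), right.tolist()))
            assert cp.count_crossings(links) == crossing_count_bruteforce(links)
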