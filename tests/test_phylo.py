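"""p-distance, neighbor joining, bootstrap, Newick round trips."""

import numpy as np
import pytest

from toxseek.phylo import (
    Alignment,
    DistanceMatrix,
    TreeNode,
    bipartitions,
    bootstrap_support,
    leaf_distance_matrix,
    nj_tree,
    parse_newick,
    pdistance_pairwise_deletion,
    write_newick,
)


def random_unrooted_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths (test oracle
    input; distances derived from it are additive by construction)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    lengths = {}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[
            (a, float(rng.uniform(0.1, 1.0))),
            (b, float(rng.uniform(0.1, 1.0)))])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=[(x, float(rng.uniform(0.1, 1.0)))
                              for x in nodes])
    return root


class TestPDistance:
    def _dm(self, rows):
        names = [f"s{i}" for i in range(len(rows))]
        return pdistance_pairwise_deletion(Alignment(names, rows))

    def test_one_mismatch_in_four(self):
        dm = self._dm(["AAAA", "AAAT"])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_column_excluded(self):
        dm = self._dm(["AA-A", "AATA"])
        assert dm.d[0, 1] == 0.0

    def test_identical_rows(self):
        dm = self._dm(["MKVL", "MKVL"])
        assert dm.d[0, 1] == 0.0

    def test_no_shared_columns_names_pair(self):
        with pytest.raises(ValueError, match="s0.*s1"):
            self._dm(["AA--", "--TT"])

    def test_brute_force_column_oracle(self):
        rng = np.random.default_rng(0)
        symbols = list("ACDEFG-")
        for _ in range(50):
            L = int(rng.integers(5, 30))
            a = "".join(rng.choice(symbols, size=L))
            b = "".join(rng.choice(symbols, size=L))
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                continue
            expected = sum(x != y for x, y in shared) / len(shared)
            dm = self._dm([a, b])
            assert dm.d[0, 1] == pytest.approx(expected)


class TestNeighborJoining:
    def test_two_taxa_bisected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        t = nj_tree(dm)
        assert write_newick(t) == "(A:0.2,B:0.2);"

    def test_four_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 5 + 2 - 5, 0]])
        d[2, 3] = d[3, 2] = 7
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        t = nj_tree(dm)
        assert bipartitions(t) == {frozenset({"A", "B"})}
        rec = leaf_distance_matrix(t, ["A", "B", "C", "D"])
        assert np.allclose(rec, d, atol=1e-12)

    def test_three_taxa_resolved(self):
        d = np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
        t = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        assert sorted(t.leaves()) == ["A", "B", "C"]
        rec = leaf_distance_matrix(t, ["A", "B", "C"])
        assert np.allclose(rec, d)

    def test_asymmetric_matrix_is_error(self):
        with pytest.raises(ValueError, match="asymmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))

    def test_recovers_random_trees(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            true = random_unrooted_tree(rng, n)
            names = sorted(true.leaves())
            d = leaf_distance_matrix(true, names)
            rec = nj_tree(DistanceMatrix(names, d))
            assert bipartitions(rec) == bipartitions(true)
            assert np.allclose(leaf_distance_matrix(rec, names), d, atol=1e-9)

    def test_agrees_with_skbio(self):
        """Independent cross-check of the NJ topology against scikit-bio."""
        import skbio

        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(5, 8))
            true = random_unrooted_tree(rng, n)
            names = sorted(true.leaves())
            d = leaf_distance_matrix(true, names)
            mine = bipartitions(nj_tree(DistanceMatrix(names, d)))
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
            sk_splits = set()
            total = frozenset(names)
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    other = total - side
                    if len(other) < len(side) or (
                            len(other) == len(side)
                            and sorted(other) < sorted(side)):
                        side = other
                    sk_splits.add(side)
            assert mine == sk_splits


class TestBootstrap:
    def _clean_alignment(self):
        # every column supports AB|CD
        return Alignment(["A", "B", "C", "D"],
                         ["AAAAAAAAAA", "AAAAAAAAAA",
                          "TTTTTTTTTT", "TTTTTTTTTT"])

    def test_unanimous_split_support_100(self):
        t = bootstrap_support(self._clean_alignment(), replicates=20, seed=1)
        supports = [c.support for c, _bl in t.children if c.children]
        internal = _collect_supports(t)
        assert internal and all(s == 100 for s in internal)

    def test_single_replicate_binary_support(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACDEF"), size=20)) for _ in range(5)]
        a = Alignment([f"s{i}" for i in range(5)], rows)
        t = bootstrap_support(a, replicates=1, seed=3)
        assert set(_collect_supports(t)) <= {0, 100}

    def test_same_seed_identical(self):
        a = self._clean_alignment()
        t1 = bootstrap_support(a, replicates=10, seed=7)
        t2 = bootstrap_support(a, replicates=10, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_leaf_order_permutation_invariance(self):
        a = self._clean_alignment()
        perm = Alignment([a.names[i] for i in (2, 0, 3, 1)],
                         [a.rows[i] for i in (2, 0, 3, 1)])
        t1 = bootstrap_support(a, replicates=25, seed=9)
        t2 = bootstrap_support(perm, replicates=25, seed=9)
        s1 = {frozenset(sorted(b)): True for b in bipartitions(t1)}
        assert set(s1) == set(
            frozenset(sorted(b)) for b in bipartitions(t2))

    def test_short_alignment_is_error(self):
        a = Alignment(["A", "B"], ["G", "T"])
        with pytest.raises(ValueError):
            bootstrap_support(a, replicates=5, seed=1)


def _collect_supports(tree):
    out = []

    def visit(node):
        for child, _bl in node.children:
            if child.children and child.support is not None:
                out.append(child.support)
            visit(child)

    visit(tree)
    return out


class TestNewick:
    def test_support_label_on_internal_node(self):
        inner = TreeNode(children=[(TreeNode(name="A"), 1.0),
                                   (TreeNode(name="B"), 2.0)], support=87)
        root = TreeNode(children=[(inner, 0.5), (TreeNode(name="C"), 3.0),
                                  (TreeNode(name="D"), 4.0)])
        s = write_newick(root)
        assert "87" in s and s.endswith(";")
        back = parse_newick(s)
        assert _collect_supports(back) == [87]

    def test_duplicate_leaves_is_error(self):
        root = TreeNode(children=[(TreeNode(name="A"), 1.0),
                                  (TreeNode(name="A"), 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            write_newick(root)

    def test_random_round_trips(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            t = random_unrooted_tree(rng, n)
            s = write_newick(t)
            back = parse_newick(s)
            assert write_newick(back) == s
            assert bipartitions(back) == bipartitions(t)
            names = sorted(t.leaves())
            assert np.allclose(leaf_distance_matrix(back, names),
                               leaf_distance_matrix(t, names), atol=1e-9)
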