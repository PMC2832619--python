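import numpy as np
import pytest

from ceafam.errors import ParseError, SaturationError
from ceafam.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap,
    distance_matrix,
    nj,
    read_newick,
    tree_distance_matrix,
    write_newick,
)
from ceafam.seqio import Sequence
from ceafam.simulate import SimConfig, random_tree, simulate_codon_evolution
from conftest import random_nt


class TestDistances:
    def test_identical_pair_zero_under_every_model(self):
        rows = [Sequence("a", "ACGTACGT"), Sequence("b", "ACGTACGT")]
        for model in ("p_nt", "jc69_nt"):
            assert distance_matrix(rows, model).matrix[0, 1] == 0.0
        rows_aa = [Sequence("a", "MKLV", "aa"), Sequence("b", "MKLV", "aa")]
        for model in ("p_aa", "poisson_aa"):
            assert distance_matrix(rows_aa, model).matrix[0, 1] == 0.0

    def test_poisson_closed_form(self):
        rows = [Sequence("a", "MKLVMKLV", "aa"), Sequence("b", "MKLVAAAA", "aa")]
        d = distance_matrix(rows, "poisson_aa").matrix[0, 1]
        assert d == pytest.approx(0.69315, abs=1e-5)

    def test_jc69_closed_form(self):
        a = "A" * 70 + "C" * 30
        b = "A" * 70 + "G" * 30
        d = distance_matrix([Sequence("a", a), Sequence("b", b)], "jc69_nt").matrix[0, 1]
        assert d == pytest.approx(0.38312, abs=1e-5)

    def test_saturation_names_the_pair(self):
        rows = [Sequence("aaa", "AAAA"), Sequence("bbb", "CCCC")]
        with pytest.raises(SaturationError, match="aaa"):
            distance_matrix(rows, "jc69_nt")

    def test_pairwise_complete_deletion(self):
        rows = [Sequence("a", "ACGT-CGT"), Sequence("b", "ACGTAGGT")]
        assert distance_matrix(rows, "p_nt").matrix[0, 1] == pytest.approx(1 / 7)


class TestNJ:
    def test_four_taxon_additive_example(self):
        labels = list("ABCD")
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        # four-point condition: AB|CD split (3+7 < 5+7 = 6+6)
        tree = nj(DistanceMatrix(labels, m))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        rec = tree_distance_matrix(tree)
        assert rec.labels == labels
        np.testing.assert_allclose(rec.matrix, m, atol=1e-9)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj(DistanceMatrix(["a", "b", "c"], m))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_random_additive_round_trip(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            tr = random_tree(n, 0.5, rng)
            for node in tr.preorder_node_iter():
                if node.edge.length is not None:
                    node.edge.length = float(rng.uniform(0.1, 1.0))
            dm = tree_distance_matrix(tr)
            rec = nj(dm)
            assert bipartitions(rec) == bipartitions(tr)
            np.testing.assert_allclose(
                tree_distance_matrix(rec).matrix, dm.matrix, atol=1e-9
            )

    def test_taxon_order_invariance(self, rng):
        tr = random_tree(8, 0.5, rng)
        for node in tr.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = float(rng.uniform(0.1, 1.0))
        dm = tree_distance_matrix(tr)
        perm = rng.permutation(dm.n)
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        assert bipartitions(nj(dm)) == bipartitions(nj(dm2))

    def test_agrees_with_independent_nj_implementation(self, rng):
        import skbio

        tr = random_tree(7, 0.5, rng)
        for node in tr.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = float(rng.uniform(0.2, 1.0))
        dm = tree_distance_matrix(tr)
        ours = nj(dm)
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
        sk_tree = read_newick(str(sk).strip())
        assert bipartitions(ours) == bipartitions(sk_tree)

    def test_negative_intermediate_lengths_clamped(self):
        # non-additive matrix known to produce a negative NJ branch estimate
        m = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], dtype=float
        )
        m[0, 1] = m[1, 0] = 6.0  # break additivity
        tree = nj(DistanceMatrix(list("ABCD"), m))
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0.0


class TestBootstrap:
    def _deep_split_alignment(self, sep: float, seed: int = 5):
        newick = (
            f"((a:0.02,b:0.02):{sep},(c:0.02,d:0.02):{sep});"
        )
        aln, _ = simulate_codon_evolution(
            SimConfig(n_codons=200, omega=0.5, seed=seed, tree=newick)
        )
        return aln

    def test_deep_bipartition_fully_supported(self):
        aln = self._deep_split_alignment(0.25)
        _, supports = bootstrap(aln, model="p_nt", B=50, seed=1)
        assert supports[frozenset({"c", "d"})] == 100.0

    def test_b_equals_one_supports_binary(self):
        aln = self._deep_split_alignment(0.1)
        _, supports = bootstrap(aln, B=1, seed=2)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_seed_determinism(self):
        aln = self._deep_split_alignment(0.05)
        _, s1 = bootstrap(aln, B=20, seed=7)
        _, s2 = bootstrap(aln, B=20, seed=7)
        assert s1 == s2

    def test_support_monotone_in_separation(self):
        vals = []
        for sep in (0.001, 0.02, 0.25):
            aln = self._deep_split_alignment(sep, seed=9)
            _, supports = bootstrap(aln, B=40, seed=3)
            vals.append(supports.get(frozenset({"c", "d"}), 0.0))
        assert vals[0] <= vals[1] <= vals[2]

    def test_supports_attached_as_labels(self):
        aln = self._deep_split_alignment(0.25)
        tree, supports = bootstrap(aln, B=10, seed=4)
        labels = [
            node.label
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node and not node.is_leaf()
        ]
        assert any(lab is not None for lab in labels)


class TestNewick:
    def test_round_trip(self):
        text = "(A:1.0,B:2.0,(C:3.0,D:4.0):1.0);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert bipartitions(tree) == bipartitions(again)
        np.testing.assert_allclose(
            tree_distance_matrix(tree).matrix,
            tree_distance_matrix(again).matrix,
            atol=1e-6,
        )

    def test_supports_survive_round_trip(self):
        text = "(A:1.0,B:2.0,(C:3.0,D:4.0)87:1.0);"
        tree = read_newick(write_newick(read_newick(text)))
        labels = {
            node.label
            for node in tree.preorder_node_iter()
            if not node.is_leaf() and node.label
        }
        assert "87" in labels

    def test_malformed_raises_parse_error(self):
        with pytest.raises(ParseError):
            read_newick("(A:1,B:2,(C:3,D:4):1;")


def test_distance_matrix_validation_rejects_asymmetry():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
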