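import itertools
import math

import dendropy
import numpy as np
import pytest

from duptrace import distances as dist
from duptrace.distances import DistanceMatrix
from duptrace.io import Alignment, CrossReferenceError, DataError

from conftest import random_alignment


def brute_force_p(seq_a: str, seq_b: str) -> float:
    comparable = diffs = 0
    for x, y in zip(seq_a, seq_b):
        if x in "-N" or y in "-N":
            continue
        comparable += 1
        diffs += x != y
    return diffs / comparable if comparable else float("nan")


class TestPDistance:
    def test_identity(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        assert dist.p_distance(aln, "a", "b") == 0.0

    def test_one_difference_in_four(self):
        aln = Alignment(["a", "b"], ["ACGT", "AGGT"])
        assert dist.p_distance(aln, "a", "b") == 0.25

    def test_pairwise_deletion_skips_gap_columns(self):
        aln = Alignment(["a", "b"], ["AC-T", "ACGT"])
        assert dist.p_distance(aln, "a", "b") == 0.0

    def test_no_comparable_columns_is_missing(self):
        aln = Alignment(["a", "b"], ["--AT", "GC--"])
        assert math.isnan(dist.p_distance(aln, "a", "b"))

    def test_unknown_id(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(CrossReferenceError):
            dist.p_distance(aln, "a", "zzz")

    def test_matrix_equals_brute_force_on_random_gapped_alignments(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            aln = random_alignment(
                rng, int(rng.integers(2, 8)), int(rng.integers(3, 30)),
                gap_frac=0.15, n_frac=0.05,
            )
            dm = dist.p_distance_matrix(aln)
            for i, j in itertools.combinations(range(aln.n_seqs), 2):
                expect = brute_force_p(aln.seqs[i], aln.seqs[j])
                got = dm.values[i, j]
                assert (math.isnan(expect) and math.isnan(got)) or got == pytest.approx(expect)
            # symmetry and zero diagonal
            assert np.allclose(np.diag(dm.values), 0)

    def test_matrix_of_identical_sequences_is_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        assert np.all(dist.p_distance_matrix(aln).values == 0)

    def test_tsv_round_trip(self, tmp_path):
        aln = random_alignment(np.random.default_rng(5), 4, 20)
        dm = dist.p_distance_matrix(aln)
        dm.to_tsv(tmp_path / "d.tsv")
        dm2 = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert dm2.labels == dm.labels
        assert np.allclose(dm2.values, dm.values)


def additive_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (an additive distance)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(tuple(t.label for t in taxa), vals)


def random_tree_with_lengths(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    from duptrace.simulate import simulate_species_tree

    t = simulate_species_tree(n_leaves, seed=int(rng.integers(2**31)))
    # perturb branch lengths so the matrix is generic, keeping positivity
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = float(e.length) + float(rng.uniform(0.05, 0.5))
    return t


def same_splits(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Unrooted split-set equality of two trees."""
    tns = dendropy.TaxonNamespace()
    trees = []
    for t in (a, b):
        t2 = dendropy.Tree.get(
            data=t.as_string(schema="newick", suppress_rooting=True),
            schema="newick",
            taxon_namespace=tns,
        )
        t2.is_rooted = False
        t2.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=True)
        trees.append(t2)
    return dendropy.calculate.treecompare.symmetric_difference(*trees) == 0


class TestNeighborJoining:
    def test_recovers_four_taxon_topology(self):
        rng = np.random.default_rng(8)
        tree = random_tree_with_lengths(4, rng)
        nj = dist.neighbor_joining(additive_matrix(tree))
        assert same_splits(tree, nj)

    def test_recovers_random_six_leaf_trees(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            tree = random_tree_with_lengths(6, rng)
            nj = dist.neighbor_joining(additive_matrix(tree))
            assert same_splits(tree, nj)

    def test_zero_matrix_gives_star_lengths(self):
        dm = DistanceMatrix(("a", "b", "c", "d"), np.zeros((4, 4)))
        nj = dist.neighbor_joining(dm)
        for e in nj.preorder_edge_iter():
            assert not e.length or e.length == 0.0

    def test_three_taxa(self):
        vals = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        nj = dist.neighbor_joining(DistanceMatrix(("a", "b", "c"), vals))
        assert {lf.taxon.label for lf in nj.leaf_node_iter()} == {"a", "b", "c"}

    def test_too_few_labels(self):
        with pytest.raises(DataError, match=">=3"):
            dist.neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_missing_distances_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        with pytest.raises(DataError, match="missing"):
            dist.neighbor_joining(DistanceMatrix(("a", "b", "c"), vals))

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, 8, 50)
        nj = dist.neighbor_joining(dist.p_distance_matrix(aln))
        for e in nj.preorder_edge_iter():
            assert e.length is None or e.length >= 0


class TestMonophyly:
    def tree(self):
        return dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")

    def test_clade_found(self):
        assert dist.is_monophyletic(self.tree(), {"A", "B"})

    def test_spanning_pair_not_monophyletic(self):
        assert not dist.is_monophyletic(self.tree(), {"A", "C"})

    def test_trivial_subsets(self):
        t = self.tree()
        assert dist.is_monophyletic(t, {"A"})
        assert dist.is_monophyletic(t, {"A", "B", "C", "D"})

    def test_complement_counts_as_bipartition(self):
        # unrooted reading: {C, D} is the complement side of the (A,B) edge
        assert dist.is_monophyletic(self.tree(), {"C", "D"})

    def test_matches_enumeration_on_four_leaf_tree(self):
        t = self.tree()
        expected_true = [{"A"}, {"B"}, {"C"}, {"D"},
                         {"A", "B"}, {"C", "D"},
                         {"A", "B", "C", "D"},
                         {"B", "C", "D"}, {"A", "C", "D"}, {"A", "B", "D"}, {"A", "B", "C"}]
        for subset in map(set, itertools.chain.from_iterable(
            itertools.combinations("ABCD", k) for k in range(1, 5)
        )):
            assert dist.is_monophyletic(t, subset) == (subset in expected_true)

    def test_unknown_label(self):
        with pytest.raises(CrossReferenceError):
            dist.is_monophyletic(self.tree(), {"A", "Z"})


# hypothesis property checks ------------------------------------------------

from hypothesis import given, settings, strategies as st

row = st.text(alphabet="ACGT-N", min_size=1, max_size=40)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(1, 40).flatmap(lambda n: st.tuples(
    st.text(alphabet="ACGT-N", min_size=n, max_size=n),
    st.text(alphabet="ACGT-N", min_size=n, max_size=n),
)))
def test_p_distance_symmetric_and_identity(pair):
    a, b = pair
    aln = Alignment(["x", "y"], [a, b])
    dxy = dist.p_distance(aln, "x", "y")
    dyx = dist.p_distance(aln, "y", "x")
    assert (math.isnan(dxy) and math.isnan(dyx)) or dxy == dyx
    dxx = dist.p_distance(aln, "x", "x")
    assert math.isnan(dxx) or dxx == 0.0
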