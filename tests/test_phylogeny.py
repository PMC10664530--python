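import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from codonuse import (
    CodingSequence,
    hierarchical_cluster,
    neighbor_joining,
    pairwise_cds_distance,
    read_newick,
    rscu_distance_matrix,
    write_newick,
)
from codonuse.phylogeny import IncomparableProfilesError


def random_additive_tree(n_leaves, seed):
    """Random rooted binary tree with branch lengths in [0.1, 1]."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in labels:
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(label)
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 1.0))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.is_rooted = False
    return tree, labels


def patristic_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return DistanceMatrix(d, ids=labels)


def rf_distance(newick_a, newick_b):
    taxa = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=taxa)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=taxa)
    t1.is_rooted = t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


def profile_frame(columns):
    return pd.DataFrame(columns)


class TestRSCUDistance:
    def test_identical_profiles_distance_zero(self):
        profiles = profile_frame({"a": [1.0, 2.0, 0.5], "b": [1.0, 2.0, 0.5]})
        dm = rscu_distance_matrix(profiles)
        assert dm["a", "b"] == 0.0

    def test_single_codon_difference_squared(self):
        profiles = profile_frame({"a": [1.0, 1.0, 1.0], "b": [3.0, 1.0, 1.0]})
        assert rscu_distance_matrix(profiles)["a", "b"] == pytest.approx(4.0)

    def test_pairwise_complete_ignores_nan(self):
        profiles = profile_frame(
            {"a": [1.0, np.nan, 2.0, 1.0], "b": [2.0, 1.0, np.nan, 1.0]}
        )
        # only rows 0 and 3 are shared: (1-2)^2 + 0
        assert rscu_distance_matrix(profiles)["a", "b"] == pytest.approx(1.0)

    def test_incomparable_when_overlap_too_small(self):
        profiles = profile_frame(
            {"a": [1.0, np.nan, np.nan], "b": [np.nan, 1.0, np.nan]}
        )
        with pytest.raises(IncomparableProfilesError):
            rscu_distance_matrix(profiles)

    def test_symmetry_on_random_profiles(self):
        rng = np.random.default_rng(0)
        profiles = profile_frame(
            {f"s{i}": rng.uniform(0, 6, size=20) for i in range(10)}
        )
        dm = rscu_distance_matrix(profiles)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)


class TestHierarchical:
    def test_nearest_pair_merges_first(self):
        dm = DistanceMatrix(
            [[0.0, 0.1, 5.0], [0.1, 0.0, 5.0], [5.0, 5.0, 0.0]],
            ids=["A", "B", "C"],
        )
        tree, order = hierarchical_cluster(dm)
        newick = write_newick(tree)
        assert rf_distance(newick, "((A,B),C);") == 0
        # dendrogram order keeps the first-merged pair adjacent
        assert abs(order.index("A") - order.index("B")) == 1

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        points = {f"s{i}": rng.normal(size=8) for i in range(6)}
        profiles = profile_frame(points)
        permuted = profiles[list(reversed(profiles.columns))]
        t1, _ = hierarchical_cluster(rscu_distance_matrix(profiles))
        t2, _ = hierarchical_cluster(rscu_distance_matrix(permuted))
        assert rf_distance(write_newick(t1), write_newick(t2)) == 0

    def test_unsupported_linkage_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(ValueError):
            hierarchical_cluster(dm, linkage="single")


class TestCDSDistance:
    def test_identical_sequences(self):
        seqs = [
            CodingSequence("a", "ATGAAACCC"),
            CodingSequence("b", "ATGAAACCC"),
        ]
        assert pairwise_cds_distance(seqs)["a", "b"] == 0.0

    def test_one_mismatch_in_three(self):
        seqs = [CodingSequence("a", "AAA"), CodingSequence("b", "AAT")]
        assert pairwise_cds_distance(seqs)["a", "b"] == pytest.approx(1 / 3)

    def test_p_distance_bounded(self):
        rng = np.random.default_rng(1)
        seqs = [
            CodingSequence(f"s{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(5)
        ]
        dm = pairwise_cds_distance(seqs)
        assert np.all(dm.data <= 1.0) and np.all(dm.data >= 0.0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]],
            ids=["A", "B", "C"],
        )
        tree = neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_additive_trees(self, seed):
        n = 4 + seed % 5
        true_tree, labels = random_additive_tree(n, seed)
        dm = patristic_matrix(true_tree, labels)
        inferred = neighbor_joining(dm)
        assert rf_distance(write_newick(true_tree), write_newick(inferred)) == 0
        back = patristic_matrix(inferred, labels)
        assert np.allclose(back.data, dm.data, atol=1e-9)

    def test_topology_agrees_with_skbio(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 2, size=(7, 7))
        d = np.triu(x, 1)
        d = d + d.T
        dm = DistanceMatrix(d, ids=[f"t{i}" for i in range(7)])
        ours = write_newick(neighbor_joining(dm))
        theirs = str(skbio_nj(dm))
        assert rf_distance(ours, theirs) == 0

    def test_ultrametric_matches_average_linkage(self):
        dm = DistanceMatrix(
            [
                [0.0, 2.0, 8.0, 8.0],
                [2.0, 0.0, 8.0, 8.0],
                [8.0, 8.0, 0.0, 3.0],
                [8.0, 8.0, 3.0, 0.0],
            ],
            ids=["A", "B", "C", "D"],
        )
        nj_tree = neighbor_joining(dm)
        upgma_tree, _ = hierarchical_cluster(dm, linkage="average")
        assert rf_distance(write_newick(nj_tree), write_newick(upgma_tree)) == 0

    def test_negative_lengths_clamped_with_warning(self):
        dm = DistanceMatrix(
            [
                [0.0, 1.0, 1.0, 10.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.0],
                [10.0, 1.0, 1.0, 0.0],
            ],
            ids=["A", "B", "C", "D"],
        )
        with pytest.warns(UserWarning, match="negative branch length"):
            tree = neighbor_joining(dm)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    def test_too_few_taxa(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)


class TestNewick:
    def test_round_trip_preserves_topology_and_length(self):
        true_tree, labels = random_additive_tree(6, seed=4)
        text = write_newick(true_tree)
        back = read_newick(text)
        assert rf_distance(text, write_newick(back)) == 0
        assert back.length() == pytest.approx(true_tree.length())

    def test_two_leaf_form(self):
        taxa = dendropy.TaxonNamespace(["A", "B"])
        tree = dendropy.Tree(taxon_namespace=taxa)
        root = dendropy.Node()
        for label, length in (("A", 1.5), ("B", 2.5)):
            leaf = dendropy.Node()
            leaf.taxon = taxa.get_taxon(label)
            root.add_child(leaf)
            leaf.edge.length = length
        tree.seed_node = root
        text = write_newick(tree)
        assert text.endswith(";")
        assert "A:1.5" in text and "B:2.5" in text

    def test_quoted_labels_with_spaces(self):
        taxa = dendropy.TaxonNamespace(["sp one", "sp two", "sp three"])
        tree = dendropy.Tree(taxon_namespace=taxa)
        root = dendropy.Node()
        for taxon in taxa:
            leaf = dendropy.Node()
            leaf.taxon = taxon
            root.add_child(leaf)
            leaf.edge.length = 1.0
        tree.seed_node = root
        back = read_newick(write_newick(tree))
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(
            t.label for t in taxa
        )
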