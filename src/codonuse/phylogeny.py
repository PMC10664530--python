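"""Codon-usage and sequence-based trees.

Two complementary views of relatedness are built from the same genes: a
rooted dendrogram from squared-Euclidean distances between RSCU profiles
(codon-usage similarity, which need not track ancestry) and an unrooted
neighbor-joining tree from pairwise alignment p-distances between the CDSs
themselves. Comparing the two separates usage convergence from descent.

Trees are :class:`dendropy.Tree` objects; distance matrices are
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .genetic_code import CodingSequence


class IncomparableProfilesError(ValueError):
    """Two profiles share too few defined codons to be compared."""


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scores for CDS p-distances."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


def rscu_distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Squared-Euclidean distances between RSCU profiles.

    ``profiles`` is the codons-by-sequences RSCU matrix (NaN = undefined).
    Codons undefined in either member of a pair are excluded from that
    pair's sum (pairwise-complete deletion): treating an unobserved amino
    acid as RSCU 0 would fabricate dissimilarity.
    """
    labels = list(profiles.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles")
    values = profiles.to_numpy(dtype=float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            if both.sum() < 2:
                raise IncomparableProfilesError(
                    f"{labels[i]} vs {labels[j]}: "
                    f"{int(both.sum())} shared defined codons"
                )
            diff = values[both, i] - values[both, j]
            d[i, j] = d[j, i] = float(diff @ diff)
    return DistanceMatrix(d, ids=labels)


def hierarchical_cluster(
    dm: DistanceMatrix, linkage: str = "average"
) -> tuple[dendropy.Tree, list[str]]:
    """Agglomerative clustering of a distance matrix into a rooted dendrogram.

    Returns the tree and the dendrogram leaf order (for heatmap row order).
    Branch lengths are differences of merge heights. SciPy's agglomeration
    is deterministic, breaking ties by the earliest pair in its traversal
    order, so identical inputs give identical trees.
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    labels = list(dm.ids)
    link = hierarchy.linkage(squareform(dm.data, checks=False), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(link)]

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, label in enumerate(labels):
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(label)
        nodes[i] = (leaf, 0.0)
    for k, (a, b, height, _size) in enumerate(link):
        parent = dendropy.Node()
        for child_id in (int(a), int(b)):
            child, child_height = nodes.pop(child_id)
            parent.add_child(child)
            child.edge.length = max(float(height) - child_height, 0.0)
        nodes[len(labels) + k] = (parent, float(height))
    (root, _), = nodes.values()
    tree.seed_node = root
    tree.is_rooted = True
    return tree, order


def pairwise_cds_distance(
    seqs: list[CodingSequence],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DistanceMatrix:
    """p-distances from global pairwise alignments of the CDSs.

    Each pair is globally aligned (Needleman-Wunsch with affine gaps) and
    the distance is mismatches / aligned non-gap columns. Gapped columns do
    not count, so the distance stays in [0, 1].
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    labels = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i].nucleotides, seqs[j].nucleotides)[0]
            matches = 0
            columns = 0
            for (a0, a1), (b0, b1) in zip(*aln.aligned):
                sa = seqs[i].nucleotides[a0:a1]
                sb = seqs[j].nucleotides[b0:b1]
                columns += len(sa)
                matches += sum(x == y for x, y in zip(sa, sb))
            if columns == 0:
                raise IncomparableProfilesError(
                    f"{labels[i]} vs {labels[j]}: empty alignment overlap"
                )
            d[i, j] = d[j, i] = (columns - matches) / columns
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining of a distance matrix.

    Standard Q-criterion agglomeration with the usual two-point branch
    length formulas; ties broken toward the lowest index pair; negative
    branch lengths clamped to zero with a warning. The result is unrooted
    (trifurcating seed node).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def clamp(length: float, context: str) -> float:
        if length < 0:
            warnings.warn(f"negative branch length {length:.4g} at {context} clamped to 0")
            return 0.0
        return length

    nodes: list[dendropy.Node] = []
    for label in labels:
        leaf = dendropy.Node()
        leaf.taxon = taxa.get_taxon(label)
        nodes.append(leaf)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima: argmin scans row-major, so the
        # first hit is the lexicographically smallest (i, j)
        i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li, f"join {i},{j}")
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj, f"join {i},{j}")
        new_row = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # three remaining nodes join a central trifurcation (three-point formulas)
    centre = dendropy.Node()
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (l0, l1, l2)):
        centre.add_child(node)
        node.edge.length = clamp(length, "final trifurcation")
    tree.seed_node = centre
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to one-line Newick with branch lengths."""
    return tree.as_string(
        schema="newick", suppress_rooting=True
    ).strip()


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
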