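#!/usr/bin/env python
"""Codon-usage clustering vs sequence phylogeny for the cohort.

Builds the RSCU squared-Euclidean dendrogram and the CDS neighbor-joining
tree, writes both as Newick under results/, and reports whether the top
RSCU split separates AT-rich from GC-rich usage (usage clusters follow
composition, not necessarily ancestry).
"""

import argparse

import dendropy

from codonuse import rscu_matrix
from codonuse.phylogeny import (
    hierarchical_cluster,
    neighbor_joining,
    pairwise_cds_distance,
    rscu_distance_matrix,
    write_newick,
)

from cohort_io import RESULTS, load_cohort

AT_RICH = {"Cryptosporidium", "Plasmodium"}


def top_split(tree: dendropy.Tree):
    children = tree.seed_node.child_nodes()
    return [
        {leaf.taxon.label for leaf in child.leaf_iter()} for child in children
    ]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--linkage", default="average",
                        choices=["average", "complete", "ward"])
    args = parser.parse_args()

    seqs, sheet = load_cohort(args.seed)
    profiles = rscu_matrix(seqs)
    dendro, order = hierarchical_cluster(
        rscu_distance_matrix(profiles), linkage=args.linkage
    )
    (RESULTS / "rscu_cluster.nwk").write_text(write_newick(dendro) + "\n")
    (RESULTS / "rscu_leaf_order.txt").write_text("\n".join(order) + "\n")

    nj_tree = neighbor_joining(pairwise_cds_distance(seqs))
    (RESULTS / "cds_nj.nwk").write_text(write_newick(nj_tree) + "\n")
    print(f"RSCU dendrogram -> {RESULTS / 'rscu_cluster.nwk'}")
    print(f"CDS NJ tree     -> {RESULTS / 'cds_nj.nwk'}")

    group_of = sheet["group"].to_dict()
    sides = top_split(dendro)
    at_ids = {i for i, g in group_of.items() if g in AT_RICH}
    purities = []
    for side in sides:
        at_fraction = len(side & at_ids) / len(side)
        purities.append(max(at_fraction, 1 - at_fraction))
    print("top RSCU split by AT-rich vs GC-rich usage: "
          f"side purities {', '.join(f'{p:.2f}' for p in purities)}")


if __name__ == "__main__":
    main()
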