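#!/usr/bin/env python
"""Codon-usage indices (CAI, CBI, FOP, ENC, GRAVY, AROMO, L_sym, L_aa) and
the full RSCU matrix for the cohort.

Writes results/indices.tsv and results/rscu_matrix.tsv; reports the cohort
mean ENC (the headline bias summary: > 35 reads as weak overall bias), the
index extremes, and the most/least preferred codons by RSCU.
"""

import argparse

from codonuse import ReferenceWeights, index_table, rscu_matrix

from cohort_io import RESULTS, load_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    seqs, _ = load_cohort(args.seed)
    ref = ReferenceWeights.builtin()
    indices = index_table(seqs, ref)
    profiles = rscu_matrix(seqs)
    indices.round(3).to_csv(RESULTS / "indices.tsv", sep="\t", index_label="id")
    profiles.round(3).to_csv(RESULTS / "rscu_matrix.tsv", sep="\t",
                             index_label="codon")
    print(f"index table -> {RESULTS / 'indices.tsv'}")
    print(f"RSCU matrix -> {RESULTS / 'rscu_matrix.tsv'}")
    print(f"  reference weights: {ref.source_label}")
    print(f"  mean ENC {indices['ENC'].mean():.2f} "
          f"(range {indices['ENC'].min():.2f}-{indices['ENC'].max():.2f}); "
          f"{int((indices['ENC'] < 35).sum())} gene(s) below the strong-bias "
          f"threshold of 35")
    for column in ("CAI", "CBI", "FOP"):
        print(f"  {column}: {indices[column].min():.3f} "
              f"({indices[column].idxmin()}) to {indices[column].max():.3f} "
              f"({indices[column].idxmax()})")
    n_hydrophobic = int((indices["GRAVY"] > 0).sum())
    print(f"  GRAVY > 0 (hydrophobic products): {n_hydrophobic}/{len(indices)}")
    top = profiles.max(axis=1).idxmax()
    print(f"  highest single-gene RSCU: {top} = {profiles.max(axis=1).max():.2f}")


if __name__ == "__main__":
    main()
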