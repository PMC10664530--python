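#!/usr/bin/env python
"""Mutation-vs-selection diagnostics on the cohort: neutrality regressions
per species group, PR2 parity coordinates, and ENC against Wright's null
curve.

Writes results/neutrality.tsv, results/pr2.tsv and results/enc_gc3.tsv.
Group slopes near 0 plus a majority of genes below the null ENC curve read
as selection shaping codon choice beyond GC pressure alone.
"""

import argparse

from codonuse import count_codons, ReferenceWeights, index_table
from codonuse.composition import composition_table
from codonuse.selection import enc_gc3_table, neutrality_by_group, pr2_table

from cohort_io import RESULTS, load_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    seqs, sheet = load_cohort(args.seed)
    comp = composition_table({s.id: count_codons(s) for s in seqs})
    groups = sheet.loc[comp.index, "group"]

    neutrality = neutrality_by_group(comp, groups)
    neutrality.to_csv(RESULTS / "neutrality.tsv", sep="\t",
                      float_format="%.4f")
    print(f"neutrality regressions -> {RESULTS / 'neutrality.tsv'}")
    for group, row in neutrality.iterrows():
        verdict = "mutation-like" if row["slope"] > 0.5 else "selection-like"
        print(f"  {group:<16s} slope {row['slope']:+.3f} "
              f"R^2 {row['r_squared']:.3f} p {row['p_value']:.3f} "
              f"({verdict})")

    pr2 = pr2_table(comp)
    pr2.to_csv(RESULTS / "pr2.tsv", sep="\t", float_format="%.4f")
    centred = ((pr2["at_bias"] - 0.5).abs() < 0.05) & (
        (pr2["gc_bias"] - 0.5).abs() < 0.05)
    print(f"PR2 coordinates -> {RESULTS / 'pr2.tsv'}; "
          f"{int(centred.sum())}/{len(pr2)} genes within 0.05 of the centre")

    indices = index_table(seqs, ReferenceWeights.builtin())
    curve = enc_gc3_table(indices["ENC"], comp["GC3"])
    curve.to_csv(RESULTS / "enc_gc3.tsv", sep="\t", float_format="%.4f")
    below = int((curve["deviation"] > 0).sum())
    print(f"ENC-GC3 table -> {RESULTS / 'enc_gc3.tsv'}; "
          f"{below}/{len(curve)} genes below the null curve "
          f"(mean deviation {curve['deviation'].mean():+.3f})")


if __name__ == "__main__":
    main()
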