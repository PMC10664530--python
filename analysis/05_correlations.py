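#!/usr/bin/env python
"""Spearman correlation matrices among the 12 per-gene quantities, one per
species group, with exact small-sample p-values.

Writes results/correlation_<group>.tsv and results/correlation_long.tsv and
reports the significant pairs (p < 0.05) per group.
"""

import argparse

import pandas as pd

from codonuse import ReferenceWeights, count_codons, index_table
from codonuse.composition import composition_table
from codonuse.correlation import spearman_by_group

from cohort_io import RESULTS, load_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    seqs, sheet = load_cohort(args.seed)
    comp = composition_table({s.id: count_codons(s) for s in seqs})
    indices = index_table(seqs, ReferenceWeights.builtin())
    table = indices.join(comp[["GC1", "GC2", "GC3", "GCs"]])
    groups = sheet.loc[table.index, "group"]

    matrices = spearman_by_group(table, groups)
    long_parts = []
    for name, cm in matrices.items():
        cm.rho.round(4).to_csv(RESULTS / f"correlation_{name}.tsv", sep="\t",
                               index_label="variable")
        long_parts.append(cm.long_format())
    long = pd.concat(long_parts, ignore_index=True)
    long.to_csv(RESULTS / "correlation_long.tsv", sep="\t", index=False,
                float_format="%.4g")
    print(f"correlation tables -> {RESULTS}/correlation_*.tsv")
    for name, cm in matrices.items():
        hits = cm.long_format().query("stars != ''")
        print(f"  {name:<16s} n={cm.n}: {len(hits)} significant pair(s)")
        for _, row in hits.head(4).iterrows():
            print(f"    {row.var1}~{row.var2}: rho {row.rho:+.2f} {row.stars}")


if __name__ == "__main__":
    main()
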