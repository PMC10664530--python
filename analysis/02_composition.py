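#!/usr/bin/env python
"""Per-position base composition of the cohort (A3/T3/G3/C3, GC1/2/3/12/s).

Writes results/composition.tsv and reports the extremes of the
third-position composition, the quantities that separate AT-rich from
GC-rich genomes.
"""

import argparse

from codonuse import count_codons
from codonuse.composition import composition_table

from cohort_io import RESULTS, load_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    seqs, _ = load_cohort(args.seed)
    table = composition_table({s.id: count_codons(s) for s in seqs})
    out = RESULTS / "composition.tsv"
    table.round(2).to_csv(out, sep="\t", index_label="id")
    print(f"composition table -> {out}")
    for column in ("A3", "T3", "G3", "C3", "GC3"):
        lo, hi = table[column].idxmin(), table[column].idxmax()
        print(f"  {column:>4s}: min {table[column].min():5.2f}% ({lo}), "
              f"max {table[column].max():5.2f}% ({hi})")
    print(f"  GC12 spread: {table['GC12'].min():.2f}-{table['GC12'].max():.2f}%")


if __name__ == "__main__":
    main()
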