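# codonuse

Codon usage bias (CUB) analysis for protein-coding genes, built for the kind
of study that asks, for one gene family sampled across many taxa — here
motivated by thioredoxin CDSs across apicomplexan parasites — whether
synonymous codon choice is shaped mainly by directional mutation pressure or
by natural selection, and whether usage similarity tracks ancestry.

The package provides, over the 59 synonymous codons of the standard genetic
code (all sense codons except ATG and TGG):

* **Composition** — A3/T3/G3/C3, GC1/GC2/GC3, GC12 = (GC1+GC2)/2, GCs/ATs.
* **RSCU** — relative synonymous codon usage,
  RSCU_ij = x_ij / (Σ_j x_ij / n_i) for codon j of amino acid i with
  degeneracy n_i; 1 = no bias, family values sum to n_i.
* **ENC** — Wright's effective number of codons,
  N_c = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 with
  F̂ = (nΣp² − 1)/(n − 1) per family, clamped to [20, 61].
* **CAI / CBI / FOP** — expression-linked indices against a reference
  weight table (default: the classic *E. coli* highly-expressed set of
  Sharp & Li 1987): CAI = exp(Σ x_j ln w_j / Σ x_j),
  CBI = (N_opt − N_ran)/(N_tot − N_ran), FOP = N_opt/N_tot.
* **GRAVY / AROMO** — Kyte–Doolittle mean hydropathy and F/Y/W fraction of
  the encoded protein; **L_sym / L_aa** — synonymous and translatable
  codon counts.
* **Selection diagnostics** — neutrality regression of GC12 on GC3 per
  species group (slope → 1 under shared mutation pressure, → 0 under
  selection), PR2 parity coordinates A3/(A3+T3) vs G3/(G3+C3), and the
  ENC–GC3 null curve N_c = 2 + s + 29/(s² + (1−s)²).
* **Spearman matrices** — rank correlations among the 12 per-gene
  quantities with exact permutation p-values for groups of ≤ 9 genes.
* **Trees** — RSCU squared-Euclidean dendrogram vs a CDS neighbor-joining
  tree (global alignment p-distances), both serialized as Newick.
* **Synthetic cohorts** — a generator with controllable amino-acid
  composition, codon-preference strength and GC3 target, so the whole
  chain is testable without downloads, including cohorts whose neutrality
  slope is 1 or 0 by construction.

## Worked example

The numbered scripts under `analysis/` run the full study on a bundled
32-gene synthetic cohort (six species-like groups spanning AT-rich to
GC-rich silent-site composition, CDS lengths 255–1665 nt):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/03_usage_indices.py  --seed 1
python analysis/04_selection_diagnostics.py --seed 1
```

prints, among other lines:

```
cohort: 32 CDSs -> results/cohort
  mean GC3 Cryptosporidium   21.3%
  mean GC3 Babesia           75.3%
  mean ENC 49.46 (range 31.88-61.00); 2 gene(s) below the strong-bias threshold of 35
  Babesia          slope +0.031 R^2 0.014 p 1.000 (selection-like)
  Theileria        slope -0.031 R^2 0.003 p 0.800 (selection-like)
ENC-GC3 table -> results/enc_gc3.tsv; 27/32 genes below the null curve (mean deviation +0.042)
```

Read: the cohort's mean ENC of 49.46 (> 35) indicates weak overall codon
bias; near-zero neutrality slopes and 27/32 genes sitting below Wright's
null curve are the signature of codon choice constrained beyond GC drift —
exactly the structure the generator encodes (per-gene GC3 targets with the
amino-acid composition held fixed). `02_composition.py`,
`05_correlations.py` and `06_phylogeny.py` produce the composition table,
per-group correlation matrices, and the two trees (the RSCU dendrogram's
top split separates AT-rich from GC-rich usage with side purities
0.93/1.00).

The same pipeline runs on real data from a FASTA plus a sample sheet:

```bash
codonuse all --input trx.fasta --samples samples.tsv --out results/real
```

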