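# Methods

## Scope and conventions

All bias statistics operate on the 59 synonymous codons of the standard
nuclear genetic code: the three stops are excluded, and so are ATG (Met) and
TGG (Trp), whose families offer no synonymous choice. The 59 codons cover 18
amino acids with degeneracies 2 (×9 families), 3 (Ile), 4 (×5) and 6 (Leu,
Ser, Arg). `L_aa` counts every translatable codon including Met/Trp;
`L_sym` counts only the 59-set. All composition percentages (A3/T3/G3/C3,
GC1/GC2/GC3, GC12, GCs/ATs) are computed over the synonymous set as well,
GCs as the direct G+C count over all three positions of the retained codons
(numerically identical to the mean of GC1/GC2/GC3 because every retained
codon contributes all three positions). Organellar genetic codes are out of
scope.

CDS validation is lenient by default: a trailing partial codon is dropped
with a warning (error under `strict`), codons containing non-ACGT symbols
are dropped with a warning, one terminal stop codon is stripped, and
internal stops are flagged but kept, so that pseudogene-like records do not
abort a cohort run. RNA input is normalized to DNA.

## Indices

**RSCU.** RSCU_ij = x_ij · n_i / Σ_j x_ij. Codons of amino acids absent
from a gene are *undefined* (NaN), not zero: a zero would claim maximal
avoidance where there is simply no observation, and would fabricate
dissimilarity in downstream clustering. Family sums over defined values
always equal the degeneracy.

**ENC.** Wright's estimator with the small-sample homozygosity
F̂ = (nΣp̂² − 1)/(n − 1), averaged within each degeneracy class, then
N_c = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6. Families with n < 2 are
inestimable and dropped. If a whole class is missing, its contribution is
interpolated: for the 3-fold class (Ile alone) the effective codon number
1/F̄3 is taken as the mean of 1/F̄2 and 1/F̄4 (the convention of classic
codon-usage tools); any other missing class borrows the mean F̄ of the
nearest defined classes. A class whose mean F̂ is exactly 0 (possible for
tiny families, e.g. n = 2 split 1/1) has no finite codon-number reading and
is treated as missing rather than letting the estimate blow up. Sampling
noise can push N_c above the 61-codon ceiling; estimates are clamped to 61.

**CAI / CBI / FOP.** These require a reference: the relative adaptiveness
w_j of each codon in a highly expressed gene set, normalized to max 1 per
family, whose argmax defines the family's optimal codon. The built-in
default is the classic *E. coli* table of Sharp & Li (1987) — the
traditional default of CodonW-style tools when no organism-specific set is
supplied — and any two-column (codon, weight) file or reference codon-count
table can replace it; unobserved reference codons receive a 0.5
pseudo-count so every w > 0. Absolute CAI/CBI/FOP values are only
comparable under the same reference; rankings are robust in practice. CAI
is the count-weighted geometric mean of w over a gene's synonymous codons;
CBI = (N_opt − N_ran)/(N_tot − N_ran) with N_ran = Σ_i (family total)/n_i;
FOP = N_opt/N_tot, treated as ranging over [0, 1] (the mathematical range
of a fraction), with 1 meaning every synonymous codon is optimal.

**GRAVY / AROMO.** Kyte–Doolittle mean hydropathy (positive = hydrophobic)
and the F/Y/W fraction of the translated protein.

## Selection diagnostics

The neutrality plot regresses GC12 on GC3 across the genes of a group
(ordinary least squares; ≥ 3 points and non-degenerate GC3 required). The
reported p-value is the two-sided Spearman rank p — the convention of these
analyses, which ask whether GC12 and GC3 co-vary at all — with the OLS
slope p also emitted. PR2 coordinates are A3/(A3+T3) and G3/(G3+C3) from
the synonymous-set third-position composition (not only fourfold families),
matching the composition table the rest of the analysis reports. The
ENC–GC3 null curve is N_c(s) = 2 + s + 29/(s² + (1−s)²); the deviation
(expected − observed)/expected is positive for genes below the curve. The
curve is Wright's closed-form approximation: even data generated exactly
under GC3-only drift sit within about ±1.1 ENC units of it across
s ∈ [0.12, 0.86] (the approximation error, largest toward the extremes).

## Correlations

Spearman rank correlations (average ranks on ties) among the 12 per-gene
quantities {GC1, GC2, GC3, GCs, CAI, CBI, FOP, ENC, GRAVY, AROMO, L_sym,
L_aa}, one matrix per species group with ≥ 4 genes. For n ≤ 9 the two-sided
p-value is exact: all n! pairings of the tied-rank vectors are enumerated
and the statistic (Pearson correlation of ranks) compared with an epsilon
guard against floating-point ties; the t approximation is used beyond. No
multiple-testing correction is applied; stars mark p < 0.05/0.01/0.001.
Constant columns yield blank (NaN) entries rather than errors, since small
groups easily tie an integer-valued index.

## Trees

The RSCU distance between two genes is the squared Euclidean distance over
codons defined in *both* profiles (pairwise-complete deletion); at least two
shared codons are required. The dendrogram uses SciPy agglomerative
clustering, average linkage by default (the distance, not the linkage, is
the conventional choice; complete and Ward are options), with the dendrogram
leaf order exported for heatmap use. The sequence tree aligns every CDS
pair globally (match +1, mismatch −1, gap open −5, gap extend −1,
configurable), takes p-distance = mismatches / aligned non-gap columns, and
runs neighbor joining implemented in-package: standard Q-criterion, ties
broken toward the lowest index pair so reruns are identical, negative
branch lengths clamped to zero with a warning. On additive distances NJ
recovers the generating tree exactly; the implementation is cross-checked
against an independent NJ implementation in the test suite. Trees are
dendropy objects serialized as Newick (labels quoted as needed).

## Synthetic cohorts

The generator draws each gene amino-acid-by-amino-acid from a composition
profile (default: a Swiss-Prot-like average composition, so GRAVY/AROMO
land in realistic ranges), then draws the codon from a per-family
distribution shaped by two knobs. Preference strength s places softmax
weight e^s on one deterministic preferred codon per family: s = 0 is
uniform usage (ENC near 61) and large s collapses to one codon per family
(ENC = 20). A GC3 target g rescales the G/C-ending side of every family to
total probability g, preserving relative weights within each side, so the
expected third-position G+C is exactly g for any preference strength; g
from ~0.1 to ~0.9 is feasible because every family has both endings. Each
gene ends with one terminal stop codon, which the validator strips
(stops are never drawn internally), and the generator returns a draw log of
realized codon counts for self-consistency checks. Per-gene substreams are
derived from (seed, index), so any single gene is reproducible alone.

Two special cohorts bracket the neutrality diagnostic. The *mutation*
cohort gives each gene its own pressure g and additionally tilts the joint
codon distribution by exp(θ·[G+C count at positions 1–2]) with θ solved
(Brent's method) so the expected GC12 also equals g: GC12 and GC3 then share
one driver and the regression slope is 1 by construction. The *selection*
cohort applies only the GC3 rescaling with uniform family weights: a
structural symmetry of the standard code (within every family, the mean
positions-1–2 G+C content of the A/T-ending and G/C-ending sides is equal)
makes the expected GC12 exactly independent of g, so the slope is 0 by
construction. Both expectations were verified analytically on the exact
joint distributions before any sampling.

The bundled 32-gene cohort mirrors a one-gene-family-across-taxa study
design: six groups of 4/4/5/9/4/6 genes with per-gene GC3 targets drawn
from group bands — two AT-rich groups (0.12–0.35), three GC-rich
(0.50–0.86), one intermediate (0.30–0.60) — moderate preference strength
(s = 1), and codon lengths uniform on [85, 555] (CDS 255–1665 nt). What
the generator does *not* emulate: real amino-acid composition differences
between taxa, phylogenetic autocorrelation (genes are i.i.d. given group
parameters; there is no substitution process along a tree), expression-
correlated codon adaptation, and dinucleotide constraints. Passing
recovery tests therefore demonstrates the correctness of the statistics
and the directionality of the diagnostics, not the biological conclusions
one would draw from real sequences.

## Problem sizes and tolerances

Chosen so the whole suite runs in seconds while keeping sampling noise
well inside the asserted bands: index-vs-oracle agreement at 1e−9 on 20
random genes of 100–400 codons; GC3 recovery within 2 percentage points at
10,000 codons; RSCU recovery within 0.1 per codon on the pooled profile of
a 20-gene × 10,000-codon cohort (pooling is needed because a single
10,000-codon gene leaves 6-fold families with per-codon RSCU noise of
about 0.05 SD, putting the worst of 59 codons near the band); neutrality
slopes within 0.1 of their constructed values of 1 and 0 at 50 genes × 300
codons; ENC within 2 units of the null curve at 2,000 codons; NJ exactness
on 100 random additive trees of 4–8 taxa. The analysis scripts and the
acceptance script use the 32-gene cohort end to end, including all 496
pairwise alignments for the NJ tree.

## Known limitations

Absolute CAI/CBI/FOP depend entirely on the reference weights; with the
default *E. coli* table they rank genes sensibly but should not be read as
organism-calibrated expression predictions. ENC's missing-class
interpolation is a convention, not an estimator with known sampling theory;
it matters only for very short or compositionally extreme genes. p-distance
underestimates divergence for distant sequences (no multiple-hit
correction), and the NJ tree carries no support values. The exact
permutation p enumerates up to 9! pairings per variable pair; groups of 10+
genes silently switch to the t approximation.
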