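"""Per-sequence codon-usage indices.

RSCU
    Relative synonymous codon usage: observed count of a codon divided by
    the mean count of its family, so a family's RSCU values sum to its
    degeneracy and 1 means no preference. Codons of amino acids absent from
    the sequence are undefined (NaN), not zero.
ENC
    Wright's effective number of codons, from the mean family homozygosity
    F within each degeneracy class: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,
    clamped to the theoretical maximum 61. A degeneracy class with no
    estimable family borrows from its neighbours (see :func:`enc`).
CAI / CBI / FOP
    Expression-linked indices against a reference weight table: CAI the
    count-weighted geometric mean of relative adaptiveness; CBI the excess
    of optimal codons over the uniform-usage expectation, normalized to
    [-1, 1]; FOP the plain optimal-codon fraction.
GRAVY / AROMO
    Kyte-Doolittle grand average of hydropathy and the aromatic-residue
    (F/Y/W) fraction of the encoded protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import (
    STANDARD_CODE,
    CodingSequence,
    CodonCountTable,
    DegenerateInputError,
    GeneticCode,
    count_codons,
    translate,
)
from .reference import ReferenceWeights

ENC_MAX = 61.0
AROMATIC = frozenset("FYW")

INDEX_COLUMNS = ("CAI", "CBI", "FOP", "ENC", "GRAVY", "AROMO", "L_sym", "L_aa")


@dataclass(frozen=True)
class RSCUProfile:
    """RSCU values over the 59 synonymous codons; NaN where undefined."""

    rscu: dict[str, float]

    def defined(self) -> dict[str, float]:
        return {c: v for c, v in self.rscu.items() if not math.isnan(v)}

    def as_series(self) -> pd.Series:
        return pd.Series(self.rscu, dtype=float)


@dataclass(frozen=True)
class IndexBundle:
    """The per-sequence index row: one gene's codon-usage summary."""

    CAI: float
    CBI: float
    FOP: float
    ENC: float
    GRAVY: float
    AROMO: float
    L_sym: int
    L_aa: int

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in INDEX_COLUMNS}


def rscu(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> RSCUProfile:
    """Relative synonymous codon usage for every observed family."""
    values: dict[str, float] = {}
    any_observed = False
    for aa, codons in code.families.items():
        family_total = sum(counts.get(c) for c in codons)
        if family_total == 0:
            for c in codons:
                values[c] = float("nan")
            continue
        any_observed = True
        expected = family_total / len(codons)
        for c in codons:
            values[c] = counts.get(c) / expected
    if not any_observed:
        raise DegenerateInputError("no synonymous codons observed")
    return RSCUProfile(rscu=values)


def _family_homozygosity(counts: CodonCountTable, codons: tuple[str, ...]):
    """Wright's F-hat for one family; None when n < 2 makes it inestimable."""
    n = sum(counts.get(c) for c in codons)
    if n < 2:
        return None
    sum_p2 = sum((counts.get(c) / n) ** 2 for c in codons)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Families with fewer than two synonymous codons observed are dropped; if
    an entire degeneracy class is then empty (or its mean homozygosity is
    zero), its contribution is interpolated: the 3-fold class (Ile alone)
    contributes the mean of the 2-fold and 4-fold per-codon contributions,
    any other missing class borrows the mean F of the nearest defined
    classes. Sampling noise can push the estimate above the 61-codon
    maximum; such values are clamped to 61.
    """
    class_codons = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    fbar: dict[int, float | None] = {}
    for k in class_codons:
        fs = [
            f
            for aa, codons in code.families.items()
            if code.degeneracy[aa] == k
            and (f := _family_homozygosity(counts, codons)) is not None
        ]
        mean_f = float(np.mean(fs)) if fs else None
        # F-hat can be 0 for tiny families (e.g. n=2 split 1/1); a zero class
        # mean has no finite codon-number reading, so treat it as missing.
        fbar[k] = mean_f if mean_f else None

    defined = [k for k, f in fbar.items() if f is not None]
    if not defined:
        raise DegenerateInputError("no degeneracy class estimable for ENC")

    def class_f(k: int) -> float:
        if fbar[k] is not None:
            return fbar[k]
        neighbours = sorted(defined, key=lambda j: (abs(j - k), j))
        nearest = [j for j in neighbours if abs(j - k) == abs(neighbours[0] - k)]
        return float(np.mean([fbar[j] for j in nearest]))

    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        # Ile-only class: interpolate its effective codon number directly.
        n3 = (1.0 / fbar[2] + 1.0 / fbar[4]) / 2.0
    else:
        n3 = 1.0 / class_f(3)
    value = 2.0 + 9.0 / class_f(2) + n3 + 5.0 / class_f(4) + 3.0 / class_f(6)
    return min(value, ENC_MAX)


def cai(counts: CodonCountTable, ref: ReferenceWeights,
        code: GeneticCode = STANDARD_CODE) -> float:
    """Codon adaptation index: weighted geometric mean of adaptiveness."""
    log_sum = 0.0
    n = 0
    for codon in code.synonymous_set:
        k = counts.get(codon)
        if k:
            log_sum += k * math.log(ref.w[codon])
            n += k
    if n == 0:
        raise DegenerateInputError("no synonymous codons observed")
    return math.exp(log_sum / n)


def _optimal_counts(counts: CodonCountTable, ref: ReferenceWeights,
                    code: GeneticCode):
    n_opt = 0
    n_tot = 0
    n_ran = 0.0
    for aa, codons in code.families.items():
        family_total = sum(counts.get(c) for c in codons)
        if family_total == 0:
            continue
        n_tot += family_total
        n_opt += counts.get(ref.optimal[aa])
        n_ran += family_total / len(codons)
    return n_opt, n_tot, n_ran


def cbi(counts: CodonCountTable, ref: ReferenceWeights,
        code: GeneticCode = STANDARD_CODE) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    Returns NaN with a warning in the degenerate case N_tot = N_ran (every
    observed family fully single-codon... impossible unless usage is exactly
    at the uniform expectation with N_tot equal to it).
    """
    n_opt, n_tot, n_ran = _optimal_counts(counts, ref, code)
    if n_tot == 0:
        raise DegenerateInputError("no synonymous codons observed")
    if math.isclose(n_tot, n_ran):
        warnings.warn("CBI undefined: N_tot equals random expectation")
        return float("nan")
    return (n_opt - n_ran) / (n_tot - n_ran)


def fop(counts: CodonCountTable, ref: ReferenceWeights,
        code: GeneticCode = STANDARD_CODE) -> float:
    """Frequency of optimal codons among synonymous codons."""
    n_opt, n_tot, _ = _optimal_counts(counts, ref, code)
    if n_tot == 0:
        raise DegenerateInputError("no synonymous codons observed")
    return n_opt / n_tot


def gravy(protein: str) -> float:
    """Kyte-Doolittle grand average of hydropathy of a protein sequence."""
    if not protein:
        raise DegenerateInputError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def aromo(protein: str) -> float:
    """Aromaticity: fraction of Phe/Tyr/Trp residues."""
    if not protein:
        raise DegenerateInputError("empty protein")
    unknown = set(protein) - set(KYTE_DOOLITTLE)
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}")
    return sum(aa in AROMATIC for aa in protein) / len(protein)


def lengths(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> tuple[int, int]:
    """(L_sym, L_aa): synonymous-codon and translatable-codon counts."""
    l_sym = 0
    l_aa = 0
    for codon in seq.codons:
        if codon in code.codon_to_aa:
            l_aa += 1
            if codon in code.synonymous_set:
                l_sym += 1
    return l_sym, l_aa


def index_bundle(
    seq: CodingSequence,
    ref: ReferenceWeights,
    code: GeneticCode = STANDARD_CODE,
) -> IndexBundle:
    """All eight indices for one validated sequence."""
    counts = count_codons(seq)
    protein = translate(seq, code)
    l_sym, l_aa = lengths(seq, code)
    return IndexBundle(
        CAI=cai(counts, ref, code),
        CBI=cbi(counts, ref, code),
        FOP=fop(counts, ref, code),
        ENC=enc(counts, code),
        GRAVY=gravy(protein),
        AROMO=aromo(protein),
        L_sym=l_sym,
        L_aa=l_aa,
    )


def index_table(
    seqs: list[CodingSequence],
    ref: ReferenceWeights,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """One index row per sequence; per-sequence failures become NaN rows."""
    if not seqs:
        raise DegenerateInputError("no sequences")
    rows: dict[str, dict[str, float]] = {}
    for seq in seqs:
        try:
            rows[seq.id] = index_bundle(seq, ref, code).as_dict()
        except (DegenerateInputError, ValueError) as exc:
            warnings.warn(f"{seq.id}: {exc}")
            rows[seq.id] = {c: float("nan") for c in INDEX_COLUMNS}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(INDEX_COLUMNS)]
    return table


def rscu_matrix(
    seqs: list[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """RSCU matrix, 59 synonymous codons (rows) by sequences (columns)."""
    cols = {
        seq.id: rscu(count_codons(seq), code).as_series() for seq in seqs
    }
    order = [
        c for aa in sorted(code.families) for c in code.families[aa]
    ]
    return pd.DataFrame(cols).reindex(order)
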