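"""Per-position nucleotide composition of the synonymous codon set.

All composition statistics are restricted to the 59 synonymous codons (the
set that actually carries codon-choice information): A3/T3/G3/C3 are the
percent shares of the four bases at synonymous third positions, GC1/GC2/GC3
the percent G+C at each codon position, GC12 their positions-1-and-2 mean,
and GCs/ATs the overall G+C and A+T percent across all three positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genetic_code import (
    STANDARD_CODE,
    CodonCountTable,
    DegenerateInputError,
    GeneticCode,
)

COMPOSITION_COLUMNS = (
    "A3", "T3", "G3", "C3", "GC1", "GC2", "GC3", "GC12", "GCs", "ATs",
)


@dataclass(frozen=True)
class PositionComposition:
    """Composition percentages for one sequence (synonymous codons only)."""

    A3: float
    T3: float
    G3: float
    C3: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float
    GCs: float
    ATs: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COMPOSITION_COLUMNS}


def position_composition(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> PositionComposition:
    """Base composition at the three codon positions, in percent.

    GCs is the direct G+C count over all three positions of the retained
    codons divided by three times the synonymous-codon total (not the mean
    of GC1/GC2/GC3, though the two coincide here because every retained
    codon contributes all three positions).
    """
    base3 = {"A": 0, "T": 0, "G": 0, "C": 0}
    gc_pos = [0, 0, 0]
    total = 0
    for codon, n in counts.counts.items():
        if codon not in code.synonymous_set:
            continue
        total += n
        base3[codon[2]] += n
        for pos in range(3):
            if codon[pos] in "GC":
                gc_pos[pos] += n
    if total == 0:
        raise DegenerateInputError("no synonymous codons observed")
    pct = 100.0 / total
    gc1, gc2, gc3 = (g * pct for g in gc_pos)
    gcs = sum(gc_pos) * 100.0 / (3 * total)
    return PositionComposition(
        A3=base3["A"] * pct,
        T3=base3["T"] * pct,
        G3=base3["G"] * pct,
        C3=base3["C"] * pct,
        GC1=gc1,
        GC2=gc2,
        GC3=gc3,
        GC12=(gc1 + gc2) / 2.0,
        GCs=gcs,
        ATs=100.0 - gcs,
    )


def composition_table(
    count_tables: dict[str, CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """One composition row per sequence id, columns in report order."""
    rows = {
        sid: position_composition(ct, code).as_dict()
        for sid, ct in count_tables.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(COMPOSITION_COLUMNS)]
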