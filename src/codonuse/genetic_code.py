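"""Genetic-code tables, CDS ingestion and validation, codon counting, translation.

The statistics in this package follow the convention of classic codon-usage
tools: of the 64 codons, the three stops plus ATG (Met) and TGG (Trp) are
excluded, leaving 59 synonymous codons covering 18 amino acids. ``L_aa``
(translatable codons) still counts Met and Trp; ``L_sym`` counts only the 59.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

#: Species groups used for grouped regressions; free-form labels are allowed
#: anywhere, these are merely the canonical six used by the bundled cohort.
KNOWN_GROUPS = (
    "Babesia",
    "Cryptosporidium",
    "Eimeria",
    "Plasmodium",
    "Theileria",
    "Other",
)


class FrameError(ValueError):
    """CDS length is not a multiple of three under strict validation."""


class DegenerateInputError(ValueError):
    """Input is empty (or becomes empty) where content is required."""


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame protein-coding sequence.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token).
    nucleotides : str
        Upper-case DNA over A/C/G/T after validation; RNA input (U) is
        normalized to T on ingestion.
    species : str
        Free-text species label for report tables.
    group : str or None
        Species-group label for grouped regressions.
    """

    id: str
    nucleotides: str
    species: str = ""
    group: str | None = None

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def codons(self) -> list[str]:
        n = len(self.nucleotides) - len(self.nucleotides) % 3
        return [self.nucleotides[i : i + 3] for i in range(0, n, 3)]


@dataclass(frozen=True)
class GeneticCode:
    """Codon-to-amino-acid map plus the synonymous-family bookkeeping.

    ``synonymous_set`` holds the 59 codons used for bias statistics: all
    sense codons except ATG and TGG (single-codon families carry no
    synonymous choice). ``families`` maps each amino acid to its codons,
    restricted to the synonymous set for the 18 multi-codon amino acids.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    degeneracy: dict[str, int]
    synonymous_set: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code (NCBI table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        fams: dict[str, list[str]] = {}
        for codon in sorted(codon_to_aa):
            fams.setdefault(codon_to_aa[codon], []).append(codon)
        families = {
            aa: tuple(codons) for aa, codons in fams.items() if len(codons) > 1
        }
        synonymous = frozenset(c for codons in families.values() for c in codons)
        degeneracy = {aa: len(codons) for aa, codons in families.items()}
        return cls(
            codon_to_aa=codon_to_aa,
            families=families,
            degeneracy=degeneracy,
            synonymous_set=synonymous,
            stop_codons=stops,
        )

    def amino_acid(self, codon: str) -> str | None:
        return self.codon_to_aa.get(codon)


#: Module-level standard code, shared by default across the package.
STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class CodonCountTable:
    """Codon occurrence counts for one sequence."""

    counts: dict[str, int]
    total_codons: int

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "CodonCountTable":
        counts = {c: int(n) for c, n in counts.items() if n > 0}
        return cls(counts=counts, total_codons=sum(counts.values()))

    def synonymous_total(self, code: GeneticCode = STANDARD_CODE) -> int:
        return sum(n for c, n in self.counts.items() if c in code.synonymous_set)

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


def _normalize(raw: str) -> str:
    return raw.upper().replace("U", "T").replace(" ", "")


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a multi-record FASTA file into :class:`CodingSequence` objects.

    The first whitespace-delimited header token becomes the id; RNA (U) is
    normalized to DNA (T). Raises on an unreadable or empty file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DegenerateInputError(f"no FASTA records in {path}")
    return [
        CodingSequence(id=rec.id, nucleotides=_normalize(str(rec.seq)))
        for rec in records
    ]


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.id, description=s.species or "")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def validate_cds(
    seq: CodingSequence,
    policy: str = "lenient",
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodingSequence, list[str]]:
    """Validate and clean a CDS for codon-usage statistics.

    Rules, in order: a trailing partial codon is an error under ``strict``
    and is dropped with a warning under ``lenient``; codons containing
    non-ACGT characters (GenBank CDSs occasionally contain Ns) are dropped
    with a warning; a terminal stop codon is removed silently as part of the
    record; internal stop codons are retained but flagged (pseudogene guard).

    Returns the cleaned sequence and the list of warning strings.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    notes: list[str] = []
    nt = _normalize(seq.nucleotides)
    if len(nt) % 3 != 0:
        if policy == "strict":
            raise FrameError(
                f"{seq.id}: length {len(nt)} is not a multiple of 3"
            )
        nt = nt[: len(nt) - len(nt) % 3]
        notes.append("trailing partial codon dropped")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    kept = []
    for cd in codons:
        if set(cd) <= VALID_BASES:
            kept.append(cd)
        else:
            notes.append(f"ambiguous codon {cd} dropped")
    if kept and kept[-1] in code.stop_codons:
        kept.pop()
        notes.append("terminal stop removed")
    for i, cd in enumerate(kept):
        if cd in code.stop_codons:
            notes.append(f"internal stop {cd} at codon {i}")
    if not kept:
        raise DegenerateInputError(f"{seq.id}: empty after cleaning")
    return replace(seq, nucleotides="".join(kept)), notes


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Tally codon occurrences of a validated sequence."""
    return CodonCountTable.from_counts(Counter(seq.codons))


def translate(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> str:
    """Translate a validated CDS; stop codons yield no character."""
    out = []
    for cd in seq.codons:
        aa = code.codon_to_aa.get(cd)
        if aa is not None:
            out.append(aa)
        elif cd not in code.stop_codons:
            raise ValueError(f"untranslatable codon {cd!r}")
    return "".join(out)
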