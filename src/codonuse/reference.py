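"""Reference codon-adaptiveness weights for CAI / CBI / FOP.

The relative adaptiveness w of a codon is its frequency in a reference set
of highly expressed genes divided by the frequency of the commonest codon of
the same amino acid, so max(w) = 1 within every family and the argmax is the
family's optimal codon. The built-in default is the classic Escherichia coli
highly-expressed-gene table of Sharp & Li (1987), the same default used by
CodonW-style tools; a user-supplied table can replace it for organisms with
known expression data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genetic_code import STANDARD_CODE, GeneticCode

# Relative adaptiveness of E. coli codons estimated from highly expressed
# genes (Sharp & Li 1987, Nucleic Acids Res 15:1281). Met/Trp included for
# completeness; they carry no synonymous information.
SHARP_ECOLI_W: dict[str, float] = {
    "GCA": 0.586, "GCC": 0.122, "GCG": 0.424, "GCT": 1.0,
    "AGA": 0.004, "AGG": 0.002, "CGA": 0.004, "CGC": 0.356,
    "CGG": 0.004, "CGT": 1.0,
    "AAC": 1.0, "AAT": 0.051,
    "GAC": 1.0, "GAT": 0.434,
    "TGC": 1.0, "TGT": 0.5,
    "CAA": 0.124, "CAG": 1.0,
    "GAA": 1.0, "GAG": 0.259,
    "GGA": 0.01, "GGC": 0.724, "GGG": 0.019, "GGT": 1.0,
    "CAC": 1.0, "CAT": 0.291,
    "ATA": 0.003, "ATC": 1.0, "ATT": 0.185,
    "CTA": 0.007, "CTC": 0.037, "CTG": 1.0, "CTT": 0.042,
    "TTA": 0.02, "TTG": 0.02,
    "AAA": 1.0, "AAG": 0.253,
    "ATG": 1.0,
    "TTC": 1.0, "TTT": 0.296,
    "CCA": 0.135, "CCC": 0.012, "CCG": 1.0, "CCT": 0.07,
    "AGC": 0.41, "AGT": 0.085, "TCA": 0.077, "TCC": 0.744,
    "TCG": 0.017, "TCT": 1.0,
    "ACA": 0.076, "ACC": 1.0, "ACG": 0.099, "ACT": 0.965,
    "TGG": 1.0,
    "TAC": 1.0, "TAT": 0.239,
    "GTA": 0.495, "GTC": 0.066, "GTG": 0.221, "GTT": 1.0,
}


class InvalidReferenceError(ValueError):
    """Reference weights are incomplete or non-positive."""


@dataclass(frozen=True)
class ReferenceWeights:
    """Per-codon relative adaptiveness plus the per-family optimal codon."""

    w: dict[str, float]
    optimal: dict[str, str]
    source_label: str = ""

    def __post_init__(self) -> None:
        code = STANDARD_CODE
        for codon in code.synonymous_set:
            weight = self.w.get(codon)
            if weight is None or weight <= 0:
                raise InvalidReferenceError(
                    f"weight for {codon} missing or non-positive"
                )
        for aa, codons in code.families.items():
            top = max(self.w[c] for c in codons)
            if abs(top - 1.0) > 1e-9:
                raise InvalidReferenceError(
                    f"family {aa}: max weight {top}, expected 1"
                )

    @classmethod
    def from_weights(
        cls, w: dict[str, float], source_label: str = "user"
    ) -> "ReferenceWeights":
        """Build from a codon→w map, renormalizing each family to max 1."""
        code = STANDARD_CODE
        norm: dict[str, float] = {}
        optimal: dict[str, str] = {}
        for aa, codons in code.families.items():
            top_codon = max(codons, key=lambda c: (w.get(c, 0.0), c))
            top = w.get(top_codon, 0.0)
            if top <= 0:
                raise InvalidReferenceError(f"family {aa} has no positive weight")
            optimal[aa] = top_codon
            for c in codons:
                norm[c] = w.get(c, 0.0) / top
        return cls(w=norm, optimal=optimal, source_label=source_label)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        source_label: str = "user-counts",
        pseudocount: float = 0.5,
    ) -> "ReferenceWeights":
        """Estimate weights from reference-gene codon counts.

        Codons unobserved in the reference receive a 0.5 pseudo-count before
        normalization so that every weight is strictly positive.
        """
        padded = {
            c: counts.get(c, 0) if counts.get(c, 0) > 0 else pseudocount
            for c in STANDARD_CODE.synonymous_set
        }
        return cls.from_weights(padded, source_label=source_label)

    @classmethod
    def builtin(cls, name: str = "sharp_ecoli") -> "ReferenceWeights":
        if name != "sharp_ecoli":
            raise KeyError(f"unknown built-in reference {name!r}")
        return cls.from_weights(
            SHARP_ECOLI_W, source_label="E. coli highly expressed (Sharp & Li 1987)"
        )


def read_weights(path: str | Path) -> ReferenceWeights:
    """Read a two-column (codon, weight) whitespace-delimited text file."""
    w: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, value = line.split()[:2]
        w[codon.upper().replace("U", "T")] = float(value)
    return ReferenceWeights.from_weights(w, source_label=str(path))


def write_weights(ref: ReferenceWeights, path: str | Path) -> None:
    lines = [f"# source: {ref.source_label}", "# codon\tw\toptimal"]
    code = STANDARD_CODE
    for aa in sorted(code.families):
        for codon in code.families[aa]:
            flag = "*" if ref.optimal[aa] == codon else ""
            lines.append(f"{codon}\t{ref.w[codon]:.6g}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")
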