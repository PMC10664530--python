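"""Shared helper for the numbered analysis scripts: load (or create) the
synthetic study cohort under results/cohort so every script sees the same
sequences for a given seed."""

from pathlib import Path

import pandas as pd

from codonuse import CodingSequence, read_fasta, validate_cds, write_fasta
from codonuse.simulate import generate_paper_like_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_cohort(seed: int = 1):
    """Validated sequences + sample sheet, cached under results/cohort."""
    cohort_dir = RESULTS / "cohort"
    fasta = cohort_dir / "cohort.fasta"
    sheet_path = cohort_dir / "samples.tsv"
    if fasta.exists() and sheet_path.exists():
        sheet = pd.read_csv(sheet_path, sep="\t", index_col=0)
        raw = read_fasta(fasta)
        seqs = [
            CodingSequence(
                id=s.id,
                nucleotides=s.nucleotides,
                species=str(sheet.loc[s.id, "species"]),
                group=str(sheet.loc[s.id, "group"]),
            )
            for s in raw
        ]
    else:
        cohort_dir.mkdir(parents=True, exist_ok=True)
        seqs, sheet = generate_paper_like_cohort(seed)
        write_fasta(seqs, fasta)
        sheet.to_csv(sheet_path, sep="\t")
    validated = [validate_cds(s)[0] for s in seqs]
    return validated, sheet
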