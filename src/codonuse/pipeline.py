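"""End-to-end study pipeline: FASTA (or synthetic cohort) in, tables out.

Every output is a TSV with a fixed column order (plus two Newick trees and
a JSON run manifest), so reruns are byte-comparable and diffing against
published supplementary tables is mechanical.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import composition_table
from .correlation import spearman_by_group
from .genetic_code import (
    STANDARD_CODE,
    CodingSequence,
    count_codons,
    read_fasta,
    validate_cds,
    write_fasta,
)
from .indices import index_table, rscu_matrix
from .phylogeny import (
    hierarchical_cluster,
    neighbor_joining,
    pairwise_cds_distance,
    rscu_distance_matrix,
    write_newick,
)
from .reference import ReferenceWeights, read_weights
from .selection import enc_gc3_table, neutrality_by_group, pr2_table
from .simulate import generate_paper_like_cohort

ALL_STAGES = ("composition", "indices", "rscu", "selection", "correlate", "tree")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    fasta: Path | None = None
    sample_sheet: Path | None = None
    ref_weights: Path | str | None = None  # path or built-in name
    stages: tuple[str, ...] = ALL_STAGES
    linkage: str = "average"
    seed: int = 0
    synthetic: bool = False  # generate the bundled cohort instead of reading

    def resolve_reference(self) -> ReferenceWeights:
        if self.ref_weights is None:
            return ReferenceWeights.builtin()
        p = Path(str(self.ref_weights))
        if p.exists():
            return read_weights(p)
        return ReferenceWeights.builtin(str(self.ref_weights))


def load_inputs(config: RunConfig) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Sequences plus sample sheet, from FASTA or the synthetic cohort."""
    if config.synthetic:
        return generate_paper_like_cohort(config.seed)
    if config.fasta is None:
        raise ValueError("either a FASTA path or synthetic=True is required")
    seqs = read_fasta(config.fasta)
    if config.sample_sheet is not None:
        sheet = pd.read_csv(config.sample_sheet, sep="\t").set_index("id")
        missing = [s.id for s in seqs if s.id not in sheet.index]
        if missing:
            raise ValueError(f"sample sheet lacks ids: {missing}")
        seqs = [
            CodingSequence(
                id=s.id,
                nucleotides=s.nucleotides,
                species=str(sheet.loc[s.id].get("species", "")),
                group=str(sheet.loc[s.id].get("group", "")) or None,
            )
            for s in seqs
        ]
    else:
        sheet = pd.DataFrame(
            {"id": [s.id for s in seqs],
             "species": [s.species for s in seqs],
             "group": [s.group or "all" for s in seqs]}
        ).set_index("id")
    return seqs, sheet


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the requested stages; returns the map of output names to paths.

    Per-sequence validation problems are warnings collected into the
    manifest; a sequence that cannot be validated at all stops the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    collected: list[str] = []

    raw_seqs, sheet = load_inputs(config)
    seqs = []
    for s in raw_seqs:
        cleaned, notes = validate_cds(s)
        collected.extend(f"{s.id}: {n}" for n in notes)
        seqs.append(cleaned)
    groups = sheet.loc[[s.id for s in seqs], "group"]

    if config.synthetic:
        fasta_path = out / "cohort.fasta"
        write_fasta(seqs, fasta_path)
        sheet.to_csv(out / "samples.tsv", sep="\t")
        outputs["cohort"] = fasta_path
        outputs["samples"] = out / "samples.tsv"

    counts = {s.id: count_codons(s) for s in seqs}
    comp = composition_table(counts)
    ref = config.resolve_reference()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        indices = index_table(seqs, ref)
        if "composition" in config.stages:
            _write_tsv(comp.round(2), out / "composition.tsv")
            outputs["composition"] = out / "composition.tsv"
        if "indices" in config.stages:
            _write_tsv(indices.round(3), out / "indices.tsv")
            outputs["indices"] = out / "indices.tsv"
        if "rscu" in config.stages:
            profiles = rscu_matrix(seqs)
            _write_tsv(profiles.round(3), out / "rscu_matrix.tsv", index_label="codon")
            outputs["rscu"] = out / "rscu_matrix.tsv"
        if "selection" in config.stages:
            _write_tsv(
                neutrality_by_group(comp, groups), out / "neutrality.tsv",
                index_label="group",
            )
            _write_tsv(pr2_table(comp), out / "pr2.tsv")
            _write_tsv(
                enc_gc3_table(indices["ENC"], comp["GC3"]), out / "enc_gc3.tsv"
            )
            outputs["neutrality"] = out / "neutrality.tsv"
            outputs["pr2"] = out / "pr2.tsv"
            outputs["enc_gc3"] = out / "enc_gc3.tsv"
        if "correlate" in config.stages:
            joined = indices.join(comp[["GC1", "GC2", "GC3", "GCs"]])
            matrices = spearman_by_group(joined, groups)
            long_parts = []
            for name, cm in matrices.items():
                _write_tsv(cm.rho.round(4), out / f"correlation_{name}.tsv",
                           index_label="variable")
                outputs[f"correlation_{name}"] = out / f"correlation_{name}.tsv"
                long_parts.append(cm.long_format())
            if long_parts:
                pd.concat(long_parts, ignore_index=True).to_csv(
                    out / "correlation_long.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                outputs["correlation_long"] = out / "correlation_long.tsv"
        if "tree" in config.stages:
            profiles = rscu_matrix(seqs)
            dm = rscu_distance_matrix(profiles)
            dendro, order = hierarchical_cluster(dm, linkage=config.linkage)
            (out / "rscu_cluster.nwk").write_text(write_newick(dendro) + "\n")
            (out / "rscu_leaf_order.txt").write_text("\n".join(order) + "\n")
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                out / "rscu_distances.tsv", sep="\t", float_format="%.6g"
            )
            nj_tree = neighbor_joining(pairwise_cds_distance(seqs))
            (out / "cds_nj.nwk").write_text(write_newick(nj_tree) + "\n")
            outputs["rscu_cluster"] = out / "rscu_cluster.nwk"
            outputs["rscu_leaf_order"] = out / "rscu_leaf_order.txt"
            outputs["rscu_distances"] = out / "rscu_distances.tsv"
            outputs["cds_nj"] = out / "cds_nj.nwk"
        collected.extend(str(w.message) for w in caught)

    manifest = {
        "codonuse_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": list(config.stages),
        "linkage": config.linkage,
        "reference": ref.source_label,
        "n_sequences": len(seqs),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in vars(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest()[:16],
        "warnings": collected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = out / "manifest.json"
    return outputs
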