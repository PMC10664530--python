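"""Synthetic CDS cohorts with controllable codon-usage structure.

Sequences are drawn amino-acid-by-amino-acid from a composition profile,
then a codon is drawn from the per-family codon distribution. Three knobs
shape that distribution:

* ``preference_strength`` s — softmax weight exp(s) on one preferred codon
  per family: s = 0 is uniform usage (ENC near 61), s -> inf collapses every
  family to a single codon (ENC = 20).
* ``gc3_target`` g — the G/C-ending side of every family receives total
  probability g (split in proportion to the preference weights within the
  side), so the expected third-position G+C equals g exactly; this emulates
  directional mutation pressure at silent sites.
* mutation mode (``mutation_cohort``) — additionally tilts the joint codon
  distribution by exp(theta * GC-count at positions 1-2) with theta solved
  so the expected GC12 equals g as well, emulating genome-wide mutation
  pressure that drags all positions together (neutrality slope 1). Without
  that tilt the amino-acid composition pins GC12 while GC3 drifts
  (neutrality slope 0): the two regimes bracket the neutrality diagnostic.

Each generated sequence carries one terminal stop codon (exercising the
validator, which strips it); stop codons are never drawn internally.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genetic_code import STANDARD_CODE, CodingSequence, GeneticCode

#: Average amino-acid composition of globular proteins (Swiss-Prot-like),
#: used as the default so GRAVY/AROMO land in realistic ranges.
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

SINGLE_CODON = {"M": "ATG", "W": "TGG"}
TERMINAL_STOP = "TAA"


class InfeasibleSpecError(ValueError):
    """The requested cohort parameters cannot be realized."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``length_aa`` is either a fixed codon count or an inclusive (lo, hi)
    range sampled uniformly per sequence. ``codon_preference`` may give
    explicit per-family codon distributions; otherwise ``preference_strength``
    builds them. ``gc3_target`` of None leaves third positions to the
    preference weights alone.
    """

    n_sequences: int
    length_aa: int | tuple[int, int]
    seed: int
    aa_frequencies: dict[str, float] | None = None
    preference_strength: float = 0.0
    codon_preference: dict[str, dict[str, float]] | None = None
    gc3_target: float | None = None
    group_label: str = "synthetic"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sequences": self.n_sequences,
            "length_aa": self.length_aa,
            "seed": self.seed,
            "aa_frequencies": self.aa_frequencies,
            "preference_strength": self.preference_strength,
            "codon_preference": self.codon_preference,
            "gc3_target": self.gc3_target,
            "group_label": self.group_label,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        payload = json.loads(Path(path).read_text())
        if isinstance(payload.get("length_aa"), list):
            payload["length_aa"] = tuple(payload["length_aa"])
        return cls(**payload)


def preferred_codon(aa: str, code: GeneticCode = STANDARD_CODE) -> str:
    """The deterministic 'preferred' codon of a family (first alphabetically)."""
    return code.families[aa][0]


def family_distributions(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> dict[str, dict[str, float]]:
    """Per-family codon probabilities implied by a spec.

    Preference weights first (softmax on the preferred codon, or the
    explicit ``codon_preference``), then the GC3 tilt: the G/C-ending side
    of each family is rescaled to total ``gc3_target``, preserving relative
    weights within each side.
    """
    dists: dict[str, dict[str, float]] = {}
    for aa, codons in code.families.items():
        if spec.codon_preference is not None:
            given = spec.codon_preference.get(aa)
            if given is None:
                weights = {c: 1.0 for c in codons}
            else:
                weights = {c: float(given.get(c, 0.0)) for c in codons}
                if sum(weights.values()) <= 0:
                    raise InfeasibleSpecError(f"family {aa}: zero total preference")
        else:
            pref = preferred_codon(aa, code)
            weights = {
                c: float(np.exp(spec.preference_strength)) if c == pref else 1.0
                for c in codons
            }
        total = sum(weights.values())
        probs = {c: w / total for c, w in weights.items()}
        if spec.gc3_target is not None:
            probs = _tilt_family(aa, probs, spec.gc3_target)
        dists[aa] = probs
    return dists


def _tilt_family(aa: str, probs: dict[str, float], g: float) -> dict[str, float]:
    if not 0.0 <= g <= 1.0:
        raise InfeasibleSpecError(f"gc3_target {g} outside [0, 1]")
    gc_side = {c: p for c, p in probs.items() if c[2] in "GC"}
    at_side = {c: p for c, p in probs.items() if c[2] not in "GC"}
    gc_mass = sum(gc_side.values())
    at_mass = sum(at_side.values())
    if g > 0 and gc_mass == 0:
        raise InfeasibleSpecError(f"family {aa}: no G/C-ending codon available")
    if g < 1 and at_mass == 0:
        raise InfeasibleSpecError(f"family {aa}: no A/T-ending codon available")
    out = {}
    for c, p in gc_side.items():
        out[c] = g * p / gc_mass if gc_mass else 0.0
    for c, p in at_side.items():
        out[c] = (1.0 - g) * p / at_mass if at_mass else 0.0
    return out


def implied_rscu(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """The asymptotic RSCU of a spec: family probability times degeneracy."""
    return {
        c: p * len(code.families[aa])
        for aa, dist in family_distributions(spec, code).items()
        for c, p in dist.items()
    }


def _aa_probs(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    freqs = spec.aa_frequencies or DEFAULT_AA_FREQS
    aas = sorted(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise InfeasibleSpecError("invalid amino-acid frequencies")
    return aas, p / p.sum()


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.length_aa, int):
        return spec.length_aa
    lo, hi = spec.length_aa
    return int(rng.integers(lo, hi + 1))


def generate_cds(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], dict[str, Counter]]:
    """Draw a cohort; returns sequences plus a per-sequence codon draw log.

    The draw log records the realized codon counts of the coding part
    (terminal stop excluded), so downstream counting can be checked against
    the generator's own bookkeeping. Per-sequence substreams are derived
    from (seed, index), so any one sequence is reproducible on its own.
    """
    dists = family_distributions(spec, code)
    aas, aa_p = _aa_probs(spec)
    seqs: list[CodingSequence] = []
    logs: dict[str, Counter] = {}
    for i in range(spec.n_sequences):
        rng = np.random.default_rng([spec.seed, i])
        length = _draw_length(spec, rng)
        aa_seq = rng.choice(len(aas), size=length, p=aa_p)
        codons = np.empty(length, dtype=object)
        for k, aa in enumerate(aas):
            mask = aa_seq == k
            m = int(mask.sum())
            if m == 0:
                continue
            if aa in SINGLE_CODON:
                codons[mask] = SINGLE_CODON[aa]
            else:
                fam = list(dists[aa])
                fam_p = np.array([dists[aa][c] for c in fam])
                codons[mask] = rng.choice(fam, size=m, p=fam_p)
        seq_id = f"{spec.group_label}_{i + 1:03d}"
        seqs.append(
            CodingSequence(
                id=seq_id,
                nucleotides="".join(codons) + TERMINAL_STOP,
                species=f"{spec.group_label} sp. {i + 1} (synthetic)",
                group=spec.group_label,
            )
        )
        logs[seq_id] = Counter(codons.tolist())
    return seqs, logs


# ---------------------------------------------------------------------------
# neutrality-regime cohorts

def _equal_split_joint(g: float, code: GeneticCode) -> tuple[list[str], np.ndarray]:
    """Joint distribution over the 59 codons: uniform families, GC3 mass g."""
    spec = SyntheticSpec(n_sequences=0, length_aa=1, seed=0, gc3_target=g)
    dists = family_distributions(spec, code)
    codons = [c for aa in sorted(code.families) for c in code.families[aa]]
    weights = np.array(
        [dists[code.codon_to_aa[c]][c] for c in codons], dtype=float
    )
    return codons, weights / weights.sum()


def _gc12_tilted(g: float, code: GeneticCode) -> tuple[list[str], np.ndarray]:
    """Tilt the joint distribution so expected GC12 (and GC3) equal g."""
    codons, base = _equal_split_joint(g, code)
    n12 = np.array([sum(b in "GC" for b in c[:2]) for c in codons], dtype=float)

    def gc12_at(theta: float) -> float:
        w = base * np.exp(theta * n12)
        w /= w.sum()
        return float(w @ n12) / 2.0

    theta = brentq(lambda t: gc12_at(t) - g, -30.0, 30.0)
    w = base * np.exp(theta * n12)
    return codons, w / w.sum()


def _joint_cohort(
    joint_for_g,
    n_sequences: int,
    length_aa: int,
    gc_range: tuple[float, float],
    seed: int,
    group_label: str,
    code: GeneticCode,
) -> list[CodingSequence]:
    seqs = []
    for i in range(n_sequences):
        rng = np.random.default_rng([seed, i])
        g = float(rng.uniform(*gc_range))
        codons, p = joint_for_g(g)
        draw = rng.choice(codons, size=length_aa, p=p)
        seqs.append(
            CodingSequence(
                id=f"{group_label}_{i + 1:03d}",
                nucleotides="".join(draw) + TERMINAL_STOP,
                species=f"{group_label} sp. {i + 1} (synthetic)",
                group=group_label,
            )
        )
    return seqs


def mutation_cohort(
    n_sequences: int = 50,
    length_aa: int = 300,
    gc_range: tuple[float, float] = (0.15, 0.85),
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> list[CodingSequence]:
    """Cohort under genome-wide GC pressure: GC12 and GC3 share one driver.

    Each sequence draws its own pressure g from ``gc_range``; the codon
    distribution is tilted so both expected GC12 and expected GC3 equal g,
    so the neutrality regression across the cohort has slope 1.
    """
    return _joint_cohort(
        lambda g: _gc12_tilted(g, code),
        n_sequences, length_aa, gc_range, seed, "mutation", code,
    )


def selection_cohort(
    n_sequences: int = 50,
    length_aa: int = 300,
    gc_range: tuple[float, float] = (0.15, 0.85),
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> list[CodingSequence]:
    """Cohort with silent-site drift only: GC3 varies, GC12 stays pinned.

    The amino-acid usage (hence positions 1-2) is independent of the
    per-sequence GC3 pressure, so the neutrality regression has slope 0.
    """
    return _joint_cohort(
        lambda g: _equal_split_joint(g, code),
        n_sequences, length_aa, gc_range, seed, "selection", code,
    )


# ---------------------------------------------------------------------------
# the bundled 32-sequence study-like cohort

#: Group sizes and third-position G+C bands of the bundled cohort: two
#: AT-rich genera, three G/C-rich blocks, one intermediate, mirroring the
#: apicomplexan thioredoxin study design (32 genes, six groups, coding
#: lengths 255-1665 nt).
COHORT_DESIGN: tuple[tuple[str, int, tuple[float, float]], ...] = (
    ("Babesia", 4, (0.50, 0.86)),
    ("Cryptosporidium", 4, (0.12, 0.35)),
    ("Eimeria", 5, (0.50, 0.86)),
    ("Plasmodium", 9, (0.12, 0.35)),
    ("Theileria", 4, (0.30, 0.60)),
    ("Other", 6, (0.50, 0.86)),
)

COHORT_LENGTH_AA = (85, 555)
COHORT_PREFERENCE = 1.0


def generate_paper_like_cohort(
    seed: int, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """32 synthetic thioredoxin-like CDSs in six species groups.

    Returns the sequences and a sample sheet (id, species, group). Each
    sequence gets its own GC3 target drawn from its group band and a
    moderate codon preference, giving the mix of AT-rich and GC-rich
    usage the grouped diagnostics expect.
    """
    seqs: list[CodingSequence] = []
    rows = []
    master = np.random.default_rng([seed, 991])
    counter = 0
    for group, size, (lo, hi) in COHORT_DESIGN:
        for k in range(size):
            counter += 1
            g = float(master.uniform(lo, hi))
            spec = SyntheticSpec(
                n_sequences=1,
                length_aa=COHORT_LENGTH_AA,
                seed=int(master.integers(0, 2**31 - 1)),
                preference_strength=COHORT_PREFERENCE,
                gc3_target=g,
                group_label=group,
            )
            (seq,), _ = generate_cds(spec, code)
            seq_id = f"{group}_{k + 1:02d}"
            seqs.append(
                CodingSequence(
                    id=seq_id,
                    nucleotides=seq.nucleotides,
                    species=f"{group}-like sp. {k + 1} (synthetic)",
                    group=group,
                )
            )
            rows.append(
                {"id": seq_id,
                 "species": f"{group}-like sp. {k + 1} (synthetic)",
                 "group": group}
            )
    sheet = pd.DataFrame(rows).set_index("id")
    return seqs, sheet
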