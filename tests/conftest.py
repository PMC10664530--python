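import numpy as np
import pytest

from codonuse import CodingSequence, ReferenceWeights, validate_cds
from codonuse.genetic_code import STANDARD_CODE, CodonCountTable


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def ref():
    return ReferenceWeights.builtin()


@pytest.fixture
def make_counts():
    def _make(d):
        return CodonCountTable.from_counts(d)

    return _make


@pytest.fixture
def random_cds(code):
    """Random validated CDS of a given codon length (sense codons only)."""
    sense = sorted(code.codon_to_aa)

    def _make(n_codons, seed):
        rng = np.random.default_rng(seed)
        nts = "".join(rng.choice(sense, size=n_codons))
        seq, _ = validate_cds(CodingSequence(f"rand{seed}", nts))
        return seq

    return _make
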