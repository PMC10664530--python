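import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonuse import (
    CodingSequence,
    ReferenceWeights,
    aromo,
    cai,
    cbi,
    count_codons,
    enc,
    fop,
    gravy,
    index_table,
    lengths,
    rscu,
    rscu_matrix,
    validate_cds,
)
from codonuse.genetic_code import STANDARD_CODE, CodonCountTable, DegenerateInputError
from codonuse.reference import InvalidReferenceError

from oracles import oracle_enc, oracle_rscu, split_codons


def uniform_counts(per_codon=10):
    return CodonCountTable.from_counts(
        {c: per_codon for c in STANDARD_CODE.synonymous_set}
    )


class TestRSCU:
    def test_hand_worked_two_fold_family(self, make_counts):
        prof = rscu(make_counts({"AAA": 3, "AAG": 1}))
        assert prof.rscu["AAA"] == pytest.approx(1.5)
        assert prof.rscu["AAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self):
        prof = rscu(uniform_counts())
        assert all(v == pytest.approx(1.0) for v in prof.defined().values())

    def test_single_codon_of_sixfold_family_scores_degeneracy(self, make_counts):
        prof = rscu(make_counts({"AGA": 7}))  # Arg, 6-fold
        assert prof.rscu["AGA"] == pytest.approx(6.0)

    def test_unobserved_family_is_nan_not_zero(self, make_counts):
        prof = rscu(make_counts({"AAA": 2}))
        assert math.isnan(prof.rscu["GGA"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_family_sums_equal_degeneracy(self, seed):
        code = STANDARD_CODE
        rng = np.random.default_rng(seed)
        codons = sorted(code.synonymous_set)
        counts = {c: int(n) for c, n in zip(codons, rng.integers(0, 30, len(codons)))}
        if sum(counts.values()) == 0:
            counts[codons[0]] = 1
        prof = rscu(CodonCountTable.from_counts(counts))
        for aa, members in code.families.items():
            total = sum(counts.get(c, 0) for c in members)
            family_rscu = [prof.rscu[c] for c in members]
            if total == 0:
                assert all(math.isnan(v) for v in family_rscu)
            else:
                assert sum(family_rscu) == pytest.approx(len(members))


class TestENC:
    def test_one_codon_per_family_is_20(self, code):
        counts = {members[0]: 3 for members in code.families.values()}
        assert enc(CodonCountTable.from_counts(counts)) == pytest.approx(20.0)

    def test_uniform_usage_clamps_to_61(self):
        # finite-sample F-hat sits below the asymptote, pushing the raw
        # estimate above 61; the cap brings it back
        assert enc(uniform_counts(100)) == 61.0

    def test_matches_oracle_on_random_counts(self, random_cds):
        for seed in range(8):
            seq = random_cds(500, seed=seed)
            expected = oracle_enc(split_codons(seq.nucleotides))
            assert enc(count_codons(seq)) == pytest.approx(expected, abs=1e-9)

    def test_scaling_counts_converges_to_asymptote(self, code):
        rng = np.random.default_rng(42)
        base = {c: int(n) for c, n in zip(
            sorted(code.synonymous_set), rng.integers(1, 12, 59))}
        # asymptotic ENC from the exact probabilities (infinite-sample F)
        fbar = {k: [] for k in (2, 3, 4, 6)}
        for aa, members in code.families.items():
            n = sum(base[c] for c in members)
            fbar[len(members)].append(sum((base[c] / n) ** 2 for c in members))
        limit = 2 + sum(
            len([a for a in code.families if code.degeneracy[a] == k]) / np.mean(v)
            for k, v in fbar.items()
        )
        errors = [
            abs(enc(CodonCountTable.from_counts({c: k * n for c, n in base.items()})) - limit)
            for k in (1, 10, 100)
        ]
        assert errors[2] < errors[0] and errors[2] < 0.05

    def test_missing_ile_class_interpolates(self, make_counts):
        # 2-fold and 4-fold present but biased, Ile absent: ENC still defined
        counts = make_counts({"AAA": 6, "AAG": 2, "GGT": 5, "GGC": 1,
                              "GGA": 1, "GGG": 1})
        value = enc(counts)
        assert 20 < value < 61


class TestReferenceIndices:
    def test_cai_is_one_when_only_optimal_codons_used(self, ref, code):
        counts = CodonCountTable.from_counts(
            {ref.optimal[aa]: 5 for aa in code.families}
        )
        assert cai(counts, ref) == pytest.approx(1.0)

    def test_cai_hand_worked_geometric_mean(self):
        weights = {c: 1.0 for c in STANDARD_CODE.synonymous_set}
        weights["AAG"] = 0.25
        ref = ReferenceWeights.from_weights(weights)
        counts = CodonCountTable.from_counts({"AAA": 1, "AAG": 1})
        assert cai(counts, ref) == pytest.approx(0.5)

    def test_cai_invariant_under_family_rescale(self, ref, random_cds):
        seq = random_cds(300, seed=3)
        counts = count_codons(seq)
        rescaled = ReferenceWeights.from_weights(
            {c: 5.0 * w for c, w in ref.w.items()}
        )
        assert cai(counts, rescaled) == pytest.approx(cai(counts, ref))

    def test_cbi_boundaries(self, ref, code):
        all_optimal = CodonCountTable.from_counts(
            {ref.optimal[aa]: 4 for aa in code.families}
        )
        assert cbi(all_optimal, ref) == pytest.approx(1.0)
        assert cbi(uniform_counts(), ref) == pytest.approx(0.0)

    def test_cbi_hand_worked_negative(self):
        weights = {c: 1.0 if c != "AAA" else 0.5 for c in STANDARD_CODE.synonymous_set}
        ref = ReferenceWeights.from_weights(weights)  # AAG optimal for Lys
        counts = CodonCountTable.from_counts({"AAA": 3, "AAG": 1})
        assert cbi(counts, ref) == pytest.approx(-0.5)

    @pytest.mark.parametrize(
        "counts, expected",
        [({"AAA": 3, "AAG": 1}, 0.25), ({"AAG": 4}, 1.0), ({"AAA": 4}, 0.0)],
    )
    def test_fop_fraction_of_optimal(self, counts, expected):
        weights = {c: 1.0 if c != "AAA" else 0.5 for c in STANDARD_CODE.synonymous_set}
        ref = ReferenceWeights.from_weights(weights)
        assert fop(CodonCountTable.from_counts(counts), ref) == pytest.approx(expected)

    def test_reference_rejects_nonpositive_weight(self):
        weights = {c: 1.0 for c in STANDARD_CODE.synonymous_set}
        weights["AAA"] = 0.0  # explicit zero: no pseudo-count rescue
        with pytest.raises(InvalidReferenceError):
            ReferenceWeights.from_weights(weights)

    def test_pseudocount_floor_for_unobserved_reference_codons(self):
        counts = {c: 100 for c in STANDARD_CODE.synonymous_set}
        del counts["AAA"]
        ref = ReferenceWeights.from_counts(counts)
        assert 0 < ref.w["AAA"] < 1


class TestProteinIndices:
    @pytest.mark.parametrize(
        "protein, expected",
        [("GG", -0.4), ("II", 4.5), ("GI", pytest.approx((4.5 - 0.4) / 2))],
    )
    def test_gravy_values(self, protein, expected):
        assert gravy(protein) == pytest.approx(expected)

    def test_gravy_order_invariant(self):
        assert gravy("MKWVFA") == pytest.approx(gravy("AFVWKM"))

    @pytest.mark.parametrize(
        "protein, expected", [("FYWA", 0.75), ("AAAA", 0.0), ("FFFF", 1.0)]
    )
    def test_aromo_values(self, protein, expected):
        assert aromo(protein) == expected

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            gravy("AXB")
        with pytest.raises(ValueError):
            aromo("AXB")


class TestLengthsAndTables:
    def test_lengths_split_met_from_synonymous(self):
        seq, _ = validate_cds(CodingSequence("s", "ATGAAATAA"))
        assert lengths(seq) == (1, 2)

    def test_met_trp_only_sequence(self):
        seq, _ = validate_cds(CodingSequence("s", "ATGTGGATG"))
        assert lengths(seq) == (0, 3)

    def test_index_table_matches_single_calls(self, ref, random_cds):
        seqs = [random_cds(200, seed=s) for s in range(4)]
        table = index_table(seqs, ref)
        one = seqs[2]
        assert table.loc[one.id, "ENC"] == pytest.approx(enc(count_codons(one)))
        assert table.loc[one.id, "CAI"] == pytest.approx(cai(count_codons(one), ref))
        assert table.loc[one.id, "L_sym"] == lengths(one)[0]

    def test_index_table_deterministic(self, ref, random_cds):
        seqs = [random_cds(150, seed=s) for s in range(3)]
        a = index_table(seqs, ref)
        b = index_table(seqs, ref)
        assert a.equals(b)

    def test_rscu_matrix_shape_and_oracle(self, random_cds):
        seqs = [random_cds(300, seed=s) for s in range(3)]
        matrix = rscu_matrix(seqs)
        assert matrix.shape == (59, 3)
        expected = oracle_rscu(split_codons(seqs[0].nucleotides))
        for codon, value in expected.items():
            assert matrix.loc[codon, seqs[0].id] == pytest.approx(value)

    def test_empty_input_rejected(self, ref):
        with pytest.raises(DegenerateInputError):
            index_table([], ref)
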