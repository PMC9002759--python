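"""Position matrices, forbidden/bias report and IUPAC consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from awbox.matrices import (
    BASES,
    PositionFrequencyMatrix,
    PositionProbabilityMatrix,
    build_pfm,
    build_ppm,
    build_pwm,
    forbidden_and_bias,
    iupac_consensus,
    score_sequence,
    text_logo,
    to_meme_minimal,
)
from awbox.pattern import FIXED_SLOTS, N_SLOTS

TOY = [
    "CCTCGTGCATATCG",
    "CATCGAGAAATCCG",
    "CTTCGTTAACTCCG",
]

# strategy: canonical 14-mers via their nine free N bases
def _assemble(ns):
    seq = list("CxTxGxxxxxxxCG")
    for slot, base in zip(N_SLOTS, ns):
        seq[slot] = base
    return "".join(seq)


boxes = st.text(alphabet="ACGT", min_size=9, max_size=9).map(_assemble)
box_sets = st.lists(boxes, min_size=1, max_size=25)


class TestBuildPfm:
    def test_hand_tally(self):
        pfm = build_pfm(TOY)
        assert pfm.n_sequences == 3
        # slot 2 (N1): C,A,T -> one each of A,C,T
        np.testing.assert_array_equal(pfm.counts[1], [1, 1, 0, 1])
        # slot 7 (N4): G,G,T
        np.testing.assert_array_equal(pfm.counts[6], [0, 0, 2, 1])
        # slot 6 (N3): T,A,T
        np.testing.assert_array_equal(pfm.counts[5], [1, 0, 0, 2])
        # fixed slot 0 is all C
        np.testing.assert_array_equal(pfm.counts[0], [0, 3, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_pfm([])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="14"):
            build_pfm(["CCTCGTGCATATCGA"])

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError, match="canonical"):
            build_pfm(["AAAAAAAAAAAAAA"])

    @given(box_sets)
    def test_conservation(self, seqs):
        """Column sums equal n; fixed slots carry all mass on their base."""
        pfm = build_pfm(seqs)
        assert (pfm.counts.sum(axis=1) == len(seqs)).all()
        for slot, base in FIXED_SLOTS.items():
            assert pfm.counts[slot, BASES.index(base)] == len(seqs)

    @given(box_sets)
    def test_permutation_invariance(self, seqs):
        pfm_a = build_pfm(seqs)
        pfm_b = build_pfm(list(reversed(seqs)))
        np.testing.assert_array_equal(pfm_a.counts, pfm_b.counts)

    def test_invariant_enforced_on_construction(self):
        counts = np.zeros((14, 4), dtype=int)
        with pytest.raises(ValueError, match="sum to n_sequences"):
            PositionFrequencyMatrix(counts, 3)


class TestBuildPpm:
    def test_zero_pseudocount_is_exact_frequency(self):
        ppm = build_ppm(build_pfm(TOY), pseudocount=0.0)
        np.testing.assert_allclose(ppm.probs[0], [0, 1, 0, 0])
        np.testing.assert_allclose(ppm.probs[1], [1 / 3, 1 / 3, 0, 1 / 3])

    def test_pseudocount_arithmetic(self):
        """(count + a) / (n + 4a): a (9,9,0,0) column with a=1 over n=18."""
        seqs = ["CATCGAGAAATCCG"] * 9 + ["CCTCGAGAAATCCG"] * 9
        ppm = build_ppm(build_pfm(seqs), pseudocount=1.0)
        np.testing.assert_allclose(ppm.probs[1],
                                   [10 / 22, 10 / 22, 1 / 22, 1 / 22])

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            build_ppm(build_pfm(TOY), pseudocount=-0.5)

    @given(box_sets, st.floats(min_value=0, max_value=5,
                               allow_nan=False, allow_infinity=False))
    def test_rows_always_normalised(self, seqs, a):
        ppm = build_ppm(build_pfm(seqs), pseudocount=a)
        np.testing.assert_allclose(ppm.probs.sum(axis=1), 1.0)

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PositionProbabilityMatrix(np.full((14, 4), 0.3), 0.0)


class TestBuildPwm:
    def test_uniform_probs_give_zero_bits(self):
        ppm = PositionProbabilityMatrix(np.full((14, 4), 0.25), 0.0)
        pwm = build_pwm(ppm)
        np.testing.assert_allclose(pwm.weights, 0.0)

    def test_elementwise_oracle(self):
        import math
        ppm = build_ppm(build_pfm(TOY), pseudocount=0.5)
        bg = (0.3, 0.2, 0.2, 0.3)
        pwm = build_pwm(ppm, bg)
        for i in range(14):
            for j in range(4):
                assert pwm.weights[i, j] == pytest.approx(
                    math.log2(ppm.probs[i, j] / bg[j]))

    def test_zero_probability_maps_to_minus_inf(self):
        ppm = build_ppm(build_pfm(TOY), pseudocount=0.0)
        pwm = build_pwm(ppm)
        assert np.isneginf(pwm.weights[0, BASES.index("A")])

    def test_bad_background_rejected(self):
        ppm = build_ppm(build_pfm(TOY), pseudocount=0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            build_pwm(ppm, (0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="> 0"):
            build_pwm(ppm, (0.5, 0.5, 0.0, 0.0))

    def test_cross_check_against_biopython(self, bound_records):
        """Independent oracle: Biopython's motif PSSM with the same
        pseudocount and uniform background."""
        from Bio import motifs
        from Bio.Seq import Seq

        seqs = [r.seq for r in bound_records]
        m = motifs.create([Seq(s) for s in seqs])
        bio_pssm = m.counts.normalize(pseudocounts=0.5).log_odds()
        pwm = build_pwm(build_ppm(build_pfm(seqs), pseudocount=0.5))
        for j, base in enumerate(BASES):
            for i in range(14):
                assert pwm.weights[i, j] == pytest.approx(bio_pssm[base][i])


class TestForbiddenAndBias:
    def test_shipped_bound_set(self, bound_records):
        rep = forbidden_and_bias(build_pfm([r.seq for r in bound_records]))
        assert rep.forbidden == {
            1: frozenset("G"), 2: frozenset("G"), 3: frozenset("C"),
            4: frozenset("A"), 5: frozenset(), 6: frozenset("C"),
            7: frozenset(), 8: frozenset("G"), 9: frozenset("G"),
        }
        assert rep.bias[2] == frozenset("C")
        assert rep.bias[6] == frozenset("A")
        assert rep.bias_probability[2] == pytest.approx(13 / 18)
        assert rep.bias_probability[6] == pytest.approx(12 / 18)

    def test_allowed_is_complement_of_forbidden(self, bound_records):
        rep = forbidden_and_bias(build_pfm([r.seq for r in bound_records]))
        for k in range(1, 10):
            assert rep.allowed(k) == frozenset("ACGT") - rep.forbidden[k]

    def test_single_sequence(self):
        rep = forbidden_and_bias(build_pfm([TOY[0]]))
        # with one sequence every unobserved base is forbidden and the
        # observed base is the bias with probability 1
        for k in range(1, 10):
            assert len(rep.forbidden[k]) == 3
            assert len(rep.bias[k]) == 1
            assert rep.bias_probability[k] == 1.0

    def test_ties_reported_as_sets(self):
        rep = forbidden_and_bias(build_pfm(["CATCGAGAAATCCG",
                                            "CCTCGAGAAATCCG"]))
        assert rep.bias[1] == frozenset("AC")
        assert rep.bias_probability[1] == 0.5


class TestIupacConsensus:
    def _ppm(self, seqs, a=0.0):
        return build_ppm(build_pfm(seqs), pseudocount=a)

    def test_shipped_bound_set(self, bound_records):
        ppm = self._ppm([r.seq for r in bound_records])
        assert iupac_consensus(ppm) == "CHTCGWKWAYWYCG"

    def test_collapse_at_threshold(self):
        # 2 of 3 sequences share T at N3 (prob 2/3 >= 0.6): collapses to T
        ppm = self._ppm(["CCTCGTGCATATCG", "CCTCGTGCATATCG", "CCTCGAGCATATCG"])
        assert iupac_consensus(ppm)[5] == "T"

    def test_inclusion_mode_never_collapses(self):
        ppm = self._ppm(["CCTCGTGCATATCG", "CCTCGTGCATATCG", "CCTCGAGCATATCG"])
        # same slot in inclusion mode keeps both observed bases (A, T -> W)
        assert iupac_consensus(ppm, mode="inclusion")[5] == "W"

    def test_fixed_slots_always_conserved(self, bound_records):
        cons = iupac_consensus(self._ppm([r.seq for r in bound_records]))
        for slot, base in FIXED_SLOTS.items():
            assert cons[slot] == base

    def test_unknown_mode_rejected(self, bound_records):
        ppm = self._ppm([r.seq for r in bound_records])
        with pytest.raises(ValueError, match="mode"):
            iupac_consensus(ppm, mode="majority")

    def test_out_of_range_thresholds_rejected(self, bound_records):
        ppm = self._ppm([r.seq for r in bound_records])
        with pytest.raises(ValueError, match="thresholds"):
            iupac_consensus(ppm, include_threshold=0.0)
        with pytest.raises(ValueError, match="thresholds"):
            iupac_consensus(ppm, collapse_threshold=1.0)

    @given(box_sets, st.floats(min_value=0.05, max_value=0.45),
           st.floats(min_value=0.05, max_value=0.45))
    def test_inclusion_monotonicity(self, seqs, lo, hi):
        """Raising the include threshold never widens any slot's base set."""
        from itertools import combinations

        from awbox.pattern import iupac_code

        lo, hi = sorted((lo, hi))
        ppm = self._ppm(seqs)
        wide = iupac_consensus(ppm, mode="inclusion", include_threshold=lo)
        narrow = iupac_consensus(ppm, mode="inclusion", include_threshold=hi)
        iupac_sets = {iupac_code(set(combo)): set(combo)
                      for r in range(1, 5) for combo in combinations("ACGT", r)}
        for slot, (w, n) in enumerate(zip(wide, narrow)):
            if ppm.probs[slot].max() < hi:
                # no base reaches the higher threshold; the documented
                # fallback covers every observed base instead
                continue
            assert iupac_sets[n] <= iupac_sets[w]


class TestScoreSequence:
    def test_forbidden_substitution_always_lowers_the_score(self, bound_records):
        """With additive per-slot weights, replacing an observed base with a
        zero-count base strictly lowers the score."""
        seqs = [r.seq for r in bound_records]
        pfm = build_pfm(seqs)
        pwm = build_pwm(build_ppm(pfm, pseudocount=0.5))
        rep = forbidden_and_bias(pfm)
        for seq in seqs:
            base_score = score_sequence(pwm, seq)
            for k, slot in enumerate(N_SLOTS, start=1):
                for bad in rep.forbidden[k]:
                    variant = seq[:slot] + bad + seq[slot + 1:]
                    assert score_sequence(pwm, variant) < base_score

    def test_lookup_oracle(self):
        pwm = build_pwm(build_ppm(build_pfm(TOY), pseudocount=0.5))
        seq = TOY[1]
        expected = sum(pwm.weights[i, BASES.index(b)] for i, b in enumerate(seq))
        assert score_sequence(pwm, seq) == pytest.approx(expected)

    def test_wrong_length_rejected(self):
        pwm = build_pwm(build_ppm(build_pfm(TOY), pseudocount=0.5))
        with pytest.raises(ValueError, match="14"):
            score_sequence(pwm, "ACGT")

    def test_invalid_base_rejected(self):
        pwm = build_pwm(build_ppm(build_pfm(TOY), pseudocount=0.5))
        with pytest.raises(ValueError, match="invalid base"):
            score_sequence(pwm, "CCTCGTGCATATCN")


class TestRendering:
    def test_meme_minimal_parses_with_biopython(self, bound_records):
        import io

        from Bio import motifs

        seqs = [r.seq for r in bound_records]
        ppm = build_ppm(build_pfm(seqs), pseudocount=0.5)
        text = to_meme_minimal(ppm, name="AW-box", n_sequences=len(seqs))
        parsed = motifs.parse(io.StringIO(text), "minimal")
        assert len(parsed) == 1
        m = parsed[0]
        assert m.length == 14
        # the minimal-format parser reconstructs integer counts from
        # nsites x probability and renormalises, so cells are quantised to
        # roughly 1/nsites; the loose tolerance still catches any
        # transposition or base-order error, which shifts cells by far more
        for j, base in enumerate(BASES):
            for i in range(14):
                assert m.pwm[base][i] == pytest.approx(ppm.probs[i, j],
                                                       abs=2.0 / len(seqs))

    def test_text_logo_has_one_line_per_slot(self, bound_records):
        ppm = build_ppm(build_pfm([r.seq for r in bound_records]))
        logo = text_logo(ppm)
        assert len(logo.splitlines()) == 15  # header + 14 slots
        assert "C:1.00" in logo  # conserved 5' C
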