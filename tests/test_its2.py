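"""ITS2 delimitation, constrained folding and helix segmentation."""

import numpy as np
import pytest

from phycodelim import (
    AnchorConfig,
    ConstraintViolationError,
    DegenerateIts2Error,
    DelimitationFailure,
    FoldParams,
    NucSequence,
    SecondaryStructure,
    annotate_barcode,
    brute_force_fold_score,
    delimit_its2,
    fold_constrained,
    gen_its2_family,
    score_structure,
    segment_helices,
)
from phycodelim.errors import AnnotationError
from phycodelim.simulate import GENERATOR_ANCHORS

from conftest import family_spec


class TestAnchorConfig:
    def test_mismatch_budget_below_stem_length(self):
        with pytest.raises(ValueError):
            AnchorConfig(min_stem_len=6, max_mismatch=6)

    def test_short_motifs_rejected(self):
        with pytest.raises(ValueError):
            AnchorConfig(motif_58s_tail="ACGT", motif_28s_head="ACGTACGT", min_stem_len=6)


class TestDelimitIts2:
    def test_recovers_planted_interval(self):
        for seed in range(10):
            records, truth = gen_its2_family(family_spec(seed, change_map={}))
            ann = delimit_its2(records[0], GENERATOR_ANCHORS)
            assert ann.its2_interval == truth.reference_its2_interval
            assert ann.stem_mismatches == 0

    def test_missing_head_motif_is_named(self):
        rec = NucSequence(id="x", residues="A" * 10 + GENERATOR_ANCHORS.motif_58s_tail + "A" * 30)
        with pytest.raises(DelimitationFailure, match="28S head"):
            delimit_its2(rec, GENERATOR_ANCHORS)

    def test_adjacent_anchors_degenerate(self):
        rec = NucSequence(
            id="x",
            residues="AAAA"
            + GENERATOR_ANCHORS.motif_58s_tail
            + GENERATOR_ANCHORS.motif_28s_head
            + "AAAA",
        )
        with pytest.raises(DegenerateIts2Error):
            delimit_its2(rec, GENERATOR_ANCHORS)

    def test_stem_pairs_are_canonical(self):
        records, _ = gen_its2_family(family_spec(3, change_map={}))
        ann = delimit_its2(records[0], GENERATOR_ANCHORS)
        tail = GENERATOR_ANCHORS.motif_58s_tail.replace("T", "U")
        head = GENERATOR_ANCHORS.motif_28s_head.replace("T", "U")
        from phycodelim import is_canonical

        for i, j in ann.stem_pairs:
            assert is_canonical(tail[i], head[j])


class TestFoldConstrained:
    def test_three_gc_hairpin(self, unconstrained_params):
        s = fold_constrained("GGGAAACCC", unconstrained_params)
        assert s.dot_bracket() == "(((...)))"

    def test_unpairable_sequence(self, unconstrained_params):
        assert fold_constrained("AAAA", unconstrained_params).dot_bracket() == "...."

    def test_missing_gguag_raises_when_required(self):
        with pytest.raises(ConstraintViolationError, match="GGUAG"):
            fold_constrained("GGGAAACCC", FoldParams(require_motifs=True))

    def test_uu_constraint_requires_u_residues(self, unconstrained_params):
        with pytest.raises(ConstraintViolationError, match="U/U"):
            fold_constrained("GGGAAACCC", unconstrained_params, uu_mismatch=(0, 8))

    def test_matches_exhaustive_enumeration(self, unconstrained_params):
        """DP optimum equals brute-force enumeration on short strings."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(4, 19))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            folded = fold_constrained(seq, unconstrained_params)
            dp = score_structure(seq, folded.pairs, unconstrained_params)
            assert dp == pytest.approx(brute_force_fold_score(seq, unconstrained_params))

    def test_forced_unpaired_respected_in_oracle_and_dp(self, unconstrained_params):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(8, 16))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            forced = tuple(int(i) for i in rng.choice(n, size=2, replace=False))
            folded = fold_constrained(seq, unconstrained_params, forced_unpaired=forced)
            assert all(folded.pairing[i] is None for i in forced)
            dp = score_structure(seq, folded.pairs, unconstrained_params)
            bf = brute_force_fold_score(seq, unconstrained_params, forced_unpaired=forced)
            assert dp == pytest.approx(bf)

    def test_refolding_is_bit_identical(self, unconstrained_params):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGU"), size=60))
        assert (
            fold_constrained(seq, unconstrained_params).dot_bracket()
            == fold_constrained(seq, unconstrained_params).dot_bracket()
        )

    def test_structures_are_valid(self, unconstrained_params):
        """Involution, no crossing pairs, hairpin loops >= min_loop."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 60))))
            s = fold_constrained(seq, unconstrained_params)
            pairs = s.pairs
            for i, j in pairs:
                assert s.pairing[j] == i
                assert j - i - 1 >= unconstrained_params.min_loop or any(
                    i < a < j for a, b in pairs if (a, b) != (i, j)
                )
            for (i, j) in pairs:
                for (a, b) in pairs:
                    assert not (i < a < j < b)  # no pseudoknots

    def test_planted_structure_attains_fold_optimum(self):
        """Constrained folding scores at least the planted design."""
        params = FoldParams()
        for seed in range(8):
            _, truth = gen_its2_family(family_spec(seed, change_map={}))
            ref = truth.reference_structure
            folded = fold_constrained(
                ref.sequence, params, uu_mismatch=truth.uu_mismatch_positions
            )
            fold_score = score_structure(ref.sequence, folded.pairs, params)
            planted_score = score_structure(ref.sequence, ref.pairs, params)
            assert fold_score >= planted_score - 1e-9
            assert all(folded.pairing[i] is None for i in truth.gguag_positions)
            assert all(folded.pairing[i] is None for i in truth.uu_mismatch_positions)


class TestSegmentation:
    def test_generator_layout_recovered(self):
        params = FoldParams()
        _, truth = gen_its2_family(family_spec(1, change_map={}))
        folded = fold_constrained(
            truth.reference_structure.sequence, params,
            uu_mismatch=truth.uu_mismatch_positions,
        )
        seg = segment_helices(folded)
        assert seg.is_four_helix_ring
        labels = [h.label for h in seg.helices]
        assert labels == ["5.8S/LSU stem", "I", "II", "III", "IV"]
        truth_helix = {h.label: h.span for h in truth.reference_structure.helices}
        seg_helix = {h.label: h.span for h in seg.helices}
        for roman in ("I", "II", "III", "IV"):
            assert seg_helix[roman] == truth_helix[roman]

    def test_gguag_sits_on_helix_iii_five_prime_side(self):
        params = FoldParams()
        _, truth = gen_its2_family(family_spec(4, change_map={}))
        folded = segment_helices(
            fold_constrained(
                truth.reference_structure.sequence, params,
                uu_mismatch=truth.uu_mismatch_positions,
            )
        )
        helix_iii = folded.helix("III")
        lo, hi = helix_iii.five_range
        assert all(lo <= i < hi for i in truth.gguag_positions)

    def test_single_hairpin_flagged_invalid(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        with pytest.warns(UserWarning, match="four-helix"):
            seg = segment_helices(s)
        assert not seg.is_four_helix_ring
        assert [h.label for h in seg.helices] == ["I"]


class TestBarcode:
    def test_helix_iv_outside_default_barcode(self):
        _, truth = gen_its2_family(family_spec(2, change_map={}))
        s = truth.reference_structure
        helix_iv = s.helix("IV")
        for i in range(*helix_iv.span):
            assert not s.within_barcode(i)

    def test_helices_i_to_iii_inside_default_barcode(self):
        _, truth = gen_its2_family(family_spec(2, change_map={}))
        s = truth.reference_structure
        for roman in ("I", "II", "III"):
            lo, hi = s.helix(roman).span
            assert all(s.within_barcode(i) for i in range(lo, hi))

    def test_custom_interval_is_verbatim(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        assert annotate_barcode(s, (2, 5)).barcode_interval == (2, 5)

    def test_default_policy_needs_helix_iii(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        with pytest.warns(UserWarning):
            seg = segment_helices(s)
        with pytest.raises(AnnotationError):
            annotate_barcode(seg, "default")


class TestStructureIO:
    def test_dot_bracket_round_trip(self, unconstrained_params):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGU"), size=50))
        s = fold_constrained(seq, unconstrained_params)
        again = SecondaryStructure.from_dot_bracket(s.sequence, s.dot_bracket())
        assert again.pairing == s.pairing

    def test_ct_output_partner_column(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAACCC", "(((...)))")
        lines = s.to_ct().splitlines()
        assert lines[1].split("\t")[4] == "9"  # base 1 pairs base 9
        assert lines[5].split("\t")[4] == "0"  # loop base unpaired
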