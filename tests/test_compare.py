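"""Structure alignment, CBC/hCBC classification and the verdict rule."""

import numpy as np
import pytest

from phycodelim import (
    AlignParams,
    ChangeReport,
    ColumnMapping,
    DelimitationThresholds,
    SecondaryStructure,
    StructuralChange,
    align_structures,
    classify_changes,
    delimit_species,
    gen_its2_family,
)

from conftest import family_spec, random_change_map


def structure(seq: str, db: str, barcode=None) -> SecondaryStructure:
    s = SecondaryStructure.from_dot_bracket(seq, db)
    if barcode is not None:
        from dataclasses import replace

        s = replace(s, barcode_interval=barcode)
    return s


def identity_mapping(n: int) -> ColumnMapping:
    return ColumnMapping(tuple((i, i) for i in range(n)))


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def brute_force_align_score(a, b, params: AlignParams) -> float:
    """Exhaustive enumeration of all global alignments (tiny inputs)."""
    sa, sb = a.sequence, b.sequence
    pa = [p is not None for p in a.pairing]
    pb = [p is not None for p in b.pairing]

    best = float("-inf")

    def rec(i, j, score):
        nonlocal best
        if i == len(sa) and j == len(sb):
            best = max(best, score)
            return
        if i < len(sa) and j < len(sb):
            gain = (
                params.match_bonus if sa[i] == sb[j] else params.mismatch_penalty
            ) + (params.structure_bonus if pa[i] == pb[j] else 0.0)
            rec(i + 1, j + 1, score + gain)
        if i < len(sa):
            rec(i + 1, j, score + params.gap_penalty)
        if j < len(sb):
            rec(i, j + 1, score + params.gap_penalty)

    rec(0, 0, 0.0)
    return best


class TestAlignStructures:
    def test_identical_structures_identity_mapping(self):
        s = structure("GGGAAACCC", "(((...)))")
        m = align_structures(s, s)
        assert m.columns == tuple((i, i) for i in range(9))

    def test_planted_deletion_places_single_gap(self):
        spec = family_spec(0, change_map={"indel": {"spacer": 1}})
        _, truth = gen_its2_family(spec)
        var = truth.variants[0]
        m = align_structures(truth.reference_structure, var.structure)
        assert m.columns == var.mapping.columns

    def test_score_matches_exhaustive_enumeration(self):
        params = AlignParams()
        rng = np.random.default_rng(3)
        for _ in range(15):
            na, nb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a = structure("".join(rng.choice(list("ACGU"), na)), "." * na)
            b = structure("".join(rng.choice(list("ACGU"), nb)), "." * nb)
            m = align_structures(a, b, params)
            score = 0.0
            for i, j in m.columns:
                if i is None or j is None:
                    score += params.gap_penalty
                else:
                    score += (
                        params.match_bonus
                        if a.sequence[i] == b.sequence[j]
                        else params.mismatch_penalty
                    ) + params.structure_bonus  # both unpaired here
            assert score == pytest.approx(brute_force_align_score(a, b, params))

    def test_empty_structure_rejected(self):
        s = structure("GGGAAACCC", "(((...)))")
        with pytest.raises(Exception):
            align_structures(s, SecondaryStructure(sequence="", pairing=()))


# ---------------------------------------------------------------------------
# Classification grammar
# ---------------------------------------------------------------------------

def paired_column_case(pair_a: str, pair_b: str):
    """Minimal aligned duplexes differing only at the closing pair."""
    xa, ya = pair_a.split("-")
    xb, yb = pair_b.split("-")
    seq_a = f"{xa}GGGAAACCC{ya}"
    seq_b = f"{xb}GGGAAACCC{yb}"
    db = "((((...))))"
    a = structure(seq_a, db, barcode=(0, 11))
    b = structure(seq_b, db, barcode=(0, 11))
    report = classify_changes(a, b, identity_mapping(11))
    assert len(report.changes) == 1
    return report.changes[0]


class TestClassificationGrammar:
    """The worked pair-change vocabulary of ITS2 taxonomy."""

    @pytest.mark.parametrize(
        "before, after, kind",
        [
            ("U-A", "C-G", "CBC"),
            ("U-G", "C-G", "hCBC"),
            ("G-C", "G-U", "hCBC"),
            ("C-G", "U-A", "CBC"),
            ("G-U", "G-C", "hCBC"),
        ],
    )
    def test_pair_changes(self, before, after, kind):
        change = paired_column_case(before, after)
        assert change.kind == kind
        assert change.before == before
        assert change.after == after

    @pytest.mark.parametrize(
        "base_a, base_b, kind",
        [
            ("A", "C", "transversion"),
            ("U", "C", "transition"),
            ("G", "A", "transition"),
            ("A", "U", "transversion"),
        ],
    )
    def test_unpaired_substitutions(self, base_a, base_b, kind):
        a = structure(f"GGGA{base_a}AACCC", "(((....)))")
        b = structure(f"GGGA{base_b}AACCC", "(((....)))")
        report = classify_changes(a, b, identity_mapping(10))
        assert [c.kind for c in report.changes] == [kind]

    def test_cbc_never_emitted_for_non_canonical_result(self):
        # A-U -> A-C keeps both positions "paired" in the mapping but the
        # resulting pair is not canonical: must not be a CBC or hCBC.
        a = structure("AGGGAAACCCU", "((((...))))")
        b = structure("AGGGAAACCCC", "((((...))))")
        report = classify_changes(a, b, identity_mapping(11))
        assert all(c.kind == "pairing_change" for c in report.changes)

    def test_gap_precedence_over_substitution(self):
        a = structure("GGGAAACCCA", "(((...))).")
        b = structure("GGGAAACCC", "(((...)))")
        mapping = ColumnMapping(tuple((i, i) for i in range(9)) + ((9, None),))
        report = classify_changes(a, b, mapping)
        assert [c.kind for c in report.changes] == ["deletion"]

    def test_paired_vs_unpaired_is_pairing_change(self):
        a = structure("GGGAAACCC", "(((...)))")
        b = structure("GGGAAACCC", ".((...)).")
        report = classify_changes(a, b, identity_mapping(9))
        kinds = {c.kind for c in report.changes}
        assert kinds == {"pairing_change"}

    def test_swapping_inputs_preserves_counts(self):
        """Deletion <-> insertion flip; CBC/hCBC/substitution counts hold."""
        rng = np.random.default_rng(17)
        for seed in range(30):
            cm = random_change_map(np.random.default_rng(seed))
            _, truth = gen_its2_family(family_spec(seed, change_map=cm))
            var = truth.variants[0]
            a, b = truth.reference_structure, var.structure
            m = align_structures(a, b)
            fwd = classify_changes(a, b, m)
            rev = classify_changes(b, a, m.swapped())
            for kind in ("CBC", "hCBC", "transition", "transversion", "pairing_change"):
                assert fwd.count(kind) == rev.count(kind)
            assert fwd.count("deletion") == rev.count("insertion")
            assert fwd.count("insertion") == rev.count("deletion")
        del rng

    def test_count_conservation(self):
        for seed in range(20):
            cm = random_change_map(np.random.default_rng(seed + 50))
            _, truth = gen_its2_family(family_spec(seed, change_map=cm))
            var = truth.variants[0]
            m = align_structures(truth.reference_structure, var.structure)
            report = classify_changes(truth.reference_structure, var.structure, m)
            total = len(report.changes)
            by_kind = sum(
                report.count(k)
                for k in (
                    "CBC", "hCBC", "transition", "transversion",
                    "deletion", "insertion", "pairing_change",
                )
            )
            assert by_kind == total
            within = sum(1 for c in report.changes if c.within_barcode)
            outside = sum(1 for c in report.changes if not c.within_barcode)
            assert within + outside == total


# ---------------------------------------------------------------------------
# Verdict rule
# ---------------------------------------------------------------------------

def report_with(changes) -> ChangeReport:
    return ChangeReport(compared_ids=("a", "b"), changes=list(changes))


def make_change(kind, within, region="helix III", substitution=False):
    return StructuralChange(
        kind=kind,
        positions=(0,),
        before="U-A" if kind in {"CBC", "hCBC"} else "U",
        after="C-G" if kind in {"CBC", "hCBC"} else "C",
        region=region,
        within_barcode=within,
        substitution=substitution,
    )


class TestDelimitSpecies:
    def test_barcode_cbc_means_distinct(self):
        report = report_with([make_change("CBC", True), make_change("CBC", True)])
        assert delimit_species(report).verdict == "distinct"

    def test_changes_only_outside_barcode_conspecific(self):
        report = report_with(
            [make_change("deletion", False), make_change("transition", False)]
        )
        assert delimit_species(report, similarity=100.0).verdict == "conspecific"

    def test_empty_report_conspecific_without_similarity(self):
        assert delimit_species(report_with([])).verdict == "conspecific"

    def test_barcode_hcbc_blocks_conspecificity_by_default(self):
        report = report_with([make_change("hCBC", True)])
        assert delimit_species(report).verdict == "ambiguous"
        relaxed = DelimitationThresholds(require_zero_hcbc=False)
        assert delimit_species(report, thresholds=relaxed).verdict == "conspecific"

    def test_similarity_floor_applies(self):
        report = report_with([])
        assert delimit_species(report, similarity=99.0).verdict == "ambiguous"
        assert delimit_species(report, similarity=99.9).verdict == "conspecific"
        loose = DelimitationThresholds(conspecific_min=98.0)
        assert delimit_species(report, similarity=99.0, thresholds=loose).verdict == "conspecific"

    def test_verdict_reproducible_from_evidence(self):
        report = report_with([make_change("CBC", True)])
        v = delimit_species(report)
        assert v.evidence["cbc_within_barcode"] == 1
        assert v.to_dict()["verdict"] == "distinct"
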