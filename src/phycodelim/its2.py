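"""ITS2 delimitation and constrained secondary-structure prediction.

The ITS2 spacer of the rDNA cistron is located by annealing the 3' end of
the 5.8S gene against the complementary 5' start of the 28S (LSU) gene:
that hybrid stem brackets the spacer, and the interval strictly between
the annealed halves is the ITS2.

Folding uses a weighted base-pair-maximisation dynamic programme
(Nussinov-style) with a stacking bonus: GC > AU >= GU pair weights plus an
increment for each directly stacked pair, hairpin loops at least
``min_loop`` unpaired bases, no pseudoknots.  Two biological constraints
of the ITS2 model can be imposed: the conserved GGUAG motif on the 5'
side of helix III is held unpaired, and a designated pyrimidine-pyrimidine
U/U opposition (helix II) is kept as an internal-loop mismatch.  The DP is
deterministic: among co-optimal structures the traceback pairs the
5'-most base first and takes the nearest co-optimal partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    ConstraintViolationError,
    DegenerateIts2Error,
    DelimitationFailure,
)
from .seqio import NucSequence

#: Canonical RNA pairs (Watson-Crick plus the G.U wobble).
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

GGUAG = "GGUAG"

STEM_LABEL = "5.8S/LSU stem"

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def is_canonical(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


# ---------------------------------------------------------------------------
# Hybrid-stem delimitation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorConfig:
    """Anchor motifs bracketing the ITS2.

    ``motif_58s_tail`` is the 3' terminal site of the 5.8S gene and
    ``motif_28s_head`` the 5' start of the 28S gene; annealed against each
    other they form the hybrid stem whose inner ends delimit the spacer.
    Defaults follow the broadly conserved eukaryote 5.8S 3' end / LSU 5'
    start; synthetic families always carry their own anchors, so analyses
    of generated data never rely on the biological defaults.
    """

    motif_58s_tail: str = "CGGCTGGATCACTC"
    motif_28s_head: str = "GAGTGATCCAGCCG"
    min_stem_len: int = 6
    max_mismatch: int = 2

    def __post_init__(self):
        if self.min_stem_len < 4:
            raise ValueError("min_stem_len must be >= 4")
        if self.max_mismatch >= self.min_stem_len:
            raise ValueError("max_mismatch must be < min_stem_len")
        for motif in (self.motif_58s_tail, self.motif_28s_head):
            if len(motif) < self.min_stem_len:
                raise ValueError("anchor motifs must be >= min_stem_len long")


@dataclass(frozen=True)
class Its2Annotation:
    """Located ITS2 interval plus the hybrid-stem annealing evidence."""

    source_id: str
    its2_interval: tuple[int, int]  # 0-based, half-open on the source record
    stem_pairs: tuple[tuple[int, int], ...]  # (pos in 5.8S tail, pos in 28S head)
    stem_mismatches: int
    tail_interval: tuple[int, int] = (0, 0)
    head_interval: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "its2_interval": list(self.its2_interval),
            "stem_pairs": [list(p) for p in self.stem_pairs],
            "stem_mismatches": self.stem_mismatches,
            "tail_interval": list(self.tail_interval),
            "head_interval": list(self.head_interval),
        }


def _anneal(tail: str, head: str) -> tuple[list[tuple[int, int]], int]:
    """Antiparallel annealing of the 5.8S tail against the 28S head.

    The innermost rung pairs the last tail base with the first head base;
    rung ``t`` pairs ``tail[-1 - t]`` with ``head[t]``.  Returns the list
    of canonically pairing rungs and the mismatch count.
    """
    tail_rna = tail.upper().replace("T", "U")
    head_rna = head.upper().replace("T", "U")
    n = min(len(tail_rna), len(head_rna))
    pairs: list[tuple[int, int]] = []
    mismatches = 0
    for t in range(n):
        i = len(tail_rna) - 1 - t
        if is_canonical(tail_rna[i], head_rna[t]):
            pairs.append((i, t))
        else:
            mismatches += 1
    return pairs, mismatches


def delimit_its2(record: NucSequence, anchors: AnchorConfig) -> Its2Annotation:
    """Delimit the ITS2 as the interval between the annealed anchor halves.

    The leftmost occurrence of the 5.8S tail motif is taken; the nearest
    downstream occurrence of the 28S head motif whose annealing yields at
    least ``min_stem_len`` canonical pairs with at most ``max_mismatch``
    mismatches closes the stem.
    """
    seq = record.canonical()
    tail = anchors.motif_58s_tail.upper().replace("U", "T")
    head = anchors.motif_28s_head.upper().replace("U", "T")
    if len(record) <= len(tail) + len(head):
        raise DelimitationFailure(
            f"record {record.id!r} is shorter than the two anchor motifs"
        )
    tail_start = seq.find(tail)
    if tail_start < 0:
        raise DelimitationFailure(
            f"5.8S tail motif {anchors.motif_58s_tail!r} not found in {record.id!r}"
        )
    tail_end = tail_start + len(tail)

    search_from = tail_end
    while True:
        head_start = seq.find(head, search_from)
        if head_start < 0:
            raise DelimitationFailure(
                f"28S head motif {anchors.motif_28s_head!r} not found downstream "
                f"of the 5.8S tail in {record.id!r}"
            )
        pairs, mismatches = _anneal(tail, head)
        if len(pairs) >= anchors.min_stem_len and mismatches <= anchors.max_mismatch:
            break
        search_from = head_start + 1

    if head_start == tail_end:
        raise DegenerateIts2Error(
            f"anchors are directly adjacent in {record.id!r}: empty ITS2"
        )
    return Its2Annotation(
        source_id=record.id,
        its2_interval=(tail_end, head_start),
        stem_pairs=tuple(pairs),
        stem_mismatches=mismatches,
        tail_interval=(tail_start, tail_end),
        head_interval=(head_start, head_start + len(head)),
    )


# ---------------------------------------------------------------------------
# Secondary structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldParams:
    """Scoring model for the base-pair-maximisation fold."""

    gc_score: float = 3.0
    au_score: float = 2.0
    gu_score: float = 1.0
    stack_bonus: float = 1.0
    min_loop: int = 3
    require_motifs: bool = True

    def __post_init__(self):
        if not (self.gc_score >= self.au_score >= self.gu_score > 0):
            raise ValueError("pair scores must satisfy GC >= AU >= GU > 0")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def pair_score(self, x: str, y: str) -> float:
        if {x, y} == {"G", "C"}:
            return self.gc_score
        if {x, y} == {"A", "U"}:
            return self.au_score
        if {x, y} == {"G", "U"}:
            return self.gu_score
        raise ValueError(f"non-canonical pair {x}-{y}")


@dataclass(frozen=True)
class Helix:
    """One labeled arm (or the closing stem) of a structure.

    ``span`` covers the whole arm including its loops; ``five_range`` and
    ``three_range`` are the 5' and 3' paired strands.  All intervals are
    0-based half-open.
    """

    label: str
    five_range: tuple[int, int]
    three_range: tuple[int, int]
    span: tuple[int, int]


@dataclass(frozen=True)
class SecondaryStructure:
    """Sequence plus pairing map, helix segmentation and barcode interval."""

    sequence: str  # RNA alphabet
    pairing: tuple[Optional[int], ...]
    helices: tuple[Helix, ...] = ()
    barcode_interval: Optional[tuple[int, int]] = None
    motif_positions: dict = field(default_factory=dict, compare=False)
    is_four_helix_ring: Optional[bool] = None

    def __post_init__(self):
        if len(self.sequence) != len(self.pairing):
            raise ValueError("pairing map length differs from sequence length")
        for i, j in enumerate(self.pairing):
            if j is None:
                continue
            if self.pairing[j] != i:
                raise ValueError(f"pairing is not an involution at {i}->{j}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [
            (i, j) for i, j in enumerate(self.pairing) if j is not None and i < j
        ]

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairing):
            if j is None:
                out.append(".")
            elif j > i:
                out.append("(")
            else:
                out.append(")")
        return "".join(out)

    @classmethod
    def from_dot_bracket(cls, sequence: str, structure: str) -> "SecondaryStructure":
        seq = sequence.upper().replace("T", "U")
        if len(seq) != len(structure):
            raise ValueError("sequence and dot-bracket lengths differ")
        pairing: list[Optional[int]] = [None] * len(seq)
        stack: list[int] = []
        for i, ch in enumerate(structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                pairing[j], pairing[i] = i, j
            elif ch != ".":
                raise ValueError(f"unexpected character {ch!r} in dot-bracket")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(sequence=seq, pairing=tuple(pairing))

    def to_ct(self) -> str:
        """Connectivity-table text (1-based, RNAstructure dialect)."""
        lines = [f"{len(self)}\tstructure"]
        for i, base in enumerate(self.sequence):
            partner = self.pairing[i]
            lines.append(
                f"{i + 1}\t{base}\t{i}\t{i + 2 if i + 1 < len(self) else 0}"
                f"\t{(partner + 1) if partner is not None else 0}\t{i + 1}"
            )
        return "\n".join(lines) + "\n"

    def region_of(self, i: int) -> str:
        """Helix/stem label covering position ``i``, else ``'spacer'``."""
        for h in self.helices:
            if h.label == STEM_LABEL:
                if h.five_range[0] <= i < h.five_range[1]:
                    return h.label
                if h.three_range[0] <= i < h.three_range[1]:
                    return h.label
            elif h.span[0] <= i < h.span[1]:
                return f"helix {h.label}"
        return "spacer"

    def within_barcode(self, i: int) -> bool:
        if self.barcode_interval is None:
            raise AnnotationError("structure has no barcode annotation")
        lo, hi = self.barcode_interval
        return lo <= i < hi

    def helix(self, label: str) -> Optional[Helix]:
        for h in self.helices:
            if h.label == label:
                return h
        return None

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "dot_bracket": self.dot_bracket(),
            "helices": [
                {
                    "label": h.label,
                    "five_range": list(h.five_range),
                    "three_range": list(h.three_range),
                    "span": list(h.span),
                }
                for h in self.helices
            ],
            "barcode_interval": list(self.barcode_interval)
            if self.barcode_interval
            else None,
            "motif_positions": {
                k: list(v) for k, v in sorted(self.motif_positions.items())
            },
            "is_four_helix_ring": self.is_four_helix_ring,
        }


def score_structure(
    seq: str,
    pairs: Iterable[tuple[int, int]],
    params: FoldParams,
) -> float:
    """Score an explicit pair set under the weighted-stacking model."""
    rna = seq.upper().replace("T", "U")
    pair_set = {(min(i, j), max(i, j)) for i, j in pairs}
    total = 0.0
    for i, j in pair_set:
        total += params.pair_score(rna[i], rna[j])
        if (i + 1, j - 1) in pair_set:
            total += params.stack_bonus
    return total


# ---------------------------------------------------------------------------
# Constrained folding DP
# ---------------------------------------------------------------------------

def fold_constrained(
    its2_seq: str,
    params: FoldParams = FoldParams(),
    *,
    forced_unpaired: Sequence[int] = (),
    uu_mismatch: Optional[tuple[int, int]] = None,
) -> SecondaryStructure:
    """Maximum-score nested structure under the weighted-stacking model.

    When ``params.require_motifs`` is set, the leftmost GGUAG occurrence
    (the helix-III 5'-side motif) is held unpaired; a missing motif raises
    :class:`ConstraintViolationError`.  ``uu_mismatch`` designates the
    helix-II U/U opposition to keep as an internal-loop mismatch; both
    positions must hold U.  ``forced_unpaired`` adds arbitrary unpaired
    constraints.  The traceback is deterministic (5'-most pair first,
    nearest co-optimal partner, stacked continuation preferred).
    """
    rna = its2_seq.upper().replace("T", "U")
    n = len(rna)
    forced = set(forced_unpaired)
    motif_positions: dict[str, tuple[int, ...]] = {}

    if params.require_motifs:
        at = rna.find(GGUAG)
        if at < 0:
            raise ConstraintViolationError(
                "constraint failed: no GGUAG motif in sequence "
                "(helix-III 5'-side motif required)"
            )
        motif_positions["GGUAG"] = tuple(range(at, at + len(GGUAG)))
        forced.update(motif_positions["GGUAG"])
    if uu_mismatch is not None:
        a, b = uu_mismatch
        if rna[a] != "U" or rna[b] != "U":
            raise ConstraintViolationError(
                f"constraint failed: positions {a},{b} are "
                f"{rna[a]},{rna[b]}, not a U/U opposition"
            )
        motif_positions["UU"] = (a, b)
        forced.update((a, b))

    if n == 0:
        return SecondaryStructure(sequence=rna, pairing=())

    minloop = params.min_loop
    neg = float("-inf")
    # Pair-score matrix honouring constraints.
    S = np.full((n, n), neg)
    for i in range(n):
        if i in forced:
            continue
        for j in range(i + minloop + 1, n):
            if j in forced:
                continue
            if is_canonical(rna[i], rna[j]):
                S[i, j] = params.pair_score(rna[i], rna[j])

    P = np.full((n, n), neg)  # best score with (i, j) paired
    B = np.zeros((n + 1, n))  # best score on [i, j]; row n / i > j is 0

    for span in range(minloop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if S[i, j] > neg:
                inner_best = B[i + 1, j - 1] if i + 1 <= j - 1 else 0.0
                stacked = (
                    P[i + 1, j - 1] + params.stack_bonus
                    if i + 1 < j - 1 and P[i + 1, j - 1] > neg
                    else neg
                )
                P[i, j] = S[i, j] + max(inner_best, stacked)
            # B[i, j]
            cand = B[i + 1, j]
            ks = np.arange(i + minloop + 1, j + 1)
            if ks.size:
                tails = np.where(ks + 1 <= j, B[ks + 1, j], 0.0)
                with np.errstate(invalid="ignore"):
                    vals = P[i, ks] + tails
                best_k = vals.max(initial=neg)
                if best_k > cand:
                    cand = best_k
            B[i, j] = cand

    # Deterministic traceback (iterative to cope with deep nesting).
    pairing: list[Optional[int]] = [None] * n
    eps = 1e-9
    work: list[tuple[str, int, int]] = [("best", 0, n - 1)]
    while work:
        mode, i, j = work.pop()
        if i >= j:
            continue
        if mode == "best":
            target = B[i, j]
            if target <= eps:
                continue
            placed = False
            for k in range(i + minloop + 1, j + 1):
                if P[i, k] <= neg:
                    continue
                tail = B[k + 1, j] if k + 1 <= j else 0.0
                if abs(P[i, k] + tail - target) <= eps:
                    work.append(("best", k + 1, j))
                    work.append(("paired", i, k))
                    placed = True
                    break
            if not placed:
                work.append(("best", i + 1, j))
        else:  # paired
            pairing[i], pairing[j] = j, i
            inner_target = P[i, j] - S[i, j]
            if (
                i + 1 < j - 1
                and P[i + 1, j - 1] > neg
                and abs(P[i + 1, j - 1] + params.stack_bonus - inner_target) <= eps
            ):
                work.append(("paired", i + 1, j - 1))
            elif i + 1 <= j - 1:
                work.append(("best", i + 1, j - 1))

    return SecondaryStructure(
        sequence=rna,
        pairing=tuple(pairing),
        motif_positions=motif_positions,
    )


def brute_force_fold_score(
    seq: str,
    params: FoldParams,
    *,
    forced_unpaired: Sequence[int] = (),
) -> float:
    """Exhaustive-enumeration optimum score (oracle for small sequences).

    Enumerates every complete nested pair set directly -- independent of
    the DP recurrences -- and scores each with :func:`score_structure`.
    Intended for sequences up to ~18 nt.
    """
    rna = seq.upper().replace("T", "U")
    n = len(rna)
    forced = set(forced_unpaired)
    minloop = params.min_loop

    def structures(lo: int, hi: int):
        """Yield all nested pair sets on the half-open interval [lo, hi)."""
        if lo >= hi:
            yield []
            return
        # position lo unpaired
        for rest in structures(lo + 1, hi):
            yield rest
        if lo in forced:
            return
        for k in range(lo + minloop + 1, hi):
            if k in forced or not is_canonical(rna[lo], rna[k]):
                continue
            for inner in structures(lo + 1, k):
                for after in structures(k + 1, hi):
                    yield [(lo, k), *inner, *after]

    best = 0.0
    for pairs in structures(0, n):
        sc = score_structure(rna, pairs, params)
        if sc > best:
            best = sc
    return best


# ---------------------------------------------------------------------------
# Helix segmentation and barcode annotation
# ---------------------------------------------------------------------------

def _child_spans(pairing, lo: int, hi: int) -> list[tuple[int, int]]:
    """Top-level pair spans within the half-open interval [lo, hi)."""
    spans = []
    pos = lo
    while pos < hi:
        partner = pairing[pos]
        if partner is not None and partner > pos and partner < hi:
            spans.append((pos, partner))
            pos = partner + 1
        else:
            pos += 1
    return spans


def segment_helices(s: SecondaryStructure) -> SecondaryStructure:
    """Label ring helices I-IV and the closing 5.8S/LSU stem.

    Helix arms are the top-level stems radiating from the central
    (multibranch) loop, numbered with Roman numerals in 5'->3' order of
    their 5' strands.  When the fold was run on the full annotated
    region, the chain of pairs enclosing the ring (the anchors annealed
    against each other) is labeled as the hybrid stem.  A structure
    without exactly four ring arms is still labeled in order found, with
    ``is_four_helix_ring`` set false and a warning emitted.
    """
    import warnings

    n = len(s)
    roots = _child_spans(s.pairing, 0, n)
    stem: Optional[Helix] = None
    arms: list[tuple[int, int]] = []

    if not roots:
        return replace(s, helices=(), is_four_helix_ring=False)
    if len(roots) > 1:
        arms = roots
    else:
        # Descend the single enclosing chain until the loop branches.
        a0, b0 = roots[0]
        a, b = a0, b0
        while True:
            inner = _child_spans(s.pairing, a + 1, b)
            if len(inner) == 1:
                a, b = inner[0]
                continue
            if len(inner) == 0:
                # Plain hairpin: the "chain" is a single helix, no ring.
                arms = [(a0, b0)]
                break
            # Multibranch loop: chain above is the closing stem.
            stem = Helix(
                label=STEM_LABEL,
                five_range=(a0, a + 1),
                three_range=(b, b0 + 1),
                span=(a0, b0 + 1),
            )
            arms = inner
            break

    helices: list[Helix] = [stem] if stem else []
    for k, (p, q) in enumerate(sorted(arms)):
        five_side = [i for i in range(p, q + 1) if s.pairing[i] is not None and s.pairing[i] > i]
        three_side = [i for i in range(p, q + 1) if s.pairing[i] is not None and s.pairing[i] < i]
        label = _ROMAN[k] if k < len(_ROMAN) else str(k + 1)
        helices.append(
            Helix(
                label=label,
                five_range=(p, max(five_side) + 1),
                three_range=(min(three_side), q + 1),
                span=(p, q + 1),
            )
        )

    is_ring = len(arms) == 4
    if not is_ring:
        warnings.warn(
            f"expected a four-helix ring, found {len(arms)} arm(s); "
            "labels assigned in order found",
            stacklevel=2,
        )
    return replace(s, helices=tuple(helices), is_four_helix_ring=is_ring)


def annotate_barcode(
    s: SecondaryStructure,
    policy: str | tuple[int, int] = "default",
) -> SecondaryStructure:
    """Mark the barcode interval used for species discrimination.

    The default policy spans from the structure start (including any
    5.8S/LSU stem portion) through the 3' end of helix III, leaving
    helix IV and everything downstream outside.  An explicit
    ``(start, end)`` interval overrides the default exactly.
    """
    if isinstance(policy, tuple):
        lo, hi = policy
        if not (0 <= lo < hi <= len(s)):
            raise AnnotationError(f"barcode interval {policy} out of range")
        return replace(s, barcode_interval=(lo, hi))
    if policy != "default":
        raise AnnotationError(f"unknown barcode policy {policy!r}")
    if not s.helices:
        raise AnnotationError("structure has no labeled helices")
    helix_iii = s.helix("III")
    if helix_iii is None:
        raise AnnotationError("default barcode policy requires helix III")
    return replace(s, barcode_interval=(0, helix_iii.span[1]))
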