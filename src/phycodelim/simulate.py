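"""Synthetic data with known ground truth for every pipeline stage.

``gen_its2_family`` builds an rDNA-fragment-like reference record whose
spacer folds into the canonical ITS2 architecture -- a four-helix ring
closed by a 5.8S/28S hybrid stem, the GGUAG motif as a bulge on the 5'
side of helix III and a U/U mismatch inside helix II -- then derives
variants by planting compensatory (CBC), hemi-compensatory (hCBC),
substitution and deletion changes at known sites, logging each one.

Design rules that make truth replay unambiguous:

* helix strands are mismatch-free Watson-Crick duplexes sampled GC-rich;
  loops are poly-A and spacers/flanks are drawn from {A, C}, so outside
  the planted motifs no unpaired region can base-pair with another;
* planted CBCs draw the replacement uniformly from canonical pairs with
  both bases changed, hCBCs from canonical pairs with exactly one base
  changed;
* deletions are placed at spacer positions whose neighbours differ, so
  the optimal sequence alignment of reference and variant is unique;
* rejection sampling keeps GGUAG and the anchor motifs unique in every
  generated record.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compare import ColumnMapping, StructuralChange
from .errors import GenerationError
from .fatty_acids import FattyAcidMeasurement
from .its2 import (
    STEM_LABEL,
    AnchorConfig,
    Helix,
    SecondaryStructure,
    is_canonical,
)
from .seqio import Alignment, NucSequence

CANONICAL_ORDERED = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"))

#: Anchors used by generated families (never the biological defaults).
#: Pure G-C motifs: annealed they form an all-Watson-Crick stem, and the
#: A/C spacers flanking it cannot extend or re-register it.
GENERATOR_ANCHORS = AnchorConfig(
    motif_58s_tail="CGGCAGGCCGCG",
    motif_28s_head="CGCGGCCTGCCG",
    min_stem_len=6,
    max_mismatch=2,
)

PLANTABLE_KINDS = ("CBC", "hCBC", "substitution", "indel")


@dataclass(frozen=True)
class Its2FamilySpec:
    """Specification of a synthetic ITS2 homolog family.

    ``planted_changes`` holds one mapping per variant, keyed by change
    kind ("CBC", "hCBC", "substitution", "indel") with per-region counts,
    e.g. ``{"CBC": {"helix III": 1}, "substitution": {"spacer": 2}}``.
    """

    seed: int
    n_variants: int = 1
    helix_lengths: tuple[int, int, int, int] = (9, 9, 10, 8)
    loop_length: int = 4
    spacer_lengths: tuple[int, int, int, int, int] = (8, 8, 8, 8, 8)
    flank_lengths: tuple[int, int] = (12, 12)
    anchors: AnchorConfig = GENERATOR_ANCHORS
    planted_changes: tuple[Mapping[str, Mapping[str, int]], ...] = ()

    def __post_init__(self):
        if self.n_variants < 0:
            raise GenerationError("n_variants must be >= 0")
        if any(h < 4 for h in self.helix_lengths):
            raise GenerationError("helix stems need >= 4 base pairs")
        if self.loop_length < 3:
            raise GenerationError("hairpin loops need >= 3 bases")
        if self.planted_changes and len(self.planted_changes) != self.n_variants:
            raise GenerationError(
                "planted_changes must list one change map per variant"
            )
        for per_variant in self.planted_changes:
            for kind, regions in per_variant.items():
                if kind not in PLANTABLE_KINDS:
                    raise GenerationError(f"unknown change kind {kind!r}")
                if any(c < 0 for c in regions.values()):
                    raise GenerationError("change counts must be non-negative")


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one generated variant."""

    record: NucSequence
    structure: SecondaryStructure  # over the stem+ITS2 domain, annotated
    its2_interval: tuple[int, int]  # on the record
    domain_interval: tuple[int, int]  # stem+ITS2+stem on the record
    mapping: ColumnMapping  # reference domain <-> variant domain
    changes: tuple[StructuralChange, ...]


@dataclass(frozen=True)
class TruthLog:
    reference_record: NucSequence
    reference_structure: SecondaryStructure
    reference_its2_interval: tuple[int, int]
    reference_domain_interval: tuple[int, int]
    uu_mismatch_positions: tuple[int, int]  # domain coordinates
    gguag_positions: tuple[int, ...]  # domain coordinates
    variants: tuple[VariantTruth, ...]

    def replay(self, idx: int) -> str:
        """Re-apply the logged changes to the reference domain sequence.

        Returns the reconstructed variant domain (RNA); equality with the
        stored variant is the log-consistency invariant.
        """
        chars: list[Optional[str]] = list(self.reference_structure.sequence)
        for change in self.variants[idx].changes:
            if change.kind in {"CBC", "hCBC"}:
                i, j = change.positions
                x, y = change.after.split("-")
                chars[i], chars[j] = x, y
            elif change.kind == "deletion":
                chars[change.positions[0]] = None
            else:  # substitution kinds
                chars[change.positions[0]] = change.after
        return "".join(c for c in chars if c is not None)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _sample_duplex(rng: np.random.Generator, n_pairs: int) -> tuple[str, str]:
    """A mismatch-free 5' strand and its reverse complement, GC-rich.

    Mixed composition keeps the pair-score spectrum (GC > AU) informative
    so alternative registrations of a helix are generically suboptimal.
    """
    pairs = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
    idx = rng.choice(len(pairs), size=n_pairs, p=[0.35, 0.35, 0.15, 0.15])
    five = "".join(pairs[i][0] for i in idx)
    three = "".join(pairs[i][1] for i in reversed(idx))
    return five, three


def _sample_ac(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C"], size=n))


def _build_reference(spec: Its2FamilySpec, rng: np.random.Generator):
    """Assemble the domain (stem+ITS2+stem) with full positional truth.

    Returns (domain_chars, pairing, region_labels, helices, gguag, uu).
    """
    tail = spec.anchors.motif_58s_tail.upper().replace("T", "U")
    head = spec.anchors.motif_28s_head.upper().replace("T", "U")
    loop = "A" * spec.loop_length

    for _attempt in range(200):
        segments: list[tuple[str, str]] = []  # (region label, fragment)
        segments.append((STEM_LABEL, tail))
        segments.append(("spacer", _sample_ac(rng, spec.spacer_lengths[0])))

        arm_meta: list[dict] = []
        for h, label in enumerate(("helix I", "helix II", "helix III", "helix IV")):
            n_pairs = spec.helix_lengths[h]
            meta: dict = {"label": label}
            if label == "helix II":
                a = n_pairs // 2
                f1, r1 = _sample_duplex(rng, a)
                f2, r2 = _sample_duplex(rng, n_pairs - a)
                arm = f1 + "U" + f2 + loop + r2 + "U" + r1
                meta["uu_offsets"] = (len(f1), len(f1) + 1 + len(f2) + len(loop) + len(r2))
                meta["layout"] = (len(f1), 1, len(f2), len(loop), len(r2), 1, len(r1))
            elif label == "helix III":
                outer = max(4, n_pairs // 2)
                g1, rg1 = _sample_duplex(rng, outer)
                g2, rg2 = _sample_duplex(rng, n_pairs - outer)
                arm = g1 + "GGUAG" + g2 + loop + rg2 + rg1
                meta["gguag_offset"] = len(g1)
                meta["layout"] = (len(g1), 5, len(g2), len(loop), len(rg2), 0, len(rg1))
            else:
                five, three = _sample_duplex(rng, n_pairs)
                arm = five + loop + three
                meta["layout"] = (n_pairs, 0, 0, len(loop), n_pairs, 0, 0)
            meta["arm"] = arm
            arm_meta.append(meta)
            segments.append((label, arm))
            segments.append(("spacer", _sample_ac(rng, spec.spacer_lengths[h + 1])))

        segments.append((STEM_LABEL, head))
        domain = "".join(frag for _, frag in segments)
        # Motif uniqueness: exactly one GGUAG, anchors occur exactly once.
        dna = domain.replace("U", "T")
        if domain.count("GGUAG") != 1:
            continue
        if dna.count(spec.anchors.motif_58s_tail.upper()) != 1:
            continue
        if dna.count(spec.anchors.motif_28s_head.upper()) != 1:
            continue
        break
    else:
        raise GenerationError("could not build a reference satisfying motif uniqueness")

    # Positional truth.
    n = len(domain)
    region = []
    for label, frag in segments:
        region.extend([label] * len(frag))
    pairing: list[Optional[int]] = [None] * n

    # Hybrid stem: full reverse-complement annealing of tail vs head.
    head_start = n - len(head)
    for t in range(min(len(tail), len(head))):
        i = len(tail) - 1 - t
        j = head_start + t
        if is_canonical(domain[i], domain[j]):
            pairing[i], pairing[j] = j, i

    helices: list[Helix] = [
        Helix(
            label=STEM_LABEL,
            five_range=(0, len(tail)),
            three_range=(head_start, n),
            span=(0, n),
        )
    ]
    gguag_positions: tuple[int, ...] = ()
    uu_positions: tuple[int, int] = (0, 0)

    offset = 0
    seg_iter = iter(segments)
    arm_idx = 0
    for label, frag in segments:
        if label.startswith("helix"):
            meta = arm_meta[arm_idx]
            arm_idx += 1
            l5a, mid5, l5b, lloop, l3a, mid3, l3b = meta["layout"]
            start = offset
            # 5' paired run(s)
            p5 = list(range(start, start + l5a)) + list(
                range(start + l5a + mid5, start + l5a + mid5 + l5b)
            )
            t3_start = start + l5a + mid5 + l5b + lloop
            p3 = list(range(t3_start, t3_start + l3a)) + list(
                range(t3_start + l3a + mid3, t3_start + l3a + mid3 + l3b)
            )
            assert len(p5) == len(p3)
            for a_pos, b_pos in zip(p5, reversed(p3)):
                pairing[a_pos], pairing[b_pos] = b_pos, a_pos
            helices.append(
                Helix(
                    label=label.split()[-1],
                    five_range=(start, start + l5a + mid5 + l5b),
                    three_range=(t3_start, start + len(frag)),
                    span=(start, start + len(frag)),
                )
            )
            if "gguag_offset" in meta:
                at = start + meta["gguag_offset"]
                gguag_positions = tuple(range(at, at + 5))
            if "uu_offsets" in meta:
                u1, u2 = meta["uu_offsets"]
                uu_positions = (start + u1, start + u2)
        offset += len(frag)
    del seg_iter

    return domain, tuple(pairing), region, tuple(helices), gguag_positions, uu_positions


def _annotate(domain: str, pairing, helices) -> SecondaryStructure:
    helix_iii = next(h for h in helices if h.label == "III")
    return SecondaryStructure(
        sequence=domain,
        pairing=tuple(pairing),
        helices=tuple(helices),
        barcode_interval=(0, helix_iii.span[1]),
        is_four_helix_ring=True,
    )


# ---------------------------------------------------------------------------
# Variant derivation
# ---------------------------------------------------------------------------

def _substitution_kind(x: str, y: str) -> str:
    purines = {"A", "G"}
    return (
        "transition"
        if (x in purines) == (y in purines)
        else "transversion"
    )


def _eligible_pairs(structure: SecondaryStructure, region: str) -> list[tuple[int, int]]:
    wanted = region if region == STEM_LABEL else region
    out = []
    for i, j in structure.pairs:
        if structure.region_of(i) == wanted:
            out.append((i, j))
    return out


def _plant_variant(
    ref_struct: SecondaryStructure,
    change_map: Mapping[str, Mapping[str, int]],
    protected: set[int],
    rng: np.random.Generator,
):
    """Apply one variant's planted changes to the reference domain.

    Returns (variant_chars_with_None_for_deleted, changes) in reference
    coordinates; the caller compacts deletions and shifts the truth.
    """
    chars: list[Optional[str]] = list(ref_struct.sequence)
    used: set[int] = set()
    changes: list[StructuralChange] = []

    def barcode(i: int) -> bool:
        return ref_struct.within_barcode(i)

    def clear_of_used(*positions: int) -> bool:
        # Changes keep >= 3 positions apart so mismatch columns never
        # cluster enough to divert the optimal sequence alignment.
        return all(abs(p - u) > 2 for p in positions for u in used)

    # Pair-level changes first so they cannot collide with substitutions.
    for kind in ("CBC", "hCBC"):
        for region, count in sorted(change_map.get(kind, {}).items()):
            for _ in range(count):
                pool = [
                    (i, j)
                    for (i, j) in _eligible_pairs(ref_struct, region)
                    if region != STEM_LABEL
                    and i not in protected
                    and j not in protected
                    and clear_of_used(i, j)
                ]
                if not pool:
                    raise GenerationError(
                        f"{kind} changes requested in {region!r} exceed the "
                        "well-separated eligible pairs"
                    )
                i, j = pool[int(rng.integers(len(pool)))]
                old = (chars[i], chars[j])
                if kind == "CBC":
                    candidates = [
                        pq
                        for pq in CANONICAL_ORDERED
                        if pq[0] != old[0] and pq[1] != old[1]
                    ]
                else:
                    candidates = [
                        pq
                        for pq in CANONICAL_ORDERED
                        if (pq[0] != old[0]) + (pq[1] != old[1]) == 1
                    ]
                if not candidates:
                    raise GenerationError(
                        f"no {kind} replacement exists for pair {old[0]}-{old[1]}"
                    )
                new = candidates[int(rng.integers(len(candidates)))]
                chars[i], chars[j] = new
                used.update((i, j))
                changes.append(
                    StructuralChange(
                        kind=kind,
                        positions=(i, j),
                        before=f"{old[0]}-{old[1]}",
                        after=f"{new[0]}-{new[1]}",
                        region=region,
                        within_barcode=barcode(i),
                    )
                )

    unpaired = [
        i
        for i in range(len(ref_struct))
        if ref_struct.pairing[i] is None and i not in protected
    ]
    # Changes at unpaired sites keep >= 3 positions apart so a planted
    # deletion can never trade places with a neighbouring substitution in
    # the optimal alignment (gap placement stays unique).
    unpaired_used: list[int] = []

    def well_separated(i: int) -> bool:
        # Keep clear of every prior change (pair-level ones included): a
        # mutated neighbourhood can otherwise make gap placement ambiguous.
        return all(abs(i - u) > 2 for u in used) and all(
            abs(i - u) > 2 for u in unpaired_used
        )

    for region, count in sorted(change_map.get("substitution", {}).items()):
        for _ in range(count):
            pool = [
                i
                for i in unpaired
                if ref_struct.region_of(i) == region
                and i not in used
                and well_separated(i)
            ]
            if not pool:
                raise GenerationError(
                    f"substitutions requested in {region!r} exceed the "
                    "well-separated eligible sites"
                )
            i = pool[int(rng.integers(len(pool)))]
            old = chars[i]
            options = [b for b in "ACGU" if b != old]
            options = [options[k] for k in rng.permutation(len(options))]
            for new in options:
                trial = chars[:]
                trial[i] = new
                window = "".join(
                    c for c in trial[max(0, i - 4) : i + 5] if c is not None
                )
                if "GGUAG" not in window:
                    break
            else:  # pragma: no cover - {A,C,G,U} always offers a safe base
                raise GenerationError("no safe substitution base found")
            chars[i] = new
            used.add(i)
            unpaired_used.append(i)
            changes.append(
                StructuralChange(
                    kind=_substitution_kind(old, new),
                    positions=(i,),
                    before=old,
                    after=new,
                    region=region,
                    within_barcode=barcode(i),
                )
            )

    for region, count in sorted(change_map.get("indel", {}).items()):
        for _ in range(count):
            pool = [
                i
                for i in unpaired
                if ref_struct.region_of(i) == region
                and i not in used
                and well_separated(i)
                and 0 < i < len(ref_struct) - 1
                and chars[i - 1] != chars[i]
                and chars[i + 1] != chars[i]
            ]
            if not pool:
                raise GenerationError(
                    f"deletions requested in {region!r} exceed the "
                    "well-separated eligible sites"
                )
            i = pool[int(rng.integers(len(pool)))]
            used.add(i)
            unpaired_used.append(i)
            changes.append(
                StructuralChange(
                    kind="deletion",
                    positions=(i,),
                    before=ref_struct.sequence[i],
                    after="-",
                    region=region,
                    within_barcode=barcode(i),
                )
            )
            chars[i] = None

    changes.sort(key=lambda c: c.positions[0])
    return chars, tuple(changes)


def gen_its2_family(spec: Its2FamilySpec) -> tuple[list[NucSequence], TruthLog]:
    """Generate a reference record plus variants with planted changes.

    Records are DNA FASTA-style sequences (flank + 5.8S tail + ITS2 +
    28S head + flank); structures in the truth log are RNA over the
    stem+ITS2 domain with helices labeled and the barcode annotated.
    Deterministic given ``spec`` (byte-identical output per seed).
    """
    rng = np.random.default_rng(spec.seed)
    domain, pairing, _region, helices, gguag, uu = _build_reference(spec, rng)
    ref_struct = _annotate(domain, pairing, helices)

    flank5 = _sample_ac(rng, spec.flank_lengths[0])
    flank3 = _sample_ac(rng, spec.flank_lengths[1])
    tail_len = len(spec.anchors.motif_58s_tail)
    head_len = len(spec.anchors.motif_28s_head)

    def to_record(name: str, domain_rna: str) -> NucSequence:
        return NucSequence(
            id=name,
            residues=(flank5 + domain_rna + flank3).replace("U", "T"),
            is_rna=False,
        )

    ref_record = to_record("ref", domain)
    n5 = len(flank5)
    ref_its2 = (n5 + tail_len, n5 + len(domain) - head_len)
    protected = set(gguag) | set(uu)
    # Anchor motifs must stay intact for delimitation.
    protected.update(range(0, tail_len))
    protected.update(range(len(domain) - head_len, len(domain)))

    records = [ref_record]
    variants: list[VariantTruth] = []
    change_maps = spec.planted_changes or tuple({} for _ in range(spec.n_variants))
    for v in range(spec.n_variants):
        chars, changes = _plant_variant(ref_struct, change_maps[v], protected, rng)
        keep = [i for i, c in enumerate(chars) if c is not None]
        new_index = {old: new for new, old in enumerate(keep)}
        var_domain = "".join(chars[i] for i in keep)
        var_pairing: list[Optional[int]] = [None] * len(keep)
        for old_i in keep:
            partner = ref_struct.pairing[old_i]
            if partner is not None:
                var_pairing[new_index[old_i]] = new_index[partner]

        def shift(interval: tuple[int, int]) -> tuple[int, int]:
            lo, hi = interval
            lo_new = new_index.get(lo, len([k for k in keep if k < lo]))
            hi_new = len([k for k in keep if k < hi])
            return (lo_new, hi_new)

        var_helices = tuple(
            Helix(
                label=h.label,
                five_range=shift(h.five_range),
                three_range=shift(h.three_range),
                span=shift(h.span),
            )
            for h in ref_struct.helices
        )
        helix_iii_end = next(h for h in var_helices if h.label == "III").span[1]
        var_struct = SecondaryStructure(
            sequence=var_domain,
            pairing=tuple(var_pairing),
            helices=var_helices,
            barcode_interval=(0, helix_iii_end),
            is_four_helix_ring=True,
        )
        mapping = ColumnMapping(
            tuple(
                (i, new_index.get(i)) for i in range(len(domain))
            )
        )
        name = f"var{v + 1}"
        records.append(to_record(name, var_domain))
        variants.append(
            VariantTruth(
                record=records[-1],
                structure=var_struct,
                its2_interval=(n5 + tail_len, n5 + len(var_domain) - head_len),
                domain_interval=(n5, n5 + len(var_domain)),
                mapping=mapping,
                changes=changes,
            )
        )

    truth = TruthLog(
        reference_record=ref_record,
        reference_structure=ref_struct,
        reference_its2_interval=ref_its2,
        reference_domain_interval=(n5, n5 + len(domain)),
        uu_mismatch_positions=uu,
        gguag_positions=gguag,
        variants=tuple(variants),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Alignments with known p-distances
# ---------------------------------------------------------------------------

def gen_alignment(
    n: int, length: int, target_p: float, seed: int
) -> tuple[Alignment, np.ndarray]:
    """Alignment whose pairwise differences are planted by construction.

    Every pair of rows differs at ``d = round(target_p * length)``
    unambiguous columns when an equidistant construction exists (disjoint
    per-row blocks for even ``d`` with ``n * d / 2 <= length``, or a
    cyclic per-column rotation exact for ``n <= 4``); the returned truth
    table of pairwise *p* values is computed by direct column counting at
    construction time and is always exact.
    """
    if length <= 0:
        raise GenerationError("alignment length must be positive")
    if not 0.0 <= target_p <= 1.0:
        raise GenerationError("target_p must be within [0, 1]")
    if n < 2:
        raise GenerationError("need at least two rows")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    base_row = rng.integers(0, 4, size=length)
    d = round(target_p * length)
    rows = np.tile(base_row, (n, 1))

    if d > 0:
        if d % 2 == 0 and n * (d // 2) <= length:
            block_cols = rng.permutation(length)[: n * (d // 2)]
            half = d // 2
            for r in range(n):
                own = block_cols[r * half : (r + 1) * half]
                rows[r, own] = (rows[r, own] + 1 + rng.integers(0, 3, size=half)) % 4
        else:
            cols = rng.permutation(length)[:d]
            for r in range(n):
                rows[r, cols] = (base_row[cols] + r) % 4

    seqs = tuple(
        NucSequence(id=f"s{r}", residues="".join(bases[rows[r]]))
        for r in range(n)
    )
    truth = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(rows[i] != rows[j]))
            truth[i, j] = truth[j, i] = p
    return Alignment(rows=seqs), truth


# ---------------------------------------------------------------------------
# Fatty-acid replicate tables
# ---------------------------------------------------------------------------

def gen_fa_replicates(
    summary: Sequence[FattyAcidMeasurement],
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-replicate values behind a mean +/- SE table.

    Each measurement yields ``n_reps`` normal draws with the printed mean
    and SD = SE * sqrt(n_reps) (the SE of a mean of ``n_reps``
    replicates).  SE = 0 gives identical replicates.
    """
    if n_reps < 2:
        raise GenerationError("need at least two replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for m in summary:
        if m.se < 0:
            raise GenerationError(f"negative SE for {m.fa.shorthand()} in {m.strain}")
        sd = m.se * np.sqrt(n_reps)
        draws = m.mean + sd * rng.standard_normal(n_reps)
        for r, value in enumerate(draws, start=1):
            rows.append(
                {
                    "strain": m.strain,
                    "fatty_acid": m.fa.shorthand(),
                    "replicate": r,
                    "value": float(value),
                    "unit": m.unit,
                }
            )
    return pd.DataFrame(rows)
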