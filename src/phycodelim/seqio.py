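"""Sequence records, FASTA I/O and p-distance similarity matrices.

Sequence similarity between rDNA fragments is reported throughout as
``(1 - p) x 100`` where *p* is the proportion of differing sites among
compared alignment columns.  Columns holding a gap or an IUPAC ambiguity
code in either row are excluded under pairwise deletion (the default);
complete deletion removes such columns across the whole alignment first.
T and U are treated as identical and comparison is case-insensitive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DuplicateIdError, FastaParseError, UndefinedDistanceError

#: Unambiguous residues compared by p-distance (U is canonicalised to T).
UNAMBIGUOUS = frozenset("ACGT")

#: Every residue accepted in a sequence record.
IUPAC_RESIDUES = frozenset("ACGTUNRYSWKMBDHV-")

GAP = "-"


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence (DNA or RNA, optionally aligned)."""

    id: str
    residues: str
    is_rna: bool = False

    def __post_init__(self):
        if not self.residues:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues.upper()) - IUPAC_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def canonical(self) -> str:
        """Upper-case residues with U mapped to T (comparison alphabet)."""
        return self.residues.upper().replace("U", "T")

    def as_rna(self) -> str:
        return self.residues.upper().replace("T", "U")


@dataclass(frozen=True)
class Alignment:
    """Equal-length rows of aligned sequences."""

    rows: tuple[NucSequence, ...]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate row ids in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SimilarityMatrix:
    """Pairwise ``(1 - p) x 100`` similarity values.

    ``values`` keeps full precision; rounding to one decimal happens only
    when writing CSV/TSV.  Cells whose pair had no comparable columns are
    NaN and flagged in ``undefined_pairs``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    n_sites_used: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", *self.ids])
            for i, name in enumerate(self.ids):
                cells = [
                    "NA" if np.isnan(v) else f"{v:.1f}" for v in self.values[i]
                ]
                writer.writerow([name, *cells])

    def to_long_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["id_i", "id_j", "similarity", "n_sites"])
            for i in range(len(self.ids)):
                for j in range(i + 1, len(self.ids)):
                    v = self.values[i, j]
                    writer.writerow(
                        [
                            self.ids[i],
                            self.ids[j],
                            "NA" if np.isnan(v) else f"{v:.1f}",
                            int(self.n_sites_used[i, j]),
                        ]
                    )


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _first_offending_line(path: Path) -> tuple[str, int] | None:
    """Locate the first non-IUPAC character in a FASTA body line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith((">", ";")):
                continue
            bad = set(stripped.upper()) - IUPAC_RESIDUES
            if bad:
                return sorted(bad)[0], lineno
    return None


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a multi-record FASTA file into :class:`NucSequence` records.

    Order is preserved and residues are upper-cased; a record is flagged
    ``is_rna`` when it contains U and no T.  Empty files, duplicate ids and
    non-IUPAC characters raise named parse errors identifying the line
    where possible.
    """
    path = Path(path)
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FastaParseError(f"{path} contains no FASTA records", line=1)
    seen: set[str] = set()
    out: list[NucSequence] = []
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - IUPAC_RESIDUES
        if bad:
            where = _first_offending_line(path)
            raise FastaParseError(
                f"record {rec.id!r} contains non-IUPAC character {sorted(bad)[0]!r}",
                line=where[1] if where else None,
            )
        if not residues:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence")
        is_rna = "U" in residues and "T" not in residues
        out.append(NucSequence(id=rec.id, residues=residues, is_rna=is_rna))
    return out


def write_fasta(records: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# p-distance and similarity
# ---------------------------------------------------------------------------

def _comparable_mask(a: str, b: str) -> list[bool]:
    return [x in UNAMBIGUOUS and y in UNAMBIGUOUS for x, y in zip(a, b)]


def p_distance(
    a: NucSequence,
    b: NucSequence,
    *,
    column_mask: Sequence[bool] | None = None,
) -> tuple[float, int]:
    """Proportion of differing sites among compared columns.

    Under pairwise deletion (default) a column is compared only when both
    residues are unambiguous non-gaps.  ``column_mask`` restricts the
    comparison to pre-selected columns (used for complete deletion, where
    the mask is shared across all pairs of the alignment).

    Returns ``(p, n_sites_used)``; raises :class:`UndefinedDistanceError`
    when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences {a.id!r}/{b.id!r} have unequal lengths")
    ca, cb = a.canonical(), b.canonical()
    mask = _comparable_mask(ca, cb)
    if column_mask is not None:
        if len(column_mask) != len(mask):
            raise ValueError("column mask length mismatch")
        mask = [m and cm for m, cm in zip(mask, column_mask)]
    n = sum(mask)
    if n == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {a.id!r} and {b.id!r}"
        )
    diffs = sum(1 for x, y, m in zip(ca, cb, mask) if m and x != y)
    return diffs / n, n


def complete_deletion_mask(aln: Alignment) -> list[bool]:
    """Columns where every row holds an unambiguous non-gap residue."""
    rows = [r.canonical() for r in aln.rows]
    return [all(row[c] in UNAMBIGUOUS for row in rows) for c in range(aln.length)]


def similarity_matrix(aln: Alignment, gap_policy: str = "pairwise") -> SimilarityMatrix:
    """Square matrix of ``(1 - p) x 100`` similarities.

    ``gap_policy`` is ``"pairwise"`` (exclude gap/ambiguity columns per
    pair) or ``"complete"`` (exclude them across the whole alignment).
    Pairs with zero comparable columns become NaN cells flagged in
    ``undefined_pairs`` rather than aborting the whole matrix.
    """
    if len(aln) < 2:
        raise ValueError("similarity matrix needs at least two rows")
    if gap_policy not in {"pairwise", "complete"}:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    mask = complete_deletion_mask(aln) if gap_policy == "complete" else None
    n = len(aln)
    values = np.full((n, n), 100.0)
    sites = np.zeros((n, n), dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        sites[i, i] = aln.length
        for j in range(i + 1, n):
            try:
                p, used = p_distance(aln.rows[i], aln.rows[j], column_mask=mask)
                values[i, j] = values[j, i] = (1.0 - p) * 100.0
                sites[i, j] = sites[j, i] = used
            except UndefinedDistanceError:
                values[i, j] = values[j, i] = np.nan
                undefined.append((aln.rows[i].id, aln.rows[j].id))
    return SimilarityMatrix(
        ids=tuple(r.id for r in aln.rows),
        values=values,
        n_sites_used=sites,
        undefined_pairs=undefined,
    )
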