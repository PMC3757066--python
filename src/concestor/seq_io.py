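"""Aligned-FASTA I/O and alignment/ungapped coordinate bookkeeping.

Every downstream analysis consumes a :class:`GappedAlignment` — an ordered,
validated collection of equal-length rows over ``{A, C, G, T, -}`` — and a
:class:`CoordinateMap` that translates between alignment columns and ungapped
sequence positions.  All coordinates are 0-based; intervals are half-open
(BED convention).  ``-`` is the only accepted gap character and IUPAC
ambiguity codes are rejected on input rather than silently mapped.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

GAP = "-"
DNA_ALPHABET = frozenset("ACGT")
ROW_ALPHABET = DNA_ALPHABET | {GAP}


class AlignmentError(ValueError):
    """Raised for structurally invalid alignments (ragged rows, all-gap columns)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,-}."""


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped DNA sequence with a unique identifier.

    Parameters
    ----------
    id : str
        Non-empty label, e.g. ``mel.14.1`` for a population allele.
    residues : str
        Uppercase string over ``{A, C, G, T}``, length >= 1.
    description : str, optional
        Free-text provenance (e.g. construct recipe), written to FASTA headers.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id}: illegal characters {sorted(bad)!r}; expected A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between a record's ungapped positions and its non-gap columns.

    ``columns[p]`` is the alignment column holding ungapped position ``p``.
    The sequence is strictly increasing, so lookups in either direction are
    binary searches.
    """

    seq_id: str
    columns: tuple[int, ...]
    n_cols: int

    @classmethod
    def from_row(cls, seq_id: str, row: str) -> "CoordinateMap":
        cols = tuple(i for i, ch in enumerate(row) if ch != GAP)
        return cls(seq_id=seq_id, columns=cols, n_cols=len(row))

    @property
    def ungapped_length(self) -> int:
        return len(self.columns)

    def position_to_column(self, pos: int) -> int:
        if not 0 <= pos < len(self.columns):
            raise IndexError(f"{self.seq_id}: position {pos} out of range")
        return self.columns[pos]

    def column_to_position(self, col: int) -> int | None:
        """Ungapped position at ``col``, or ``None`` if the row is gapped there."""
        if not 0 <= col < self.n_cols:
            raise IndexError(f"{self.seq_id}: column {col} out of range")
        i = bisect.bisect_left(self.columns, col)
        if i < len(self.columns) and self.columns[i] == col:
            return i
        return None

    def positions_before(self, col: int) -> int:
        """Number of non-gap characters strictly before alignment column ``col``."""
        if not 0 <= col <= self.n_cols:
            raise IndexError(f"{self.seq_id}: column {col} out of range")
        return bisect.bisect_left(self.columns, col)

    def span_to_positions(self, col_start: int, col_end: int) -> tuple[int, int]:
        """Map a half-open column span to the half-open ungapped position span."""
        if col_start > col_end:
            raise ValueError("col_start must be <= col_end")
        return self.positions_before(col_start), self.positions_before(col_end)


class GappedAlignment:
    """An ordered multiple alignment over ``{A, C, G, T, -}``.

    Invariants enforced at construction: all rows equal length, uppercase,
    alphabet-clean, unique non-empty ids, and no all-gap column.
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        recs = [(str(i), str(r)) for i, r in records]
        if not recs:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r) for _, r in recs}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        (self._n_cols,) = lengths
        if self._n_cols == 0:
            raise AlignmentError("alignment has zero columns")
        ids = [i for i, _ in recs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dupes}")
        if any(not i for i in ids):
            raise AlignmentError("record ids must be non-empty")
        for rid, row in recs:
            bad = set(row) - ROW_ALPHABET
            if bad:
                raise AlphabetError(
                    f"{rid}: illegal characters {sorted(bad)!r}; "
                    "only A/C/G/T/- are accepted ('.' and IUPAC codes are rejected)"
                )
        for c in range(self._n_cols):
            if all(row[c] == GAP for _, row in recs):
                raise AlignmentError(f"column {c} is all-gap")
        self._records = recs
        self._index = {rid: k for k, (rid, _) in enumerate(recs)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GappedAlignment) and self._records == other._records

    @property
    def n_cols(self) -> int:
        return self._n_cols

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self._records]

    def row(self, seq_id: str) -> str:
        try:
            return self._records[self._index[seq_id]][1]
        except KeyError:
            raise KeyError(f"unknown record id {seq_id!r}") from None

    def ungapped(self, seq_id: str) -> SequenceRecord:
        return SequenceRecord(id=seq_id, residues=self.row(seq_id).replace(GAP, ""))

    def coordinate_map(self, seq_id: str) -> CoordinateMap:
        return CoordinateMap.from_row(seq_id, self.row(seq_id))

    def column(self, col: int) -> list[str]:
        if not 0 <= col < self._n_cols:
            raise IndexError(f"column {col} out of range")
        return [row[col] for _, row in self._records]


def column_to_position(aln: GappedAlignment, seq_id: str, col: int) -> int | None:
    """Ungapped position of ``col`` in ``seq_id``'s row, or ``None`` at a gap.

    The position counts non-gap characters strictly before ``col``.
    """
    return aln.coordinate_map(seq_id).column_to_position(col)


def _clean(seq_id: str, raw: str, *, gapped: bool) -> str:
    s = str(raw)
    if s != s.upper():
        warnings.warn(f"{seq_id}: lowercase residues uppercased on read", stacklevel=3)
        s = s.upper()
    if "." in s:
        raise AlphabetError(f"{seq_id}: '.' gap characters are rejected; use '-'")
    allowed = ROW_ALPHABET if gapped else DNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(f"{seq_id}: illegal characters {sorted(bad)!r}")
    return s


def read_alignment(path: str | Path) -> GappedAlignment:
    """Read an aligned FASTA file into a validated :class:`GappedAlignment`.

    Record order is preserved.  Lowercase input is uppercased with a warning;
    ragged rows, ``.`` gaps and ambiguity codes raise.
    """
    records = [
        (rec.id, _clean(rec.id, rec.seq, gapped=True))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    return GappedAlignment(records)


def write_alignment(aln: GappedAlignment, path: str | Path) -> None:
    """Write an alignment as gapped FASTA (round-trips with read_alignment)."""
    recs = [_BioRecord(Seq(row), id=rid, description="") for rid, row in aln]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped FASTA records (gaps are an error here)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SequenceRecord(rec.id, _clean(rec.id, rec.seq, gapped=False)))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    recs = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(intervals: Iterable[tuple[str, int, int, str, int, str]], path: str | Path) -> None:
    """Write BED6 lines: (chrom, start, end, name, score, strand), 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
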