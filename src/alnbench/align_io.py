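"""Alignment data model and I/O for aligned FASTA and TSV annotation files.

Conventions
-----------
All in-memory coordinates are 0-based, half-open ``[start, stop)``.
All on-disk formats (FASTA headers aside) use 1-based inclusive
coordinates; every TSV written by this module carries a comment line
stating that convention.

Residues are upper-cased on input; ``.`` is normalised to the gap
character ``-``; any symbol outside the 20-letter amino-acid alphabet
is mapped to ``X``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
_VALID = set(ALPHABET)

COORD_COMMENT = "# coordinates: 1-based, inclusive"


class AlignmentFormatError(ValueError):
    """Raised when an on-disk alignment or annotation file is malformed."""


def _normalise(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == "." or ch == GAP:
            out.append(GAP)
        elif ch in _VALID:
            out.append(ch)
        else:
            out.append("X")
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment over a shared column axis.

    ``ids`` and ``seqs`` are parallel tuples; every sequence has the same
    length (the number of columns) and may contain the gap character.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must be parallel")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence id(s): {dupes}")
        if any(not i for i in self.ids):
            raise AlignmentFormatError("empty sequence id")
        if self.seqs:
            n = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != n:
                    raise AlignmentFormatError(
                        f"record '{sid}' has length {len(s)}, expected {n}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row_index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id '{seq_id}'") from None

    def row(self, seq_id: str) -> str:
        return self.seqs[self.row_index(seq_id)]

    def column(self, col: int) -> tuple[str, ...]:
        if not 0 <= col < self.n_cols:
            raise IndexError(f"column {col} out of range [0, {self.n_cols})")
        return tuple(s[col] for s in self.seqs)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def ungapped_length(self, seq_id: str) -> int:
        return len(self.ungapped(seq_id))

    # -- sub-alignments -------------------------------------------------
    def take_rows(self, keep_ids: Iterable[str]) -> "Alignment":
        """Row subset in the order given; all columns kept."""
        keep = list(keep_ids)
        rows = {i: s for i, s in zip(self.ids, self.seqs)}
        return Alignment(tuple(keep), tuple(rows[i] for i in keep))

    def take_cols(self, start: int, stop: int) -> "Alignment":
        return Alignment(self.ids, tuple(s[start:stop] for s in self.seqs))

    def drop_allgap_columns(self) -> tuple["Alignment", list[int]]:
        """Remove columns with no residue; return (alignment, kept column indices)."""
        kept = [
            c for c in range(self.n_cols)
            if any(s[c] != GAP for s in self.seqs)
        ]
        seqs = tuple("".join(s[c] for c in kept) for s in self.seqs)
        return Alignment(self.ids, seqs), kept

    # -- coordinate maps ------------------------------------------------
    def ungapped_to_column(self, seq_id: str, residue_index: int) -> int:
        """Column (0-based) holding the ``residue_index``-th (0-based) residue."""
        row = self.row(seq_id)
        if residue_index < 0:
            raise IndexError(f"residue index {residue_index} out of range")
        k = -1
        for c, ch in enumerate(row):
            if ch != GAP:
                k += 1
                if k == residue_index:
                    return c
        raise IndexError(
            f"residue index {residue_index} past end of '{seq_id}' "
            f"(ungapped length {k + 1})"
        )

    def column_to_ungapped(self, seq_id: str, col: int) -> int:
        """Residue index (0-based) at column ``col``; error if the cell is a gap."""
        row = self.row(seq_id)
        if not 0 <= col < self.n_cols:
            raise IndexError(f"column {col} out of range")
        if row[col] == GAP:
            raise ValueError(f"'{seq_id}' is gapped at column {col}")
        return sum(1 for ch in row[:col] if ch != GAP)

    def first_residue_column(self, seq_id: str) -> int | None:
        row = self.row(seq_id)
        for c, ch in enumerate(row):
            if ch != GAP:
                return c
        return None

    def last_residue_column(self, seq_id: str) -> int | None:
        row = self.row(seq_id)
        for c in range(len(row) - 1, -1, -1):
            if row[c] != GAP:
                return c
        return None


def column_counts(
    aln: Alignment, col: int, excluded: Iterable[str] = ()
) -> tuple[int, int]:
    """Occupancy bookkeeping for one column.

    Returns ``(n, N)`` where ``N`` is the number of non-excluded sequences
    and ``n`` the number of those with a residue (non-gap) at ``col``.
    """
    if not 0 <= col < aln.n_cols:
        raise IndexError(f"column {col} out of range [0, {aln.n_cols})")
    excl = set(excluded)
    big_n = 0
    n = 0
    for sid, s in zip(aln.ids, aln.seqs):
        if sid in excl:
            continue
        big_n += 1
        if s[col] != GAP:
            n += 1
    return n, big_n


@dataclass(frozen=True)
class BlockAnnotation:
    """A reliably aligned region: a column interval plus the member subset.

    ``start``/``stop`` are 0-based half-open internally; the TSV dialect
    stores them 1-based inclusive.
    """

    block_id: str
    start: int
    stop: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(
                f"block '{self.block_id}': stop ({self.stop}) must exceed "
                f"start ({self.start})"
            )
        if not self.members:
            raise ValueError(f"block '{self.block_id}': no members")

    @property
    def n_cols(self) -> int:
        return self.stop - self.start

    def validate(self, aln: Alignment, min_cols: int = 1) -> None:
        if self.n_cols < min_cols:
            raise ValueError(
                f"block '{self.block_id}' spans {self.n_cols} < {min_cols} columns"
            )
        if self.stop > aln.n_cols:
            raise ValueError(f"block '{self.block_id}' exceeds alignment width")
        unknown = self.members - set(aln.ids)
        if unknown:
            raise ValueError(
                f"block '{self.block_id}': members not in alignment: "
                f"{sorted(unknown)}"
            )
        for sid in sorted(self.members):
            row = aln.row(sid)
            if all(ch == GAP for ch in row[self.start : self.stop]):
                raise ValueError(
                    f"block '{self.block_id}': member '{sid}' has no residue "
                    f"inside [{self.start}, {self.stop})"
                )


@dataclass
class DisorderAnnotation:
    """Per-sequence disordered-residue intervals in ungapped coordinates.

    Intervals are 0-based half-open internally (1-based inclusive on disk)
    and are merged/sorted on construction.
    """

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            sid: _merge_intervals(ivs) for sid, ivs in self.intervals.items()
        }

    def is_disordered(self, seq_id: str, residue_index: int) -> bool:
        for a, b in self.intervals.get(seq_id, ()):
            if a <= residue_index < b:
                return True
        return False

    def validate(self, aln: Alignment) -> None:
        for sid, ivs in self.intervals.items():
            length = aln.ungapped_length(sid)
            for a, b in ivs:
                if a < 0 or b > length:
                    raise ValueError(
                        f"disorder interval [{a}, {b}) outside '{sid}' "
                        f"(length {length})"
                    )


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivs):
        if b <= a:
            raise ValueError(f"empty interval [{a}, {b})")
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order is preserved; ragged lengths and duplicate ids raise
    :class:`AlignmentFormatError` naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no records")
    ids = tuple(r.id for r in records)
    seqs = tuple(_normalise(str(r.seq)) for r in records)
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_blocks(
    path: str | Path, aln: Alignment | None = None
) -> list[BlockAnnotation]:
    """Read a blocks TSV (columns block_id, col_start, col_end, members).

    File coordinates are 1-based inclusive. If ``aln`` is given, every
    block is validated against it (members present, ≥1 residue each).
    """
    blocks: list[BlockAnnotation] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise AlignmentFormatError(f"{path}: empty blocks file")
    header = rows[0]
    if header[:4] != ["block_id", "col_start", "col_end", "members"]:
        raise AlignmentFormatError(f"{path}: unexpected header {header!r}")
    for row in rows[1:]:
        block_id, s, e, members = row[0], int(row[1]), int(row[2]), row[3]
        if e < s:
            raise AlignmentFormatError(
                f"{path}: block '{block_id}' has col_start > col_end"
            )
        blk = BlockAnnotation(
            block_id=block_id,
            start=s - 1,
            stop=e,
            members=frozenset(m for m in members.split(",") if m),
        )
        if aln is not None:
            blk.validate(aln)
        blocks.append(blk)
    return blocks


def write_blocks(
    blocks: Iterable[BlockAnnotation],
    path: str | Path,
    extra_comments: Iterable[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(COORD_COMMENT + "\n")
        for c in extra_comments:
            fh.write(f"# {c}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["block_id", "col_start", "col_end", "members"])
        for b in blocks:
            w.writerow(
                [b.block_id, b.start + 1, b.stop, ",".join(sorted(b.members))]
            )


def read_disorder(path: str | Path) -> DisorderAnnotation:
    """Read a disorder TSV (columns seq_id, start, end; 1-based inclusive,
    ungapped residue coordinates)."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows or rows[0][:3] != ["seq_id", "start", "end"]:
        raise AlignmentFormatError(f"{path}: missing disorder header")
    for row in rows[1:]:
        sid, a, b = row[0], int(row[1]), int(row[2])
        ivs.setdefault(sid, []).append((a - 1, b))
    return DisorderAnnotation(ivs)


def write_disorder(dis: DisorderAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(COORD_COMMENT + " (ungapped residue coordinates)\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "start", "end"])
        for sid in sorted(dis.intervals):
            for a, b in dis.intervals[sid]:
                w.writerow([sid, a + 1, b])
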