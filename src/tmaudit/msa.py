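"""Domain alignments with exact column <-> ungapped-position coordinate maps.

A domain seed alignment is the substrate of consensus SP/TM detection: the
per-column statistics need to know, for every row, which alignment columns
carry residues and which ungapped sequence position each residue corresponds
to.  Both ``-`` and ``.`` are treated as gaps; lowercase residues (Pfam
full-alignment dialect) are accepted on input and normalised to uppercase.
All public coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment as _BioMSA
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-.")
#: residues remapped to X for scoring (kept verbatim in I/O)
AMBIGUOUS = frozenset("BZUOJ*")

_FORMATS = {"stockholm": "stockholm", "aligned-fasta": "fasta", "fasta": "fasta"}


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates the format contract."""


class DomainAlignment:
    """Gapped residue matrix plus per-row coordinate maps.

    Parameters
    ----------
    records
        Iterable of ``(sequence_id, aligned_residues)`` pairs.  Rows must be
        equal length, ids unique.  Input case and ``.`` gaps are preserved in
        :attr:`raw_rows`; all computation uses the normalised :attr:`rows`
        (uppercase, gaps as ``-``).
    """

    def __init__(self, records: Iterable[tuple[str, str]]):
        recs = [(str(i), str(s)) for i, s in records]
        if not recs:
            raise AlignmentFormatError("alignment has no rows")
        width = len(recs[0][1])
        if width == 0:
            raise AlignmentFormatError(f"row {recs[0][0]!r} is empty")
        for rid, row in recs:
            if len(row) != width:
                raise AlignmentFormatError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {width}"
                )
        ids = [rid for rid, _ in recs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate row identifier(s): {dup}")
        self.ids: list[str] = ids
        self.raw_rows: list[str] = [row for _, row in recs]
        self.rows: list[str] = [
            "".join("-" if c in GAP_CHARS else c.upper() for c in row)
            for row in self.raw_rows
        ]
        self.n_columns: int = width
        self._index = {rid: i for i, rid in enumerate(ids)}
        self._build_maps()

    def _build_maps(self) -> None:
        self._col2pos: list[np.ndarray] = []
        self._pos2col: list[np.ndarray] = []
        for row in self.rows:
            arr = np.frombuffer(row.encode("ascii"), dtype="S1")
            nongap = arr != b"-"
            c2p = np.where(nongap, np.cumsum(nongap), 0)  # 1-based, 0 at gaps
            p2c = np.flatnonzero(nongap) + 1  # 1-based columns
            self._col2pos.append(c2p.astype(np.int64))
            self._pos2col.append(p2c.astype(np.int64))

    # -- basic accessors ---------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def row_index(self, sequence_id: str) -> int:
        try:
            return self._index[sequence_id]
        except KeyError:
            raise KeyError(f"no row {sequence_id!r} in alignment") from None

    def _check_col(self, j: int) -> None:
        if not 1 <= j <= self.n_columns:
            raise IndexError(
                f"column {j} out of range 1..{self.n_columns}"
            )

    def column(self, j: int) -> str:
        """Residues of column *j* (1-based), gaps as ``-``."""
        self._check_col(j)
        return "".join(row[j - 1] for row in self.rows)

    def is_gap(self, i: int, j: int) -> bool:
        self._check_col(j)
        return self.rows[i][j - 1] == "-"

    def column_depth(self, j: int) -> int:
        """n_j: number of non-gap residues in column *j* (1-based)."""
        self._check_col(j)
        return sum(row[j - 1] != "-" for row in self.rows)

    def depths(self) -> np.ndarray:
        """Vector of n_j for all columns."""
        mat = np.array(
            [np.frombuffer(r.encode("ascii"), dtype="S1") for r in self.rows]
        )
        return (mat != b"-").sum(axis=0)

    def gap_matrix(self) -> np.ndarray:
        """Boolean (n_rows, n_columns) matrix, True where gap."""
        mat = np.array(
            [np.frombuffer(r.encode("ascii"), dtype="S1") for r in self.rows]
        )
        return mat == b"-"

    # -- coordinate maps ---------------------------------------------------

    def col_to_pos(self, sequence_id: str, j: int) -> int | None:
        """1-based ungapped position of column *j* in a row, None at gaps."""
        self._check_col(j)
        p = int(self._col2pos[self.row_index(sequence_id)][j - 1])
        return p if p > 0 else None

    def pos_to_col(self, sequence_id: str, p: int) -> int:
        """1-based column holding ungapped position *p* of a row."""
        p2c = self._pos2col[self.row_index(sequence_id)]
        if not 1 <= p <= len(p2c):
            raise IndexError(
                f"position {p} out of range 1..{len(p2c)} for row {sequence_id!r}"
            )
        return int(p2c[p - 1])

    def ungapped(self, sequence_id: str) -> str:
        return self.rows[self.row_index(sequence_id)].replace("-", "")

    def ungapped_length(self, sequence_id: str) -> int:
        return len(self._pos2col[self.row_index(sequence_id)])

    # -- misc ----------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DomainAlignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"DomainAlignment({self.n_rows} rows x {self.n_columns} columns)"


def _as_handle(source) -> TextIO:
    if isinstance(source, str) and ("\n" in source or source.strip().startswith(">")):
        return io.StringIO(source)
    if hasattr(source, "read"):
        return source
    return open(source)


def read_alignment(source, format: str = "aligned-fasta") -> DomainAlignment:
    """Read a Stockholm or aligned-FASTA alignment.

    ``source`` may be a path, an open handle, or literal text.  Annotation
    lines (``#=GC`` etc.) are ignored; ``.`` and ``-`` are both gaps.
    """
    try:
        fmt = _FORMATS[format]
    except KeyError:
        raise ValueError(f"unknown alignment format {format!r}") from None
    handle = _as_handle(source)
    close = not hasattr(source, "read")
    try:
        if fmt == "fasta":
            records = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
        else:
            try:
                aln = AlignIO.read(handle, "stockholm")
            except ValueError as exc:
                raise AlignmentFormatError(f"bad Stockholm alignment: {exc}") from exc
            records = [(r.id, str(r.seq)) for r in aln]
        return DomainAlignment(records)
    finally:
        if close:
            handle.close()


def write_alignment(msa: DomainAlignment, sink, format: str = "aligned-fasta") -> None:
    """Write normalised rows (uppercase, ``-`` gaps); Stockholm ends with ``//``."""
    try:
        fmt = _FORMATS[format]
    except KeyError:
        raise ValueError(f"unknown alignment format {format!r}") from None
    bio = _BioMSA(
        [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(msa.ids, msa.rows)]
    )
    if hasattr(sink, "write"):
        AlignIO.write(bio, sink, fmt)
    else:
        with open(sink, "w") as fh:
            AlignIO.write(bio, fh, fmt)
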