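"""Cleanup alignments: removal of retained SP/TM segment columns.

A cleaned ("cleanup") domain alignment drops the full column spans of every
retained segment — including the restored linkers between re-united TM
fragments — so that a model rebuilt from it no longer carries the
hydrophobic block.  Rebuilding and recalibrating the HMM itself is a
downstream step outside this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import DetectedSegment, DomainAuditResults
from .masks import MaskSet, PredictionMask
from .msa import DomainAlignment

__all__ = ["strip_columns", "strip_mask_calls", "cleanup_report", "CleanupRecord"]


def strip_columns(
    msa: DomainAlignment, segments: list[DetectedSegment]
) -> DomainAlignment:
    """Delete all columns inside the segments' [start_col, end_col] spans.

    Overlapping spans are removed once (set union); rows left all-gap are
    dropped with a warning; coordinate maps are rebuilt.
    """
    drop: set[int] = set()
    for seg in segments:
        if seg.start_col < 1 or seg.end_col > msa.n_columns:
            raise IndexError(
                f"segment {seg.start_col}-{seg.end_col} outside "
                f"1..{msa.n_columns}"
            )
        drop.update(range(seg.start_col, seg.end_col + 1))
    keep = [j for j in range(1, msa.n_columns + 1) if j not in drop]
    if not keep:
        raise ValueError("all columns would be removed")
    records = []
    for rid, row in zip(msa.ids, msa.rows):
        new_row = "".join(row[j - 1] for j in keep)
        if set(new_row) <= {"-"}:
            warnings.warn(
                f"row {rid!r} is all-gap after cleanup; dropped", stacklevel=2
            )
            continue
        records.append((rid, new_row))
    return DomainAlignment(records)


def strip_mask_calls(
    msa: DomainAlignment,
    maskset: MaskSet,
    segments: list[DetectedSegment],
) -> MaskSet:
    """Project masks onto the cleaned alignment produced by ``strip_columns``.

    Residues sitting in removed columns disappear from each sequence, so
    their calls are deleted from the corresponding mask vectors; the
    surviving calls are otherwise unchanged.
    """
    drop_cols: set[int] = set()
    for seg in segments:
        drop_cols.update(range(seg.start_col, seg.end_col + 1))
    out = MaskSet(roster={c: list(p) for c, p in maskset.roster.items()})
    for (sid, pid), mask in maskset.masks.items():
        if sid not in msa.ids:
            continue
        removed_pos = [
            msa.col_to_pos(sid, j) - 1
            for j in sorted(drop_cols)
            if msa.col_to_pos(sid, j) is not None
        ]
        calls = np.delete(mask.calls, removed_pos)
        out.add(PredictionMask(sid, pid, mask.category, calls))
    return out


@dataclass
class CleanupRecord:
    domain_id: str
    n_columns_before: int
    n_columns_after: int
    n_columns_removed: int
    n_rows_dropped: int
    segments: list[tuple[str, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain_id": self.domain_id,
                    "columns_before": self.n_columns_before,
                    "columns_after": self.n_columns_after,
                    "columns_removed": self.n_columns_removed,
                    "rows_dropped": self.n_rows_dropped,
                    "segments": ";".join(
                        f"{c},{s}-{e}" for c, s, e in self.segments
                    ),
                }
            ]
        )


def cleanup_report(
    audit: DomainAuditResults,
    before: DomainAlignment,
    after: DomainAlignment,
) -> CleanupRecord:
    """Summarise what a cleanup removed from one domain alignment."""
    return CleanupRecord(
        domain_id=audit.domain_id,
        n_columns_before=before.n_columns,
        n_columns_after=after.n_columns,
        n_columns_removed=before.n_columns - after.n_columns,
        n_rows_dropped=before.n_rows - after.n_rows,
        segments=[
            (s.category, s.start_col, s.end_col) for s in audit.retained()
        ],
    )
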