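"""Per-residue binary SP/TM prediction masks and their projection onto columns.

The consensus detector consumes only the binary per-residue calls of the
upstream predictors; their native scores are deliberately ignored.  The
canonical interchange format is a run-list TSV (sequence_id, predictor_id,
category, start, end with 1-based inclusive residue coordinates) together
with a manifest declaring the predictor roster per category.  A registered
(sequence, predictor) pair with no records is an all-zero mask; an
*unregistered* pair is an error at projection time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import DomainAlignment

CATEGORIES = ("TM", "SP")

MASK_COLUMNS = ["sequence_id", "predictor_id", "category", "start", "end"]


class MaskError(ValueError):
    pass


class MissingMaskError(KeyError):
    """A row of the alignment lacks a mask for a registered predictor."""


@dataclass
class PredictionMask:
    """Binary SP/TM calls over the ungapped residues of one sequence."""

    sequence_id: str
    predictor_id: str
    category: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise MaskError(f"unknown category {self.category!r}")
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.ndim != 1:
            raise MaskError("calls must be a 1-D binary vector")
        if self.calls.size and self.calls.max() > 1:
            raise MaskError("calls must be 0/1")

    def runs(self) -> list[tuple[int, int]]:
        """Maximal 1-runs as 1-based inclusive (start, end) pairs."""
        out: list[tuple[int, int]] = []
        padded = np.concatenate([[0], self.calls, [0]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1)
        out.extend((int(s), int(e)) for s, e in zip(starts, ends))
        return out


@dataclass
class MaskSet:
    """All masks for one domain, indexed by (sequence_id, predictor_id).

    ``roster`` maps category -> ordered predictor ids; ``D(category)`` is the
    number of predictors audited for that category (the paper's reference
    configuration runs 5 TM and 2 SP predictors).
    """

    roster: dict[str, list[str]]
    masks: dict[tuple[str, str], PredictionMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in self.roster:
            if cat not in CATEGORIES:
                raise MaskError(f"unknown category {cat!r} in roster")

    def D(self, category: str) -> int:
        return len(self.roster.get(category, []))

    def predictors(self, category: str) -> list[str]:
        return list(self.roster.get(category, []))

    def add(self, mask: PredictionMask) -> None:
        self.masks[(mask.sequence_id, mask.predictor_id)] = mask

    def get(self, sequence_id: str, predictor_id: str) -> PredictionMask:
        try:
            return self.masks[(sequence_id, predictor_id)]
        except KeyError:
            raise MissingMaskError(
                f"no mask for sequence {sequence_id!r}, predictor {predictor_id!r}"
            ) from None

    def validate_sp_nterminal(self) -> None:
        """Optional check: SP 1-runs must start at residue 1.

        Only meaningful when masks cover full-length sequences; domain
        fragments may legitimately begin inside a signal peptide.
        """
        sp = set(self.roster.get("SP", []))
        for (sid, pid), mask in self.masks.items():
            if pid in sp:
                for s, _ in mask.runs():
                    if s != 1:
                        raise MaskError(
                            f"SP mask ({sid}, {pid}) has a run starting at "
                            f"residue {s}; expected residue 1"
                        )


def read_manifest(source) -> dict[str, list[str]]:
    """Read the predictor roster: TSV with columns predictor_id, category."""
    df = _read_tsv(source)
    need = {"predictor_id", "category"}
    if not need.issubset(df.columns):
        raise MaskError(f"manifest needs columns {sorted(need)}")
    roster: dict[str, list[str]] = {}
    for _, rec in df.iterrows():
        cat = str(rec["category"])
        if cat not in CATEGORIES:
            raise MaskError(f"unknown category {cat!r} in manifest")
        roster.setdefault(cat, []).append(str(rec["predictor_id"]))
    return roster


def _read_tsv(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", comment="#")


def read_masks(
    source,
    roster: dict[str, list[str]],
    lengths: dict[str, int],
) -> MaskSet:
    """Build a MaskSet from a run-list table.

    Overlapping runs of one (sequence, predictor) are merged (union);
    registered pairs without records get all-zero masks.
    """
    df = _read_tsv(source)
    missing = set(MASK_COLUMNS) - set(df.columns)
    if missing:
        raise MaskError(f"mask table lacks columns {sorted(missing)}")
    cat_of = {p: c for c, preds in roster.items() for p in preds}
    ms = MaskSet(roster={c: list(p) for c, p in roster.items()})
    calls: dict[tuple[str, str], np.ndarray] = {
        (sid, pid): np.zeros(lengths[sid], dtype=np.uint8)
        for sid in lengths
        for pid in cat_of
    }
    for _, rec in df.iterrows():
        sid, pid = str(rec["sequence_id"]), str(rec["predictor_id"])
        cat = str(rec["category"])
        if cat not in CATEGORIES:
            raise MaskError(f"unknown category token {cat!r}")
        if pid not in cat_of:
            raise MaskError(f"predictor {pid!r} not in manifest roster")
        if cat_of[pid] != cat:
            raise MaskError(
                f"predictor {pid!r} registered as {cat_of[pid]}, record says {cat}"
            )
        if sid not in lengths:
            raise MaskError(f"unknown sequence {sid!r} in mask table")
        start, end = int(rec["start"]), int(rec["end"])
        if start < 1:
            raise MaskError(f"start={start} violates the 1-based contract")
        if start > end:
            raise MaskError(f"start {start} > end {end} for ({sid}, {pid})")
        if end > lengths[sid]:
            raise MaskError(
                f"end {end} exceeds length {lengths[sid]} of sequence {sid!r}"
            )
        calls[(sid, pid)][start - 1 : end] = 1
    for (sid, pid), vec in calls.items():
        ms.add(PredictionMask(sid, pid, cat_of[pid], vec))
    return ms


def write_masks(maskset: MaskSet, sink) -> None:
    """Write the run-list TSV (merged runs, sorted for determinism)."""
    rows = []
    for (sid, pid), mask in sorted(maskset.masks.items()):
        for s, e in mask.runs():
            rows.append((sid, pid, mask.category, s, e))
    pd.DataFrame(rows, columns=MASK_COLUMNS).to_csv(sink, sep="\t", index=False)


def project_to_columns(
    msa: DomainAlignment, maskset: MaskSet, category: str
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Project masks onto alignment columns.

    Returns ``(n, k)`` where ``n[j-1]`` is the non-gap depth of column j and
    ``k[predictor][j-1]`` the number of rows whose residue at column j is
    non-gap *and* called positive by that predictor.  ``0 <= k <= n``
    columnwise.
    """
    if category not in CATEGORIES:
        raise MaskError(f"unknown category {category!r}")
    preds = maskset.predictors(category)
    if not preds:
        raise MaskError(f"no predictors registered for category {category}")
    C = msa.n_columns
    n = msa.depths().astype(np.int64)
    k = {p: np.zeros(C, dtype=np.int64) for p in preds}
    for sid in msa.ids:
        ungapped_len = msa.ungapped_length(sid)
        # columns (0-based) holding residue p (1-based) of this row
        cols = np.array(
            [msa.pos_to_col(sid, p) - 1 for p in range(1, ungapped_len + 1)],
            dtype=np.int64,
        )
        for pid in preds:
            mask = maskset.get(sid, pid)
            if len(mask.calls) != ungapped_len:
                raise MaskError(
                    f"mask ({sid}, {pid}) length {len(mask.calls)} != "
                    f"ungapped length {ungapped_len}"
                )
            if ungapped_len:
                np.add.at(k[pid], cols, mask.calls.astype(np.int64))
    return n, k
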