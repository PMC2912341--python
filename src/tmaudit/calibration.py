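"""Cutoff calibration: FP/FN rate tables over candidate segment-score cutoffs.

Calibration scores a labelled negative set (e.g. structural helices, which
must not be called transmembrane) and a positive set (genuine TM helices or
signal peptides) with the same psi statistic used on alignments, tabulates
false-positive and false-negative rates per candidate cutoff, and picks the
most permissive cutoff keeping the FP rate under a target (5% in the
reference configuration, giving the -12 TM and -1 SP defaults).

Since the labelled sets are single sequences rather than alignments, the
binomial column test is bypassed: the estimated column probability is the
raw call (floored at epsilon) and everything downstream is unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DetectConfig
from .consensus import (
    DetectedSegment,
    _runs,
    merge_tm_fragments,
    score_segment,
    sp_segment_span,
)

__all__ = [
    "RateTable",
    "rate_table",
    "select_cutoff",
    "single_sequence_scores",
    "read_scores",
]


@dataclass
class RateTable:
    """FP/FN counts and percentage rates per cutoff (cutoffs descending).

    A negative scoring at or above the cutoff is a false positive (the >=
    matches the retention rule); a positive scoring below it is a false
    negative.  Rates are percentages of the respective set sizes, printed
    to two decimals.
    """

    table: pd.DataFrame
    n_neg_total: int
    n_pos_total: int

    def row(self, cutoff: float) -> pd.Series:
        match = self.table[np.isclose(self.table["cutoff"], cutoff)]
        if match.empty:
            raise KeyError(f"no cutoff {cutoff} in rate table")
        return match.iloc[0]

    def fp_rate(self, cutoff: float) -> float:
        return float(self.row(cutoff)["fp_rate"])

    def fn_rate(self, cutoff: float) -> float:
        return float(self.row(cutoff)["fn_rate"])

    def to_csv(self, sink) -> None:
        self.table.to_csv(sink, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)


def rate_table(neg_scores, pos_scores, cutoffs) -> RateTable:
    """Tabulate FP/FN counts and rates for each candidate cutoff."""
    neg = np.asarray(list(neg_scores), dtype=float)
    pos = np.asarray(list(pos_scores), dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score sets must be non-empty")
    cuts = sorted((float(c) for c in cutoffs), reverse=True)
    rows = []
    for c in cuts:
        n_fp = int((neg >= c).sum())
        n_fn = int((pos < c).sum())
        rows.append(
            {
                "cutoff": c,
                "n_fp": n_fp,
                "fp_rate": round(100.0 * n_fp / neg.size, 2),
                "n_fn": n_fn,
                "fn_rate": round(100.0 * n_fn / pos.size, 2),
            }
        )
    return RateTable(pd.DataFrame(rows), int(neg.size), int(pos.size))


def select_cutoff(table: RateTable, max_fp_rate: float) -> float:
    """Most permissive (lowest) cutoff whose FP rate is below max_fp_rate."""
    ok = table.table[table.table["fp_rate"] < max_fp_rate]
    if ok.empty:
        raise ValueError(
            f"no cutoff achieves an FP rate below {max_fp_rate}%"
        )
    return float(ok["cutoff"].min())


def single_sequence_scores(
    masks: dict[str, np.ndarray],
    category: str,
    config: DetectConfig | None = None,
) -> list[DetectedSegment]:
    """Per-segment psi scores for a single sequence (depth-1 degenerate path).

    ``masks`` maps predictor id -> binary call vector over the sequence.
    With one sequence there is nothing to test: p_hat is the call itself,
    floored at epsilon, and delineation/merging/scoring proceed as for
    alignments (column == residue position here).
    """
    config = config or DetectConfig()
    preds = list(masks)
    if not preds:
        raise ValueError("no predictor masks supplied")
    K = np.stack([np.asarray(masks[p], dtype=np.int64) for p in preds])
    if K.size and K.max() > 1:
        raise ValueError("masks must be binary")
    C = K.shape[1]
    p_hat = np.maximum(K.astype(float), config.epsilon)
    L = np.log(p_hat).sum(axis=0)
    positive = K.any(axis=0)
    raw = _runs(positive)
    segments: list[DetectedSegment] = []
    if raw:
        if category == "SP":
            segments = [sp_segment_span(raw, L)]
        else:
            k = {p: K[i] for i, p in enumerate(preds)}
            for frags in merge_tm_fragments(raw, k, C):
                frag_L = [L[s - 1 : e] for s, e in frags]
                cols = [c for s, e in frags for c in range(s, e + 1)]
                segments.append(
                    DetectedSegment(
                        category=category,
                        start_col=frags[0][0],
                        end_col=frags[-1][1],
                        fragments=frags,
                        n_pred_columns=len(cols),
                        score=score_segment(frag_L),
                        scored_columns=cols,
                    )
                )
    for seg in segments:
        seg.retained = seg.score >= config.cutoff(category)
    return segments


def read_scores(source) -> np.ndarray:
    """Read a single-column list of psi scores (one float per line)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    vals = [float(t) for t in text.split()]
    return np.asarray(vals, dtype=float)
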