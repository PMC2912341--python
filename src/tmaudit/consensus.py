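"""Consensus detection of SP/TM segments inside domain alignments.

The detector treats each predictor's per-residue binary call as a Bernoulli
variable; within an alignment column the calls of one predictor across the
non-gap rows form a binomial sample.  Columns where the one-sided exact
binomial test (null p = 1/2) rejects for at least one predictor are marked
positive, maximal runs of positive columns become candidate segments, TM
fragments split by alignment gaps are re-united via union/intersection
indicators built from the raw calls, and every segment receives an average
log-probability score psi that is compared against calibrated category
cutoffs.

The public entry point is :class:`ConsensusModel` (statsmodels-style:
``ConsensusModel(msa, masks).fit()`` returns :class:`DomainAuditResults`)
or the functional wrapper :func:`audit_domain`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .config import DetectConfig
from .masks import MaskSet, project_to_columns
from .msa import DomainAlignment

__all__ = [
    "binomial_tail",
    "column_test",
    "column_probability",
    "column_log_probability",
    "ColumnStats",
    "DetectedSegment",
    "TMRegion",
    "delineate_segments",
    "merge_tm_fragments",
    "score_segment",
    "sp_segment_span",
    "concatenate_tm_regions",
    "apply_cutoffs",
    "detect_segments",
    "audit_domain",
    "ConsensusModel",
    "DomainAuditResults",
]


# ---------------------------------------------------------------------------
# per-column statistics


def binomial_tail(n: int, k: int) -> float:
    """Exact one-sided upper tail P(K >= k) for K ~ Binomial(n, 1/2).

    Returns 1.0 for n = 0 (the whole sample space).  This is the type I
    error of calling a column an SP/TM residue under the equal-chance null.
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    if n == 0 or k == 0:
        return 1.0
    return float(_st.binom.sf(k - 1, n, 0.5))


def column_test(n: int, k: int, alpha: float = 0.05) -> tuple[bool, int]:
    """One column, one predictor: reject the null? and the expected positives.

    Rejection requires tail probability <= alpha; at alpha = 0.05 this is
    impossible for n <= 4 (the minimum tail is (1/2)^n > 0.05), so the test
    needs alignments of five or more sequences.  On rejection the expected
    positive count E_hat is the observed k; otherwise 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rejected = binomial_tail(n, k) <= alpha
    return rejected, (k if rejected else 0)


def column_probability(E_hat: float, n: int, epsilon: float) -> float:
    """Estimated probability that the column is a true SP/TM residue.

    p_hat = max(E_hat / n, epsilon); the epsilon floor avoids log(0).
    """
    if n < 1:
        raise ValueError("column probability undefined for empty columns")
    return max(E_hat / n, epsilon)


def column_log_probability(p_hats) -> float:
    """Total log probability of a column: sum of ln(p_hat) over predictors."""
    p = np.asarray(p_hats, dtype=float)
    if p.size == 0:
        raise ValueError("empty predictor set")
    return float(np.log(p).sum())


@dataclass
class ColumnStats:
    """Vectorised per-column test results for one category.

    Arrays are indexed ``[predictor, column]`` (predictors in roster order)
    except ``n``, ``L`` and ``positive`` which are per-column.  Columns with
    n = 0 get L = D*ln(epsilon) and are never positive.
    """

    category: str
    predictors: list[str]
    n: np.ndarray
    k: np.ndarray
    p_value: np.ndarray
    rejected: np.ndarray
    E_hat: np.ndarray
    p_hat: np.ndarray
    L: np.ndarray
    positive: np.ndarray
    config: DetectConfig

    @property
    def D(self) -> int:
        return len(self.predictors)

    @classmethod
    def from_counts(
        cls,
        n: np.ndarray,
        k: dict[str, np.ndarray],
        category: str,
        config: DetectConfig,
    ) -> "ColumnStats":
        preds = list(k)
        n = np.asarray(n, dtype=np.int64)
        K = np.stack([np.asarray(k[p], dtype=np.int64) for p in preds])
        nz = n > 0
        pval = np.ones_like(K, dtype=float)
        pval[:, nz] = _st.binom.sf(K[:, nz] - 1, n[nz], 0.5)
        pval[K == 0] = 1.0
        rejected = pval <= config.alpha
        E_hat = np.where(rejected, K, 0)
        p_hat = np.full(K.shape, config.epsilon, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(nz, E_hat / np.where(nz, n, 1), 0.0)
        p_hat = np.maximum(ratio, config.epsilon)
        L = np.log(p_hat).sum(axis=0)
        positive = rejected.any(axis=0) & nz
        return cls(
            category, preds, n, K, pval, rejected, E_hat, p_hat, L, positive, config
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {"column": np.arange(1, len(self.n) + 1), "n": self.n}
        for i, p in enumerate(self.predictors):
            rows[f"k[{p}]"] = self.k[i]
            rows[f"pvalue[{p}]"] = self.p_value[i]
        rows["L"] = self.L
        rows["positive"] = self.positive.astype(int)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segments


@dataclass
class DetectedSegment:
    """A detected SP/TM segment: a column span with fragments and a score.

    ``fragments`` are the raw positive runs (1-based inclusive column
    ranges); for TM segments re-united across alignment gaps the span
    [start_col, end_col] includes the restored linkers.  ``scored_columns``
    are the columns whose L values entered psi (predicted columns for TM;
    the whole N-terminal span for SP).
    """

    category: str
    start_col: int
    end_col: int
    fragments: list[tuple[int, int]]
    n_pred_columns: int
    score: float
    retained: bool = False
    scored_columns: list[int] = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def span(self) -> tuple[int, int]:
        return self.start_col, self.end_col


@dataclass
class TMRegion:
    """One or more TM helices separated by short (< linker_max) linkers."""

    start_col: int
    end_col: int
    helices: list[DetectedSegment]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True-runs of a boolean vector as 1-based inclusive ranges."""
    padded = np.concatenate([[False], np.asarray(mask, bool), [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def delineate_segments(stats: ColumnStats) -> list[tuple[int, int]]:
    """Maximal runs of positive columns, in column order."""
    return _runs(stats.positive)


def merge_tm_fragments(
    raw_segments: list[tuple[int, int]],
    k: dict[str, np.ndarray],
    n_columns: int,
) -> list[list[tuple[int, int]]]:
    """Group raw TM runs that belong to one helix split by alignment gaps.

    Per predictor, the union indicator I_u marks columns where *any*
    sequence carries a positive call (k > 0).  Within each maximal run of
    the OR over predictors, the composite indicator I_c keeps only columns
    where every predictor contributing to that run agrees — the union
    preserves continuity within a helix, the intersection keeps distinct
    helices apart.  Raw runs overlapping the same I_c run become fragments
    of one segment (the gap between them is restored).
    """
    if not raw_segments:
        return []
    I_u = {p: np.asarray(v) > 0 for p, v in k.items()}
    overall = np.zeros(n_columns, dtype=bool)
    for v in I_u.values():
        overall |= v
    I_c = np.zeros(n_columns, dtype=bool)
    for s, e in _runs(overall):
        sl = slice(s - 1, e)
        involved = [p for p, v in I_u.items() if v[sl].any()]
        agree = np.ones(e - s + 1, dtype=bool)
        for p in involved:
            agree &= I_u[p][sl]
        I_c[sl] = agree
    c_runs = _runs(I_c)

    def c_run_of(seg: tuple[int, int]) -> set[int]:
        s, e = seg
        return {
            idx for idx, (cs, ce) in enumerate(c_runs) if not (ce < s or cs > e)
        }

    groups: list[list[tuple[int, int]]] = []
    open_runs: set[int] = set()
    for seg in sorted(raw_segments):
        mine = c_run_of(seg)
        if groups and mine and (mine & open_runs):
            groups[-1].append(seg)
            open_runs |= mine
        else:
            groups.append([seg])
            open_runs = mine
    return groups


def score_segment(fragment_L: list[np.ndarray]) -> float:
    """Average log probability psi of a segment.

    A single fragment scores as the arithmetic mean of its column L values;
    a multi-fragment segment as the weighted mean over fragments with
    weights N_f, the predicted-column count of fragment f.
    """
    if not fragment_L:
        raise ValueError("segment has no fragments")
    sizes = [len(np.atleast_1d(f)) for f in fragment_L]
    if sum(sizes) == 0:
        raise ValueError("segment has zero predicted columns")
    total = sum(float(np.sum(f)) for f in fragment_L)
    return total / sum(sizes)


def sp_segment_span(
    raw_segments: list[tuple[int, int]], L: np.ndarray
) -> DetectedSegment:
    """Collapse SP fragments into the smallest N-terminal span.

    Signal-peptide fragments are assumed to come from one signal peptide,
    so the segment spans column 1 through the C-terminal boundary of the
    most C-terminal fragment, and psi is the plain mean of L over that
    whole span (non-predicted columns sit at the epsilon floor).
    """
    if not raw_segments:
        raise ValueError("no SP segments to span")
    frags = sorted(raw_segments)
    end = max(e for _, e in frags)
    span_cols = list(range(1, end + 1))
    psi = float(np.mean(L[:end]))
    return DetectedSegment(
        category="SP",
        start_col=1,
        end_col=end,
        fragments=frags,
        n_pred_columns=sum(e - s + 1 for s, e in frags),
        score=psi,
        scored_columns=span_cols,
    )


def concatenate_tm_regions(
    segments: list[DetectedSegment], linker_max: int = 40
) -> list[TMRegion]:
    """Concatenate adjacent TM helices separated by < linker_max columns.

    Spacers shorter than the smallest globular domains (~40 residues) are
    linkers, so the helices they separate form one membrane region.  The
    inequality is strict: a gap of exactly linker_max keeps two regions.
    """
    tm = sorted(
        (s for s in segments if s.category == "TM"), key=lambda s: s.start_col
    )
    regions: list[TMRegion] = []
    for seg in tm:
        if regions and (seg.start_col - regions[-1].end_col - 1) < linker_max:
            regions[-1].helices.append(seg)
            regions[-1].end_col = max(regions[-1].end_col, seg.end_col)
        else:
            regions.append(TMRegion(seg.start_col, seg.end_col, [seg]))
    return regions


def apply_cutoffs(
    segments: list[DetectedSegment], config: DetectConfig
) -> list[DetectedSegment]:
    """Retain segments scoring at or above their category cutoff (>=)."""
    for seg in segments:
        seg.retained = seg.score >= config.cutoff(seg.category)
    return [s for s in segments if s.retained]


# ---------------------------------------------------------------------------
# pipeline


def detect_segments(
    msa: DomainAlignment,
    maskset: MaskSet,
    category: str,
    config: DetectConfig | None = None,
) -> tuple[ColumnStats, list[DetectedSegment]]:
    """Run the column tests and segment delineation for one category."""
    config = config or DetectConfig()
    n, k = project_to_columns(msa, maskset, category)
    stats = ColumnStats.from_counts(n, k, category, config)
    raw = delineate_segments(stats)
    segments: list[DetectedSegment] = []
    if raw:
        if category == "SP":
            segments = [sp_segment_span(raw, stats.L)]
        else:
            for frags in merge_tm_fragments(raw, k, msa.n_columns):
                frag_L = [stats.L[s - 1 : e] for s, e in frags]
                cols = [c for s, e in frags for c in range(s, e + 1)]
                segments.append(
                    DetectedSegment(
                        category="TM",
                        start_col=frags[0][0],
                        end_col=frags[-1][1],
                        fragments=frags,
                        n_pred_columns=len(cols),
                        score=score_segment(frag_L),
                        scored_columns=cols,
                    )
                )
    apply_cutoffs(segments, config)
    return stats, segments


class ConsensusModel:
    """Consensus SP/TM detection model over one domain alignment.

    Parameters
    ----------
    msa
        The domain (seed) alignment.
    maskset
        Per-sequence binary predictions for every registered predictor.
    config
        Detection parameters; defaults to the calibrated reference values.
    domain_id
        Label used in reports.
    """

    def __init__(
        self,
        msa: DomainAlignment,
        maskset: MaskSet,
        config: DetectConfig | None = None,
        domain_id: str = "domain",
    ):
        self.msa = msa
        self.maskset = maskset
        self.config = config or DetectConfig()
        self.domain_id = domain_id

    @classmethod
    def from_files(
        cls,
        alignment_path,
        mask_path,
        manifest_path,
        alignment_format: str = "aligned-fasta",
        config: DetectConfig | None = None,
        domain_id: str = "domain",
    ) -> "ConsensusModel":
        from .masks import read_manifest, read_masks
        from .msa import read_alignment

        msa = read_alignment(alignment_path, alignment_format)
        roster = read_manifest(manifest_path)
        lengths = {sid: msa.ungapped_length(sid) for sid in msa.ids}
        return cls(msa, read_masks(mask_path, roster, lengths), config, domain_id)

    def fit(self, categories: list[str] | None = None) -> "DomainAuditResults":
        cats = categories or [c for c in ("TM", "SP") if self.maskset.D(c) > 0]
        stats: dict[str, ColumnStats] = {}
        segments: list[DetectedSegment] = []
        for cat in cats:
            st, segs = detect_segments(self.msa, self.maskset, cat, self.config)
            stats[cat] = st
            segments.extend(segs)
        return DomainAuditResults(self, stats, segments)


class DomainAuditResults:
    """Results of a consensus audit: segments, flags and per-domain scores."""

    def __init__(
        self,
        model: ConsensusModel,
        column_stats: dict[str, ColumnStats],
        segments: list[DetectedSegment],
    ):
        self.model = model
        self.domain_id = model.domain_id
        self.config = model.config
        self.column_stats = column_stats
        self.segments = segments

    def retained(self, category: str | None = None) -> list[DetectedSegment]:
        return [
            s
            for s in self.segments
            if s.retained and (category is None or s.category == category)
        ]

    @property
    def tm_problematic(self) -> bool:
        return bool(self.retained("TM"))

    @property
    def sp_problematic(self) -> bool:
        return bool(self.retained("SP"))

    @property
    def problematic(self) -> bool:
        return self.tm_problematic or self.sp_problematic

    def domain_score(self, category: str) -> float:
        """Weighted-average psi over all retained segments of a category.

        Weights are the scored-column counts of each segment (the same
        weighted mean used to join fragments, applied domain-wide); NaN
        when no segment of the category is retained.
        """
        segs = self.retained(category)
        if not segs:
            return math.nan
        w = np.array([len(s.scored_columns) for s in segs], dtype=float)
        psi = np.array([s.score for s in segs])
        return float(np.sum(w * psi) / np.sum(w))

    @property
    def cumulative_predicted_length(self) -> int:
        return sum(s.n_pred_columns for s in self.retained())

    def tm_regions(self) -> list[TMRegion]:
        return concatenate_tm_regions(self.retained("TM"), self.config.linker_max)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain_id": self.domain_id,
                "category": s.category,
                "start": s.start_col,
                "end": s.end_col,
                "n_fragments": s.n_fragments,
                "n_pred_columns": s.n_pred_columns,
                "psi": round(s.score, 4),
                "retained": int(s.retained),
            }
            for s in self.segments
        ]
        cols = [
            "domain_id",
            "category",
            "start",
            "end",
            "n_fragments",
            "n_pred_columns",
            "psi",
            "retained",
        ]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            f"SP/TM consensus audit: {self.domain_id}",
            f"  alignment: {self.model.msa.n_rows} rows x "
            f"{self.model.msa.n_columns} columns",
            f"  alpha={cfg.alpha} epsilon={cfg.epsilon} "
            f"tm_cutoff={cfg.tm_cutoff} sp_cutoff={cfg.sp_cutoff} "
            f"linker_max={cfg.linker_max}",
            f"  TM problematic: {self.tm_problematic}"
            + (
                f" (domain psi={self.domain_score('TM'):.3f}, "
                f"{len(self.tm_regions())} region(s))"
                if self.tm_problematic
                else ""
            ),
            f"  SP problematic: {self.sp_problematic}"
            + (
                f" (domain psi={self.domain_score('SP'):.3f})"
                if self.sp_problematic
                else ""
            ),
        ]
        frame = self.to_frame()
        if len(frame):
            lines.append(frame.to_string(index=False))
        else:
            lines.append("  no segments detected")
        return "\n".join(lines)


def audit_domain(
    msa: DomainAlignment,
    maskset: MaskSet,
    config: DetectConfig | None = None,
    domain_id: str = "domain",
) -> DomainAuditResults:
    """Full pipeline: project -> test -> delineate -> merge -> score -> cutoffs."""
    return ConsensusModel(msa, maskset, config, domain_id).fit()
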