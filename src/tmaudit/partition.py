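"""Decomposition of profile-HMM hit scores into SP/TM and globular parts.

A hit's Viterbi score is a linear combination of position-specific emission
and transition terms, so it splits exactly into a non-SP/TM-specific part
S_NG (terms at globular model nodes), an SP/TM-specific part S_TM (terms at
flagged nodes) and a position-independent part S_const (begin-entry and
end-exit): S = S_NG + S_TM + S_const.

The gathering threshold GA is partitioned the same way using the seed
sequences of the model: assuming the proportion between S_NG and S_TM seen
in seeds also holds for true hits scoring near GA, each seed i yields a
scaling factor c_i with c_i * (S_NG_i + S_TM_i) + S_const_i = GA; the
expected SP/TM share is G_TM = mean_i(c_i * S_TM_i) and the non-SP/TM
gathering threshold is G_NG = GA - G_TM.  A hit with S >= GA but
S_NG < G_NG passes the threshold only by virtue of its SP/TM match and is
flagged *unjustified*; a hit with S < GA but S_NG >= G_NG is a recoverable
*false negative* (the SP/TM block acted as a penalty).

Exposed statsmodels-style as ``GatheringModel(hmm, mask, seeds).fit()``
returning :class:`GatheringResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import ProfileHMM, ViterbiAlignment, encode_sequence, evalue, viterbi_hmmls

__all__ = [
    "ModelRegionMask",
    "ScorePartition",
    "GatheringPartition",
    "HitClassification",
    "partition_score",
    "gathering_partition",
    "classify_hit",
    "rescore_without_region",
    "GatheringModel",
    "GatheringResults",
    "read_region_mask",
]

VERDICTS = ("true_positive", "unjustified", "false_negative", "no_call")


@dataclass(frozen=True)
class ModelRegionMask:
    """Model nodes flagged as SP/TM (e.g. the validated "TM,102-177" block)."""

    M: int
    nodes: frozenset[int]
    category: str = "TM"

    @classmethod
    def from_ranges(
        cls, M: int, ranges: list[tuple[int, int]], category: str = "TM"
    ) -> "ModelRegionMask":
        nodes: set[int] = set()
        for s, e in ranges:
            if s < 1 or e > M or s > e:
                raise ValueError(f"bad node range {s}-{e} for model length {M}")
            nodes.update(range(s, e + 1))
        return cls(M, frozenset(nodes), category)

    def __post_init__(self) -> None:
        if self.nodes and (min(self.nodes) < 1 or max(self.nodes) > self.M):
            raise ValueError("mask references nodes outside 1..M")

    def flagged(self, node: int) -> bool:
        return node in self.nodes

    @property
    def complement(self) -> frozenset[int]:
        return frozenset(range(1, self.M + 1)) - self.nodes


def read_region_mask(source, M: int) -> dict[str, ModelRegionMask]:
    """Read a region-mask TSV: domain_id, category, start_node, end_node."""
    df = pd.read_csv(source, sep="\t", comment="#")
    need = {"domain_id", "category", "start_node", "end_node"}
    if not need.issubset(df.columns):
        raise ValueError(f"region mask table needs columns {sorted(need)}")
    out: dict[str, ModelRegionMask] = {}
    for did, grp in df.groupby("domain_id"):
        ranges = [
            (int(r["start_node"]), int(r["end_node"])) for _, r in grp.iterrows()
        ]
        out[str(did)] = ModelRegionMask.from_ranges(
            M, ranges, str(grp["category"].iloc[0])
        )
    return out


@dataclass
class ScorePartition:
    """Exact additive split of a total Viterbi score (bits)."""

    S_total: float
    S_NG: float
    S_TM: float
    S_const: float

    def __post_init__(self) -> None:
        resid = abs(self.S_NG + self.S_TM + self.S_const - self.S_total)
        if resid > 1e-9:
            raise ValueError(f"partition not additive (residual {resid:g})")


def partition_score(
    alignment: ViterbiAlignment,
    hmm: ProfileHMM,
    mask: ModelRegionMask,
    sequence: str,
) -> ScorePartition:
    """Attribute every path term to S_TM, S_NG or S_const.

    Emissions belong to the node that emits; a transition belongs to the
    node it departs from; begin-entry and end-exit are position-independent.
    The split is exact by construction.
    """
    if mask.M != hmm.M:
        raise ValueError(f"mask is for model length {mask.M}, hmm has {hmm.M}")
    terms = alignment.path_terms(hmm, encode_sequence(sequence))
    s_ng = s_tm = s_const = 0.0
    for kind, node, value in terms:
        if kind in ("entry", "exit"):
            s_const += value
        elif mask.flagged(node):
            s_tm += value
        else:
            s_ng += value
    total = s_ng + s_tm + s_const
    if abs(total - alignment.total_score) > 1e-6:
        raise AssertionError(
            "path terms do not reproduce the Viterbi score "
            f"({total} vs {alignment.total_score})"
        )
    return ScorePartition(alignment.total_score, s_ng, s_tm, s_const)


def score_and_partition(
    hmm: ProfileHMM, mask: ModelRegionMask, sequence: str
) -> ScorePartition:
    aln = viterbi_hmmls(hmm, sequence)
    return partition_score(aln, hmm, mask, sequence)


@dataclass
class GatheringPartition:
    """Partition of the gathering threshold into SP/TM and globular shares."""

    GA: float
    G_TM: float
    G_NG: float
    seed_table: pd.DataFrame  # per-seed S_NG, S_TM, S_const, c
    n_seeds_used: int
    n_seeds_excluded: int


def gathering_partition(
    hmm: ProfileHMM,
    seeds: list[str],
    mask: ModelRegionMask,
    GA: float | None = None,
) -> GatheringPartition:
    """Estimate G_TM and G_NG from the seed sequences of the model.

    Per seed: c_i = (GA - S_const_i) / (S_NG_i + S_TM_i) (excluded with a
    warning when the denominator vanishes); G_TM = mean_i(c_i * S_TM_i);
    G_NG = GA - G_TM.  With an empty mask S_TM is identically zero and
    G_NG = GA exactly.
    """
    if not seeds:
        raise ValueError("need at least one seed sequence")
    if GA is None:
        GA = hmm.ga
    if GA is None:
        raise ValueError("no gathering score: pass GA or set hmm.ga")
    rows = []
    excluded = 0
    for idx, seq in enumerate(seeds):
        part = score_and_partition(hmm, mask, seq)
        denom = part.S_NG + part.S_TM
        if denom == 0.0:
            warnings.warn(
                f"seed {idx} has S_NG + S_TM = 0; excluded from the "
                "gathering partition",
                stacklevel=2,
            )
            excluded += 1
            continue
        c = (GA - part.S_const) / denom
        rows.append(
            {
                "seed": idx,
                "S_total": part.S_total,
                "S_NG": part.S_NG,
                "S_TM": part.S_TM,
                "S_const": part.S_const,
                "c": c,
            }
        )
    if not rows:
        raise ValueError("all seeds excluded: cannot partition GA")
    table = pd.DataFrame(rows)
    G_TM = float((table["c"] * table["S_TM"]).mean())
    return GatheringPartition(
        GA=float(GA),
        G_TM=G_TM,
        G_NG=float(GA) - G_TM,
        seed_table=table,
        n_seeds_used=len(rows),
        n_seeds_excluded=excluded,
    )


@dataclass
class HitClassification:
    """Verdict for one hit from (S_total, S_NG) against (GA, G_NG)."""

    verdict: str
    S_total: float
    S_NG: float
    GA: float
    G_NG: float


def classify_hit(
    partition: ScorePartition, GA: float, G_NG: float
) -> HitClassification:
    """Four-quadrant hit classification.

    true_positive: S >= GA and S_NG >= G_NG (both parts justified);
    unjustified:   S >= GA but S_NG < G_NG (carried by the SP/TM match);
    false_negative: S < GA but S_NG >= G_NG (SP/TM block penalised a
    genuine globular match); no_call otherwise.
    """
    if not (np.isfinite(GA) and np.isfinite(G_NG)):
        raise ValueError("GA and G_NG must be finite")
    passes_ga = partition.S_total >= GA
    passes_ng = partition.S_NG >= G_NG
    if passes_ga and passes_ng:
        verdict = "true_positive"
    elif passes_ga:
        verdict = "unjustified"
    elif passes_ng:
        verdict = "false_negative"
    else:
        verdict = "no_call"
    return HitClassification(verdict, partition.S_total, partition.S_NG, GA, G_NG)


def submodel_without_region(hmm: ProfileHMM, mask: ModelRegionMask) -> ProfileHMM:
    """Excise the flagged nodes, splicing the survivors together.

    Consecutive kept nodes are rejoined with the upstream (donor) node's
    original outgoing transitions; insert states of removed nodes are
    dropped.  GA and EVD parameters are inherited from the original model.
    """
    kept = sorted(mask.complement)
    if not kept:
        raise ValueError("all nodes flagged: nothing left to score")
    idx = [s - 1 for s in kept]
    return ProfileHMM(
        M=len(kept),
        match_emit=hmm.match_emit[idx].copy(),
        insert_emit=hmm.insert_emit[idx].copy(),
        trans=hmm.trans[idx].copy(),
        entry_m=hmm.entry_m,
        entry_d=hmm.entry_d,
        exit_m=hmm.exit_m,
        exit_d=hmm.exit_d,
        ga=hmm.ga,
        evd_mu=hmm.evd_mu,
        evd_lambda=hmm.evd_lambda,
        null=hmm.null.copy(),
        name=f"{hmm.name}-cleanup",
    )


def rescore_without_region(
    hmm: ProfileHMM,
    mask: ModelRegionMask,
    sequence: str,
    db_size: int | None = None,
) -> tuple[float, float | None]:
    """Re-score a sequence against the model with the SP/TM block removed.

    The E-value (when ``db_size`` is given) uses the ORIGINAL model's EVD
    parameters, mirroring re-computation of scores without the SP/TM
    segments but with unchanged statistics.
    """
    sub = submodel_without_region(hmm, mask)
    score = viterbi_hmmls(sub, sequence).total_score
    ev = None
    if db_size is not None:
        if hmm.evd_mu is None or hmm.evd_lambda is None:
            raise ValueError("E-value requested but the model has no EVD parameters")
        ev = evalue(score, db_size, hmm.evd_mu, hmm.evd_lambda)
    return score, ev


# ---------------------------------------------------------------------------
# model/results front-end


class GatheringModel:
    """Gathering-threshold partition model for one profile HMM.

    Parameters
    ----------
    hmm
        The profile with a finite gathering score (or pass ``ga``).
    region_mask
        Model nodes belonging to the SP/TM block.
    seeds
        Seed sequences of the domain (the data the proportion between
        globular and SP/TM score parts is estimated from).
    """

    def __init__(
        self,
        hmm: ProfileHMM,
        region_mask: ModelRegionMask,
        seeds: list[str],
        ga: float | None = None,
    ):
        self.hmm = hmm
        self.region_mask = region_mask
        self.seeds = list(seeds)
        self.ga = ga if ga is not None else hmm.ga

    def fit(self) -> "GatheringResults":
        gp = gathering_partition(self.hmm, self.seeds, self.region_mask, self.ga)
        return GatheringResults(self, gp)


class GatheringResults:
    """Fitted gathering partition: G_TM/G_NG estimates plus hit triage."""

    def __init__(self, model: GatheringModel, partition: GatheringPartition):
        self.model = model
        self.partition = partition

    @property
    def GA(self) -> float:
        return self.partition.GA

    @property
    def G_TM(self) -> float:
        return self.partition.G_TM

    @property
    def G_NG(self) -> float:
        return self.partition.G_NG

    @property
    def G_TM_se(self) -> float:
        """Standard error of the G_TM estimate over seeds."""
        contrib = self.partition.seed_table["c"] * self.partition.seed_table["S_TM"]
        n = len(contrib)
        return float(contrib.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def classify(self, sequence: str) -> HitClassification:
        part = score_and_partition(self.model.hmm, self.model.region_mask, sequence)
        return classify_hit(part, self.GA, self.G_NG)

    def classify_many(
        self, sequences: dict[str, str] | list[str]
    ) -> pd.DataFrame:
        if isinstance(sequences, dict):
            items = list(sequences.items())
        else:
            items = [(f"query{i + 1}", s) for i, s in enumerate(sequences)]
        rows = []
        for sid, seq in items:
            part = score_and_partition(
                self.model.hmm, self.model.region_mask, seq
            )
            cls = classify_hit(part, self.GA, self.G_NG)
            rows.append(
                {
                    "sequence_id": sid,
                    "S_total": round(part.S_total, 4),
                    "S_NG": round(part.S_NG, 4),
                    "S_TM": round(part.S_TM, 4),
                    "S_const": round(part.S_const, 4),
                    "GA": self.GA,
                    "G_NG": round(self.G_NG, 4),
                    "verdict": cls.verdict,
                }
            )
        cols = [
            "sequence_id",
            "S_total",
            "S_NG",
            "S_TM",
            "S_const",
            "GA",
            "G_NG",
            "verdict",
        ]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        p = self.partition
        lines = [
            f"Gathering-score partition: {self.model.hmm.name}",
            f"  model length M={self.model.hmm.M}, flagged nodes: "
            f"{len(self.model.region_mask.nodes)}",
            f"  GA    = {p.GA:.3f} bits",
            f"  G_TM  = {p.G_TM:.3f} bits (se {self.G_TM_se:.3f})",
            f"  G_NG  = {p.G_NG:.3f} bits",
            f"  seeds used: {p.n_seeds_used} (excluded: {p.n_seeds_excluded})",
            p.seed_table.round(3).to_string(index=False),
        ]
        return "\n".join(lines)
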