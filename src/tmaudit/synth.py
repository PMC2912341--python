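"""Deterministic synthetic fixtures: alignments, masks, profiles, queries.

Everything the toolkit consumes can be generated here so that tests and
demonstrations run without downloads.  The generators emulate the relevant
*statistical* features of real inputs — hydrophobic composition of planted
TM/SP spans, per-predictor sensitivity and false-positive rates, a profile
with an information-rich globular block next to a hydrophobicity-matching
SP/TM block — not evolutionary realism.  All outputs are pure functions of
(spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .hmm import AMINO, ProfileHMM
from .masks import MaskSet, PredictionMask
from .msa import DomainAlignment
from .partition import ModelRegionMask

__all__ = [
    "SynthSpec",
    "ProfileSpec",
    "ProfileFixture",
    "make_alignment",
    "make_masks",
    "make_profile",
]

HYDROPHOBIC = "ILVFAM"

# rough background amino-acid weights (order = AMINO); flat-ish with mild
# enrichment of the common residues
_BACKGROUND = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}


def _weights(enrich: dict[str, float] | None = None) -> np.ndarray:
    w = np.array([_BACKGROUND[a] for a in AMINO], dtype=float)
    if enrich:
        for a, f in enrich.items():
            w[AMINO.index(a)] *= f
    return w / w.sum()


BACKGROUND_W = _weights()
#: composition of planted TM/SP-core spans: strongly I/L/V/F/A/M-enriched
HYDRO_W = _weights({a: 12.0 for a in HYDROPHOBIC})


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic domain alignment and its masks.

    ``segments`` are planted (category, (start_col, end_col)) spans,
    1-based inclusive; SP spans must begin at column 1.  ``sensitivity``
    is each predictor's per-residue recall inside planted spans and
    ``fp_rate`` its per-residue false-positive rate outside; calls are
    independent across predictors and rows.  Gaps appear only outside
    planted spans.
    """

    n_sequences: int = 25
    n_columns: int = 120
    segments: tuple[tuple[str, tuple[int, int]], ...] = (("TM", (45, 66)),)
    gap_rate: float = 0.05
    sensitivity: float = 0.9
    fp_rate: float = 0.05
    n_tm_predictors: int = 5
    n_sp_predictors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for prob in (self.gap_rate, self.sensitivity, self.fp_rate):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        for cat, (s, e) in self.segments:
            if cat not in ("TM", "SP"):
                raise ValueError(f"unknown planted category {cat!r}")
            if not 1 <= s <= e <= self.n_columns:
                raise ValueError(f"planted span {s}-{e} outside the alignment")
            if cat == "SP" and s != 1:
                raise ValueError("planted SP spans must start at column 1")

    def roster(self) -> dict[str, list[str]]:
        return {
            "TM": [f"tm{i + 1}" for i in range(self.n_tm_predictors)],
            "SP": [f"sp{i + 1}" for i in range(self.n_sp_predictors)],
        }

    def span_columns(self, category: str) -> set[int]:
        cols: set[int] = set()
        for cat, (s, e) in self.segments:
            if cat == category:
                cols.update(range(s, e + 1))
        return cols

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SynthSpec":
        d = json.loads(text)
        d["segments"] = tuple(
            (cat, (int(s), int(e))) for cat, (s, e) in d.get("segments", [])
        )
        return cls(**d)


def make_alignment(spec: SynthSpec) -> DomainAlignment:
    """Sample an alignment with hydrophobic planted spans and random gaps."""
    rng = np.random.default_rng(spec.seed)
    planted = spec.span_columns("TM") | spec.span_columns("SP")
    aa = np.array(list(AMINO))
    records = []
    for i in range(spec.n_sequences):
        chars = []
        for j in range(1, spec.n_columns + 1):
            if j in planted:
                chars.append(rng.choice(aa, p=HYDRO_W))
            elif spec.gap_rate and rng.random() < spec.gap_rate:
                chars.append("-")
            else:
                chars.append(rng.choice(aa, p=BACKGROUND_W))
        records.append((f"seq{i + 1:03d}", "".join(chars)))
    return DomainAlignment(records)


def make_masks(msa: DomainAlignment, spec: SynthSpec) -> MaskSet:
    """Sample predictor masks with the spec's sensitivity / FP rate.

    A residue whose alignment column lies in a planted span of the
    predictor's category is called positive with probability
    ``sensitivity``, any other residue with probability ``fp_rate``.
    Randomness is seeded from ``spec.seed`` (offset so masks differ from
    the alignment stream).
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    roster = spec.roster()
    ms = MaskSet(roster=roster)
    span = {cat: spec.span_columns(cat) for cat in roster}
    for cat, preds in roster.items():
        for pid in preds:
            for sid in msa.ids:
                n_res = msa.ungapped_length(sid)
                calls = np.zeros(n_res, dtype=np.uint8)
                for p in range(1, n_res + 1):
                    inside = msa.pos_to_col(sid, p) in span[cat]
                    prob = spec.sensitivity if inside else spec.fp_rate
                    calls[p - 1] = 1 if rng.random() < prob else 0
                ms.add(PredictionMask(sid, pid, cat, calls))
    return ms


# ---------------------------------------------------------------------------
# toy profiles with a designated SP/TM block


@dataclass(frozen=True)
class ProfileSpec:
    """Conditions for a toy profile with a flagged hydrophobic block.

    The model has ``g_len`` information-rich globular nodes (one favoured
    motif residue each) followed by ``tm_len`` flagged nodes favouring any
    hydrophobic residue.  Members match both blocks (motif residue with
    probability ``member_fidelity``); decoys carry only a hydrophobic run
    against the flagged block over a random background, emulating spurious
    hits whose score rests entirely on the SP/TM match.
    """

    g_len: int = 30
    tm_len: int = 25
    motif_strength: float = 3.2
    mismatch: float = -1.5
    hydro_strength: float = 2.2
    hydro_mismatch: float = -2.0
    member_fidelity: float = 0.85
    decoy_hydro_frac: float = 0.8
    ga: float = 25.0
    evd_mu: float = 20.0
    evd_lambda: float = 0.7
    n_seeds: int = 12
    n_members: int = 40
    n_decoys: int = 60
    seed: int = 0


@dataclass
class ProfileFixture:
    hmm: ProfileHMM
    region_mask: ModelRegionMask
    seeds: list[str]
    members: list[str]
    decoys: list[str]
    motif: str = ""


def _sample_member(rng: np.random.Generator, motif: str, spec: ProfileSpec) -> str:
    aa = np.array(list(AMINO))
    hydro = np.array(list(HYDROPHOBIC))
    out = []
    for s, r in enumerate(motif):
        if rng.random() < spec.member_fidelity:
            out.append(r if s < spec.g_len else str(rng.choice(hydro)))
        else:
            out.append(str(rng.choice(aa, p=BACKGROUND_W)))
    return "".join(out)


def _sample_decoy(rng: np.random.Generator, spec: ProfileSpec) -> str:
    aa = np.array(list(AMINO))
    hydro = np.array(list(HYDROPHOBIC))
    prefix = [str(rng.choice(aa, p=BACKGROUND_W)) for _ in range(10)]
    run = []
    for _ in range(spec.tm_len + 3):
        if rng.random() < spec.decoy_hydro_frac:
            run.append(str(rng.choice(hydro)))
        else:
            run.append(str(rng.choice(aa, p=BACKGROUND_W)))
    suffix = [str(rng.choice(aa, p=BACKGROUND_W)) for _ in range(8)]
    return "".join(prefix + run + suffix)


def make_profile(spec: ProfileSpec | None = None) -> ProfileFixture:
    """Build (profile, flagged-region mask, seed/member/decoy sequences)."""
    spec = spec or ProfileSpec()
    rng = np.random.default_rng(spec.seed)
    M = spec.g_len + spec.tm_len
    match = np.full((M, 21), spec.mismatch)
    motif_chars = []
    for s in range(spec.g_len):
        r = AMINO[rng.integers(0, 20)]
        motif_chars.append(r)
        match[s, AMINO.index(r)] = spec.motif_strength
    for s in range(spec.g_len, M):
        match[s, :20] = spec.hydro_mismatch
        for a in HYDROPHOBIC:
            match[s, AMINO.index(a)] = spec.hydro_strength
        motif_chars.append("L")  # representative hydrophobic residue
    insert = np.zeros((M, 21))
    trans = np.tile(
        # mm, mi, md, im, ii, dm, dd
        np.array([-0.05, -6.0, -2.0, -1.0, -1.0, -1.5, -0.2]), (M, 1)
    )
    hmm = ProfileHMM(
        M=M,
        match_emit=match,
        insert_emit=insert,
        trans=trans,
        entry_m=0.0,
        entry_d=-6.0,
        exit_m=0.0,
        exit_d=-6.0,
        ga=spec.ga,
        evd_mu=spec.evd_mu,
        evd_lambda=spec.evd_lambda,
        name="synthetic-tm-domain",
    )
    mask = ModelRegionMask.from_ranges(M, [(spec.g_len + 1, M)], "TM")
    motif = "".join(motif_chars)
    seeds = [_sample_member(rng, motif, spec) for _ in range(spec.n_seeds)]
    members = [_sample_member(rng, motif, spec) for _ in range(spec.n_members)]
    decoys = [_sample_decoy(rng, spec) for _ in range(spec.n_decoys)]
    return ProfileFixture(hmm, mask, seeds, members, decoys, motif)
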