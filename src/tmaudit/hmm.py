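"""Minimal plan7-like profile HMM: parsing, hmmls-style Viterbi, E-values.

The model is global with respect to the domain (every path threads nodes
1..M through match or delete states) and local with respect to the query
(flanking residues are emitted by the null model at zero log-odds cost).
Scores are log-odds in bits.  There is no multi-hit (J) state and no null2
correction; EVD parameters for E-values are inputs, not calibrated here.

Two on-disk formats are supported: a native JSON profile (canonical,
round-trips exactly) and a best-effort subset of the HMMER2 ASCII save
format (header keys NAME/LENG/ALPH/GA/EVD plus the three per-node integer
score lines, integer scores being bits * 1000, ``*`` meaning forbidden).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

AMINO = "ACDEFGHIKLMNPQRSTVWY"
#: index of the neutral residue X (log-odds 0 against every state)
X_INDEX = len(AMINO)
_RES_INDEX = {a: i for i, a in enumerate(AMINO)}

NEG_INF = float("-inf")

#: transition columns, all departing node s (towards node s+1)
TRANS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class ProfileFormatError(ValueError):
    pass


def residue_index(aa: str) -> int:
    """Alphabet index of a residue; ambiguous codes (B, Z, U, O...) map to X."""
    return _RES_INDEX.get(aa.upper(), X_INDEX)


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([residue_index(a) for a in seq], dtype=np.int64)


@dataclass
class ProfileHMM:
    """Plan7-like profile over the 20 amino acids (+X neutral).

    match_emit / insert_emit
        (M, 21) log-odds bits; column 20 is X and must be 0.
    trans
        (M, 7) transitions departing node s (rows 0..M-2 used; the last
        row's entries are ignored since node M exits to E).
    entry_m / entry_d
        B -> M1 and B -> D1 scores; exit_m / exit_d the M_M -> E and
        D_M -> E scores.
    ga
        Gathering score threshold in bits (None if absent).
    evd_mu / evd_lambda
        Extreme-value (Gumbel) location and slope for E-values.
    """

    M: int
    match_emit: np.ndarray
    insert_emit: np.ndarray
    trans: np.ndarray
    entry_m: float = 0.0
    entry_d: float = NEG_INF
    exit_m: float = 0.0
    exit_d: float = NEG_INF
    ga: float | None = None
    evd_mu: float | None = None
    evd_lambda: float | None = None
    null: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    name: str = "model"

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.M < 1:
            raise ProfileFormatError("model length M must be >= 1")
        if self.match_emit.shape != (self.M, 21):
            raise ProfileFormatError(
                f"match_emit must be (M, 21), got {self.match_emit.shape}"
            )
        if self.insert_emit.shape != (self.M, 21):
            raise ProfileFormatError(
                f"insert_emit must be (M, 21), got {self.insert_emit.shape}"
            )
        if self.trans.shape != (self.M, 7):
            raise ProfileFormatError(
                f"trans must be (M, 7), got {self.trans.shape}"
            )
        if self.evd_lambda is not None and self.evd_lambda <= 0:
            raise ProfileFormatError("evd_lambda must be positive")
        # X column is the neutral residue
        self.match_emit[:, X_INDEX] = 0.0
        self.insert_emit[:, X_INDEX] = 0.0

    def t(self, s: int, kind: str) -> float:
        """Transition score departing node s (1-based)."""
        return float(self.trans[s - 1, TRANS.index(kind)])

    # -- native JSON format ------------------------------------------------

    def to_json(self) -> str:
        def enc(x: float) -> float | str:
            return "*" if x == NEG_INF else x

        payload = {
            "format": "tmaudit-profile-1",
            "name": self.name,
            "M": self.M,
            "alphabet": AMINO + "X",
            "match_emit": [[enc(v) for v in row] for row in self.match_emit],
            "insert_emit": [[enc(v) for v in row] for row in self.insert_emit],
            "transitions": [[enc(v) for v in row] for row in self.trans],
            "entry_m": enc(self.entry_m),
            "entry_d": enc(self.entry_d),
            "exit_m": enc(self.exit_m),
            "exit_d": enc(self.exit_d),
            "ga": self.ga,
            "evd_mu": self.evd_mu,
            "evd_lambda": self.evd_lambda,
            "null": list(self.null),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        def dec(x) -> float:
            return NEG_INF if x == "*" else float(x)

        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProfileFormatError(f"bad profile JSON: {exc}") from exc
        if payload.get("format") != "tmaudit-profile-1":
            raise ProfileFormatError("not a tmaudit native profile")
        return cls(
            M=int(payload["M"]),
            match_emit=np.array(
                [[dec(v) for v in row] for row in payload["match_emit"]]
            ),
            insert_emit=np.array(
                [[dec(v) for v in row] for row in payload["insert_emit"]]
            ),
            trans=np.array(
                [[dec(v) for v in row] for row in payload["transitions"]]
            ),
            entry_m=dec(payload["entry_m"]),
            entry_d=dec(payload["entry_d"]),
            exit_m=dec(payload["exit_m"]),
            exit_d=dec(payload["exit_d"]),
            ga=payload.get("ga"),
            evd_mu=payload.get("evd_mu"),
            evd_lambda=payload.get("evd_lambda"),
            null=np.array(payload.get("null", [0.05] * 20)),
            name=payload.get("name", "model"),
        )


def _h2_score(tok: str) -> float:
    """HMMER2 integer score token -> bits (INTSCALE = 1000; '*' forbidden)."""
    return NEG_INF if tok == "*" else int(tok) / 1000.0


def _read_hmmer2(text: str) -> ProfileHMM:
    """Best-effort reader for the HMMER2 plan7 ASCII save-file subset."""
    lines = text.splitlines()
    name, leng, ga, mu, lam = "model", None, None, None, None
    alpha_order: list[str] = list(AMINO)
    i = 0
    while i < len(lines):
        line = lines[i]
        key = line.split()[0] if line.split() else ""
        if key == "NAME":
            name = line.split(None, 1)[1].strip()
        elif key == "LENG":
            leng = int(line.split()[1])
        elif key == "GA":
            ga = float(line.split()[1])
        elif key == "EVD":
            _, mu_s, lam_s = line.split()[:3]
            mu, lam = float(mu_s), float(lam_s)
        elif key == "HMM":
            alpha_order = line.split()[1:]
            i += 1  # skip transition-order header line
            break
        i += 1
    if leng is None:
        raise ProfileFormatError("HMMER2 file lacks a LENG line")
    perm = [residue_index(a) for a in alpha_order]

    match = np.zeros((leng, 21))
    insert = np.zeros((leng, 21))
    trans = np.zeros((leng, 7))
    entry_m = 0.0
    exit_m = 0.0
    node = 0
    i += 1
    while i < len(lines) and node < leng:
        toks = lines[i].split()
        if toks and toks[0] == str(node + 1):
            try:
                mrow = [_h2_score(t) for t in toks[1 : 1 + len(alpha_order)]]
                irow = [_h2_score(t) for t in lines[i + 1].split()[1 : 1 + len(alpha_order)]]
                trow = [_h2_score(t) for t in lines[i + 2].split()[1:10]]
            except (ValueError, IndexError) as exc:
                raise ProfileFormatError(
                    f"malformed node block at line {i + 1}: {exc}"
                ) from exc
            for a_idx, v in zip(perm, mrow):
                match[node, a_idx] = v
            for a_idx, v in zip(perm, irow):
                insert[node, a_idx] = v
            trans[node, :] = trow[:7]
            if node == 0:
                entry_m = trow[7] if len(trow) > 7 else 0.0
            if node == leng - 1 and len(trow) > 8:
                exit_m = trow[8]
            node += 1
            i += 3
        else:
            i += 1
    if node < leng:
        raise ProfileFormatError(
            f"HMMER2 file declares LENG {leng} but only {node} node blocks parsed"
        )
    entry_m = 0.0 if entry_m == NEG_INF else entry_m
    exit_m = 0.0 if exit_m == NEG_INF else exit_m
    return ProfileHMM(
        M=leng,
        match_emit=match,
        insert_emit=insert,
        trans=trans,
        entry_m=entry_m,
        exit_m=exit_m,
        ga=ga,
        evd_mu=mu,
        evd_lambda=lam,
        name=name,
    )


def read_profile(source, format: str = "native-json") -> ProfileHMM:
    """Read a profile HMM (``native-json`` or ``hmmer2-ascii-subset``)."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    if format == "native-json":
        return ProfileHMM.from_json(text)
    if format == "hmmer2-ascii-subset":
        return _read_hmmer2(text)
    raise ValueError(f"unknown profile format {format!r}")


def write_profile(hmm: ProfileHMM, sink) -> None:
    if hasattr(sink, "write"):
        sink.write(hmm.to_json())
    else:
        with open(sink, "w") as fh:
            fh.write(hmm.to_json())


# ---------------------------------------------------------------------------
# Viterbi


@dataclass
class ViterbiAlignment:
    """Best plan7 path: (state, node, seqpos) triples plus the total score.

    ``seqpos`` is the 1-based sequence position emitted (None for D).
    Flanking residues outside [seq_start, seq_end] are null-emitted at zero
    cost and do not appear in the path.
    """

    path: list[tuple[str, int, int | None]]
    total_score: float
    model_span: tuple[int, int]
    seq_span: tuple[int, int]

    def path_terms(self, hmm: ProfileHMM, encoded: np.ndarray) -> list[tuple[str, int | None, float]]:
        """Score terms of the path: (kind, departing/emitting node, bits).

        kinds: 'entry', 'exit' (position-independent), 'emit' and 'trans'
        (attributed to a model node).  Their sum equals total_score.
        """
        terms: list[tuple[str, int | None, float]] = []
        first_state, _, _ = self.path[0]
        terms.append(
            ("entry", None, hmm.entry_m if first_state == "M" else hmm.entry_d)
        )
        prev: tuple[str, int] | None = None
        for state, node, pos in self.path:
            if prev is not None:
                ps, pn = prev
                terms.append(("trans", pn, hmm.t(pn, (ps + state).lower())))
            if state == "M":
                terms.append(("emit", node, float(hmm.match_emit[node - 1, encoded[pos - 1]])))
            elif state == "I":
                terms.append(("emit", node, float(hmm.insert_emit[node - 1, encoded[pos - 1]])))
            prev = (state, node)
        last_state, _, _ = self.path[-1]
        terms.append(("exit", None, hmm.exit_m if last_state == "M" else hmm.exit_d))
        return terms


def viterbi_hmmls(hmm: ProfileHMM, sequence: str) -> ViterbiAlignment:
    """Best-scoring alignment, global in the model, local in the sequence.

    Dynamic programming over states M/I/D with deterministic tie-breaking
    (M preferred over D over I; earlier sequence positions win ties).
    """
    if not sequence:
        raise ValueError("empty sequence")
    x = encode_sequence(sequence)
    L, M = len(x), hmm.M
    me, ie, tr = hmm.match_emit, hmm.insert_emit, hmm.trans
    # V?[i][s]: best score ending in state ? at node s+1 having consumed i residues
    VM = np.full((L + 1, M), NEG_INF)
    VI = np.full((L + 1, M), NEG_INF)
    VD = np.full((L + 1, M), NEG_INF)
    # backpointers: 0=entry, 1=from M, 2=from D, 3=from I
    BM = np.zeros((L + 1, M), dtype=np.int8)
    BI = np.zeros((L + 1, M), dtype=np.int8)
    BD = np.zeros((L + 1, M), dtype=np.int8)

    def best(cands: list[tuple[float, int]]) -> tuple[float, int]:
        b_score, b_tag = NEG_INF, 0
        for score, tag in cands:
            if score > b_score:
                b_score, b_tag = score, tag
        return b_score, b_tag

    for i in range(0, L + 1):
        # D column sweep happens after M at same i; M/I need i >= 1
        if i >= 1:
            a = x[i - 1]
            # node 1 match: entry only
            VM[i, 0], BM[i, 0] = me[0, a] + hmm.entry_m, 0
            for s in range(1, M):
                cands = [
                    (VM[i - 1, s - 1] + tr[s - 1, 0], 1),  # m->m
                    (VD[i - 1, s - 1] + tr[s - 1, 5], 2),  # d->m
                    (VI[i - 1, s - 1] + tr[s - 1, 3], 3),  # i->m
                ]
                sc, tag = best(cands)
                VM[i, s], BM[i, s] = me[s, a] + sc, tag
            for s in range(0, M - 1):  # insert states I_1..I_{M-1}
                cands = [
                    (VM[i - 1, s] + tr[s, 1], 1),  # m->i
                    (VI[i - 1, s] + tr[s, 4], 3),  # i->i
                ]
                sc, tag = best(cands)
                VI[i, s], BI[i, s] = ie[s, a] + sc, tag
        # delete states at consumed-count i
        VD[i, 0], BD[i, 0] = hmm.entry_d, 0
        for s in range(1, M):
            cands = [
                (VM[i, s - 1] + tr[s - 1, 2], 1),  # m->d
                (VD[i, s - 1] + tr[s - 1, 6], 2),  # d->d
            ]
            sc, tag = best(cands)
            VD[i, s], BD[i, s] = sc, tag

    # termination: exit from M_M or D_M at any consumed count (trailing flank free)
    best_score, best_end = NEG_INF, None
    for i in range(0, L + 1):
        for state, V, ex in (("M", VM, hmm.exit_m), ("D", VD, hmm.exit_d)):
            sc = V[i, M - 1] + ex
            if sc > best_score:
                best_score, best_end = sc, (state, i)
    if best_end is None or best_score == NEG_INF:
        raise ValueError("no valid path through the model")

    # traceback
    path: list[tuple[str, int, int | None]] = []
    state, i = best_end
    s = M - 1
    while True:
        if state == "M":
            path.append(("M", s + 1, i))
            tag = BM[i, s]
            i -= 1
            if tag == 0:
                break
            state = {1: "M", 2: "D", 3: "I"}[tag]
            if state != "I":
                s -= 1
            else:
                s -= 1  # I_s sits between node s and s+1; predecessor node index s
        elif state == "D":
            path.append(("D", s + 1, None))
            tag = BD[i, s]
            if tag == 0:
                break
            state = {1: "M", 2: "D"}[tag]
            s -= 1
        else:  # I
            path.append(("I", s + 1, i))
            tag = BI[i, s]
            i -= 1
            state = {1: "M", 3: "I"}[tag]
            # insert loops stay at the same node
    path.reverse()
    emitted = [p for _, _, p in path if p is not None]
    seq_span = (min(emitted), max(emitted)) if emitted else (0, 0)
    return ViterbiAlignment(
        path=path,
        total_score=float(best_score),
        model_span=(1, M),
        seq_span=seq_span,
    )


def evalue(score_bits: float, db_size: int, mu: float, lam: float) -> float:
    """E-value of a bit score under the Gumbel law.

    E = N * P(S >= x) with P(S >= x) = 1 - exp(-exp(-lambda * (x - mu))),
    clamped to [0, N].
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if db_size < 1:
        raise ValueError("database size must be >= 1")
    p = -math.expm1(-math.exp(-lam * (score_bits - mu)))
    return float(min(max(db_size * p, 0.0), float(db_size)))
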