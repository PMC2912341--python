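"""Independent reference implementations used to cross-check the package.

These are deliberately naive (enumeration / direct summation) and share no
code with the implementation paths they verify.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import numpy as np

from tmaudit.hmm import ProfileHMM, encode_sequence


def binomial_tail_by_summation(n: int, k: int) -> float:
    """P(K >= k), K ~ Binomial(n, 1/2), by exact rational summation."""
    if n == 0:
        return 1.0
    total = sum(Fraction(comb(n, j)) for j in range(k, n + 1))
    return float(total / Fraction(2) ** n)


def brute_force_hmmls(hmm: ProfileHMM, sequence: str) -> float:
    """Best hmmls path score by exhaustive path enumeration.

    Global in the model (nodes 1..M via M/D), local in the sequence
    (any contiguous consumed span, flanks free).  Only usable for tiny
    models/sequences.
    """
    x = encode_sequence(sequence)
    L, M = len(x), hmm.M
    me, ie = hmm.match_emit, hmm.insert_emit
    best = [-inf]

    def finish(state: str, score: float) -> None:
        ex = hmm.exit_m if state == "M" else hmm.exit_d
        if score + ex > best[0]:
            best[0] = score + ex

    def rec(state: str, s: int, i: int, score: float) -> None:
        # in `state` at node s (1-based), having consumed residues x[0..i-1]
        if score == -inf:
            return
        if state in ("M", "D") and s == M:
            finish(state, score)
            return
        if state in ("M", "D"):
            pre = "m" if state == "M" else "d"
            if i < L:
                rec("M", s + 1, i + 1,
                    score + hmm.t(s, pre + "m") + me[s, x[i]])
            rec("D", s + 1, i, score + hmm.t(s, pre + "d"))
            if state == "M" and i < L and s < M:
                rec("I", s, i + 1, score + hmm.t(s, "mi") + ie[s - 1, x[i]])
        else:  # insert at node s
            if i < L:
                rec("I", s, i + 1, score + hmm.t(s, "ii") + ie[s - 1, x[i]])
                rec("M", s + 1, i + 1,
                    score + hmm.t(s, "im") + me[s, x[i]])

    for p in range(L):  # enter M1 emitting x[p] after a free flank of p residues
        rec("M", 1, p + 1, hmm.entry_m + me[0, x[p]])
    for p in range(L + 1):  # enter D1 (consumes nothing)
        rec("D", 1, p, hmm.entry_d)
    return best[0]


def random_profile(
    rng: np.random.Generator,
    M: int,
    allow_forbidden: bool = False,
) -> ProfileHMM:
    """A random, finite-scoring profile for fuzz tests."""
    match = rng.normal(0.0, 2.0, size=(M, 21))
    insert = rng.normal(-0.5, 1.0, size=(M, 21))
    trans = -np.abs(rng.normal(1.0, 1.0, size=(M, 7)))
    if allow_forbidden:
        forbid = rng.random(size=(M, 7)) < 0.05
        trans = np.where(forbid, -np.inf, trans)
        # keep at least one route between consecutive nodes alive
        trans[:, 0] = np.where(np.isinf(trans[:, 0]), -5.0, trans[:, 0])
    return ProfileHMM(
        M=M,
        match_emit=match,
        insert_emit=insert,
        trans=trans,
        entry_m=float(-abs(rng.normal(0, 0.5))),
        entry_d=float(-abs(rng.normal(2, 1))),
        exit_m=0.0,
        exit_d=float(-abs(rng.normal(2, 1))),
        ga=10.0,
        evd_mu=5.0,
        evd_lambda=0.6,
        name=f"fuzz-M{M}",
    )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    from tmaudit.hmm import AMINO

    return "".join(rng.choice(list(AMINO), size=length))


def published_tm_calibration_sets():
    """Score multisets reproducing the published TM calibration counts.

    2293 negative (structural) helices with the cumulative counts
    {>= -6: 21, -7: 37, -8: 45, -9: 47, -10: 72, -11: 84, -12: 107,
    -13: 125, -14: 206} and 5592 positive (membrane) helices with
    false-negative counts {< -6: 4519, ..., < -14: 362}.
    """
    neg_cum = [(-6, 21), (-7, 37), (-8, 45), (-9, 47), (-10, 72),
               (-11, 84), (-12, 107), (-13, 125), (-14, 206)]
    pos_fn = [(-6, 4519), (-7, 3401), (-8, 2520), (-9, 1593), (-10, 910),
              (-11, 526), (-12, 418), (-13, 381), (-14, 362)]
    return (_scores_from_cumulative(neg_cum, 2293),
            _scores_from_fn(pos_fn, 5592))


def published_sp_calibration_sets():
    """Score multisets reproducing the published SP calibration counts.

    572 negatives with cumulative counts {>= -0.5: 20, -1: 23, -2: 38,
    -3: 38, -4: 44}; 45 positives with one below every cutoff but -0.5
    (8 false negatives at -0.5).
    """
    neg_cum = [(-0.5, 20), (-1, 23), (-2, 38), (-3, 38), (-4, 44)]
    pos_fn = [(-0.5, 8), (-1, 1), (-2, 1), (-3, 1), (-4, 1)]
    return _scores_from_cumulative(neg_cum, 572), _scores_from_fn(pos_fn, 45)


def _scores_from_cumulative(cum, total):
    """Scores such that #{s >= c} equals each cumulative (c, count) pair."""
    out = []
    prev_cut, prev_count = None, 0
    for cut, count in cum:
        n_new = count - prev_count
        out.extend([cut + 0.1] * n_new)
        prev_cut, prev_count = cut, count
    out.extend([prev_cut - 50.0] * (total - prev_count))
    return out


def _scores_from_fn(fn, total):
    """Scores such that #{s < c} equals each false-negative (c, count) pair."""
    out = []
    cuts = [c for c, _ in fn]
    counts = [n for _, n in fn]
    out.extend([0.0] * (total - counts[0]))  # psi ceiling, above every cutoff
    for i in range(len(fn) - 1):
        out.extend([cuts[i] - 0.1] * (counts[i] - counts[i + 1]))
    out.extend([cuts[-1] - 10.0] * counts[-1])
    return out


def naive_positive_columns(msa, maskset, category: str, alpha: float):
    """Exhaustive per-column consensus reference for tiny alignments.

    Loops residue by residue, computes each predictor's binomial tail by
    rational summation, and marks a column positive when any predictor
    rejects at level alpha.
    """
    positives = []
    for j in range(1, msa.n_columns + 1):
        rejected_any = False
        for pid in maskset.predictors(category):
            n = 0
            k = 0
            for sid in msa.ids:
                pos = msa.col_to_pos(sid, j)
                if pos is None:
                    continue
                n += 1
                k += int(maskset.get(sid, pid).calls[pos - 1])
            if n > 0 and binomial_tail_by_summation(n, k) <= alpha:
                rejected_any = True
        positives.append(rejected_any)
    runs = []
    start = None
    for j, flag in enumerate(positives, 1):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(positives)))
    return positives, runs
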