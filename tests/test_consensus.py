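import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaudit.config import DetectConfig
from tmaudit.consensus import (
    ColumnStats,
    DetectedSegment,
    apply_cutoffs,
    audit_domain,
    binomial_tail,
    column_log_probability,
    column_probability,
    column_test,
    concatenate_tm_regions,
    delineate_segments,
    detect_segments,
    merge_tm_fragments,
    score_segment,
    sp_segment_span,
)
from tmaudit.synth import SynthSpec, make_alignment, make_masks

from .conftest import perfect_maskset
from .oracles import binomial_tail_by_summation, naive_positive_columns

LN_EPS = math.log(1e-4)


# ---------------------------------------------------------------------------
# column statistics


@pytest.mark.parametrize(
    "n, k, expected",
    [(5, 5, 0.03125), (4, 4, 0.0625), (7, 0, 1.0), (0, 0, 1.0), (10, 9, 11 / 1024)],
)
def test_binomial_tail_values(n, k, expected):
    assert binomial_tail(n, k) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("n, k", [(3, 4), (-1, 0), (2, -1)])
def test_binomial_tail_rejects_bad_input(n, k):
    with pytest.raises(ValueError):
        binomial_tail(n, k)


def test_binomial_tail_matches_summation_oracle_exhaustively():
    for n in range(0, 21):
        for k in range(0, n + 1):
            assert binomial_tail(n, k) == pytest.approx(
                binomial_tail_by_summation(n, k), rel=1e-10
            )


def test_binomial_tail_strictly_decreasing_in_k():
    for n in range(1, 21):
        tails = [binomial_tail(n, k) for k in range(n + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))


@pytest.mark.parametrize(
    "n, k, rejected, e_hat",
    [(5, 5, True, 5), (4, 4, False, 0), (10, 9, True, 9), (10, 8, False, 0)],
)
def test_column_test(n, k, rejected, e_hat):
    assert column_test(n, k, 0.05) == (rejected, e_hat)


def test_column_test_alpha_domain():
    with pytest.raises(ValueError):
        column_test(5, 5, alpha=0.0)


@pytest.mark.parametrize(
    "e_hat, n, eps, expected",
    [(5, 5, 1e-4, 1.0), (0, 8, 1e-4, 1e-4), (9, 10, 1e-4, 0.9)],
)
def test_column_probability(e_hat, n, eps, expected):
    assert column_probability(e_hat, n, eps) == pytest.approx(expected)


def test_column_log_probability():
    assert column_log_probability([1.0, 1.0, 1.0]) == 0.0
    assert column_log_probability([1e-4] * 5) == pytest.approx(5 * LN_EPS)
    assert column_log_probability([1.0, 0.5]) == pytest.approx(math.log(0.5))
    with pytest.raises(ValueError):
        column_log_probability([])


def test_column_stats_depth_gate():
    # depth <= 4 never rejects even with unanimous calls
    cfg = DetectConfig()
    stats = ColumnStats.from_counts(
        np.array([4, 5]), {"p": np.array([4, 5])}, "TM", cfg
    )
    assert not stats.rejected[0, 0] and stats.rejected[0, 1]
    assert not stats.positive[0] and stats.positive[1]
    assert stats.L[0] == pytest.approx(LN_EPS)
    assert stats.L[1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# segments


def stats_from_positive(positive):
    n = len(positive)
    cfg = DetectConfig()
    return ColumnStats(
        "TM", ["p"], np.full(n, 10), np.zeros((1, n)), np.ones((1, n)),
        np.zeros((1, n), bool), np.zeros((1, n)), np.full((1, n), 1.0),
        np.zeros(n), np.asarray(positive, bool), cfg,
    )


def test_delineate_segments():
    pos = np.zeros(25, bool)
    pos[2:9] = True  # columns 3..9
    pos[14:20] = True  # columns 15..20
    assert delineate_segments(stats_from_positive(pos)) == [(3, 9), (15, 20)]
    assert delineate_segments(stats_from_positive(np.zeros(5, bool))) == []
    single = np.zeros(5, bool)
    single[3] = True
    assert delineate_segments(stats_from_positive(single)) == [(4, 4)]


def union_k(runs_by_pred, n_cols):
    out = {}
    for pid, runs in runs_by_pred.items():
        v = np.zeros(n_cols, dtype=int)
        for s, e in runs:
            v[s - 1 : e] = 3  # any positive count
        out[pid] = v
    return out


def test_merge_fragments_bridged_by_union_run():
    # both raw runs sit inside one continuous union run of every predictor
    k = union_k({"a": [(8, 32)], "b": [(8, 32)]}, 40)
    groups = merge_tm_fragments([(10, 18), (22, 30)], k, 40)
    assert groups == [[(10, 18), (22, 30)]]


def test_merge_fragments_in_distinct_union_runs_stay_apart():
    k = union_k({"a": [(10, 18), (22, 30)], "b": [(10, 18), (22, 30)]}, 40)
    groups = merge_tm_fragments([(10, 18), (22, 30)], k, 40)
    assert groups == [[(10, 18)], [(22, 30)]]


def test_merge_single_run_unchanged():
    k = union_k({"a": [(5, 15)]}, 20)
    assert merge_tm_fragments([(6, 14)], k, 20) == [[(6, 14)]]


def test_merge_intersection_separates_overlapping_predictors():
    # predictor a bridges 10..30; predictor b separates two helices
    k = union_k({"a": [(10, 30)], "b": [(10, 18), (24, 30)]}, 40)
    groups = merge_tm_fragments([(11, 17), (25, 29)], k, 40)
    assert groups == [[(11, 17)], [(25, 29)]]


def test_score_segment_single_and_weighted():
    assert score_segment([np.array([-2.0, -4.0, -6.0])]) == pytest.approx(-4.0)
    frags = [np.full(2, -3.0), np.full(6, -7.0)]
    assert score_segment(frags) == pytest.approx(-6.0)
    assert score_segment([np.zeros(4)]) == 0.0
    with pytest.raises(ValueError):
        score_segment([])


def test_sp_segment_span_rule():
    L = np.zeros(30)
    seg = sp_segment_span([(2, 8), (12, 19)], L)
    assert (seg.start_col, seg.end_col) == (1, 19)
    seg2 = sp_segment_span([(1, 20)], L)
    assert (seg2.start_col, seg2.end_col) == (1, 20)


def test_sp_segment_span_score_is_mean_over_whole_span():
    # predicted columns score 0, the rest sit at the 2-predictor floor
    L = np.full(19, 2 * LN_EPS)
    predicted = [(2, 8), (12, 19)]
    for s, e in predicted:
        L[s - 1 : e] = 0.0
    seg = sp_segment_span(predicted, L)
    assert seg.score == pytest.approx(np.mean(L[:19]))


def seg(cat, start, end, score=0.0):
    return DetectedSegment(cat, start, end, [(start, end)], end - start + 1, score)


def test_concatenate_tm_regions_linker_rule():
    regions = concatenate_tm_regions([seg("TM", 30, 50), seg("TM", 89, 100)], 40)
    assert len(regions) == 1  # gap 38 < 40
    regions = concatenate_tm_regions([seg("TM", 30, 50), seg("TM", 91, 100)], 40)
    assert len(regions) == 2  # gap exactly 40
    assert len(concatenate_tm_regions([seg("TM", 5, 25)], 40)) == 1


def test_apply_cutoffs_inclusive():
    cfg = DetectConfig()
    segments = [
        seg("TM", 1, 5, -11.0),
        seg("TM", 10, 15, -12.5),
        seg("SP", 1, 8, -1.0),
    ]
    retained = apply_cutoffs(segments, cfg)
    assert [s.score for s in retained] == [-11.0, -1.0]
    assert segments[1].retained is False


# ---------------------------------------------------------------------------
# audit pipeline


def test_audit_recovers_perfect_planted_block():
    spec = SynthSpec(n_sequences=8, n_columns=60, segments=(("TM", (20, 40)),),
                     gap_rate=0.0, seed=1)
    msa = make_alignment(spec)
    masks = perfect_maskset(msa, {"TM": set(range(20, 41))})
    res = audit_domain(msa, masks, domain_id="perfect")
    tm = res.retained("TM")
    assert len(tm) == 1
    assert (tm[0].start_col, tm[0].end_col) == (20, 40)
    assert tm[0].score == pytest.approx(0.0)
    assert res.tm_problematic and not res.sp_problematic


def test_audit_all_zero_masks_not_problematic():
    spec = SynthSpec(n_sequences=8, n_columns=60, segments=(), gap_rate=0.0, seed=2)
    msa = make_alignment(spec)
    masks = perfect_maskset(msa, {})
    res = audit_domain(msa, masks)
    assert res.segments == [] and not res.problematic


@pytest.mark.parametrize("n_rows", [1, 2, 3, 4])
def test_audit_shallow_alignments_never_flag(n_rows):
    # the binomial gate: <= 4 sequences cannot reject even perfect masks
    spec = SynthSpec(n_sequences=n_rows, n_columns=50,
                     segments=(("TM", (10, 30)),), gap_rate=0.0, seed=3)
    msa = make_alignment(spec)
    masks = perfect_maskset(msa, {"TM": set(range(10, 31))})
    res = audit_domain(msa, masks)
    assert res.segments == []


def test_audit_row_permutation_invariance(planted_fixture):
    spec, msa, masks = planted_fixture
    res = audit_domain(msa, masks)
    from tmaudit.msa import DomainAlignment

    perm = DomainAlignment(list(zip(msa.ids, msa.rows))[::-1])
    res2 = audit_domain(perm, masks)
    assert res.to_frame().equals(res2.to_frame())


def test_psi_bounds(planted_fixture):
    spec, msa, masks = planted_fixture
    res = audit_domain(msa, masks)
    for s in res.segments:
        D = masks.D(s.category)
        assert D * LN_EPS - 1e-9 <= s.score <= 0.0


def test_delineation_matches_naive_reference_on_small_alignments():
    # exhaustive cross-check on alignments of <= 8 columns
    for seed in range(6):
        spec = SynthSpec(n_sequences=7, n_columns=8,
                         segments=(("TM", (3, 6)),), gap_rate=0.1,
                         sensitivity=0.8, fp_rate=0.1, seed=seed)
        msa = make_alignment(spec)
        masks = make_masks(msa, spec)
        stats, _ = detect_segments(msa, masks, "TM")
        naive_pos, naive_runs = naive_positive_columns(msa, masks, "TM", 0.05)
        assert list(stats.positive) == naive_pos
        assert delineate_segments(stats) == naive_runs


def test_domain_score_is_weighted_over_retained_segments():
    spec = SynthSpec(n_sequences=8, n_columns=100,
                     segments=(("TM", (10, 19)), ("TM", (70, 99))),
                     gap_rate=0.0, seed=4)
    msa = make_alignment(spec)
    masks = perfect_maskset(
        msa, {"TM": set(range(10, 20)) | set(range(70, 100))}
    )
    res = audit_domain(msa, masks)
    segs = res.retained("TM")
    assert len(segs) == 2
    w = np.array([len(s.scored_columns) for s in segs], float)
    psi = np.array([s.score for s in segs])
    assert res.domain_score("TM") == pytest.approx((w * psi).sum() / w.sum())
    # the two helices are 50 columns apart: >= 40, so two TM regions
    assert len(res.tm_regions()) == 2


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(5, 30), st.integers(0, 30))
def test_monotonicity_more_calls_never_lower_L(n, extra):
    cfg = DetectConfig()
    k1 = min(n, extra)
    k2 = min(n, k1 + 1)
    s1 = ColumnStats.from_counts(np.array([n]), {"p": np.array([k1])}, "TM", cfg)
    s2 = ColumnStats.from_counts(np.array([n]), {"p": np.array([k2])}, "TM", cfg)
    assert s2.L[0] >= s1.L[0] - 1e-12


def test_summary_mentions_parameters(planted_fixture):
    _, msa, masks = planted_fixture
    res = audit_domain(msa, masks, domain_id="demo")
    text = res.summary()
    assert "alpha=0.05" in text and "tm_cutoff=-12.0" in text and "demo" in text
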