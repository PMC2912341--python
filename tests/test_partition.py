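import numpy as np
import pytest

from tmaudit.hmm import AMINO, ProfileHMM, viterbi_hmmls
from tmaudit.partition import (
    GatheringModel,
    ModelRegionMask,
    ScorePartition,
    classify_hit,
    gathering_partition,
    partition_score,
    read_region_mask,
    rescore_without_region,
    score_and_partition,
    submodel_without_region,
)
from tmaudit.synth import ProfileSpec, make_profile

from .oracles import brute_force_hmmls, random_profile, random_sequence


def fixed_hmm(emissions, flagged=(), trans_mm=0.0, ga=20.0):
    """Model whose Viterbi path on the favoured sequence is all-match with
    hand-computable terms: node s strongly favours the s-th residue of the
    favoured sequence with the given emission score."""
    M = len(emissions)
    match = np.full((M, 21), -50.0)
    favored = "ACDEFGHIKLMNPQRSTVWY"[:M]
    for s, e in enumerate(emissions):
        match[s, AMINO.index(favored[s])] = e
    trans = np.tile(
        np.array([trans_mm, -30.0, -30.0, -5.0, -5.0, -5.0, -5.0]), (M, 1)
    )
    hmm = ProfileHMM(
        M=M, match_emit=match, insert_emit=np.zeros((M, 21)), trans=trans,
        entry_m=0.0, entry_d=-50.0, exit_m=0.0, exit_d=-50.0, ga=ga,
        evd_mu=0.0, evd_lambda=0.5,
    )
    return hmm, favored


def test_region_mask_construction_and_validation():
    mask = ModelRegionMask.from_ranges(10, [(3, 5), (8, 8)])
    assert mask.nodes == frozenset({3, 4, 5, 8})
    assert mask.complement == frozenset({1, 2, 6, 7, 9, 10})
    with pytest.raises(ValueError):
        ModelRegionMask.from_ranges(10, [(9, 12)])


def test_region_mask_tsv_reader(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text(
        "domain_id\tcategory\tstart_node\tend_node\n"
        "PFX\tTM\t102\t150\nPFX\tTM\t160\t177\n"
    )
    masks = read_region_mask(path, 200)
    assert masks["PFX"].nodes == frozenset(range(102, 151)) | frozenset(
        range(160, 178)
    )


def test_partition_empty_and_full_masks():
    hmm, seq = fixed_hmm([1.0, 2.0, 3.0, 4.0])
    empty = ModelRegionMask.from_ranges(4, [])
    part = score_and_partition(hmm, empty, seq)
    assert part.S_TM == 0.0
    assert part.S_NG + part.S_const == pytest.approx(part.S_total)
    full = ModelRegionMask.from_ranges(4, [(1, 4)])
    part2 = score_and_partition(hmm, full, seq)
    assert part2.S_NG == 0.0


def test_partition_hand_summed_terms():
    # nodes 3-4 flagged; all-match path on the favoured 4-residue sequence
    hmm, seq = fixed_hmm([1.0, 2.0, 3.0, 4.0], trans_mm=-0.25)
    mask = ModelRegionMask.from_ranges(4, [(3, 4)])
    aln = viterbi_hmmls(hmm, seq)
    assert [s for s, _, _ in aln.path] == ["M", "M", "M", "M"]
    part = partition_score(aln, hmm, mask, seq)
    # S_NG: emissions at nodes 1,2 plus transitions departing nodes 1,2
    assert part.S_NG == pytest.approx(1.0 + 2.0 - 0.25 - 0.25)
    # S_TM: emissions at nodes 3,4 plus the transition departing node 3
    assert part.S_TM == pytest.approx(3.0 + 4.0 - 0.25)
    # S_const: entry + exit
    assert part.S_const == pytest.approx(0.0)
    assert part.S_total == pytest.approx(aln.total_score)


def test_partition_additivity_is_validated():
    with pytest.raises(ValueError):
        ScorePartition(10.0, 5.0, 3.0, 1.0)


def test_partition_additivity_fuzz():
    rng = np.random.default_rng(99)
    for _ in range(60):
        M = int(rng.integers(2, 9))
        hmm = random_profile(rng, M)
        seq = random_sequence(rng, int(rng.integers(2, 16)))
        lo = int(rng.integers(1, M + 1))
        hi = int(rng.integers(lo, M + 1))
        mask = ModelRegionMask.from_ranges(M, [(lo, hi)])
        part = score_and_partition(hmm, mask, seq)
        assert abs(
            part.S_NG + part.S_TM + part.S_const - part.S_total
        ) < 1e-9


# ---------------------------------------------------------------------------
# gathering partition


def test_gathering_partition_single_seed_arithmetic():
    # engineered so that S_const=0, S_NG=30, S_TM=10 at GA=20
    hmm, seq = fixed_hmm([30.0, 10.0], flagged=(2,), trans_mm=0.0, ga=20.0)
    mask = ModelRegionMask.from_ranges(2, [(2, 2)])
    gp = gathering_partition(hmm, [seq], mask)
    row = gp.seed_table.iloc[0]
    assert (row["S_NG"], row["S_TM"], row["S_const"]) == (30.0, 10.0, 0.0)
    assert row["c"] == pytest.approx(0.5)
    assert gp.G_TM == pytest.approx(5.0)
    assert gp.G_NG == pytest.approx(15.0)


def test_gathering_partition_empty_mask_returns_ga():
    hmm, seq = fixed_hmm([5.0, 5.0, 5.0], ga=7.0)
    mask = ModelRegionMask.from_ranges(3, [])
    gp = gathering_partition(hmm, [seq, seq], mask)
    assert gp.G_TM == 0.0
    assert gp.G_NG == 7.0  # exactly GA


def test_gathering_partition_identical_seeds_idempotent():
    hmm, seq = fixed_hmm([8.0, 2.0], ga=6.0)
    mask = ModelRegionMask.from_ranges(2, [(2, 2)])
    one = gathering_partition(hmm, [seq], mask)
    three = gathering_partition(hmm, [seq, seq, seq], mask)
    assert three.G_NG == pytest.approx(one.G_NG)
    assert three.G_TM == pytest.approx(one.G_TM)


def test_gathering_partition_per_seed_identity(profile_fixture):
    fx = profile_fixture
    gp = gathering_partition(fx.hmm, fx.seeds, fx.region_mask)
    for _, row in gp.seed_table.iterrows():
        recon = row["c"] * (row["S_NG"] + row["S_TM"]) + row["S_const"]
        assert recon == pytest.approx(gp.GA, abs=1e-9)


def test_gathering_partition_degenerate_seed_excluded():
    # all-X sequence on a zero-emission model: every path term is zero
    M = 2
    hmm = ProfileHMM(
        M=M, match_emit=np.zeros((M, 21)), insert_emit=np.zeros((M, 21)),
        trans=np.zeros((M, 7)), entry_m=0.0, exit_m=0.0, ga=5.0,
    )
    mask = ModelRegionMask.from_ranges(M, [(2, 2)])
    with pytest.warns(UserWarning, match="excluded"):
        with pytest.raises(ValueError, match="all seeds excluded"):
            gathering_partition(hmm, ["XX"], mask)


def test_gathering_partition_requires_ga():
    hmm, seq = fixed_hmm([1.0, 1.0])
    hmm.ga = None
    mask = ModelRegionMask.from_ranges(2, [(2, 2)])
    with pytest.raises(ValueError, match="gathering score"):
        gathering_partition(hmm, [seq], mask)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "s_total, s_ng, verdict",
    [
        (25.0, 18.0, "true_positive"),
        (25.0, 5.0, "unjustified"),
        (15.0, 18.0, "false_negative"),
        (15.0, 5.0, "no_call"),
        (20.0, 10.0, "true_positive"),  # ties are inclusive on both axes
    ],
)
def test_classify_hit_quadrants(s_total, s_ng, verdict):
    part = ScorePartition(s_total, s_ng, s_total - s_ng, 0.0)
    assert classify_hit(part, GA=20.0, G_NG=10.0).verdict == verdict


def test_classify_hit_exactly_one_verdict_everywhere():
    rng = np.random.default_rng(3)
    from tmaudit.partition import VERDICTS

    for _ in range(200):
        s_ng, s_tm, s_c = rng.normal(0, 20, 3)
        part = ScorePartition(s_ng + s_tm + s_c, s_ng, s_tm, s_c)
        v = classify_hit(part, 5.0, 2.0).verdict
        assert v in VERDICTS


# ---------------------------------------------------------------------------
# rescoring without the SP/TM region


def test_rescore_empty_mask_is_identity(profile_fixture):
    fx = profile_fixture
    seq = fx.members[0]
    empty = ModelRegionMask.from_ranges(fx.hmm.M, [])
    score, _ = rescore_without_region(fx.hmm, empty, seq)
    assert score == pytest.approx(viterbi_hmmls(fx.hmm, seq).total_score)


def test_rescore_removing_penalising_block_raises_score():
    fx = make_profile(ProfileSpec(seed=5))
    # globular-only sequence: the flagged TM block can only penalise it
    globular_only = fx.motif[: fx.hmm.M - len(fx.region_mask.nodes)]
    orig = viterbi_hmmls(fx.hmm, globular_only).total_score
    rescored, ev = rescore_without_region(
        fx.hmm, fx.region_mask, globular_only, db_size=10_000
    )
    assert rescored > orig
    assert ev is not None and 0 <= ev <= 10_000


def test_rescore_matches_brute_force_on_manual_submodel():
    rng = np.random.default_rng(21)
    hmm = random_profile(rng, 4)
    mask = ModelRegionMask.from_ranges(4, [(2, 3)])
    sub = submodel_without_region(hmm, mask)
    assert sub.M == 2
    # splice keeps the donor node's outgoing transitions
    assert np.allclose(sub.trans[0], hmm.trans[0])
    for seq in ("MKVLA", "GG", "IIVVLLFF"):
        score, _ = rescore_without_region(hmm, mask, seq)
        assert score == pytest.approx(brute_force_hmmls(sub, seq), abs=1e-9)


def test_rescore_all_nodes_flagged_is_an_error():
    hmm, seq = fixed_hmm([1.0, 1.0])
    mask = ModelRegionMask.from_ranges(2, [(1, 2)])
    with pytest.raises(ValueError, match="all nodes flagged"):
        rescore_without_region(hmm, mask, seq)


def test_rescore_without_evd_cannot_report_evalue():
    hmm, seq = fixed_hmm([1.0, 1.0])
    hmm.evd_mu = hmm.evd_lambda = None
    mask = ModelRegionMask.from_ranges(2, [(2, 2)])
    with pytest.raises(ValueError, match="EVD"):
        rescore_without_region(hmm, mask, seq, db_size=100)


# ---------------------------------------------------------------------------
# model/results front-end


def test_gathering_results_summary_and_se(profile_fixture):
    fx = profile_fixture
    res = GatheringModel(fx.hmm, fx.region_mask, fx.seeds).fit()
    assert res.G_NG == pytest.approx(res.GA - res.G_TM)
    assert res.G_TM_se > 0
    text = res.summary()
    assert "G_NG" in text and "seeds used: 12" in text
    frame = res.classify_many({"m": fx.members[0], "d": fx.decoys[0]})
    assert list(frame["sequence_id"]) == ["m", "d"]
    assert set(frame["verdict"]) <= {
        "true_positive", "unjustified", "false_negative", "no_call"
    }
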