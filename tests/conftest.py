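import numpy as np
import pytest

from tmaudit.config import DetectConfig
from tmaudit.masks import MaskSet, PredictionMask
from tmaudit.msa import DomainAlignment
from tmaudit.synth import ProfileSpec, SynthSpec, make_alignment, make_masks, make_profile


@pytest.fixture
def tiny_msa() -> DomainAlignment:
    return DomainAlignment(
        [
            ("s1", "MKV-LLIP"),
            ("s2", "MRVA-LIP"),
            ("s3", "MKVALL-P"),
        ]
    )


def perfect_maskset(msa: DomainAlignment, spans, roster=None) -> MaskSet:
    """Masks calling exactly the residues whose columns lie in `spans`.

    spans: dict category -> set of 1-based columns.
    """
    roster = roster or {"TM": [f"tm{i}" for i in range(1, 6)], "SP": ["sp1", "sp2"]}
    ms = MaskSet(roster=roster)
    for cat, preds in roster.items():
        cols = spans.get(cat, set())
        for pid in preds:
            for sid in msa.ids:
                n = msa.ungapped_length(sid)
                calls = np.zeros(n, dtype=np.uint8)
                for p in range(1, n + 1):
                    if msa.pos_to_col(sid, p) in cols:
                        calls[p - 1] = 1
                ms.add(PredictionMask(sid, pid, cat, calls))
    return ms


@pytest.fixture
def config() -> DetectConfig:
    return DetectConfig()


@pytest.fixture(scope="session")
def planted_spec() -> SynthSpec:
    # reference study conditions: 25 rows, 5 TM + 2 SP predictors,
    # sensitivity 0.9, per-residue FP rate 0.05, fixed seed
    return SynthSpec(
        n_sequences=25,
        n_columns=120,
        segments=(("TM", (45, 66)), ("SP", (1, 18))),
        gap_rate=0.05,
        sensitivity=0.9,
        fp_rate=0.05,
        seed=20100729,
    )


@pytest.fixture(scope="session")
def planted_fixture(planted_spec):
    msa = make_alignment(planted_spec)
    masks = make_masks(msa, planted_spec)
    return planted_spec, msa, masks


@pytest.fixture(scope="session")
def profile_fixture():
    return make_profile(ProfileSpec(seed=20100729))
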