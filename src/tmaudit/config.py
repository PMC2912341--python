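"""Detection configuration: significance level, probability floor, cutoffs."""

from __future__ import annotations

import io
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DetectConfig:
    """Tunable parameters of the consensus SP/TM detector.

    alpha
        Significance level of the per-column one-sided binomial test
        (null p = 1/2).  At 0.05, alignments of four or fewer sequences can
        never reject, so detection requires depth >= 5.
    epsilon
        Floor for the estimated column probability, keeping logarithms
        finite when a predictor's null is not rejected.
    tm_cutoff, sp_cutoff
        Retention thresholds on the average log probability psi of a
        detected segment (natural log); segments with psi >= cutoff are
        retained.  Defaults are the calibrated values with false-positive
        rates just under 5% (4.67% TM, 4.02% SP).
    linker_max
        Adjacent retained TM helices separated by fewer than this many
        columns are concatenated into one TM region (smallest globular
        domains are ~40 residues, so shorter spacers are mere linkers).
    """

    alpha: float = 0.05
    epsilon: float = 1e-4
    tm_cutoff: float = -12.0
    sp_cutoff: float = -1.0
    linker_max: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if self.linker_max < 0:
            raise ValueError("linker_max must be non-negative")

    def cutoff(self, category: str) -> float:
        if category == "TM":
            return self.tm_cutoff
        if category == "SP":
            return self.sp_cutoff
        raise ValueError(f"unknown category {category!r}")

    def replace(self, **kw) -> "DetectConfig":
        return replace(self, **kw)


_FLOATS = {"alpha", "epsilon", "tm_cutoff", "sp_cutoff"}
_INTS = {"linker_max"}


def read_config(source) -> DetectConfig:
    """Parse a plain-text ``key = value`` config file (# comments allowed)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    kw: dict[str, float | int] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key in _FLOATS:
            kw[key] = float(val)
        elif key in _INTS:
            kw[key] = int(val)
        else:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
    return DetectConfig(**kw)
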