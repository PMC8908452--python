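"""Clonal heterogeneity via Shannon diversity and true diversity (Hill number).

Cells sharing a copy-number signature form a clone. At the individual level a
signature is the full tuple of signal counts over the six probed chromosomes;
at the chromosome level it is the single count for that chromosome. Shannon
diversity H = -sum p_i ln p_i over clone abundances uses the natural
logarithm, so true diversity TD = exp(H) is the effective number of equally
abundant clones. CH classes follow the thresholds: TD < 1.5 low,
1.5 <= TD <= 2 intermediate, TD > 2 high.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fish import FishCountMatrix

__all__ = [
    "CH_LOW_BOUND",
    "CH_HIGH_BOUND",
    "CloneDistribution",
    "DiversityResult",
    "clone_distribution",
    "shannon",
    "true_diversity",
    "classify_ch",
    "diversity_of",
    "chromosome_mean_td",
]

CH_LOW_BOUND = 1.5
CH_HIGH_BOUND = 2.0


@dataclass(frozen=True)
class CloneDistribution:
    """Distinct copy-number signatures and their empirical abundances."""

    signatures: tuple
    abundances: tuple[float, ...]
    n_cells: int

    def __post_init__(self) -> None:
        if len(self.signatures) != len(self.abundances):
            raise ValueError("signatures and abundances differ in length")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be strictly positive")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class DiversityResult:
    sdi: float  # Shannon index, nats
    td: float  # exp(sdi): effective clone number
    ch_class: str  # "low" | "intermediate" | "high"
    n_clones: int


def clone_distribution(m: FishCountMatrix, level: str = "individual") -> CloneDistribution:
    """Group cells into clones.

    ``level="individual"`` uses the full 6-tuple signature; ``level="chr8"``
    (any probe label) uses that chromosome's count alone.
    """
    if m.n_nuclei == 0:
        raise ValueError("empty count matrix")
    if level == "individual":
        keys = [tuple(int(v) for v in row) for row in m.counts]
    elif level in m.probes:
        j = m.probes.index(level)
        keys = [int(v) for v in m.counts[:, j]]
    else:
        raise ValueError(f"level must be 'individual' or one of {m.probes}, got {level!r}")
    counts = Counter(keys)
    sigs = tuple(sorted(counts, key=lambda s: (-counts[s], str(s))))
    n = m.n_nuclei
    abund = tuple(counts[s] / n for s in sigs)
    return CloneDistribution(signatures=sigs, abundances=abund, n_cells=n)


def shannon(d: CloneDistribution) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    return float(sps.entropy(np.asarray(d.abundances)))


def true_diversity(sdi: float) -> float:
    """True diversity (Hill number of order 1): TD = exp(H)."""
    if sdi < 0:
        raise ValueError("sdi must be nonnegative")
    return math.exp(sdi)


def classify_ch(td: float) -> str:
    """CH class from true diversity: <1.5 low, [1.5, 2] intermediate, >2 high."""
    if td < 1.0 - 1e-12:
        raise ValueError("true diversity cannot be below 1")
    if td < CH_LOW_BOUND:
        return "low"
    if td <= CH_HIGH_BOUND:
        return "intermediate"
    return "high"


def diversity_of(m: FishCountMatrix, level: str = "individual") -> DiversityResult:
    """Convenience: clone distribution -> SDI -> TD -> CH class."""
    d = clone_distribution(m, level=level)
    h = shannon(d)
    td = true_diversity(h)
    return DiversityResult(sdi=h, td=td, ch_class=classify_ch(td), n_clones=len(d.signatures))


def chromosome_mean_td(m: FishCountMatrix) -> float:
    """Mean over probes of the per-chromosome (marginal) true diversity."""
    return float(np.mean([diversity_of(m, level=p).td for p in m.probes]))
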