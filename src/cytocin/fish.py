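"""Chromosomal-instability (CIN) scoring from centromeric-FISH signal counts.

Six chromosome-enumeration probes (chromosomes 2, 3, 8, 11, 15 and 17) give,
for every scored interphase nucleus, an integer signal count per chromosome.
For each chromosome the modal count of the cell population is the reference;
the CIN of that chromosome is the percentage of nuclei whose count deviates
from the mode. An individual's CIN is the unweighted mean of the six
per-chromosome percentages, and the individual is classed as high-CIN when
that mean is >= 25%, low-CIN otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, kruskal_wallis

__all__ = [
    "DEFAULT_PROBES",
    "CIN_HIGH_THRESHOLD",
    "MIN_NUCLEI",
    "FishCountMatrix",
    "CinProfile",
    "modal_count",
    "cin_per_chromosome",
    "cin_individual",
    "chromosome_stability",
    "read_fish_counts",
    "write_fish_counts",
]

DEFAULT_PROBES: tuple[str, ...] = ("chr2", "chr3", "chr8", "chr11", "chr15", "chr17")
CIN_HIGH_THRESHOLD = 25.0  # percent; >= is high
MIN_NUCLEI = 100  # headline analyses expect at least this many scored nuclei


@dataclass(frozen=True)
class FishCountMatrix:
    """Per-nucleus signal counts for one individual (nuclei x probes)."""

    individual_id: str
    counts: np.ndarray
    probes: tuple[str, ...] = DEFAULT_PROBES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D nuclei x probes array")
        if counts.shape[1] != len(self.probes):
            raise ValueError(
                f"counts has {counts.shape[1]} columns for {len(self.probes)} probes"
            )
        if (counts < 0).any():
            raise ValueError("signal counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class CinProfile:
    """Per-chromosome CIN percentages and the low/high class for one individual."""

    individual_id: str
    probes: tuple[str, ...]
    per_chromosome_cin: tuple[float, ...]
    modal_counts: tuple[int, ...]
    mean_cin: float
    cin_class: str  # "low" | "high"
    n_nuclei: int
    low_n_warning: bool = False

    def as_dict(self) -> dict:
        d = {"individual_id": self.individual_id, "n_nuclei": self.n_nuclei}
        d.update({p: c for p, c in zip(self.probes, self.per_chromosome_cin)})
        d.update(
            mean_cin=self.mean_cin, cin_class=self.cin_class,
            low_n_warning=self.low_n_warning,
        )
        return d


def modal_count(counts: Sequence[int]) -> int:
    """Most frequent signal count; ties prefer the value nearest 2, then smaller."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("modal_count needs a non-empty count vector")
    freq = np.bincount(counts)
    best = freq.max()
    candidates = np.flatnonzero(freq == best)
    return int(min(candidates, key=lambda v: (abs(v - 2), v)))


def cin_per_chromosome(
    counts: Sequence[int], modal: int, drop_zero: bool = False
) -> float:
    """Percentage of nuclei whose count deviates from the modal count.

    ``drop_zero=True`` excludes zero-signal nuclei (treated as hybridization
    failures) from both numerator and denominator; by default they count as
    deviant like any other non-modal value.
    """
    counts = np.asarray(counts, dtype=int)
    if drop_zero and modal != 0:
        counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no nuclei left to score")
    return float(100.0 * np.count_nonzero(counts != modal) / counts.size)


def cin_individual(m: FishCountMatrix, drop_zero: bool = False) -> CinProfile:
    """CIN profile of one individual: six per-chromosome CINs, their mean,
    and the low/high class (boundary 25% inclusive for high)."""
    if len(m.probes) != len(DEFAULT_PROBES):
        raise ValueError(f"expected {len(DEFAULT_PROBES)} probe columns, got {len(m.probes)}")
    low_n = m.n_nuclei < MIN_NUCLEI
    if low_n:
        warnings.warn(
            f"{m.individual_id}: only {m.n_nuclei} nuclei scored "
            f"(headline analyses expect >= {MIN_NUCLEI})",
            stacklevel=2,
        )
    modals = tuple(modal_count(m.counts[:, j]) for j in range(len(m.probes)))
    cins = tuple(
        cin_per_chromosome(m.counts[:, j], modals[j], drop_zero=drop_zero)
        for j in range(len(m.probes))
    )
    mean = float(np.mean(cins))
    return CinProfile(
        individual_id=m.individual_id,
        probes=m.probes,
        per_chromosome_cin=cins,
        modal_counts=modals,
        mean_cin=mean,
        cin_class="high" if mean >= CIN_HIGH_THRESHOLD else "low",
        n_nuclei=m.n_nuclei,
        low_n_warning=low_n,
    )


def chromosome_stability(
    profiles: Sequence[CinProfile],
) -> tuple[list[tuple[str, float]], TestResult]:
    """Rank chromosomes by mean CIN across individuals (most stable first)
    and test for per-chromosome differences with Kruskal-Wallis."""
    if len(profiles) < 2:
        raise ValueError("chromosome_stability requires at least 2 individuals")
    probes = profiles[0].probes
    if len(probes) < 2:
        raise ValueError("chromosome_stability requires at least 2 chromosomes")
    mat = np.array([p.per_chromosome_cin for p in profiles])  # individuals x probes
    result = kruskal_wallis([mat[:, j] for j in range(mat.shape[1])])
    means = mat.mean(axis=0)
    order = np.argsort(means, kind="stable")
    ranking = [(probes[j], float(means[j])) for j in order]
    return ranking, result


def read_fish_counts(path) -> list[FishCountMatrix]:
    """Read the FISH TSV (individual_id, nucleus_id, chr2..chr17) into matrices."""
    df = pd.read_csv(path, sep="\t")
    missing = ({"individual_id", "nucleus_id"} | set(DEFAULT_PROBES)) - set(df.columns)
    if missing:
        raise ValueError(f"FISH table missing columns: {sorted(missing)}")
    out = []
    for ind, sub in df.groupby("individual_id", sort=True):
        out.append(
            FishCountMatrix(
                individual_id=str(ind),
                counts=sub[list(DEFAULT_PROBES)].to_numpy(dtype=int),
            )
        )
    return out


def write_fish_counts(matrices: Sequence[FishCountMatrix], path) -> None:
    """Write matrices in the FISH TSV schema consumed by :func:`read_fish_counts`."""
    frames = []
    for m in matrices:
        sub = pd.DataFrame(m.counts, columns=list(m.probes))
        sub.insert(0, "nucleus_id", [f"n{i+1}" for i in range(m.n_nuclei)])
        sub.insert(0, "individual_id", m.individual_id)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
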