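"""Synthetic cohort generator with known ground truth.

Two generators stand in for the study's unpublished raw data:

* **FISH**: each individual is a mixture of clones. A clone is a 6-tuple of
  integer copy counts for chromosomes 2, 3, 8, 11, 15, 17; each nucleus draws
  a clone by frequency and then per-probe technical noise is applied (a
  dropout that misses a true signal, a split that adds a spurious one).
  Per-individual, per-chromosome deviant-cell fractions are realised through
  *nested* clones — chromosomes ordered by instability, clone k deviating on
  the top-k of them — which yields exact marginal deviant fractions with at
  most seven clones and resembles stepwise clonal evolution. Group-level
  defaults target the observed CIN distributions of the motivating cohort
  (mean 34.57% +/- 6.03 exposed, 6.48% +/- 3.13 unexposed) after accounting
  for the noise floor.

* **Karyotypes**: per metaphase, the number of events in each aberration
  category is Poisson with a category rate; chromosomes and bands are drawn
  from a fixed catalog of major bands; optional clonal injections copy a
  given aberration verbatim into a set number of metaphases of one
  individual. Default rates are the motivating cohort's group event totals
  divided by its group metaphase totals.

All randomness flows from one root ``numpy`` generator seeded explicitly;
identical seed and configuration give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .fish import DEFAULT_PROBES, FishCountMatrix
from .iscn import AUTOSOMES, MetaphaseRecord, format_aberration, parse_aberration

__all__ = [
    "CloneSpec",
    "NoiseModel",
    "GroupFishParams",
    "CohortConfig",
    "CohortBundle",
    "KaryotypeRateModel",
    "KaryotypeSimResult",
    "DEFAULT_CHROMOSOME_WEIGHTS",
    "BAND_CATALOG",
    "nested_clones",
    "simulate_fish_individual",
    "simulate_cohort",
    "default_karyotype_model",
    "simulate_karyotypes",
    "load_config",
]

#: relative instability of the six probed chromosomes (mean 1); chromosomes 8
#: and 17 are the stable pair in both groups of the motivating cohort
DEFAULT_CHROMOSOME_WEIGHTS: tuple[float, ...] = (1.25, 1.20, 0.50, 1.20, 1.25, 0.60)

_DIPLOID = (2, 2, 2, 2, 2, 2)


@dataclass(frozen=True)
class CloneSpec:
    """One clone: a copy-count signature and its population frequency."""

    signature: tuple[int, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.signature) != len(DEFAULT_PROBES):
            raise ValueError("signature must have one count per probe")
        if any(not 0 <= c <= 6 for c in self.signature):
            raise ValueError("copy counts must be in 0..6")
        if not 0 < self.frequency <= 1:
            raise ValueError("clone frequency must be in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Per-probe, per-nucleus technical noise: dropout then split."""

    p_dropout: float = 0.015
    p_split: float = 0.01

    def __post_init__(self) -> None:
        for name in ("p_dropout", "p_split"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")

    @property
    def diploid_deviation_rate(self) -> float:
        """Probability noise alone makes a diploid probe read non-2."""
        pd_, ps = self.p_dropout, self.p_split
        return 1.0 - ((1 - pd_) ** 2 * (1 - ps) + 2 * pd_ * (1 - pd_) * ps)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def nested_clones(
    deviant_fractions: Sequence[float], rng: np.random.Generator
) -> list[CloneSpec]:
    """Build a nested clone list with the given per-chromosome deviant fractions.

    Chromosomes are sorted by fraction; the k-th clone deviates on the k most
    unstable chromosomes and has frequency f(k) - f(k+1), the diploid clone
    taking the rest. Deviant copy counts alternate between 3 and 1 across
    clones so that no single non-diploid count can overtake the mode.
    """
    f = np.clip(np.asarray(deviant_fractions, dtype=float), 0.0, 1.0)
    if len(f) != len(DEFAULT_PROBES):
        raise ValueError("need one deviant fraction per probe")
    order = np.argsort(-f, kind="stable")
    sorted_f = f[order]
    clones: list[CloneSpec] = []
    boundaries = np.append(sorted_f, 0.0)
    for k in range(1, len(f) + 1):
        freq = boundaries[k - 1] - boundaries[k]
        if freq <= 1e-12:
            continue
        sig = list(_DIPLOID)
        deviant_value = 3 if (len(clones) % 2 == 0) else 1
        for j in order[:k]:
            sig[j] = deviant_value
        clones.append(CloneSpec(signature=tuple(sig), frequency=float(freq)))
    base = 1.0 - sum(c.frequency for c in clones)
    if base > 1e-12:
        clones.insert(0, CloneSpec(signature=_DIPLOID, frequency=float(base)))
    # normalise away accumulated float error
    total = sum(c.frequency for c in clones)
    return [replace(c, frequency=c.frequency / total) for c in clones]


def simulate_fish_individual(
    clones: Sequence[CloneSpec],
    noise: NoiseModel,
    n_nuclei: int,
    seed,
    individual_id: str = "S1",
) -> FishCountMatrix:
    """Draw nuclei from a clone mixture and apply per-probe technical noise."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    freqs = np.array([c.frequency for c in clones], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6 or (freqs <= 0).any():
        raise ValueError("clone frequencies must be positive and sum to 1")
    rng = _as_rng(seed)
    sig = np.array([c.signature for c in clones], dtype=int)
    idx = rng.choice(len(clones), size=n_nuclei, p=freqs / freqs.sum())
    counts = sig[idx]
    dropped = rng.binomial(counts, noise.p_dropout)
    split = rng.binomial(1, noise.p_split, size=counts.shape)
    return FishCountMatrix(individual_id=individual_id, counts=counts - dropped + split)


@dataclass(frozen=True)
class GroupFishParams:
    """Between-individual distribution of the observed CIN target (percent)."""

    mean_cin: float
    sd_cin: float
    chromosome_weights: tuple[float, ...] = DEFAULT_CHROMOSOME_WEIGHTS
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass(frozen=True)
class CohortConfig:
    exposed: GroupFishParams = field(
        default_factory=lambda: GroupFishParams(*reference.CIN_SUMMARY["exposed"])
    )
    unexposed: GroupFishParams = field(
        default_factory=lambda: GroupFishParams(*reference.CIN_SUMMARY["unexposed"])
    )
    n_per_group: int = reference.N_PER_GROUP
    n_nuclei: int = 100


@dataclass(frozen=True)
class CohortBundle:
    """Simulated cohort: FISH matrices keyed by individual, metadata, truth."""

    fish: dict[str, FishCountMatrix]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig
    seed: int | None = None


def _simulate_group_fish(
    params: GroupFishParams,
    n: int,
    n_nuclei: int,
    prefix: str,
    rng: np.random.Generator,
) -> tuple[dict[str, FishCountMatrix], list[dict]]:
    nu = params.noise.diploid_deviation_rate
    w = np.asarray(params.chromosome_weights, dtype=float)
    fish: dict[str, FishCountMatrix] = {}
    truth_rows: list[dict] = []
    for i in range(n):
        ind = f"{prefix}{i + 1}"
        t_i = float(np.clip(rng.normal(params.mean_cin, params.sd_cin) / 100.0, 0.0, 0.55))
        t_ic = np.clip(t_i * w, 0.0, 0.60)
        # noise correction: observed deviance ~ f + (1-f)*nu
        f_ic = np.clip((t_ic - nu) / (1.0 - nu), 0.0, 1.0)
        clones = nested_clones(f_ic, rng)
        fish[ind] = simulate_fish_individual(
            clones, params.noise, n_nuclei, rng, individual_id=ind
        )
        row = {
            "individual_id": ind,
            "target_cin_pct": 100.0 * float(np.mean(t_ic)),
            "clone_deviant_mean_pct": 100.0 * float(np.mean(f_ic)),
        }
        row.update({f"f_{p}": float(v) for p, v in zip(DEFAULT_PROBES, f_ic)})
        truth_rows.append(row)
    return fish, truth_rows


def _group_metadata(
    group: str, n: int, prefix: str, rng: np.random.Generator
) -> list[dict]:
    gi = 0 if group == "exposed" else 1
    age_mean, age_sd = reference.AGE_MEAN_SD[gi]
    n_male, _ = reference.SEX_MALE_FEMALE[gi]
    n_male = min(n_male, n)
    smokers = set(rng.choice(n, size=min(reference.SMOKERS[gi], n), replace=False))
    drinkers = set(rng.choice(n, size=min(reference.DRINKERS[gi], n), replace=False))
    mu, sd = reference.EXPOSURE_MONTHS_MEAN_SD
    shape = (mu / sd) ** 2
    rows = []
    for i in range(n):
        exposure = float(rng.gamma(shape, mu / shape)) if group == "exposed" else 0.0
        rows.append(
            {
                "individual_id": f"{prefix}{i + 1}",
                "group": group,
                "sex": "M" if i < n_male else "F",
                "age": int(np.clip(round(rng.normal(age_mean, age_sd)), 23, 70)),
                "exposure_months": round(exposure, 1),
                "smoker": i in smokers,
                "drinker": i in drinkers,
            }
        )
    return rows


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortBundle:
    """Simulate a two-group cohort of FISH count matrices with metadata.

    Ground truth (the configured per-individual CIN target and the clone-level
    deviant fractions) is recorded in ``bundle.truth`` for estimator checks.
    """
    config = config or CohortConfig()
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    fish: dict[str, FishCountMatrix] = {}
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    for group, params, prefix in (
        ("exposed", config.exposed, "E"),
        ("unexposed", config.unexposed, "UE"),
    ):
        gfish, gtruth = _simulate_group_fish(
            params, config.n_per_group, config.n_nuclei, prefix, rng
        )
        fish.update(gfish)
        for row in gtruth:
            row["group"] = group
        truth_rows.extend(gtruth)
        meta_rows.extend(_group_metadata(group, config.n_per_group, prefix, rng))
    return CohortBundle(
        fish=fish,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
        seed=seed,
    )


# --------------------------------------------------------------------------
# karyotype simulation
# --------------------------------------------------------------------------

#: major-band catalog (not a full ideogram); enough resolution for
#: recurrence analyses over the bands seen in biomonitoring reports
BAND_CATALOG: dict[str, tuple[str, ...]] = {
    "1": ("p36", "p31", "p22", "q10", "q21", "q25", "q32", "q42"),
    "2": ("p23", "p16", "q21", "q33", "q37"),
    "3": ("p25", "p21", "p14", "q21", "q26"),
    "4": ("p16", "p14", "q21", "q28", "q31"),
    "5": ("p15", "q13", "q23", "q31", "q35"),
    "6": ("p23", "p21", "q15", "q21", "q25"),
    "7": ("p22", "p15", "q11", "q22", "q32"),
    "8": ("p23", "p21", "q13", "q22", "q24"),
    "9": ("p24", "p21", "q12", "q22", "q34"),
    "10": ("p15", "p11", "q22", "q24", "q26"),
    "11": ("p15", "p13", "q11", "q13", "q23"),
    "12": ("p13", "p11", "q13", "q15", "q24"),
    "13": ("q12", "q14", "q21", "q31", "q34"),
    "14": ("q11", "q12", "q24", "q32"),
    "15": ("q11", "q15", "q22", "q26"),
    "16": ("p13", "p11", "q12", "q22", "q24"),
    "17": ("p13", "p11", "q12", "q21", "q25"),
    "18": ("p11", "q11", "q21", "q23"),
    "19": ("p13", "p10", "q13"),
    "20": ("p13", "p11", "q11", "q13"),
    "21": ("q11", "q21", "q22"),
    "22": ("q11", "q12", "q13"),
    "X": ("p22", "p11", "q13", "q21", "q25"),
    "Y": ("p11", "q11", "q12"),
}

_SCA_SUBTYPES = ("del", "t", "add", "der", "inv", "dic", "dup", "iso", "ring")
#: subtype mix follows the observed ordering (deletions most common, then
#: translocations and added material, the rest rare)
_SCA_WEIGHTS = (0.40, 0.16, 0.10, 0.09, 0.08, 0.05, 0.04, 0.04, 0.04)

_RATE_CATEGORIES = (
    "monosomies", "trisomies", "scas", "chtb_chrb",
    "fra_other", "fra_9q12", "cv_1qh", "cv_9qh", "cv_inv9", "cv_16qh",
)


@dataclass(frozen=True)
class KaryotypeRateModel:
    """Per-metaphase Poisson rates by category, plus optional clonal injections."""

    rates: Mapping[str, float]
    clonal_injections: tuple[tuple[str, int], ...] = ()
    metaphases_range: tuple[int, int] = reference.METAPHASES_PER_INDIVIDUAL_RANGE

    def __post_init__(self) -> None:
        unknown = set(self.rates) - set(_RATE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown rate categories: {sorted(unknown)}")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rates must be nonnegative")
        lo, hi = self.metaphases_range
        if not 1 <= lo <= hi:
            raise ValueError("bad metaphases_range")
        for token, n in self.clonal_injections:
            parse_aberration(token)  # validates
            if n < 1 or n > lo:
                raise ValueError(
                    f"injection count {n} for {token!r} must be in 1..{lo} "
                    "(the minimum metaphase count)"
                )


def default_karyotype_model(group: str) -> KaryotypeRateModel:
    """Default rate model per group: observed group totals / group metaphases."""
    if group == "exposed":
        total = reference.EXPOSED_METAPHASE_TOTAL
        numerical, structural = 384, 88
        breaks, frag, cvs = 107, 625, 267
        mono_share, fra912_share = 0.60, 0.65
        cv_split = (20, 8, 7, 9)  # carrier ratio 1qh : 9qh : inv9 : 16qh
        mrange = (19, 95)
    elif group == "unexposed":
        total = reference.UNEXPOSED_METAPHASE_TOTAL
        numerical, structural = 43, 13
        breaks, frag, cvs = 26, 97, 30
        mono_share, fra912_share = 0.80, 0.70
        cv_split = (4, 4, 1, 0)
        mrange = (19, 45)
    else:
        raise ValueError(f"unknown group {group!r}")
    cv_total = sum(cv_split)
    rates = {
        "monosomies": numerical * mono_share / total,
        "trisomies": numerical * (1 - mono_share) / total,
        "scas": structural / total,
        "chtb_chrb": breaks / total,
        "fra_other": frag * (1 - fra912_share) / total,
        "fra_9q12": frag * fra912_share / total,
        "cv_1qh": cvs * cv_split[0] / cv_total / total,
        "cv_9qh": cvs * cv_split[1] / cv_total / total,
        "cv_inv9": cvs * cv_split[2] / cv_total / total,
        "cv_16qh": cvs * cv_split[3] / cv_total / total,
    }
    return KaryotypeRateModel(rates=rates, metaphases_range=mrange)


@dataclass(frozen=True)
class KaryotypeSimResult:
    records: tuple[MetaphaseRecord, ...]
    #: (individual_id, token, n_metaphases) for each clonal injection
    injections: tuple[tuple[str, str, int], ...]
    constitutional_sex: dict[str, str]


def _pick_band(chrom: str, rng: np.random.Generator, arm: str | None = None) -> str:
    bands = BAND_CATALOG[chrom]
    if arm is not None:
        bands = tuple(b for b in bands if b.startswith(arm)) or bands
    return bands[rng.integers(len(bands))]


def _random_sca(rng: np.random.Generator) -> str:
    subtype = _SCA_SUBTYPES[rng.choice(len(_SCA_SUBTYPES), p=_SCA_WEIGHTS)]
    chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
    if subtype in ("del", "dup", "add", "der"):
        return f"{subtype}({chrom})({_pick_band(chrom, rng)})"
    if subtype == "inv":
        # paracentric on 9 (a pericentric inv(9) is a heteromorphism, not an SCA)
        arm = "q" if chrom == "9" else None
        bands = {_pick_band(chrom, rng, arm) for _ in range(4)}
        if len(bands) < 2:
            return f"del({chrom})({next(iter(bands))})"
        b1, b2 = sorted(bands)[:2]
        return f"inv({chrom})({b1}{b2})"
    if subtype in ("t", "dic"):
        c1, c2 = rng.choice(len(AUTOSOMES), size=2, replace=False)
        ch1, ch2 = AUTOSOMES[c1], AUTOSOMES[c2]
        if int(ch1) > int(ch2):
            ch1, ch2 = ch2, ch1
        return f"{subtype}({ch1};{ch2})({_pick_band(ch1, rng)};{_pick_band(ch2, rng)})"
    if subtype == "iso":
        return f"i({chrom})({'q10' if rng.random() < 0.7 else 'p10'})"
    # ring
    pb = _pick_band(chrom, rng, "p")
    qb = _pick_band(chrom, rng, "q")
    if pb.startswith("q"):  # acrocentric chromosome with no p bands
        pb, qb = sorted({pb, qb})[0], sorted({pb, qb})[-1]
        if pb == qb:
            return f"r({chrom})"
    return f"r({chrom})({pb}{qb})"


def _random_event_token(category: str, sex: str, rng: np.random.Generator) -> str:
    if category == "monosomies":
        pool = AUTOSOMES + (("X",) if sex == "XX" else ("Y",))
        chrom = pool[rng.integers(len(pool))]
        return f"-{chrom}"
    if category == "trisomies":
        if rng.random() < 0.45:
            return "+mar"
        pool = AUTOSOMES + ("X",)
        return f"+{pool[rng.integers(len(pool))]}"
    if category == "scas":
        return _random_sca(rng)
    if category == "chtb_chrb":
        prefix = "chtb" if rng.random() < 0.6 else "chrb"
        chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
        return f"{prefix}({chrom})({_pick_band(chrom, rng)})"
    if category == "fra_9q12":
        return "fra(9)(q12)"
    if category == "fra_other":
        while True:
            chrom = AUTOSOMES[rng.integers(len(AUTOSOMES))]
            band = _pick_band(chrom, rng)
            if (chrom, band) != ("9", "q12"):
                return f"fra({chrom})({band})"
    if category == "cv_1qh":
        return "1qh+"
    if category == "cv_9qh":
        return "9qh+"
    if category == "cv_16qh":
        return "16qh+"
    if category == "cv_inv9":
        return "inv(9)(p11q13)"
    raise ValueError(f"unknown category {category!r}")


def simulate_karyotypes(
    model: KaryotypeRateModel,
    n_individuals: int,
    seed,
    id_prefix: str = "S",
    constitutional_sexes: Sequence[str] | None = None,
) -> KaryotypeSimResult:
    """Generate per-metaphase karyotype records under the rate model.

    Every generated string round-trips through the parser; clonal injections
    are copied verbatim into randomly chosen metaphases of one randomly
    chosen individual each. ``constitutional_sexes`` (XX/XY per individual)
    fixes each individual's sex; otherwise sexes are drawn 1:1.
    """
    rng = _as_rng(seed)
    lo, hi = model.metaphases_range
    if constitutional_sexes is not None and len(constitutional_sexes) != n_individuals:
        raise ValueError("constitutional_sexes length must equal n_individuals")
    records: list[MetaphaseRecord] = []
    sexes: dict[str, str] = {}
    for i in range(n_individuals):
        ind = f"{id_prefix}{i + 1}"
        if constitutional_sexes is not None:
            sex = constitutional_sexes[i]
            if sex not in ("XX", "XY"):
                raise ValueError(f"bad constitutional sex {sex!r}")
        else:
            sex = "XY" if rng.random() < 0.5 else "XX"
        sexes[ind] = sex
        n_meta = int(rng.integers(lo, hi + 1))
        for j in range(n_meta):
            events = []
            for cat in _RATE_CATEGORIES:
                rate = model.rates.get(cat, 0.0)
                if rate <= 0:
                    continue
                for _ in range(rng.poisson(rate)):
                    events.append(parse_aberration(_random_event_token(cat, sex, rng)))
            complement = sex
            gains = sum(1 for e in events if e.category in ("gain", "marker_gain"))
            losses = 0
            kept = []
            sex_lost = False
            for e in events:
                if e.category == "loss" and e.chromosomes[0] in ("X", "Y"):
                    if sex_lost:
                        continue  # at most one implied sex-chromosome loss
                    sex_lost = True
                    complement = "X"  # 45,X; which homolog was lost is implicit
                    losses += 1
                else:
                    kept.append(e)
                    if e.category == "loss":
                        losses += 1
            records.append(
                MetaphaseRecord(
                    chromosome_count=46 + gains - losses,
                    sex_complement=complement,
                    events=tuple(kept),
                    individual_id=ind,
                    metaphase_id=f"{ind}.m{j + 1}",
                )
            )

    injections: list[tuple[str, str, int]] = []
    for token, n in model.clonal_injections:
        event = parse_aberration(token)
        ind = f"{id_prefix}{int(rng.integers(n_individuals)) + 1}"
        positions = [k for k, r in enumerate(records) if r.individual_id == ind]
        targets = rng.choice(len(positions), size=n, replace=False)
        for t in targets:
            k = positions[int(t)]
            r = records[k]
            delta = 1 if event.category in ("gain", "marker_gain") else (
                -1 if event.category == "loss" else 0
            )
            records[k] = replace(
                r,
                events=r.events + (event,),
                chromosome_count=r.chromosome_count + delta,
            )
        injections.append((ind, format_aberration(event), n))

    return KaryotypeSimResult(
        records=tuple(records),
        injections=tuple(injections),
        constitutional_sex=sexes,
    )


def load_config(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML.

    Schema::

        n_per_group: 34
        n_nuclei: 100
        exposed:
          mean_cin: 34.57
          sd_cin: 6.03
          chromosome_weights: [1.25, 1.2, 0.5, 1.2, 1.25, 0.6]
          noise: {p_dropout: 0.015, p_split: 0.01}
        unexposed: { ... }
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def group(name: str, default: GroupFishParams) -> GroupFishParams:
        g = raw.get(name)
        if g is None:
            return default
        noise = NoiseModel(**g.get("noise", {}))
        return GroupFishParams(
            mean_cin=float(g["mean_cin"]),
            sd_cin=float(g["sd_cin"]),
            chromosome_weights=tuple(
                g.get("chromosome_weights", DEFAULT_CHROMOSOME_WEIGHTS)
            ),
            noise=noise,
        )

    base = CohortConfig()
    return CohortConfig(
        exposed=group("exposed", base.exposed),
        unexposed=group("unexposed", base.unexposed),
        n_per_group=int(raw.get("n_per_group", base.n_per_group)),
        n_nuclei=int(raw.get("n_nuclei", base.n_nuclei)),
    )
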