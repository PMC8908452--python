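"""Per-metaphase classification, clonality calls and cohort frequency tables.

Events parsed from karyotype strings are grouped into the tally categories
used in biomonitoring frequency tables: monosomies, trisomies (including
marker-chromosome gains), structural alterations (SCAs), chromatid/chromosome
breaks, fragile sites (with the common 9q12 fragility kept separate), and the
heterochromatic variants 1qh+/9qh+/inv(9)/16qh+.

Clonality follows the standard clone definition: an identical structural
aberration or identical whole-chromosome gain seen in at least two metaphases
of one individual constitutes a clone (CCA); an identical loss requires at
least three metaphases; anything rarer is non-clonal (NCCA). Breaks, fragile
sites and heteromorphisms are tallied per occurrence and never given
clonality calls.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .iscn import (
    BREAK_CATEGORIES,
    CV_CATEGORIES,
    FRAGILITY_CATEGORIES,
    NCA_CATEGORIES,
    SCA_CATEGORIES,
    AberrationEvent,
    MetaphaseRecord,
    format_aberration,
)

__all__ = [
    "TALLY_CATEGORIES",
    "IndividualTally",
    "GroupCarrierTable",
    "ClonalityCall",
    "round_half_up",
    "classify_metaphase",
    "call_clonality",
    "tally_individual",
    "carriers_table",
    "recurrent_regions",
]

#: tally categories, in the order frequency tables print them
TALLY_CATEGORIES = (
    "monosomies",
    "trisomies",
    "scas",
    "chtb_chrb",
    "fra_other",
    "fra_9q12",
    "cv_1qh",
    "cv_9qh",
    "cv_inv9",
    "cv_16qh",
)

_CV_TO_TALLY = {
    "cv_1qh_plus": "cv_1qh",
    "cv_9qh_plus": "cv_9qh",
    "cv_16qh_plus": "cv_16qh",
    "cv_inv9": "cv_inv9",
}


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IndividualTally:
    """Per-individual event counts across the tally categories."""

    individual_id: str
    group: str
    monosomies: int = 0
    trisomies: int = 0
    scas: int = 0
    chtb_chrb: int = 0
    fra_other: int = 0
    fra_9q12: int = 0
    cv_1qh: int = 0
    cv_9qh: int = 0
    cv_inv9: int = 0
    cv_16qh: int = 0
    total_events: int = 0
    pct_of_group_metaphases: float = 0.0

    def category_counts(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in TALLY_CATEGORIES}


@dataclass(frozen=True)
class GroupCarrierTable:
    """One row of a carrier-frequency comparison between two groups."""

    category: str
    exposed_carriers: int
    exposed_n: int
    unexposed_carriers: int
    unexposed_n: int
    pct_exposed: float
    pct_unexposed: float
    p_two_sided: float


@dataclass(frozen=True)
class ClonalityCall:
    """Clonal (CCA) vs non-clonal (NCCA) call for one recurring aberration."""

    key: str
    category: str
    n_metaphases_with_event: int
    call: str  # "CCA" | "NCCA"


def _implicit_sex_events(r: MetaphaseRecord, constitutional_sex: str) -> list[tuple[str, str]]:
    """Gains/losses of sex chromosomes implied by the complement alone.

    ``45,X`` in a constitutionally XY individual means loss of Y; in an XX
    individual, loss of one X. ``47,XXX`` in an XX individual is a gained X.
    """
    have = Counter(r.sex_complement)
    want = Counter(constitutional_sex)
    out: list[tuple[str, str]] = []
    for chrom in ("X", "Y"):
        diff = have[chrom] - want[chrom]
        while diff < 0:
            out.append(("monosomy", chrom))
            diff += 1
        while diff > 0:
            out.append(("trisomy", chrom))
            diff -= 1
    return out


def classify_metaphase(
    r: MetaphaseRecord, constitutional_sex: str
) -> list[tuple[str, str]]:
    """Map one metaphase to ``(tally_category, chromosome)`` pairs.

    Explicit ``+N``/``-N`` terms become trisomy/monosomy events; a sex
    complement deviating from the constitutional one yields the implied
    sex-chromosome gain/loss; marker gains count in the trisomy group with
    chromosome label ``"mar"``. A chromosome count inconsistent with the
    events raises a warning and the explicit events are kept as-is.
    """
    if constitutional_sex not in ("XX", "XY"):
        raise ValueError(f"constitutional sex must be XX or XY, got {constitutional_sex!r}")
    out: list[tuple[str, str]] = []
    n_gain = n_loss = 0
    for e in r.events:
        if e.category == "loss":
            out.append(("monosomies", e.chromosomes[0]))
            n_loss += 1
        elif e.category == "gain":
            out.append(("trisomies", e.chromosomes[0]))
            n_gain += 1
        elif e.category == "marker_gain":
            out.append(("trisomies", "mar"))
            n_gain += 1
        elif e.category in SCA_CATEGORIES:
            out.append(("scas", ";".join(e.chromosomes)))
        elif e.category in BREAK_CATEGORIES:
            out.append(("chtb_chrb", e.chromosomes[0]))
        elif e.category in FRAGILITY_CATEGORIES:
            if e.chromosomes[0] == "9" and e.breakpoints == ("q12",):
                out.append(("fra_9q12", "9"))
            else:
                out.append(("fra_other", e.chromosomes[0]))
        elif e.category in CV_CATEGORIES:
            out.append((_CV_TO_TALLY[e.category], e.chromosomes[0]))

    implicit = _implicit_sex_events(r, constitutional_sex)
    for kind, chrom in implicit:
        out.append(("monosomies" if kind == "monosomy" else "trisomies", chrom))
        if kind == "monosomy":
            n_loss += 1
        else:
            n_gain += 1

    expected = 46 + n_gain - n_loss
    if r.chromosome_count != expected:
        warnings.warn(
            f"metaphase {r.metaphase_id or '?'}: chromosome count "
            f"{r.chromosome_count} disagrees with events (expected {expected}); "
            "keeping explicit events only",
            stacklevel=2,
        )
    return out


def _clonality_key(e: AberrationEvent) -> str | None:
    """Canonical identity used to decide whether two events are 'identical'."""
    if e.category in SCA_CATEGORIES or e.category in NCA_CATEGORIES:
        return format_aberration(e)
    return None  # breaks, fragilities, CVs: no clonality calls


def call_clonality(
    records: Sequence[MetaphaseRecord], constitutional_sex: str | None = None
) -> list[ClonalityCall]:
    """Call CCA/NCCA for the gain/loss/structural aberrations of one individual.

    Implied sex-chromosome losses (``45,X`` complements) participate via the
    individual's constitutional sex; if not given it is inferred from the
    majority complement of the records.
    """
    if not records:
        raise ValueError("call_clonality requires at least one record")
    if constitutional_sex is None:
        comps = Counter(r.sex_complement for r in records)
        constitutional_sex = "XY" if comps["XY"] >= comps["XX"] and "XY" in comps else "XX"

    counts: Counter[tuple[str, str]] = Counter()
    for r in records:
        seen: set[tuple[str, str]] = set()
        for e in r.events:
            key = _clonality_key(e)
            if key is not None:
                seen.add((e.category, key))
        for kind, chrom in _implicit_sex_events(r, constitutional_sex):
            cat = "loss" if kind == "monosomy" else "gain"
            sign = "-" if cat == "loss" else "+"
            seen.add((cat, f"{sign}{chrom}"))
        counts.update(seen)

    calls = []
    for (category, key), n in sorted(counts.items(), key=lambda kv: kv[0][1]):
        threshold = 3 if category == "loss" else 2
        call = "CCA" if n >= threshold else "NCCA"
        calls.append(ClonalityCall(key=key, category=category,
                                   n_metaphases_with_event=n, call=call))
    return calls


def tally_individual(
    records: Sequence[MetaphaseRecord],
    group_metaphase_total: int,
    group: str = "",
    constitutional_sex: str = "XX",
) -> IndividualTally:
    """Count events per category; percentage is of the *group* metaphase total.

    Every occurrence counts, clonal or not. The percentage convention matches
    paired frequency tables: 100 x total_events / group_metaphase_total,
    rounded half-up to 2 decimals.
    """
    if group_metaphase_total <= 0:
        raise ValueError("group_metaphase_total must be positive")
    if group_metaphase_total < len(records):
        raise ValueError("group total smaller than this individual's metaphase count")
    counts = Counter()
    for r in records:
        for cat, _chrom in classify_metaphase(r, constitutional_sex):
            counts[cat] += 1
    total = sum(counts.values())
    pct = round_half_up(100.0 * total / group_metaphase_total, 2)
    individual_id = records[0].individual_id if records else ""
    return IndividualTally(
        individual_id=individual_id,
        group=group,
        total_events=total,
        pct_of_group_metaphases=pct,
        **{c: counts.get(c, 0) for c in TALLY_CATEGORIES},
    )


def carriers_table(
    exposed: Sequence[IndividualTally],
    unexposed: Sequence[IndividualTally],
    category: str,
) -> GroupCarrierTable:
    """Carrier counts (>=1 event of the category) and two-sided Fisher p."""
    from .stats import TwoByTwo, fisher_exact

    if not exposed or not unexposed:
        raise ValueError("both groups must be non-empty")
    if category not in TALLY_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    ec = sum(1 for t in exposed if getattr(t, category) > 0)
    uc = sum(1 for t in unexposed if getattr(t, category) > 0)
    en, un = len(exposed), len(unexposed)
    if ec + uc == 0 or (en - ec) + (un - uc) == 0:
        p = 1.0  # everyone (or no one) is a carrier: no association to test
    else:
        p = fisher_exact(TwoByTwo(ec, en - ec, uc, un - uc)).p_two_sided
    return GroupCarrierTable(
        category=category,
        exposed_carriers=ec,
        exposed_n=en,
        unexposed_carriers=uc,
        unexposed_n=un,
        pct_exposed=round_half_up(100.0 * ec / en, 1),
        pct_unexposed=round_half_up(100.0 * uc / un, 1),
        p_two_sided=p,
    )


def recurrent_regions(
    records: Iterable[MetaphaseRecord], min_individuals: int = 1
) -> pd.DataFrame:
    """Chromosome bands hit by structural aberrations, by distinct individuals.

    Each breakpoint of each SCA contributes a (chromosome, band) hit; the
    table counts distinct carriers per band and can be filtered at
    ``min_individuals`` (>=2 for 'recurrently altered regions').
    """
    hits: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        for e in r.events:
            if e.category not in SCA_CATEGORIES or not e.breakpoints:
                continue
            if e.category in ("t", "dic"):
                pairs = zip(e.chromosomes, e.breakpoints)
            else:
                pairs = ((e.chromosomes[0], b) for b in e.breakpoints)
            for chrom, band in pairs:
                hits[(chrom, band)].add(r.individual_id)
    rows = [
        {"chromosome": chrom, "band": band, "n_individuals": len(ids)}
        for (chrom, band), ids in hits.items()
        if len(ids) >= min_individuals
    ]
    df = pd.DataFrame(rows, columns=["chromosome", "band", "n_individuals"])
    if not df.empty:
        df = df.sort_values(
            ["n_individuals", "chromosome", "band"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
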