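"""Parsing, validation and formatting of a working subset of ISCN 2020.

Karyotype strings such as ``"46,XX,inv(9)(p21q22)"`` describe one metaphase:
a chromosome count, a sex-chromosome complement, and zero or more aberration
terms. This module covers the subset of the nomenclature needed for
constitutional biomonitoring work on peripheral-blood metaphases: whole
chromosome gains/losses (``+22``, ``-20``), marker gains (``+mar``), the common
structural rearrangements (``del``, ``dup``, ``inv``, ``t``, ``dic``, ``add``,
``der``, ``i``, ``r``), fragile-site expressions (``fra``), chromatid and
chromosome breaks (``chtb``/``chrb``) and the heterochromatic variants
(``1qh+``, ``9qh+``, ``16qh+`` and the pericentric inversion of chromosome 9).

Mosaicism slashes, stemline shorthand (``idem``/``sl``/``sdl``) and uncertain
``?`` qualifiers are deliberately rejected rather than guessed at, except that
a pericentric inversion of chromosome 9 — a population-level heteromorphism —
is given its own category so downstream tallies can treat it as a variant
rather than a structural alteration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "AberrationEvent",
    "MetaphaseRecord",
    "IscnParseError",
    "parse_aberration",
    "parse_karyotype",
    "format_aberration",
    "format_karyotype",
    "read_karyotypes",
    "write_karyotypes",
    "AUTOSOMES",
    "CHROMOSOMES",
    "NCA_CATEGORIES",
    "SCA_CATEGORIES",
    "BREAK_CATEGORIES",
    "FRAGILITY_CATEGORIES",
    "CV_CATEGORIES",
]

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

#: numerical alterations
NCA_CATEGORIES = frozenset({"loss", "gain", "marker_gain"})
#: structural alterations
SCA_CATEGORIES = frozenset({"del", "t", "add", "der", "inv", "dic", "dup", "iso", "ring"})
#: chromatid / chromosome breaks
BREAK_CATEGORIES = frozenset({"chtb", "chrb"})
#: fragile-site expression
FRAGILITY_CATEGORIES = frozenset({"fra"})
#: heterochromatic variants (heteromorphisms)
CV_CATEGORIES = frozenset({"cv_1qh_plus", "cv_9qh_plus", "cv_16qh_plus", "cv_inv9"})

ALL_CATEGORIES = NCA_CATEGORIES | SCA_CATEGORIES | BREAK_CATEGORIES | FRAGILITY_CATEGORIES | CV_CATEGORIES

# categories that must carry band-level breakpoints
_BAND_REQUIRED = frozenset({"del", "t", "inv", "fra", "chtb", "chrb", "add", "dup", "dic", "iso", "cv_inv9"})

# token prefix -> category for the parenthesised structural grammar
_PREFIX_CATEGORY = {
    "del": "del",
    "dup": "dup",
    "inv": "inv",
    "add": "add",
    "der": "der",
    "dic": "dic",
    "fra": "fra",
    "chtb": "chtb",
    "chrb": "chrb",
    "t": "t",
    "i": "iso",
    "r": "ring",
}
_CATEGORY_PREFIX = {v: k for k, v in _PREFIX_CATEGORY.items()}

_BAND_RE = re.compile(r"[pq]\d{1,2}(?:\.\d{1,2})?")
_STRUCT_RE = re.compile(
    r"^(?P<prefix>[a-z]+)\((?P<chroms>[^()]+)\)(?:\((?P<bands>[^()]+)\))?$"
)
_QH_RE = re.compile(r"^(?P<chrom>1|9|16)qh\+$")
_COMPLEMENT_RE = re.compile(r"^[XYxy]{1,4}$")


class IscnParseError(ValueError):
    """Raised when a karyotype string or aberration token cannot be parsed.

    The message always names the offending span of text.
    """


@dataclass(frozen=True)
class AberrationEvent:
    """One parsed aberration term.

    ``raw_token`` is kept for error messages and provenance but excluded from
    equality so that parse → format → parse round trips compare equal.
    """

    category: str
    chromosomes: tuple[str, ...] = ()
    breakpoints: tuple[str, ...] = ()
    raw_token: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.category not in ALL_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for c in self.chromosomes:
            if c not in CHROMOSOMES:
                raise ValueError(f"bad chromosome label {c!r}")
        if not self.chromosomes and self.category != "marker_gain":
            raise ValueError(f"category {self.category!r} requires chromosomes")


@dataclass(frozen=True)
class MetaphaseRecord:
    """One metaphase: chromosome count, sex complement, aberration events."""

    chromosome_count: int
    sex_complement: str
    events: tuple[AberrationEvent, ...] = ()
    individual_id: str = field(default="", compare=False)
    metaphase_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.chromosome_count < 1:
            raise ValueError("chromosome_count must be >= 1")
        if not _COMPLEMENT_RE.match(self.sex_complement):
            raise ValueError(f"bad sex complement {self.sex_complement!r}")
        object.__setattr__(self, "sex_complement", self.sex_complement.upper())
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def is_normal(self) -> bool:
        return (
            self.chromosome_count == 46
            and self.sex_complement in ("XX", "XY")
            and not self.events
        )


def _norm_chrom(label: str, token: str) -> str:
    label = label.strip()
    up = label.upper()
    if up in ("X", "Y"):
        return up
    if label in AUTOSOMES:
        return label
    raise IscnParseError(f"bad chromosome label {label!r} in {token!r}")


def _split_bands(group: str, token: str) -> tuple[str, ...]:
    """Split a concatenated band run like 'p21q22' into ('p21', 'q22')."""
    group = group.strip()
    bands = _BAND_RE.findall(group)
    if "".join(bands) != group or not bands:
        raise IscnParseError(f"bad band designation {group!r} in {token!r}")
    return tuple(bands)


def parse_aberration(token: str) -> AberrationEvent:
    """Parse a single aberration term into an :class:`AberrationEvent`.

    Examples
    --------
    >>> parse_aberration("del(6)(q25)")
    AberrationEvent(category='del', chromosomes=('6',), breakpoints=('q25',), ...)
    >>> parse_aberration("t(7;14)(p22;q12)").chromosomes
    ('7', '14')
    """
    raw = token
    token = token.strip()
    if not token:
        raise IscnParseError("empty aberration token")

    # numerical terms: +N / -N / +mar  (accept the unicode minus sign)
    token_n = token.replace("−", "-").replace("–", "-")
    if token_n[0] in "+-":
        body = token_n[1:].strip()
        if token_n[0] == "+" and body == "mar":
            return AberrationEvent("marker_gain", (), (), raw_token=raw)
        chrom = _norm_chrom(body, token)
        cat = "gain" if token_n[0] == "+" else "loss"
        return AberrationEvent(cat, (chrom,), (), raw_token=raw)

    m = _QH_RE.match(token)
    if m:
        chrom = m.group("chrom")
        return AberrationEvent(f"cv_{chrom}qh_plus", (chrom,), (), raw_token=raw)

    if token.count("(") != token.count(")"):
        raise IscnParseError(f"unbalanced parentheses in {token!r}")

    m = _STRUCT_RE.match(token)
    if not m:
        raise IscnParseError(f"malformed aberration token {token!r}")
    prefix = m.group("prefix")
    if prefix not in _PREFIX_CATEGORY:
        raise IscnParseError(f"unknown aberration prefix {prefix!r} in {token!r}")
    category = _PREFIX_CATEGORY[prefix]

    chroms = tuple(_norm_chrom(c, token) for c in m.group("chroms").split(";"))
    band_text = m.group("bands")

    multi = category in ("t", "dic")
    if multi:
        if len(chroms) < 2:
            raise IscnParseError(f"{prefix} requires at least two chromosomes: {token!r}")
        if band_text is None:
            raise IscnParseError(f"{prefix} requires breakpoints: {token!r}")
        groups = [g.strip() for g in band_text.split(";")]
        if len(groups) != len(chroms):
            raise IscnParseError(
                f"breakpoint count does not match chromosome count in {token!r}"
            )
        breakpoints: tuple[str, ...] = ()
        for g in groups:
            bands = _split_bands(g, token)
            if len(bands) != 1:
                raise IscnParseError(f"expected one band per chromosome in {token!r}")
            breakpoints += bands
    else:
        if len(chroms) != 1:
            raise IscnParseError(f"{prefix} takes a single chromosome: {token!r}")
        if band_text is None:
            breakpoints = ()
        elif ";" in band_text:
            raise IscnParseError(f"unexpected ';' in band group of {token!r}")
        else:
            breakpoints = _split_bands(band_text, token)

    if category == "inv":
        if len(breakpoints) != 2:
            raise IscnParseError(f"inversion requires two breakpoints: {token!r}")
        # pericentric inv(9) is a common heteromorphism, not a structural CA
        arms = {b[0] for b in breakpoints}
        if chroms[0] == "9" and arms == {"p", "q"}:
            category = "cv_inv9"
    elif category in ("del", "dup", "add", "fra", "chtb", "chrb"):
        if not 1 <= len(breakpoints) <= 2:
            raise IscnParseError(f"{prefix} requires one or two breakpoints: {token!r}")
    elif category == "iso":
        if len(breakpoints) != 1:
            raise IscnParseError(f"isochromosome requires one breakpoint: {token!r}")
    elif category == "ring":
        if breakpoints and len(breakpoints) != 2:
            raise IscnParseError(f"ring takes zero or two breakpoints: {token!r}")
    elif category == "der":
        if len(breakpoints) > 2:
            raise IscnParseError(f"too many breakpoints in {token!r}")

    if category in _BAND_REQUIRED and not breakpoints:
        raise IscnParseError(f"{prefix} requires breakpoints: {token!r}")

    return AberrationEvent(category, chroms, breakpoints, raw_token=raw)


def format_aberration(e: AberrationEvent) -> str:
    """Canonical ISCN text for one event; inverse of :func:`parse_aberration`."""
    if e.category == "loss":
        return f"-{e.chromosomes[0]}"
    if e.category == "gain":
        return f"+{e.chromosomes[0]}"
    if e.category == "marker_gain":
        return "+mar"
    if e.category in ("cv_1qh_plus", "cv_9qh_plus", "cv_16qh_plus"):
        return f"{e.chromosomes[0]}qh+"
    prefix = _CATEGORY_PREFIX.get(e.category, "inv" if e.category == "cv_inv9" else None)
    if e.category == "cv_inv9":
        prefix = "inv"
    if e.category in ("t", "dic"):
        chrom_part = ";".join(e.chromosomes)
        band_part = ";".join(e.breakpoints)
        return f"{prefix}({chrom_part})({band_part})"
    chrom_part = e.chromosomes[0]
    if e.breakpoints:
        return f"{prefix}({chrom_part})({''.join(e.breakpoints)})"
    return f"{prefix}({chrom_part})"


def parse_karyotype(s: str, individual_id: str = "", metaphase_id: str = "") -> MetaphaseRecord:
    """Parse a full karyotype string ``"count,complement[,term]*"``.

    >>> r = parse_karyotype("46,XX,inv(9)(p21q22)")
    >>> r.chromosome_count, r.sex_complement, len(r.events)
    (46, 'XX', 1)
    """
    parts = [p.strip() for p in s.strip().split(",")]
    if len(parts) < 2:
        raise IscnParseError(f"karyotype {s!r} needs at least count and sex complement")
    try:
        count = int(parts[0])
    except ValueError:
        raise IscnParseError(f"chromosome count {parts[0]!r} is not an integer") from None
    complement = parts[1]
    if not _COMPLEMENT_RE.match(complement):
        raise IscnParseError(f"bad sex complement {complement!r} in {s!r}")
    events = tuple(parse_aberration(t) for t in parts[2:] if t)
    return MetaphaseRecord(
        chromosome_count=count,
        sex_complement=complement,
        events=events,
        individual_id=individual_id,
        metaphase_id=metaphase_id,
    )


def format_karyotype(r: MetaphaseRecord) -> str:
    """Canonical karyotype string; ``parse_karyotype(format_karyotype(r)) == r``."""
    parts = [str(r.chromosome_count), r.sex_complement]
    parts.extend(format_aberration(e) for e in r.events)
    return ",".join(parts)


def read_karyotypes(path) -> list[MetaphaseRecord]:
    """Read a karyotype TSV (columns individual_id, metaphase_id, karyotype)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "metaphase_id", "karyotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"karyotype table missing columns: {sorted(missing)}")
    return [
        parse_karyotype(row.karyotype, individual_id=row.individual_id,
                        metaphase_id=row.metaphase_id)
        for row in df.itertuples()
    ]


def write_karyotypes(records, path) -> None:
    """Write records to the karyotype TSV schema."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "metaphase_id": [r.metaphase_id for r in records],
            "karyotype": [format_karyotype(r) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
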