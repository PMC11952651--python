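"""Shared vocabulary: ancestry codes, pathogenicity tiers, inheritance modes,
ICD-10 disease groups, and the chromosome→ploidy convention.

These are the fixed labels of the gnomAD-style input contract; everything that
reads, writes or simulates variant tables imports them from here.
"""

from __future__ import annotations

from .errors import ConfigurationError

#: The eight gnomAD exome genetic ancestry groups.
ANCESTRIES: tuple[str, ...] = ("afr", "amr", "asj", "eas", "fin", "mid", "nfe", "sas")

#: Seven-level pathogenicity tiers, ordered from most to least pathogenic
#: (posterior odds of pathogenicity: P > 99%, LP 90%, VUS-H 67.5%, ...).
TIERS: tuple[str, ...] = ("P", "LP", "VUS-H", "VUS-M", "VUS-L", "LB", "B")

#: Nested tier sets used for burden sensitivity: P ⊂ P+LP ⊂ P+LP+VUS-H.
TIER_SETS: dict[str, tuple[str, ...]] = {
    "P": ("P",),
    "P+LP": ("P", "LP"),
    "P+LP+VUS-H": ("P", "LP", "VUS-H"),
}

TIER_SET_LABELS: tuple[str, ...] = tuple(TIER_SETS)

# Inheritance modes with a genetic-prevalence rule.
MODE_AD = "AD"
MODE_AR = "AR"
MODE_ADAR = "AD/AR"
MODE_XLR = "XLR"
MODE_XLD = "XLD"
MODE_PAD = "pseudoautosomal-dominant"
MODE_PAR = "pseudoautosomal-recessive"

DISPATCHABLE_MODES: tuple[str, ...] = (
    MODE_AD, MODE_AR, MODE_ADAR, MODE_XLR, MODE_XLD, MODE_PAD, MODE_PAR,
)

#: Modes treated as dominant for group-level "per dominant gene" adjustment.
DOMINANT_MODES: frozenset[str] = frozenset({MODE_AD, MODE_ADAR, MODE_XLD, MODE_PAD})

#: Inheritance labels that make a gene ineligible for burden analysis.
INELIGIBLE_INHERITANCE: frozenset[str] = frozenset({"undefined", "mitochondrial"})

MECHANISMS: tuple[str, ...] = ("LoF", "GoF", "LoF+GoF", "repeat-expansion-only", "undefined")

#: The 13 ICD-10 based disease groups.
ICD10_GROUPS: tuple[str, ...] = (
    "congenital",
    "nervous",
    "blood/immune",
    "musculoskeletal/connective",
    "skin",
    "endocrine/metabolic",
    "circulatory",
    "eye",
    "ear",
    "genitourinary",
    "neoplasm",
    "digestive",
    "respiratory",
)

#: Alleles carried per individual, by chromosome class, assuming a 1:1 sex
#: ratio: autosomes and the pseudoautosomal regions are diploid everywhere,
#: chrX non-PAR averages 1.5 copies (2 in females, 1 in males), chrY 0.5.
DEFAULT_PLOIDY: dict[str, float] = {
    "autosome": 2.0,
    "X": 1.5,
    "X_PAR": 2.0,
    "Y": 0.5,
}


def chrom_class(chrom: str) -> str:
    """Classify a chromosome label into a ploidy class.

    ``chrX_PAR`` (the pseudoautosomal region) is diploid; plain ``chrX``/``X``
    is the non-PAR hemizygous class.
    """
    c = chrom.removeprefix("chr")
    if c.upper() in {"X_PAR", "XPAR"}:
        return "X_PAR"
    if c.upper() == "X":
        return "X"
    if c.upper() == "Y":
        return "Y"
    return "autosome"


def ploidy_of(chrom: str, ploidy_map: dict[str, float] | None = None) -> float:
    """Average callable alleles per individual for *chrom*."""
    pm = DEFAULT_PLOIDY if ploidy_map is None else ploidy_map
    cls = chrom_class(chrom)
    try:
        return pm[cls]
    except KeyError:
        raise ConfigurationError(f"ploidy_map lacks an entry for chromosome class {cls!r}")


def ac_col(ancestry: str) -> str:
    return f"ac_{ancestry}"


def an_col(ancestry: str) -> str:
    return f"an_{ancestry}"


VARIANT_KEY_COLUMNS: tuple[str, ...] = ("chrom", "pos", "ref", "alt")


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant identity string used in restriction lists."""
    return f"{chrom}:{pos}:{ref}:{alt}"
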