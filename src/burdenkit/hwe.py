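"""Hardy-Weinberg formula core.

Everything downstream reduces to a handful of closed-form quantities derived
from a gene's cumulative allele frequency (CAF), the sum of the allele
frequencies of its qualifying variants under independent assortment:

* carrier frequency        CrF  = 2·CAF·(1−CAF)
* homozygote + compound-heterozygote frequency
                           HomF = CAF²
* genetic prevalence (GP), dispatched on inheritance mode:
    dominant (AD, AD/AR, pseudoautosomal-dominant)   GP = CrF
    recessive (AR, pseudoautosomal-recessive)        GP = HomF
    X-linked recessive                               GP = CAF·(CAF+1)/2
    X-linked dominant                GP = CAF·(1−CAF) + CAF·(CAF+1)/2

The X-linked forms assume a 1:1 sex ratio with hemizygous males: for XLR the
affected fraction is (males carrying, CAF)/2 plus (females homozygous,
CAF²)/2 = CAF(CAF+1)/2; XLD adds the heterozygous females, CAF(1−CAF).

CAF sums use :func:`math.fsum` (correctly rounded), so a gene's CAF does not
depend on the order in which its variants are listed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import DispatchError, DomainError, UndefinedFrequencyError
from .schema import (
    DISPATCHABLE_MODES,
    MODE_AD,
    MODE_ADAR,
    MODE_AR,
    MODE_PAD,
    MODE_PAR,
    MODE_XLD,
    MODE_XLR,
    TIER_SETS,
    TIER_SET_LABELS,
    ac_col,
    an_col,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TierSet",
    "GeneBurden",
    "allele_frequency",
    "cumulative_af",
    "carrier_frequency",
    "homozygote_frequency",
    "compound_het_frequency",
    "genetic_prevalence",
    "reported_crf",
    "invert_crf",
    "gene_burden",
    "burden_table",
    "one_in_x",
    "format_one_in_x",
]


@dataclass(frozen=True)
class TierSet:
    """A nested variant-inclusion level (P ⊂ P+LP ⊂ P+LP+VUS-H)."""

    label: str
    members: tuple[str, ...]

    @classmethod
    def from_label(cls, label: str) -> "TierSet":
        try:
            return cls(label, TIER_SETS[label])
        except KeyError:
            raise DomainError(
                f"unknown tier set {label!r}; expected one of {sorted(TIER_SETS)}"
            )


@dataclass
class GeneBurden:
    """Per gene × ancestry × tier-set burden for one inheritance mode.

    ``caf_capped`` flags a CAF that exceeded 1 and was capped; ``high_caf``
    flags CAF > 0.5, where the literal CrF formula enters its decreasing
    branch (seen in reality only for genes like HFE with very common alleles).
    """

    gene: str
    ancestry: str
    tier_set: str
    mode_used: str
    n_variants: int
    caf: float
    crf: float
    homf: float
    gp: float
    caf_capped: bool = False
    high_caf: bool = False
    warnings: list[str] = field(default_factory=list)


def allele_frequency(ac: int, an: int) -> float:
    """AF = AC/AN for one variant in one ancestry.

    AN == 0 means the site was not called in this ancestry; that is an
    undefined frequency, not a frequency of zero.
    """
    if an == 0:
        raise UndefinedFrequencyError("AN is 0: allele frequency is undefined, not 0")
    if an < 0 or ac < 0 or ac > an:
        raise DomainError(f"require 0 <= AC <= AN, got AC={ac}, AN={an}")
    return ac / an


def cumulative_af(afs, cap: bool = True) -> float:
    """Sum allele frequencies under independent assortment.

    Values above 1 (pathological but possible for an additive sum) are capped
    at 1.0 with a logged warning when *cap* is true.
    """
    afs = list(afs)
    for af in afs:
        if not 0.0 <= af <= 1.0:
            raise DomainError(f"allele frequency {af} outside [0, 1]")
    caf = math.fsum(afs)
    if cap and caf > 1.0:
        logger.warning("CAF %.6g exceeds 1; capped at 1.0", caf)
        return 1.0
    return caf


def carrier_frequency(caf: float) -> float:
    """CrF = 2·CAF·(1−CAF): the heterozygous-carrier fraction under HWE."""
    if not 0.0 <= caf <= 1.0:
        raise DomainError(f"CAF {caf} outside [0, 1]")
    return 2.0 * caf * (1.0 - caf)


def homozygote_frequency(caf: float) -> float:
    """HomF = CAF²: combined homozygote and compound-heterozygote fraction."""
    if not 0.0 <= caf <= 1.0:
        raise DomainError(f"CAF {caf} outside [0, 1]")
    return caf * caf


def compound_het_frequency(af_i: float, af_j: float) -> float:
    """Frequency of the compound heterozygote for two distinct alleles, 2·AFi·AFj."""
    for af in (af_i, af_j):
        if not 0.0 <= af <= 1.0:
            raise DomainError(f"allele frequency {af} outside [0, 1]")
    return 2.0 * af_i * af_j


_DOMINANT = {MODE_AD, MODE_ADAR, MODE_PAD}
_RECESSIVE = {MODE_AR, MODE_PAR}


def genetic_prevalence(caf: float, mode: str) -> float:
    """Fraction of the population with a disease-compatible genotype.

    Dispatches on inheritance mode; see the module docstring for the forms.
    """
    if not 0.0 <= caf <= 1.0:
        raise DomainError(f"CAF {caf} outside [0, 1]")
    if mode in _DOMINANT:
        return carrier_frequency(caf)
    if mode in _RECESSIVE:
        return homozygote_frequency(caf)
    if mode == MODE_XLR:
        return caf * (caf + 1.0) / 2.0
    if mode == MODE_XLD:
        return (1.0 - caf) * caf + caf * (caf + 1.0) / 2.0
    raise DispatchError(f"no genetic-prevalence rule for inheritance mode {mode!r}")


def reported_crf(rp: float, convention: str = "as-printed") -> float:
    """Carrier frequency implied by a reported disease prevalence rP.

    ``as-printed`` applies 2·rP·(1−rP) directly. ``sqrt-prevalence`` first
    recovers the allele frequency as √rP (the HWE relation for a fully
    penetrant recessive disease, prevalence = CAF²) and returns
    2·√rP·(1−√rP). Both are offered because the direct form treats the
    prevalence itself as an allele frequency; the default follows the direct
    form, and the choice is surfaced rather than decided silently.
    """
    if not 0.0 < rp < 1.0:
        raise DomainError(f"reported prevalence {rp} outside (0, 1)")
    if convention == "as-printed":
        return 2.0 * rp * (1.0 - rp)
    if convention == "sqrt-prevalence":
        q = math.sqrt(rp)
        return 2.0 * q * (1.0 - q)
    raise DomainError(f"unknown rCrF convention {convention!r}")


def invert_crf(crf: float) -> float:
    """The smaller root c of 2c(1−c) = CrF, i.e. (1 − √(1 − 2·CrF)) / 2.

    CrF cannot exceed 0.5 (the maximum of 2c(1−c)); larger values have no
    real pre-image.
    """
    if not 0.0 <= crf <= 0.5:
        raise DomainError(f"carrier frequency {crf} outside [0, 0.5]")
    return (1.0 - math.sqrt(1.0 - 2.0 * crf)) / 2.0


def gene_burden(records, tier_set, mode: str, gene: str = "", ancestry: str = "") -> GeneBurden:
    """Burden for one gene in one ancestry under one tier set and mode.

    *records* is an iterable of ``(tier, af)`` pairs (or a DataFrame with
    ``tier`` and ``af`` columns) already QC-retained for this ancestry.
    A gene with no retained variants has CAF = CrF = GP = 0; that is a valid
    result, not an error.
    """
    ts = tier_set if isinstance(tier_set, TierSet) else TierSet.from_label(tier_set)
    if hasattr(records, "itertuples"):  # DataFrame
        pairs = list(zip(records["tier"], records["af"]))
    else:
        pairs = list(records)
    members = set(ts.members)
    afs = [af for tier, af in pairs if tier in members]
    raw = cumulative_af(afs, cap=False)
    warnings: list[str] = []
    capped = raw > 1.0
    caf = 1.0 if capped else raw
    if capped:
        warnings.append(f"CAF {raw:.6g} exceeded 1 and was capped")
        logger.warning("gene %s ancestry %s tier_set %s: CAF %.6g capped at 1.0",
                       gene, ancestry, ts.label, raw)
    high = caf > 0.5
    if high:
        warnings.append("CAF > 0.5: CrF formula is in its decreasing branch")
    return GeneBurden(
        gene=gene,
        ancestry=ancestry,
        tier_set=ts.label,
        mode_used=mode,
        n_variants=len(afs),
        caf=caf,
        crf=carrier_frequency(caf),
        homf=homozygote_frequency(caf),
        gp=genetic_prevalence(caf, mode),
        caf_capped=capped,
        high_caf=high,
        warnings=warnings,
    )


def burden_table(variants, retained, meta, tier_sets=None, ancestries=None):
    """Per-gene burden table: one row per gene × ancestry × tier set × mode.

    *variants* is the tidy variant frame, *retained* the per-ancestry QC
    masks from :func:`burdenkit.ingest.qc_filter`, and *meta* a mapping
    gene → object with an ``inheritance`` set (e.g.
    :class:`burdenkit.ingest.GeneMeta`). A gene with several dispatchable
    inheritance modes (an ANO5-like dual-phenotype gene listing AD and AR)
    yields one row per (gene, mode); genes with no QC-retained variants get
    zero-burden rows rather than being dropped.
    """
    import pandas as pd

    tier_labels = list(tier_sets or TIER_SET_LABELS)
    ts_objects = {lab: TierSet.from_label(lab) for lab in tier_labels}
    if ancestries is None:
        ancestries = list(retained)
    gene_modes: dict[str, list[str]] = {}
    for gene, gm in meta.items():
        modes = [m for m in DISPATCHABLE_MODES if m in gm.inheritance]
        if not modes:
            logger.warning("gene %s has no dispatchable inheritance mode; skipped", gene)
            continue
        gene_modes[gene] = modes

    rows = []
    for anc in ancestries:
        mask = retained[anc]
        sub = variants[mask.to_numpy()] if len(variants) else variants
        per_gene: dict[str, list[tuple[str, float]]] = {}
        if len(sub):
            af = sub[ac_col(anc)].to_numpy() / sub[an_col(anc)].to_numpy()
            for gene, tier, a in zip(sub["gene"], sub["tier"], af):
                per_gene.setdefault(gene, []).append((tier, a))
        for gene in sorted(gene_modes):
            pairs = per_gene.get(gene, [])
            for lab in tier_labels:
                for mode in gene_modes[gene]:
                    gb = gene_burden(pairs, ts_objects[lab], mode, gene=gene, ancestry=anc)
                    rows.append({
                        "gene": gb.gene, "ancestry": gb.ancestry,
                        "tier_set": gb.tier_set, "mode": gb.mode_used,
                        "n_variants": gb.n_variants, "caf": gb.caf,
                        "crf": gb.crf, "homf": gb.homf, "gp": gb.gp,
                        "caf_capped": gb.caf_capped, "high_caf": gb.high_caf,
                    })
    return pd.DataFrame(
        rows, columns=["gene", "ancestry", "tier_set", "mode", "n_variants",
                       "caf", "crf", "homf", "gp", "caf_capped", "high_caf"])


def one_in_x(value: float) -> float:
    """Reciprocal of a positive fraction; inf for 0."""
    if value < 0:
        raise DomainError(f"cannot express negative value {value} as '1 in x'")
    return math.inf if value == 0 else 1.0 / value


def format_one_in_x(value: float) -> str:
    """Render a fraction as ``1 in x`` with K/M abbreviation at 10³/10⁶.

    Matches report style: x is rounded to the nearest integer below 1000;
    above, it is shown with at most one decimal ("22K", "2.2K", "23M").
    """
    if value == 0:
        return "1 in inf"
    x = one_in_x(value)
    if x >= 1e6:
        v = x / 1e6
        suffix = "M"
    elif x >= 1e3:
        v = x / 1e3
        suffix = "K"
    else:
        return f"1 in {round(x)}"
    s = f"{v:.1f}".rstrip("0").rstrip(".")
    return f"1 in {s}{suffix}"
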