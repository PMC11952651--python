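"""Disease-group burdens, ACMG secondary findings, carrier-screening
candidates and gene-constraint flags.

Disease groups follow the ICD-10 nesting used for gene panels: a gene
assigned to k groups contributes its prevalence to all k, and a gene with
both a dominant and a recessive phenotype contributes once per inheritance
mode within each group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import BurdenKitError, DomainError
from .hwe import (
    TierSet,
    carrier_frequency,
    cumulative_af,
    format_one_in_x,
    genetic_prevalence,
    homozygote_frequency,
)
from .schema import (
    DOMINANT_MODES,
    ICD10_GROUPS,
    ac_col,
    an_col,
    variant_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupBurden", "ScreeningResult",
    "group_burden", "group_burden_table", "dominant_adjusted_burden",
    "secondary_findings_summary", "screening_candidates", "constraint_flags",
    "CONSTRAINT_THRESHOLDS",
]


@dataclass
class GroupBurden:
    """Cumulative genetic prevalence of one ICD-10 group in one ancestry."""

    group: str
    ancestry: str
    tier_set: str
    cumulative_gp: float
    one_in_x: float
    n_genes: int
    n_gene_mode_pairs: int
    mean_gp_per_dominant_gene: float | None = None


@dataclass
class ScreeningResult:
    """Genes exceeding the carrier-screening threshold, per ancestry."""

    threshold: float
    per_ancestry: dict[str, set] = field(default_factory=dict)

    @property
    def shared_across_ancestries(self) -> set:
        sets = list(self.per_ancestry.values())
        return set.intersection(*sets) if sets else set()


def _gene_groups(meta) -> dict[str, frozenset]:
    return {g: gm.icd10_groups for g, gm in meta.items()}


def group_burden(gene_burdens: pd.DataFrame, meta, group: str,
                 ancestry: str, tier_set: str) -> GroupBurden:
    """Cumulative GP for one group: Σ GP over (gene, mode) pairs whose gene
    belongs to the group. Genes in several groups count in each."""
    if group not in ICD10_GROUPS:
        raise BurdenKitError(f"unknown ICD-10 group {group!r}")
    members = {g for g, gm in meta.items() if group in gm.icd10_groups}
    sub = gene_burdens[
        (gene_burdens["ancestry"] == ancestry)
        & (gene_burdens["tier_set"] == tier_set)
        & gene_burdens["gene"].isin(members)]
    cum = math.fsum(sub["gp"])
    dom = sub[sub["mode"].isin(DOMINANT_MODES)]
    mean_dom = math.fsum(dom["gp"]) / len(dom) if len(dom) else None
    return GroupBurden(
        group=group, ancestry=ancestry, tier_set=tier_set,
        cumulative_gp=cum,
        one_in_x=(math.inf if cum == 0 else 1.0 / cum),
        n_genes=sub["gene"].nunique(),
        n_gene_mode_pairs=len(sub),
        mean_gp_per_dominant_gene=mean_dom,
    )


def group_burden_table(gene_burdens: pd.DataFrame, meta,
                       groups=ICD10_GROUPS) -> pd.DataFrame:
    """Group burden for every group × ancestry × tier set present."""
    rows = []
    for anc in sorted(gene_burdens["ancestry"].unique()):
        for lab in dict.fromkeys(gene_burdens["tier_set"]):
            for group in groups:
                gb = group_burden(gene_burdens, meta, group, anc, lab)
                rows.append({
                    "group": gb.group, "ancestry": gb.ancestry,
                    "tier_set": gb.tier_set, "cumulative_gp": gb.cumulative_gp,
                    "one_in_x": format_one_in_x(gb.cumulative_gp),
                    "n_genes": gb.n_genes,
                    "n_gene_mode_pairs": gb.n_gene_mode_pairs,
                    "mean_gp_per_dominant_gene": gb.mean_gp_per_dominant_gene,
                })
    return pd.DataFrame(rows)


def dominant_adjusted_burden(gene_burdens: pd.DataFrame, meta, group: str,
                             ancestry: str, tier_set: str) -> float | None:
    """Mean GP per dominant (gene, mode) pair in the group.

    This normalizes a group's dominant-disease burden by its number of
    dominant genes, so groups whose dominant genes are depleted of
    pathogenic variation (haploinsufficiency under selection) rank low.
    One declared interpretation of "adjusting for dominant disorders";
    isolated here so alternatives can be swapped in. ``None`` when the group
    has no dominant (gene, mode) pair.
    """
    return group_burden(gene_burdens, meta, group, ancestry,
                        tier_set).mean_gp_per_dominant_gene


def secondary_findings_summary(
        gene_burdens: pd.DataFrame, meta,
        sf_genes=None, variant_restrictions: dict | None = None,
        variants: pd.DataFrame | None = None, retained: dict | None = None,
        acmg_categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Cumulative CrF and GP over the actionable secondary-findings genes.

    ``sf_genes`` defaults to the metadata's ``is_secondary_finding`` flags.
    A gene with an entry in ``variant_restrictions`` (e.g. HFE restricted to
    C282Y) has its CAF recomputed over the allowed variant identities only,
    which requires *variants* and the QC *retained* masks; a restriction
    naming a variant absent from the table leaves that gene at CAF 0 with a
    warning. With ``acmg_categories`` (gene → phenotype category) per-category
    rows are emitted alongside the ALL row.
    """
    if sf_genes is None:
        sf_genes = {g for g, gm in meta.items() if gm.is_secondary_finding}
    sf_genes = set(sf_genes)
    if variant_restrictions is None:
        variant_restrictions = {
            g: list(gm.sf_variant_restriction) for g, gm in meta.items()
            if gm.sf_variant_restriction and g in sf_genes}
    restricted = {g: v for g, v in variant_restrictions.items() if v}
    if restricted and (variants is None or retained is None):
        raise BurdenKitError(
            "variant_restrictions require the variant table and QC masks "
            "to recompute restricted CAFs")

    rows = []
    ancestries = sorted(gene_burdens["ancestry"].unique())
    tier_sets = list(dict.fromkeys(gene_burdens["tier_set"]))
    for anc in ancestries:
        for lab in tier_sets:
            sub = gene_burdens[
                (gene_burdens["ancestry"] == anc)
                & (gene_burdens["tier_set"] == lab)
                & gene_burdens["gene"].isin(sf_genes)].copy()
            for gene, allowed in restricted.items():
                idx = sub.index[sub["gene"] == gene]
                if len(idx) == 0:
                    continue
                caf = _restricted_caf(variants, retained[anc], anc, gene, allowed, lab)
                crf = carrier_frequency(caf)
                sub.loc[idx, "caf"] = caf
                sub.loc[idx, "crf"] = crf
                sub.loc[idx, "homf"] = homozygote_frequency(caf)
                for i in idx:
                    sub.loc[i, "gp"] = genetic_prevalence(caf, sub.loc[i, "mode"])
            gene_level = sub.drop_duplicates(subset="gene")
            cats = {"ALL": sf_genes}
            if acmg_categories:
                for g in sf_genes:
                    cats.setdefault(acmg_categories.get(g, "uncategorized"),
                                    set()).add(g)
            for cat, members in cats.items():
                gsub = sub[sub["gene"].isin(members)]
                glev = gene_level[gene_level["gene"].isin(members)]
                cum_crf = math.fsum(glev["crf"])
                cum_gp = math.fsum(gsub["gp"])
                rows.append({
                    "ancestry": anc, "tier_set": lab, "category": cat,
                    "n_genes": glev["gene"].nunique(),
                    "cumulative_crf": cum_crf,
                    "cumulative_gp": cum_gp,
                    "gp_one_in_x": format_one_in_x(cum_gp),
                })
    return pd.DataFrame(rows)


def _restricted_caf(variants: pd.DataFrame, retained_mask, ancestry: str,
                    gene: str, allowed: list[str], tier_set_label: str) -> float:
    ts = TierSet.from_label(tier_set_label)
    sub = variants[retained_mask.to_numpy() & (variants["gene"] == gene).to_numpy()
                   & variants["tier"].isin(ts.members).to_numpy()]
    ids = [variant_id(c, int(p), r, a) for c, p, r, a
           in zip(sub["chrom"], sub["pos"], sub["ref"], sub["alt"])]
    keep = [i for i, vid in enumerate(ids) if vid in set(allowed)]
    present = {ids[i] for i in keep}
    for vid in allowed:
        if vid not in present:
            logger.warning("SF restriction for %s names absent variant %s", gene, vid)
    if not keep:
        return 0.0
    rows = sub.iloc[keep]
    afs = rows[ac_col(ancestry)].to_numpy() / rows[an_col(ancestry)].to_numpy()
    return cumulative_af(afs, cap=True)


def screening_candidates(gene_burdens: pd.DataFrame,
                         threshold: float = 1.0 / 200.0,
                         tier_set: str = "P+LP") -> ScreeningResult:
    """Per-ancestry genes with CrF strictly above the screening threshold.

    The boundary is strict ("higher than 1 in 200"): a gene at exactly the
    threshold is not a candidate.
    """
    if threshold <= 0:
        raise DomainError("screening threshold must be positive")
    res = ScreeningResult(threshold=threshold)
    sub = gene_burdens[gene_burdens["tier_set"] == tier_set]
    for anc in sorted(gene_burdens["ancestry"].unique()):
        asub = sub[sub["ancestry"] == anc].drop_duplicates(subset="gene")
        res.per_ancestry[anc] = set(asub.loc[asub["crf"] > threshold, "gene"])
    return res


#: Constraint thresholds (strict comparisons): a gene is constrained when
#: pLI > 0.9, LOEUF < 0.6, S_het > 0.073, missense Z > 3.09 or synonymous
#: Z > 3.71 (LOEUF cutoff per the gnomAD v4 guidance update).
CONSTRAINT_THRESHOLDS = {
    "pLI": (">", 0.9),
    "LOEUF": ("<", 0.6),
    "s_het": (">", 0.073),
    "mis_z": (">", 3.09),
    "syn_z": (">", 3.71),
}

_FLAG_NAMES = {
    "pLI": "pLI_constrained",
    "LOEUF": "loeuf_constrained",
    "s_het": "shet_constrained",
    "mis_z": "misZ_constrained",
    "syn_z": "synZ_constrained",
}


def constraint_flags(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-gene constraint flags at the standard thresholds.

    A missing metric yields a missing flag (pandas NA), not False — absence
    of evidence is distinguished from evidence of tolerance.
    """
    out = pd.DataFrame({"gene": metrics["gene"]})
    for metric, (op, cut) in CONSTRAINT_THRESHOLDS.items():
        name = _FLAG_NAMES[metric]
        if metric not in metrics.columns:
            out[name] = pd.array([pd.NA] * len(metrics), dtype="boolean")
            continue
        vals = pd.to_numeric(metrics[metric], errors="coerce")
        flag = (vals > cut) if op == ">" else (vals < cut)
        flag = flag.astype("boolean")
        flag[vals.isna()] = pd.NA
        out[name] = flag
    return out
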