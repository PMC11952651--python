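"""Synthetic gnomAD-like cohort generator with recorded ground truth.

The generator emulates the *structure* of a classified gnomAD exome callset —
per-ancestry AC/AN for the eight genetic ancestry groups, a seven-tier
pathogenicity label per variant, a VQSR-style FILTER column, and a gene panel
with inheritance modes, disease mechanisms and ICD-10 group assignments — so
that every downstream stage (ingestion, QC, Hardy-Weinberg burden,
aggregation, grouping, screening) can be tested against known truth without
the multi-terabyte real download.

Frequencies only: no haplotypes, no linkage disequilibrium, no sequence
content. Variants within a gene assort independently, matching the additive
CAF model downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .schema import (
    ANCESTRIES,
    ICD10_GROUPS,
    MODE_AD,
    MODE_ADAR,
    MODE_AR,
    MODE_PAD,
    MODE_PAR,
    MODE_XLD,
    MODE_XLR,
    TIERS,
    TIER_SETS,
    ac_col,
    an_col,
    ploidy_of,
    variant_id,
)

__all__ = ["SimConfig", "SimulatedCohort", "GenotypeCounts", "simulate_cohort",
           "simulate_genotypes", "write_cohort"]

# Desk-scale per-ancestry exome counts (diploid individuals), shaped like the
# real callset's ancestry imbalance (nfe-dominated, mid smallest).
_DEFAULT_SAMPLE_SIZES = {
    "afr": 20_000, "amr": 15_000, "asj": 5_000, "eas": 10_000,
    "fin": 12_000, "mid": 3_000, "nfe": 60_000, "sas": 15_000,
}

# Tier fractions of all classified variants. P/LP/VUS-H match the observed
# classification breakdown (0.6% / 2.2% / 1.0%); the benign-side remainder is
# distributed so the seven tiers sum to exactly 1.
_DEFAULT_TIER_PROPORTIONS = {
    "P": 0.006, "LP": 0.022, "VUS-H": 0.010, "VUS-M": 0.032,
    "VUS-L": 0.399, "LB": 0.517, "B": 0.014,
}

# Proportional to the PanelApp inheritance breakdown over modes the pipeline
# can dispatch (2013 AR : 1425 AD : 256 AD/AR : 148 XLR : 65 XLD : 1 : 1).
_PANELAPP_COUNTS = {
    MODE_AR: 2013, MODE_AD: 1425, MODE_ADAR: 256, MODE_XLR: 148,
    MODE_XLD: 65, MODE_PAD: 1, MODE_PAR: 1,
}
_DEFAULT_INHERITANCE_MIX = {m: c / sum(_PANELAPP_COUNTS.values())
                            for m, c in _PANELAPP_COUNTS.items()}

# Genes per ICD-10 group count: ~33% in one group, ~35% in two, rest in 3-9
# with a long tail up to nine groups (KMT2D-like).
_DEFAULT_GROUPS_PER_GENE = {1: 0.33, 2: 0.35, 3: 0.16, 4: 0.08, 5: 0.04,
                            6: 0.02, 7: 0.01, 8: 0.005, 9: 0.005}

# World-scale population headcounts per ancestry group (plausible 2023-like
# magnitudes; used only for headcount conversion demos).
_DEFAULT_POPULATIONS = {
    "afr": 1_300_000_000, "amr": 660_000_000, "asj": 10_000_000,
    "eas": 1_900_000_000, "fin": 5_600_000, "mid": 500_000_000,
    "nfe": 1_000_000_000, "sas": 2_000_000_000,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Allele frequencies default to a truncated exponential on (0, 0.05]
    (rare-dominated, matching the pathogenic spectrum); ``common_fraction``
    mixes in uniform draws on ``common_range`` to emulate common-variant
    outliers like HFE C282Y or G6PD A-.
    """

    n_genes: int = 100
    ancestries: tuple[str, ...] = ANCESTRIES
    sample_size_per_ancestry: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_SAMPLE_SIZES))
    tier_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TIER_PROPORTIONS))
    inheritance_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INHERITANCE_MIX))
    af_distribution: dict = field(default_factory=lambda: {
        "name": "truncated-exponential", "scale": 0.002, "upper": 0.05,
        "common_fraction": 0.0, "common_range": (0.05, 0.45)})
    variants_per_gene: dict = field(default_factory=lambda: {
        "name": "poisson", "mean": 60.0})
    icd10_groups_per_gene: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS_PER_GENE))
    population_sizes: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_POPULATIONS))
    dual_phenotype_fraction: float = 0.01
    sf_fraction: float = 0.02
    sf_single_variant_fraction: float = 0.0
    non_pass_fraction: float = 0.05
    an_jitter: tuple[float, float] = (0.4, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or self.n_genes < 0:
            raise ConfigurationError(f"n_genes must be a nonnegative integer, got {self.n_genes!r}")
        if not self.ancestries:
            raise ConfigurationError("ancestries must be non-empty")
        for anc in self.ancestries:
            n = self.sample_size_per_ancestry.get(anc)
            if n is None or n <= 0:
                raise ConfigurationError(
                    f"sample_size_per_ancestry missing or non-positive for {anc!r}")
        for tier, p in self.tier_proportions.items():
            if tier not in TIERS:
                raise ConfigurationError(f"tier_proportions has unknown tier {tier!r}")
            if p < 0:
                raise ConfigurationError(f"tier_proportions[{tier!r}] negative")
        if math.fsum(self.tier_proportions.values()) > 1.0 + 1e-12:
            raise ConfigurationError("tier_proportions sum exceeds 1")
        mix_sum = math.fsum(self.inheritance_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigurationError(f"inheritance_mix must sum to 1, got {mix_sum}")
        for k, p in self.icd10_groups_per_gene.items():
            if not 1 <= int(k) <= 9 or p < 0:
                raise ConfigurationError("icd10_groups_per_gene keys must be in [1, 9] with nonnegative weights")
        lo, hi = self.an_jitter
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"an_jitter must satisfy 0 < lo <= hi <= 1, got {self.an_jitter}")
        if not 0.0 <= self.non_pass_fraction <= 1.0:
            raise ConfigurationError("non_pass_fraction outside [0, 1]")
        for anc in self.ancestries:
            if self.population_sizes.get(anc, 1) <= 0:
                raise ConfigurationError(f"population_sizes non-positive for {anc!r}")


@dataclass
class SimulatedCohort:
    """Generator output: input tables plus the recorded ground truth.

    ``ground_truth`` has one row per gene × ancestry × tier set with the
    exact (fsum) cumulative allele frequency over QC-surviving variants —
    what a correct pipeline must recover bit-for-bit.
    """

    variants: pd.DataFrame
    gene_meta: pd.DataFrame
    populations: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimConfig


def _chrom_for(mode: str, idx: int) -> str:
    if mode in (MODE_XLR, MODE_XLD):
        return "chrX"
    if mode in (MODE_PAD, MODE_PAR):
        return "chrX_PAR"
    return f"chr{1 + idx % 22}"


def _draw_afs(rng: np.random.Generator, n: int, spec: dict) -> np.ndarray:
    name = spec.get("name", "truncated-exponential")
    if name != "truncated-exponential":
        raise ConfigurationError(f"af_distribution name {name!r} not supported")
    scale = float(spec.get("scale", 0.002))
    upper = float(spec.get("upper", 0.05))
    if not (0.0 < upper <= 1.0) or scale <= 0:
        raise ConfigurationError("af_distribution requires scale > 0 and upper in (0, 1]")
    u = rng.random(n)
    # inverse CDF of Exp(scale) truncated to (0, upper]
    z = 1.0 - math.exp(-upper / scale)
    afs = -scale * np.log1p(-u * z)
    afs = np.clip(afs, np.nextafter(0.0, 1.0), upper)
    cf = float(spec.get("common_fraction", 0.0))
    if cf > 0:
        lo, hi = spec.get("common_range", (0.05, 0.45))
        common = rng.random(n) < cf
        afs[common] = rng.uniform(lo, hi, size=int(common.sum()))
    return afs


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a classified variant table, gene panel, populations and truth.

    Deterministic for a fixed seed. Per variant and ancestry, AN is drawn
    between ``an_jitter`` fractions of the callable alleles (ploidy ×
    sample size) so the downstream coverage filter sees both passing and
    failing rows, and AC ~ Binomial(AN, AF) for a variant-level true AF.
    Ground-truth CAF is the fsum of realized AC/AN over the rows that
    survive the PASS + coverage rule in that ancestry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ancestries = list(config.ancestries)

    empty_variants = _empty_variant_frame(ancestries)
    if config.n_genes == 0:
        return SimulatedCohort(
            variants=empty_variants,
            gene_meta=_empty_meta_frame(),
            populations=_population_frame(config, ancestries),
            ground_truth=pd.DataFrame(columns=["gene", "ancestry", "tier_set", "caf"]),
            config=config,
        )

    # --- gene panel ---------------------------------------------------
    n = config.n_genes
    genes = [f"GENE{i + 1:05d}" for i in range(n)]
    modes = list(config.inheritance_mix)
    mode_p = np.array([config.inheritance_mix[m] for m in modes], dtype=float)
    mode_p = mode_p / mode_p.sum()
    gene_mode = rng.choice(len(modes), size=n, p=mode_p)
    dual = rng.random(n) < config.dual_phenotype_fraction
    mech = np.where(dual, "LoF+GoF",
                    rng.choice(["LoF", "GoF", "LoF+GoF"], size=n, p=[0.92, 0.04, 0.04]))
    group_ks = sorted(int(k) for k in config.icd10_groups_per_gene)
    gk_p = np.array([config.icd10_groups_per_gene[k] for k in group_ks], dtype=float)
    gk_p = gk_p / gk_p.sum()
    n_groups = rng.choice(group_ks, size=n, p=gk_p)
    is_sf = rng.random(n) < config.sf_fraction

    meta_rows = []
    for i, g in enumerate(genes):
        mode = modes[gene_mode[i]]
        # dual-phenotype genes (ANO5-like): distinct dominant GoF and
        # recessive LoF conditions -> two inheritance entries
        inh = (MODE_AD, MODE_AR) if (dual[i] and mode in (MODE_AD, MODE_AR, MODE_ADAR)) else (mode,)
        groups = tuple(rng.choice(len(ICD10_GROUPS), size=n_groups[i], replace=False))
        group_labels = tuple(ICD10_GROUPS[j] for j in sorted(groups))
        meta_rows.append({
            "gene": g,
            "inheritance": "|".join(inh),
            "mechanism": mech[i],
            "icd10_groups": "|".join(group_labels),
            "panels": "|".join(f"{lab} panel" for lab in group_labels),
            "is_secondary_finding": int(is_sf[i]),
            "sf_variant_restriction": "",
            "chrom": _chrom_for(mode, i),
        })
    gene_meta = pd.DataFrame(meta_rows)

    # --- variants -----------------------------------------------------
    if config.variants_per_gene.get("name", "poisson") != "poisson":
        raise ConfigurationError("variants_per_gene distribution must be 'poisson'")
    n_var = rng.poisson(float(config.variants_per_gene["mean"]), size=n)

    tier_labels = list(TIERS)
    tier_p = np.array([config.tier_proportions.get(t, 0.0) for t in tier_labels])
    rem = 1.0 - tier_p.sum()
    if rem > 1e-12:
        # remainder goes to the most benign class not explicitly weighted
        tier_p = tier_p.copy()
        tier_p[tier_labels.index("B")] += rem
    tier_p = tier_p / tier_p.sum()

    alts = np.array(["T", "G", "C"])
    var_rows = []
    for i, g in enumerate(genes):
        m = int(n_var[i])
        if m == 0:
            continue
        chrom = gene_meta.loc[i, "chrom"]
        tiers = rng.choice(len(tier_labels), size=m, p=tier_p)
        afs = _draw_afs(rng, m, config.af_distribution)
        filt = np.where(rng.random(m) < config.non_pass_fraction, "LowQual", "PASS")
        alt_idx = rng.integers(0, len(alts), size=m)
        base_pos = 1_000_000 * (i + 1)
        for j in range(m):
            var_rows.append({
                "chrom": chrom,
                "pos": base_pos + 10 * j,
                "ref": "A",
                "alt": alts[alt_idx[j]],
                "gene": g,
                "tier": tier_labels[tiers[j]],
                "filter": filt[j],
                "_af_true": afs[j],
            })
    variants = pd.DataFrame(var_rows) if var_rows else empty_variants.assign(_af_true=[])

    if len(variants):
        lo, hi = config.an_jitter
        for anc in ancestries:
            n_ind = config.sample_size_per_ancestry[anc]
            ploidy = variants["chrom"].map(ploidy_of).to_numpy()
            callable_alleles = np.rint(ploidy * n_ind).astype(np.int64)
            an_lo = np.ceil(lo * callable_alleles).astype(np.int64)
            an_hi = np.floor(hi * callable_alleles).astype(np.int64)
            an = rng.integers(an_lo, an_hi + 1)
            ac = rng.binomial(an, variants["_af_true"].to_numpy())
            variants[ac_col(anc)] = ac
            variants[an_col(anc)] = an

    # --- SF single-variant restrictions (HFE-like) --------------------
    if config.sf_single_variant_fraction > 0 and len(variants):
        sf_idx = [i for i in range(n) if is_sf[i]]
        for i in sf_idx:
            if rng.random() >= config.sf_single_variant_fraction:
                continue
            rows = variants.index[variants["gene"] == genes[i]]
            if len(rows) == 0:
                continue
            pick = variants.loc[rng.choice(rows)]
            gene_meta.loc[i, "sf_variant_restriction"] = variant_id(
                pick["chrom"], int(pick["pos"]), pick["ref"], pick["alt"])

    # --- ground truth over QC-surviving rows --------------------------
    gt_rows = []
    gene_col = variants["gene"].to_numpy() if len(variants) else np.array([], dtype=object)
    for anc in ancestries:
        n_ind = config.sample_size_per_ancestry[anc]
        if len(variants):
            ploidy = variants["chrom"].map(ploidy_of).to_numpy()
            threshold = 0.5 * ploidy * n_ind
            retained = ((variants["filter"] == "PASS").to_numpy()
                        & (variants[an_col(anc)].to_numpy() > threshold))
            af = variants[ac_col(anc)].to_numpy() / variants[an_col(anc)].to_numpy()
        else:
            retained = np.zeros(0, dtype=bool)
            af = np.zeros(0)
        for label, members in TIER_SETS.items():
            if len(variants):
                mask = retained & variants["tier"].isin(members).to_numpy()
                sums = (pd.Series(af[mask])
                        .groupby(pd.Series(gene_col[mask]))
                        .agg(lambda x: math.fsum(x)))
            else:
                sums = pd.Series(dtype=float)
            for g in genes:
                gt_rows.append({"gene": g, "ancestry": anc, "tier_set": label,
                                "caf": float(sums.get(g, 0.0))})
    ground_truth = pd.DataFrame(gt_rows)

    variants = variants.drop(columns=["_af_true"], errors="ignore")
    gene_meta = gene_meta.drop(columns=["chrom"])
    return SimulatedCohort(
        variants=variants.reset_index(drop=True),
        gene_meta=gene_meta,
        populations=_population_frame(config, ancestries),
        ground_truth=ground_truth,
        config=config,
    )


def _empty_variant_frame(ancestries) -> pd.DataFrame:
    cols = ["chrom", "pos", "ref", "alt", "gene", "tier", "filter"]
    for anc in ancestries:
        cols += [ac_col(anc), an_col(anc)]
    return pd.DataFrame(columns=cols)


def _empty_meta_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "inheritance", "mechanism", "icd10_groups",
                                 "panels", "is_secondary_finding", "sf_variant_restriction"])


def _population_frame(config: SimConfig, ancestries) -> pd.DataFrame:
    return pd.DataFrame({
        "ancestry": ancestries,
        "population": [config.population_sizes[a] for a in ancestries],
    })


@dataclass
class GenotypeCounts:
    """Monte-Carlo genotype tallies for one gene-level CAF."""

    non_carrier: int
    heterozygous: int
    biallelic_or_hemizygous: int

    @property
    def n(self) -> int:
        return self.non_carrier + self.heterozygous + self.biallelic_or_hemizygous

    def fractions(self) -> dict[str, float]:
        n = self.n
        return {
            "non_carrier": self.non_carrier / n,
            "heterozygous": self.heterozygous / n,
            "biallelic_or_hemizygous": self.biallelic_or_hemizygous / n,
        }


_X_MODES = {MODE_XLR, MODE_XLD}


def simulate_genotypes(caf: float, n_individuals: int, mode: str = MODE_AR,
                       seed: int = 0) -> GenotypeCounts:
    """Draw individual genotypes for a gene with cumulative allele
    frequency *caf* and tally carriers.

    Autosomal modes draw two independent alleles per individual (HWE); for
    X-linked modes sexes are drawn 1:1 and males carry a single allele, so a
    carrier male is hemizygous (counted with biallelic genotypes).

    This is the independent Monte-Carlo oracle for the closed-form CrF, HomF
    and X-linked prevalence formulas.
    """
    if not 0.0 <= caf <= 1.0:
        raise DomainError(f"CAF {caf} outside [0, 1]")
    if n_individuals <= 0:
        raise DomainError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    if mode in _X_MODES:
        males = int(rng.binomial(n_individuals, 0.5))
        females = n_individuals - males
        male_carriers = int(rng.binomial(males, caf))
        f_counts = rng.multinomial(
            females, [(1 - caf) ** 2, 2 * caf * (1 - caf), caf ** 2])
        return GenotypeCounts(
            non_carrier=(males - male_carriers) + int(f_counts[0]),
            heterozygous=int(f_counts[1]),
            biallelic_or_hemizygous=male_carriers + int(f_counts[2]),
        )
    counts = rng.multinomial(
        n_individuals, [(1 - caf) ** 2, 2 * caf * (1 - caf), caf ** 2])
    return GenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2]))


# ---------------------------------------------------------------------------
# writers

_VCF_INFO_ORDER = ("GENE", "TIER")


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, str]:
    """Write the cohort bundle as TSVs plus a VCF rendering of the variants.

    Returns a name→path map of everything written.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants_tsv": out / "variants.tsv",
        "variants_vcf": out / "variants.vcf",
        "gene_meta": out / "gene_meta.tsv",
        "populations": out / "populations.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    cohort.variants.to_csv(paths["variants_tsv"], sep="\t", index=False)
    write_vcf(cohort.variants, paths["variants_vcf"],
              ancestries=list(cohort.config.ancestries))
    cohort.gene_meta.to_csv(paths["gene_meta"], sep="\t", index=False)
    cohort.populations.to_csv(paths["populations"], sep="\t", index=False)
    cohort.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False,
                               float_format="%.17g")
    return {k: str(v) for k, v in paths.items()}


def write_vcf(variants: pd.DataFrame, path, ancestries=None) -> None:
    """Render a variant frame as VCF 4.2 with AC_<anc>/AN_<anc>, GENE and
    TIER INFO keys and the FILTER column carrying the QC status."""
    ancestries = list(ancestries or ANCESTRIES)
    chroms = list(dict.fromkeys(variants["chrom"])) if len(variants) else []
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FILTER=<ID=LowQual,Description="Failed variant quality recalibration">')
    for anc in ancestries:
        lines.append(f'##INFO=<ID=AC_{anc},Number=A,Type=Integer,'
                     f'Description="Allele count in {anc} ancestry">')
        lines.append(f'##INFO=<ID=AN_{anc},Number=1,Type=Integer,'
                     f'Description="Allele number in {anc} ancestry">')
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##INFO=<ID=TIER,Number=1,Type=String,Description="Pathogenicity tier">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for row in variants.itertuples(index=False):
        info = []
        for anc in ancestries:
            info.append(f"AC_{anc}={getattr(row, ac_col(anc))}")
            info.append(f"AN_{anc}={getattr(row, an_col(anc))}")
        info.append(f"GENE={row.gene}")
        info.append(f"TIER={row.tier}")
        lines.append("\t".join([
            str(row.chrom), str(row.pos), ".", row.ref, row.alt, ".",
            row.filter, ";".join(info)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
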