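"""Input readers and the quality-control / gene-eligibility filters.

Variant tables arrive either as VCF (INFO keys ``AC_<anc>``/``AN_<anc>``,
``GENE``, ``TIER``; FILTER column) or as a TSV with matching column names.
Gene metadata, population sizes, constraint metrics and reported prevalences
are TSVs; multi-valued metadata fields are pipe-delimited.

Two filters gate the analysis:

* **QC retention** — a variant is retained *per ancestry* iff its FILTER is
  PASS and its AN exceeds half the callable alleles for that ancestry
  (coverage in more than 50% of individuals, translated to allele numbers
  via ploidy: 2 for autosomes/PAR, 1.5 for chrX non-PAR, 0.5 for chrY).
  The boundary is strict ("more than").
* **Gene eligibility** — genes with undefined or mitochondrial inheritance,
  an undefined disease mechanism, or a repeat-expansion-only mechanism are
  excluded with a machine-readable reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, IntegrityError
from .schema import (
    ANCESTRIES,
    ICD10_GROUPS,
    INELIGIBLE_INHERITANCE,
    TIERS,
    ac_col,
    an_col,
    ploidy_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord", "GeneMeta",
    "read_variants", "variants_to_frame", "qc_filter", "eligible_genes",
    "read_gene_meta", "read_population_sizes", "read_constraints",
    "read_reported_prevalence", "constraint_columns",
]


@dataclass
class VariantRecord:
    """One classified variant with per-ancestry allele counts."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    tier: str
    filter_status: str
    ac: dict[str, int] = field(default_factory=dict)
    an: dict[str, int] = field(default_factory=dict)


@dataclass
class GeneMeta:
    """Panel metadata for one gene."""

    gene: str
    inheritance: frozenset[str]
    mechanism: str
    icd10_groups: frozenset[str]
    panels: frozenset[str] = frozenset()
    is_secondary_finding: bool = False
    sf_variant_restriction: tuple[str, ...] = ()


def _check_record(rec: VariantRecord, where: str) -> None:
    if rec.tier not in TIERS:
        raise FormatError(f"{where}: unknown tier {rec.tier!r}")
    for anc, ac in rec.ac.items():
        an = rec.an[anc]
        if ac < 0 or an < 0:
            raise IntegrityError(f"{where}: negative AC or AN for ancestry {anc}")
        if ac > an:
            raise IntegrityError(
                f"{where}: AC_{anc}={ac} exceeds AN_{anc}={an}")


def read_variants(path, dialect: str = "tsv",
                  ancestries: tuple[str, ...] = ANCESTRIES) -> list[VariantRecord]:
    """Read a classified variant table.

    ``dialect`` is ``"tsv"`` or ``"vcf"``. Multiallelic VCF sites are split
    into one record per alternate allele. Rows violating AC ≤ AN raise an
    :class:`IntegrityError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"variant table {path} does not exist")
    if dialect == "tsv":
        return _read_variants_tsv(path, ancestries)
    if dialect == "vcf":
        return _read_variants_vcf(path, ancestries)
    raise ConfigurationError(f"unknown variant dialect {dialect!r}")


def _read_variants_tsv(path: Path, ancestries) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = ["chrom", "pos", "ref", "alt", "gene", "tier", "filter"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for anc in ancestries:
        for col in (ac_col(anc), an_col(anc)):
            if col not in df.columns:
                raise FormatError(f"{path}: missing AC/AN column {col!r} "
                                  f"for declared ancestry {anc!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=row.gene, tier=row.tier, filter_status=getattr(row, "filter"),
            ac={anc: int(getattr(row, ac_col(anc))) for anc in ancestries},
            an={anc: int(getattr(row, an_col(anc))) for anc in ancestries},
        )
        _check_record(rec, f"{path} line {i}")
        records.append(rec)
    logger.info("read %d variant records from %s", len(records), path)
    return records


def _read_variants_vcf(path: Path, ancestries) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for anc in ancestries:
            for key in (f"AC_{anc}", f"AN_{anc}"):
                if key not in vcf.header.info:
                    raise FormatError(
                        f"{path}: VCF header lacks INFO field {key} "
                        f"for declared ancestry {anc!r}")
        for n, site in enumerate(vcf, start=1):
            where = f"{path} record {n} ({site.chrom}:{site.pos})"
            filt = list(site.filter.keys())
            status = "PASS" if (not filt or filt == ["PASS"]) else ";".join(filt)
            alts = site.alts or ()
            gene = _info_scalar(site.info.get("GENE"))
            tier = _info_scalar(site.info.get("TIER"))
            if gene is None or tier is None:
                raise FormatError(f"{where}: missing GENE or TIER INFO field")
            for ai, alt in enumerate(alts):  # split multiallelics, one record per alt
                ac, an = {}, {}
                for anc in ancestries:
                    ac_val = site.info.get(f"AC_{anc}")
                    an_val = site.info.get(f"AN_{anc}")
                    if ac_val is None or an_val is None:
                        raise FormatError(f"{where}: missing AC_{anc}/AN_{anc}")
                    ac[anc] = int(ac_val[ai] if isinstance(ac_val, tuple) else ac_val)
                    an[anc] = int(_info_scalar(an_val))
                rec = VariantRecord(
                    chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt,
                    gene=gene, tier=tier, filter_status=status, ac=ac, an=an)
                _check_record(rec, where)
                records.append(rec)
    logger.info("read %d variant records from %s", len(records), path)
    return records


def _info_scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value


def variants_to_frame(records: list[VariantRecord],
                      ancestries: tuple[str, ...] = ANCESTRIES) -> pd.DataFrame:
    """Tidy frame with one row per record — the working representation."""
    rows = []
    for r in records:
        row = {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
               "gene": r.gene, "tier": r.tier, "filter": r.filter_status}
        for anc in ancestries:
            row[ac_col(anc)] = r.ac[anc]
            row[an_col(anc)] = r.an[anc]
        rows.append(row)
    if not rows:
        cols = ["chrom", "pos", "ref", "alt", "gene", "tier", "filter"]
        for anc in ancestries:
            cols += [ac_col(anc), an_col(anc)]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def qc_filter(variants: pd.DataFrame,
              sample_size_per_ancestry: dict[str, int],
              ploidy_map: dict[str, float] | None = None,
              ancestries: tuple[str, ...] | None = None,
              denominator: str = "per-ancestry") -> dict[str, pd.Series]:
    """Per-ancestry retention masks for the PASS + coverage rule.

    Returns ``{ancestry: boolean Series}`` aligned to the frame's index.
    Retention is independent across ancestries: a variant well covered in one
    group may fail coverage in another. ``denominator`` selects whether the
    50% rule is evaluated against the ancestry's own sample size
    (``"per-ancestry"``, default) or the total across ancestries
    (``"total"``).
    """
    if ancestries is None:
        ancestries = tuple(a for a in ANCESTRIES if ac_col(a) in variants.columns)
    for anc in ancestries:
        if anc not in sample_size_per_ancestry:
            raise ConfigurationError(f"sample_size_per_ancestry lacks ancestry {anc!r}")
        if sample_size_per_ancestry[anc] <= 0:
            raise ConfigurationError(f"sample size for {anc!r} must be positive")
    if denominator not in ("per-ancestry", "total"):
        raise ConfigurationError(f"unknown coverage denominator {denominator!r}")
    total_n = sum(sample_size_per_ancestry[a] for a in ancestries)
    is_pass = variants["filter"] == "PASS" if len(variants) else pd.Series(dtype=bool)
    ploidy = (variants["chrom"].map(lambda c: ploidy_of(c, ploidy_map)).to_numpy()
              if len(variants) else np.zeros(0))
    out = {}
    for anc in ancestries:
        n_ind = total_n if denominator == "total" else sample_size_per_ancestry[anc]
        if len(variants):
            threshold = 0.5 * ploidy * n_ind
            mask = is_pass & (variants[an_col(anc)].to_numpy() > threshold)
        else:
            mask = pd.Series(dtype=bool)
        out[anc] = mask
        logger.info("qc_filter[%s]: retained %d of %d variants",
                    anc, int(mask.sum()), len(variants))
    return out


# reason codes for gene exclusion
REASON_INHERITANCE = "inheritance"
REASON_MECHANISM = "mechanism"


def eligible_genes(meta: pd.DataFrame) -> tuple[set, pd.DataFrame]:
    """Partition the gene panel into analyzable and excluded genes.

    Excluded: inheritance entirely undefined/mitochondrial (reason
    ``inheritance``); mechanism undefined or repeat-expansion-only (reason
    ``mechanism``). Returns ``(kept gene set, frame of gene/reason rows)``.
    """
    kept, excluded = set(), []
    for row in meta.itertuples(index=False):
        inh = set(_split_multi(row.inheritance))
        if inh and inh <= INELIGIBLE_INHERITANCE:
            excluded.append({"gene": row.gene, "reason": REASON_INHERITANCE})
        elif not inh:
            excluded.append({"gene": row.gene, "reason": REASON_INHERITANCE})
        elif row.mechanism in ("undefined", "repeat-expansion-only"):
            excluded.append({"gene": row.gene, "reason": REASON_MECHANISM})
        else:
            kept.add(row.gene)
    exc = pd.DataFrame(excluded, columns=["gene", "reason"])
    logger.info("eligible_genes: kept %d, excluded %d", len(kept), len(exc))
    return kept, exc


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    return [p for p in s.split("|") if p] if s else []


def read_gene_meta(path) -> pd.DataFrame:
    """Gene panel metadata TSV with pipe-delimited multi-valued fields."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, keep_default_na=False)
    required = ["gene", "inheritance", "mechanism", "icd10_groups"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: gene metadata missing column {col!r}")
    for optional, default in (("panels", ""), ("is_secondary_finding", 0),
                              ("sf_variant_restriction", "")):
        if optional not in df.columns:
            df[optional] = default
    df["is_secondary_finding"] = df["is_secondary_finding"].astype(int).astype(bool)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        groups = _split_multi(row.icd10_groups)
        if not 1 <= len(groups) <= 9:
            raise IntegrityError(
                f"{path} line {i}: gene {row.gene} has {len(groups)} ICD-10 "
                f"groups; expected 1-9")
        for g in groups:
            if g not in ICD10_GROUPS:
                raise FormatError(f"{path} line {i}: unknown ICD-10 group {g!r}")
    return df


def gene_meta_records(meta: pd.DataFrame) -> dict[str, GeneMeta]:
    """Parse the metadata frame into per-gene :class:`GeneMeta` objects."""
    out = {}
    for row in meta.itertuples(index=False):
        out[row.gene] = GeneMeta(
            gene=row.gene,
            inheritance=frozenset(_split_multi(row.inheritance)),
            mechanism=row.mechanism,
            icd10_groups=frozenset(_split_multi(row.icd10_groups)),
            panels=frozenset(_split_multi(getattr(row, "panels", ""))),
            is_secondary_finding=bool(getattr(row, "is_secondary_finding", False)),
            sf_variant_restriction=tuple(
                _split_multi(getattr(row, "sf_variant_restriction", ""))),
        )
    return out


def read_population_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    for col in ("ancestry", "population"):
        if col not in df.columns:
            raise FormatError(f"{path}: population table missing column {col!r}")
    sizes = dict(zip(df["ancestry"], df["population"].astype(int)))
    for anc, n in sizes.items():
        if n <= 0:
            raise IntegrityError(f"{path}: population for {anc!r} must be positive")
    return sizes


def constraint_columns() -> tuple[str, ...]:
    return ("pLI", "LOEUF", "s_het", "mis_z", "syn_z")


def read_constraints(path) -> pd.DataFrame:
    """Optional per-gene constraint metrics; missing values stay missing."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise FormatError(f"{path}: constraint table missing 'gene' column")
    present = [c for c in constraint_columns() if c in df.columns]
    if not present:
        raise FormatError(f"{path}: no recognized constraint metric columns "
                          f"(expected any of {constraint_columns()})")
    pli = df.get("pLI")
    if pli is not None and ((pli.dropna() < 0) | (pli.dropna() > 1)).any():
        raise IntegrityError(f"{path}: pLI values outside [0, 1]")
    return df


def read_reported_prevalence(path) -> pd.DataFrame:
    """Reported disease prevalences for validation (gene, rp, stratum/region)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "rp"):
        if col not in df.columns:
            raise FormatError(f"{path}: reported-prevalence table missing column {col!r}")
    bad = df[(df["rp"] <= 0) | (df["rp"] >= 1)]
    if len(bad):
        raise IntegrityError(
            f"{path}: reported prevalence outside (0, 1) for genes "
            f"{bad['gene'].tolist()}")
    return df
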