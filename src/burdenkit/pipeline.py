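"""End-to-end pipeline: ingest → QC → Hardy-Weinberg burden → cohort
aggregation → disease groups / secondary findings / screening → validation.

A :class:`PipelineConfig` names the input tables and the analysis knobs;
:func:`run_pipeline` executes every stage, writes all output tables to the
output directory along with a JSON manifest (carrying a hash of the
configuration) and a run log recording retention counts and every warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate, compare, groups as groups_mod, ingest
from .errors import ConfigurationError
from .hwe import burden_table, format_one_in_x
from .schema import ANCESTRIES, TIER_SET_LABELS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    variants_path: str
    gene_meta_path: str
    populations_path: str
    sample_size_per_ancestry: dict[str, int]
    out_dir: str = "burden_out"
    dialect: str = "tsv"
    constraints_path: str | None = None
    reported_path: str | None = None
    ancestries: tuple[str, ...] = ANCESTRIES
    tier_sets: tuple[str, ...] = TIER_SET_LABELS
    screening_threshold: float = 1.0 / 200.0
    screening_tier_set: str = "P+LP"
    rcrf_convention: str = "as-printed"
    stratum_map: dict[str, str] = field(
        default_factory=lambda: dict(compare.DEFAULT_STRATUM_MAP))
    qc_denominator: str = "per-ancestry"

    def validate(self) -> None:
        for lab in self.tier_sets:
            if lab not in TIER_SET_LABELS:
                raise ConfigurationError(
                    f"unknown tier set label {lab!r}; expected one of {TIER_SET_LABELS}")
        if self.screening_tier_set not in self.tier_sets:
            raise ConfigurationError(
                f"screening_tier_set {self.screening_tier_set!r} not among tier_sets")
        if self.dialect not in ("tsv", "vcf"):
            raise ConfigurationError(f"unknown variant dialect {self.dialect!r}")
        if self.qc_denominator not in ("per-ancestry", "total"):
            raise ConfigurationError(
                f"unknown qc_denominator {self.qc_denominator!r}")
        if self.screening_threshold <= 0:
            raise ConfigurationError("screening_threshold must be positive")
        for anc in self.ancestries:
            if self.sample_size_per_ancestry.get(anc, 0) <= 0:
                raise ConfigurationError(
                    f"sample_size_per_ancestry missing or non-positive for {anc!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.ancestries, list):
            cfg.ancestries = tuple(cfg.ancestries)
        if isinstance(cfg.tier_sets, list):
            cfg.tier_sets = tuple(cfg.tier_sets)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory view of everything a run computed and wrote."""

    config: PipelineConfig
    variants: pd.DataFrame
    retained: dict[str, pd.Series]
    gene_burdens: pd.DataFrame
    cohort: pd.DataFrame
    group_burdens: pd.DataFrame
    screening: groups_mod.ScreeningResult
    sf_summary: pd.DataFrame
    constraint_flags: pd.DataFrame | None
    comparisons: pd.DataFrame | None
    regressions: dict | None
    paths: dict[str, str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    Configuration errors surface before any computation; stage errors
    propagate with their module context intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = logging.getLogger("burdenkit")
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(config, out, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prior_level)


def _run(config: PipelineConfig, out: Path, log_path: Path) -> PipelineResult:
    logger.info("pipeline start; config hash %s", config.config_hash())

    records = ingest.read_variants(config.variants_path, dialect=config.dialect,
                                   ancestries=config.ancestries)
    variants = ingest.variants_to_frame(records, ancestries=config.ancestries)
    meta_frame = ingest.read_gene_meta(config.gene_meta_path)
    populations = ingest.read_population_sizes(config.populations_path)

    kept, excluded = ingest.eligible_genes(meta_frame)
    meta = {g: m for g, m in ingest.gene_meta_records(meta_frame).items()
            if g in kept}
    retained = ingest.qc_filter(
        variants, config.sample_size_per_ancestry,
        ancestries=config.ancestries, denominator=config.qc_denominator)

    gene_burdens = burden_table(variants, retained, meta,
                                tier_sets=config.tier_sets,
                                ancestries=list(config.ancestries))
    cohort = aggregate.cohort_summary(gene_burdens, populations=populations)
    group_burdens = groups_mod.group_burden_table(gene_burdens, meta)
    screening = groups_mod.screening_candidates(
        gene_burdens, threshold=config.screening_threshold,
        tier_set=config.screening_tier_set)
    sf_summary = groups_mod.secondary_findings_summary(
        gene_burdens, meta, variants=variants, retained=retained)

    flags = None
    if config.constraints_path:
        flags = groups_mod.constraint_flags(
            ingest.read_constraints(config.constraints_path))

    comparisons = regressions = None
    if config.reported_path:
        reported = ingest.read_reported_prevalence(config.reported_path)
        comp_list, regressions = compare.compare_crf(
            gene_burdens, reported, convention=config.rcrf_convention,
            stratum_map=config.stratum_map)
        comparisons = compare.comparisons_to_frame(comp_list)

    paths = _write_outputs(config, out, excluded, gene_burdens, cohort,
                           group_burdens, screening, sf_summary, flags,
                           comparisons, regressions)
    paths["run_log"] = str(log_path)
    logger.info("pipeline done; outputs in %s", out)
    return PipelineResult(
        config=config, variants=variants, retained=retained,
        gene_burdens=gene_burdens, cohort=cohort, group_burdens=group_burdens,
        screening=screening, sf_summary=sf_summary, constraint_flags=flags,
        comparisons=comparisons, regressions=regressions, paths=paths)


def _write_outputs(config, out: Path, excluded, gene_burdens, cohort,
                   group_burdens, screening, sf_summary, flags,
                   comparisons, regressions) -> dict[str, str]:
    paths: dict[str, str] = {}

    gb = gene_burdens.copy()
    gb["crf_one_in_x"] = gb["crf"].map(format_one_in_x)
    gb["gp_one_in_x"] = gb["gp"].map(format_one_in_x)
    paths["gene_burdens"] = _write(gb, out / "gene_burdens.tsv")
    paths["excluded_genes"] = _write(excluded, out / "excluded_genes.tsv")
    paths["cohort_summary"] = _write(cohort, out / "cohort_summary.tsv")
    paths["group_burdens"] = _write(group_burdens, out / "group_burdens.tsv")

    scr_rows = [{"ancestry": anc, "gene": g, "shared": g in screening.shared_across_ancestries}
                for anc, genes in screening.per_ancestry.items()
                for g in sorted(genes)]
    paths["screening"] = _write(
        pd.DataFrame(scr_rows, columns=["ancestry", "gene", "shared"]),
        out / "screening_candidates.tsv")
    paths["sf_summary"] = _write(sf_summary, out / "secondary_findings.tsv")
    if flags is not None:
        paths["constraint_flags"] = _write(flags, out / "constraint_flags.tsv")
    if comparisons is not None:
        paths["crf_comparison"] = _write(comparisons, out / "crf_comparison.tsv")
        reg = {s: dataclasses.asdict(r) for s, r in (regressions or {}).items()}
        reg_path = out / "crf_regression.json"
        reg_path.write_text(json.dumps(reg, indent=2))
        paths["crf_regression"] = str(reg_path)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": dict(paths),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(mpath)
    return paths


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return str(path)
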