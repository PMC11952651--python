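"""Cohort-level aggregation of per-gene burdens.

Three population summaries per ancestry × tier set:

* expected number of genes in which an individual carries at least one
  qualifying variant — Σ CrF over genes, each gene counted once regardless
  of inheritance mode;
* expected number of disease-compatible genotypes — Σ GP over (gene, mode)
  pairs, so a dual-phenotype gene contributes both its dominant and its
  recessive prevalence;
* the likelihood of carrying nothing at all, Π(1 − CrFᵢ), evaluated in log
  space.

Σ CrF is an expected count, not a probability: with thousands of genes it
routinely exceeds 1 (each CrF is the marginal probability of carrying in
that gene, and expectations add).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BurdenKitError, DomainError, IntegrityError
from .hwe import format_one_in_x
from .schema import ANCESTRIES

logger = logging.getLogger(__name__)

__all__ = [
    "CohortBurden", "expected_carried_genes", "expected_disease_genotypes",
    "non_carrier_likelihood", "ancestry_mean", "headcount", "cohort_summary",
]


@dataclass
class CohortBurden:
    """Aggregate burden for one ancestry (or the cross-ancestry mean)."""

    ancestry: str
    tier_set: str
    expected_carried_genes: float
    expected_disease_genotypes: float
    non_carrier_likelihood: float
    headcount: int | None = None


def expected_carried_genes(burdens: pd.DataFrame) -> float:
    """Σ CrF over genes for one ancestry × tier set.

    *burdens* must carry one row per gene (deduplicate (gene, mode) rows
    first — CrF depends only on CAF, so any mode's row serves).
    """
    if burdens["gene"].duplicated().any():
        dups = burdens.loc[burdens["gene"].duplicated(), "gene"].tolist()
        raise IntegrityError(f"duplicate gene entries after dedup: {dups}")
    return math.fsum(burdens["crf"])


def expected_disease_genotypes(burdens: pd.DataFrame) -> float:
    """Σ GP over unique (gene, mode) pairs for one ancestry × tier set."""
    if burdens.duplicated(subset=["gene", "mode"]).any():
        raise IntegrityError("duplicate (gene, mode) pairs in burden table")
    return math.fsum(burdens["gp"])


def non_carrier_likelihood(crfs) -> float:
    """Π(1 − CrFᵢ), computed as exp(Σ log1p(−CrFᵢ)) for stability.

    Empty input gives 1 (the empty product); any CrF of exactly 1 gives 0
    with a warning.
    """
    crfs = np.asarray(list(crfs), dtype=float)
    if crfs.size == 0:
        return 1.0
    if ((crfs < 0) | (crfs > 1)).any():
        raise DomainError("carrier frequencies must lie in [0, 1]")
    if (crfs == 1.0).any():
        logger.warning("non_carrier_likelihood: a CrF of exactly 1 forces the product to 0")
        return 0.0
    return float(np.exp(np.sum(np.log1p(-crfs))))


def ancestry_mean(values: dict[str, float],
                  expected: tuple[str, ...] = ANCESTRIES) -> float:
    """Unweighted arithmetic mean across ancestries.

    Warns (but proceeds) when a subset of the expected ancestries is
    supplied; raises on empty input.
    """
    if not values:
        raise BurdenKitError("ancestry_mean of empty input")
    missing = set(expected) - set(values)
    if missing:
        logger.warning("ancestry_mean over subset; missing %s", sorted(missing))
    return float(np.mean(list(values.values())))


def headcount(rate, populations: dict[str, int], scope: str = "all") -> int:
    """Convert a rate (or per-ancestry rates) into affected individuals.

    *rate* may be a scalar (applied to every scoped population) or a
    per-ancestry mapping; ``scope`` is ``"all"`` or a single ancestry code.
    """
    ancs = list(populations) if scope == "all" else [scope]
    for anc in ancs:
        if anc not in populations:
            raise BurdenKitError(f"population size missing for ancestry {anc!r}")
        if populations[anc] <= 0:
            raise DomainError(f"population for {anc!r} must be positive")
    if isinstance(rate, dict):
        for anc in ancs:
            if anc not in rate:
                raise BurdenKitError(f"rate missing for ancestry {anc!r}")
        total = math.fsum(rate[a] * populations[a] for a in ancs)
    else:
        total = math.fsum(rate * populations[a] for a in ancs)
    return int(round(total))


def cohort_summary(burden_table: pd.DataFrame,
                   populations: dict[str, int] | None = None) -> pd.DataFrame:
    """Cohort summary keyed by (ancestry | ALL, tier_set).

    Per ancestry × tier set: expected carried genes (Σ CrF, one entry per
    gene), expected disease genotypes (Σ GP over (gene, mode)), non-carrier
    likelihood, "1 in x" renderings, and — when population sizes are given —
    the implied headcount of non-carriers. The ``ALL`` rows are unweighted
    means across the ancestries present (headcounts summed).
    """
    rows = []
    ancestries = sorted(burden_table["ancestry"].unique())
    tier_sets = list(dict.fromkeys(burden_table["tier_set"]))
    for lab in tier_sets:
        per_anc: dict[str, CohortBurden] = {}
        for anc in ancestries:
            sub = burden_table[(burden_table["ancestry"] == anc)
                               & (burden_table["tier_set"] == lab)]
            gene_level = sub.drop_duplicates(subset="gene")
            ecg = expected_carried_genes(gene_level)
            edg = expected_disease_genotypes(sub)
            ncl = non_carrier_likelihood(gene_level["crf"])
            hc = (headcount(ncl, populations, scope=anc)
                  if populations is not None and anc in populations else None)
            per_anc[anc] = CohortBurden(anc, lab, ecg, edg, ncl, hc)
        for anc, cb in per_anc.items():
            rows.append(_summary_row(cb))
        mean_cb = CohortBurden(
            ancestry="ALL", tier_set=lab,
            expected_carried_genes=ancestry_mean(
                {a: c.expected_carried_genes for a, c in per_anc.items()},
                expected=tuple(ancestries)),
            expected_disease_genotypes=ancestry_mean(
                {a: c.expected_disease_genotypes for a, c in per_anc.items()},
                expected=tuple(ancestries)),
            non_carrier_likelihood=ancestry_mean(
                {a: c.non_carrier_likelihood for a, c in per_anc.items()},
                expected=tuple(ancestries)),
            headcount=(sum(c.headcount for c in per_anc.values())
                       if populations is not None
                       and all(c.headcount is not None for c in per_anc.values())
                       else None),
        )
        rows.append(_summary_row(mean_cb))
    return pd.DataFrame(rows)


def _summary_row(cb: CohortBurden) -> dict:
    return {
        "ancestry": cb.ancestry,
        "tier_set": cb.tier_set,
        "expected_carried_genes": cb.expected_carried_genes,
        "expected_disease_genotypes": cb.expected_disease_genotypes,
        "non_carrier_likelihood": cb.non_carrier_likelihood,
        "non_carrier_one_in_x": format_one_in_x(cb.non_carrier_likelihood),
        "non_carrier_headcount": cb.headcount,
    }
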