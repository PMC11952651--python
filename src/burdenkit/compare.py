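"""Validation of estimated carrier frequencies against reported epidemiology.

For autosomal recessive diseases with a literature-reported prevalence rP,
the reported carrier frequency rCrF = 2·rP·(1−rP) is compared with the
estimated CrF by ordinary least squares on log-transformed values, stratified
(by default) into European (nfe, fin) and non-European ancestries. Pearson's
R and its two-sided t-test p-value summarize each stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BurdenKitError
from .hwe import reported_crf

logger = logging.getLogger(__name__)

__all__ = ["CrfComparison", "RegressionSummary", "compare_crf",
           "DEFAULT_STRATUM_MAP"]

#: Default ancestry → stratum assignment for the regression.
DEFAULT_STRATUM_MAP = {
    "nfe": "European", "fin": "European",
    "afr": "non-European", "amr": "non-European", "asj": "non-European",
    "eas": "non-European", "mid": "non-European", "sas": "non-European",
}


@dataclass
class CrfComparison:
    """One gene's estimated vs reported carrier frequency."""

    gene: str
    stratum: str
    estimated_crf: float
    reported_crf: float
    log_estimated: float
    log_reported: float


@dataclass
class RegressionSummary:
    """OLS of log estimated CrF on log reported CrF within one stratum."""

    stratum: str
    slope: float | None
    intercept: float | None
    r: float | None
    p_value: float | None
    n: int


def compare_crf(gene_burdens: pd.DataFrame, reported: pd.DataFrame,
                convention: str = "as-printed",
                stratum_map: dict[str, str] | None = None,
                tier_set: str = "P+LP"
                ) -> tuple[list[CrfComparison], dict[str, RegressionSummary]]:
    """Pair estimated CrFs with reported prevalences and regress per stratum.

    *reported* needs columns ``gene``, ``rp`` and ``ancestry`` (the ancestry
    whose estimate the report should be compared against). Pairs where
    either CrF is non-positive are dropped (logs undefined). Strata with
    fewer than 3 pairs get an undefined R.
    """
    stratum_map = DEFAULT_STRATUM_MAP if stratum_map is None else stratum_map
    if "ancestry" not in reported.columns:
        raise BurdenKitError("reported-prevalence table needs an 'ancestry' column")
    est = gene_burdens[gene_burdens["tier_set"] == tier_set]
    est = est.drop_duplicates(subset=["gene", "ancestry"])
    lookup = {(r.gene, r.ancestry): r.crf for r in est.itertuples(index=False)}

    comparisons: list[CrfComparison] = []
    for row in reported.itertuples(index=False):
        crf_est = lookup.get((row.gene, row.ancestry))
        if crf_est is None:
            logger.warning("no estimated CrF for %s in %s; skipped",
                           row.gene, row.ancestry)
            continue
        rcrf = reported_crf(float(row.rp), convention=convention)
        if crf_est <= 0 or rcrf <= 0:
            logger.warning("non-positive CrF pair for %s/%s; log undefined, skipped",
                           row.gene, row.ancestry)
            continue
        stratum = stratum_map.get(row.ancestry, "non-European")
        comparisons.append(CrfComparison(
            gene=row.gene, stratum=stratum,
            estimated_crf=crf_est, reported_crf=rcrf,
            log_estimated=math.log(crf_est), log_reported=math.log(rcrf)))

    summaries: dict[str, RegressionSummary] = {}
    for stratum in sorted({c.stratum for c in comparisons}):
        xs = np.array([c.log_reported for c in comparisons if c.stratum == stratum])
        ys = np.array([c.log_estimated for c in comparisons if c.stratum == stratum])
        n = len(xs)
        if n < 3 or np.allclose(xs, xs[0]):
            summaries[stratum] = RegressionSummary(stratum, None, None, None, None, n)
            continue
        res = stats.linregress(xs, ys)
        summaries[stratum] = RegressionSummary(
            stratum=stratum, slope=float(res.slope),
            intercept=float(res.intercept), r=float(res.rvalue),
            p_value=float(res.pvalue), n=n)
    return comparisons, summaries


def comparisons_to_frame(comparisons: list[CrfComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons],
                        columns=["gene", "stratum", "estimated_crf",
                                 "reported_crf", "log_estimated", "log_reported"])
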