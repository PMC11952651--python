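"""Cohort aggregation: expected counts, non-carrier likelihood, headcounts."""

import math

import numpy as np
import pandas as pd
import pytest

from burdenkit.aggregate import (
    ancestry_mean,
    cohort_summary,
    expected_carried_genes,
    expected_disease_genotypes,
    headcount,
    non_carrier_likelihood,
)
from burdenkit.errors import BurdenKitError, IntegrityError
from burdenkit.hwe import carrier_frequency, homozygote_frequency


def _gene_frame(crfs, genes=None):
    genes = genes or [f"G{i}" for i in range(len(crfs))]
    return pd.DataFrame({"gene": genes, "crf": crfs})


def test_expected_carried_genes_sums_crf():
    assert expected_carried_genes(_gene_frame([0.0, 0.0])) == 0.0
    assert expected_carried_genes(_gene_frame([0.1, 0.2, 0.3])) == pytest.approx(0.6)


def test_expected_carried_genes_rejects_duplicates():
    with pytest.raises(IntegrityError):
        expected_carried_genes(_gene_frame([0.1, 0.2], genes=["G", "G"]))


def test_expected_disease_genotypes_single_ad_gene_equals_crf():
    crf = carrier_frequency(0.01)
    df = pd.DataFrame({"gene": ["G"], "mode": ["AD"], "gp": [crf]})
    assert expected_disease_genotypes(df) == crf


def test_dual_phenotype_gene_contributes_both_modes():
    """An ANO5-like gene with dominant and recessive phenotypes adds
    GP(AD) + GP(AR)."""
    caf = 0.02
    df = pd.DataFrame({
        "gene": ["ANO5like", "ANO5like"],
        "mode": ["AD", "AR"],
        "gp": [carrier_frequency(caf), homozygote_frequency(caf)],
    })
    assert expected_disease_genotypes(df) == pytest.approx(
        carrier_frequency(caf) + homozygote_frequency(caf))


def test_non_carrier_likelihood_basics():
    assert non_carrier_likelihood([]) == 1.0
    assert non_carrier_likelihood([0.5, 0.5]) == pytest.approx(0.25)
    assert non_carrier_likelihood([0.2, 1.0]) == 0.0


def test_non_carrier_likelihood_matches_naive_product():
    rng = np.random.default_rng(1)
    crfs = rng.uniform(0, 0.5, size=10_000)
    naive = np.prod(1.0 - crfs)
    assert non_carrier_likelihood(crfs) == pytest.approx(naive, rel=1e-12)


def test_non_carrier_likelihood_matches_genotype_simulation():
    """Fraction of simulated individuals carrying nothing agrees with
    Π(1−CrFᵢ) within 3 binomial SE."""
    rng = np.random.default_rng(7)
    crfs = rng.uniform(0, 0.01, size=300)
    n = 20_000
    carried = np.zeros(n, dtype=bool)
    for crf in crfs:
        carried |= rng.random(n) < crf
    frac_clean = 1.0 - carried.mean()
    p = non_carrier_likelihood(crfs)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac_clean - p) < 3 * se


def test_union_bound():
    rng = np.random.default_rng(3)
    crfs = rng.uniform(0, 0.3, size=200)
    assert 1.0 - non_carrier_likelihood(crfs) <= math.fsum(crfs)


def test_ancestry_mean():
    assert ancestry_mean({a: 0.4 for a in "abcdefgh"}, expected=tuple("abcdefgh")) == 0.4
    vals = {f"a{i}": 0.1 for i in range(7)}
    vals["a7"] = 0.9
    assert ancestry_mean(vals, expected=tuple(vals)) == pytest.approx(0.2)
    with pytest.raises(BurdenKitError):
        ancestry_mean({})


def test_recessive_prevalence_is_convex_in_caf():
    """Jensen: mean over ancestries of CAF² ≥ (mean CAF)²."""
    rng = np.random.default_rng(5)
    cafs = rng.uniform(0, 0.2, size=8)
    mean_gp = np.mean([homozygote_frequency(c) for c in cafs])
    assert mean_gp >= homozygote_frequency(float(np.mean(cafs)))


def test_headcount():
    assert headcount(0.0, {"afr": 1000}) == 0
    assert headcount(0.5, {"afr": 1000}, scope="afr") == 500
    rates = {"afr": 0.1, "nfe": 0.2}
    pops = {"afr": 1_000_000, "nfe": 2_000_000}
    assert headcount(rates, pops) == 100_000 + 400_000
    with pytest.raises(BurdenKitError):
        headcount({"afr": 0.1}, pops)


def test_cohort_summary_permutation_invariant(burdens):
    """Aggregates do not depend on gene order in the burden table."""
    bt, _, _ = burdens
    shuffled = bt.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = cohort_summary(bt).sort_values(["ancestry", "tier_set"]).reset_index(drop=True)
    b = (cohort_summary(shuffled).sort_values(["ancestry", "tier_set"])
         .reset_index(drop=True))
    pd.testing.assert_frame_equal(a, b)


def test_cohort_summary_monotone_in_tier_set(burdens):
    bt, _, _ = burdens
    summary = cohort_summary(bt).set_index(["ancestry", "tier_set"])
    for anc in bt["ancestry"].unique():
        e = [summary.loc[(anc, lab), "expected_carried_genes"]
             for lab in ("P", "P+LP", "P+LP+VUS-H")]
        assert e[0] <= e[1] <= e[2]
        ncl = [summary.loc[(anc, lab), "non_carrier_likelihood"]
               for lab in ("P", "P+LP", "P+LP+VUS-H")]
        assert ncl[0] >= ncl[1] >= ncl[2]


def test_cohort_summary_matches_ground_truth(cohort, burdens):
    """Σ CrF from the pipeline equals the brute-force sum over the
    generator's recorded per-gene CAFs."""
    bt, _, meta = burdens
    gt = cohort.ground_truth
    for anc in ("afr", "nfe"):
        sub = gt[(gt["ancestry"] == anc) & (gt["tier_set"] == "P+LP")]
        expected = math.fsum(carrier_frequency(min(c, 1.0)) for c in sub["caf"])
        got = expected_carried_genes(
            bt[(bt["ancestry"] == anc) & (bt["tier_set"] == "P+LP")]
            .drop_duplicates(subset="gene"))
        assert got == pytest.approx(expected, rel=1e-12)
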