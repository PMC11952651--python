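"""Disease groups, secondary findings, screening, constraint flags."""

import math

import pandas as pd
import pytest

from burdenkit.groups import (
    constraint_flags,
    dominant_adjusted_burden,
    group_burden,
    group_burden_table,
    screening_candidates,
    secondary_findings_summary,
)
from burdenkit.ingest import GeneMeta
from burdenkit.errors import BurdenKitError
from burdenkit.hwe import carrier_frequency


def _meta(entries):
    """entries: gene -> (inheritance modes, groups[, sf, restriction])."""
    out = {}
    for gene, spec in entries.items():
        modes, groups = spec[0], spec[1]
        out[gene] = GeneMeta(
            gene=gene, inheritance=frozenset(modes), mechanism="LoF",
            icd10_groups=frozenset(groups),
            is_secondary_finding=len(spec) > 2 and spec[2],
            sf_variant_restriction=tuple(spec[3]) if len(spec) > 3 else ())
    return out


def _burden_rows(rows):
    return pd.DataFrame(rows, columns=["gene", "ancestry", "tier_set", "mode",
                                       "caf", "crf", "homf", "gp"])


def test_group_burden_single_ad_gene_equals_crf():
    crf = carrier_frequency(0.01)
    bt = _burden_rows([["G1", "nfe", "P+LP", "AD", 0.01, crf, 0.0001, crf]])
    meta = _meta({"G1": ({"AD"}, {"eye"})})
    gb = group_burden(bt, meta, "eye", "nfe", "P+LP")
    assert gb.cumulative_gp == crf
    assert gb.n_genes == 1 and gb.n_gene_mode_pairs == 1


def test_gene_in_five_groups_counts_in_each():
    """A CFTR-like gene assigned to five groups contributes to all five."""
    groups5 = {"blood/immune", "congenital", "digestive",
               "endocrine/metabolic", "respiratory"}
    bt = _burden_rows([["CFTRlike", "nfe", "P+LP", "AR", 0.03, 0.058, 0.0009, 0.0009]])
    meta = _meta({"CFTRlike": ({"AR"}, groups5)})
    for grp in groups5:
        assert group_burden(bt, meta, grp, "nfe", "P+LP").cumulative_gp == 0.0009
    assert group_burden(bt, meta, "eye", "nfe", "P+LP").cumulative_gp == 0.0


def test_group_burden_unknown_group():
    with pytest.raises(BurdenKitError):
        group_burden(_burden_rows([]), {}, "bogus", "nfe", "P+LP")


def test_group_sums_are_additive():
    """Removing a gene lowers the group sum by exactly its contributions."""
    bt = _burden_rows([
        ["G1", "nfe", "P+LP", "AD", 0.01, 0.0198, 1e-4, 0.0198],
        ["G2", "nfe", "P+LP", "AD", 0.02, 0.0392, 4e-4, 0.0392],
        ["G2", "nfe", "P+LP", "AR", 0.02, 0.0392, 4e-4, 4e-4],
    ])
    meta = _meta({"G1": ({"AD"}, {"skin"}), "G2": ({"AD", "AR"}, {"skin"})})
    full = group_burden(bt, meta, "skin", "nfe", "P+LP").cumulative_gp
    without = group_burden(bt[bt["gene"] != "G2"], meta, "skin", "nfe",
                           "P+LP").cumulative_gp
    assert full - without == pytest.approx(0.0392 + 4e-4)


def test_group_table_matches_brute_force(cohort, burdens):
    """Simulated panel: group sums equal a brute-force recomputation."""
    bt, _, meta = burdens
    table = group_burden_table(bt, meta)
    sub = table[(table["ancestry"] == "eas") & (table["tier_set"] == "P+LP")]
    for row in sub.itertuples(index=False):
        members = {g for g, gm in meta.items() if row.group in gm.icd10_groups}
        brute = math.fsum(
            r.gp for r in bt.itertuples(index=False)
            if r.gene in members and r.ancestry == "eas" and r.tier_set == "P+LP")
        assert row.cumulative_gp == pytest.approx(brute, rel=1e-12, abs=1e-300)


def test_dominant_adjusted_burden():
    bt = _burden_rows([
        ["G1", "nfe", "P+LP", "AD", 0.01, 0.0198, 1e-4, 0.01],
        ["G2", "nfe", "P+LP", "AD", 0.02, 0.0392, 4e-4, 0.03],
        ["G3", "nfe", "P+LP", "AR", 0.02, 0.0392, 4e-4, 4e-4],
    ])
    meta = _meta({"G1": ({"AD"}, {"ear"}), "G2": ({"AD"}, {"ear"}),
                  "G3": ({"AR"}, {"ear"})})
    assert dominant_adjusted_burden(bt, meta, "ear", "nfe", "P+LP") == pytest.approx(0.02)
    only_g1 = bt[bt["gene"] == "G1"]
    assert dominant_adjusted_burden(only_g1, meta, "ear", "nfe", "P+LP") == 0.01
    only_ar = bt[bt["gene"] == "G3"]
    assert dominant_adjusted_burden(only_ar, meta, "ear", "nfe", "P+LP") is None


# ---------------------------------------------------------------------------
# secondary findings

def test_sf_empty_list_gives_zeros():
    bt = _burden_rows([["G1", "nfe", "P+LP", "AD", 0.01, 0.0198, 1e-4, 0.0198]])
    meta = _meta({"G1": ({"AD"}, {"eye"})})
    out = secondary_findings_summary(bt, meta, sf_genes=set())
    assert (out["cumulative_crf"] == 0).all() and (out["cumulative_gp"] == 0).all()


def test_sf_single_variant_restriction(cohort, burdens):
    """HFE-like rule: a restricted gene's CAF equals the one allowed AF."""
    bt, retained, meta = burdens
    restricted = {g: gm for g, gm in meta.items() if gm.sf_variant_restriction}
    assert restricted, "fixture must contain restricted SF genes"
    out = secondary_findings_summary(bt, meta, variants=cohort.variants,
                                     retained=retained)
    # with restrictions active, cumulative CrF never exceeds the unrestricted sum
    free = secondary_findings_summary(
        bt, meta, variant_restrictions={}, variants=cohort.variants,
        retained=retained)
    merged = out.merge(free, on=["ancestry", "tier_set", "category"],
                       suffixes=("_restr", "_free"))
    assert (merged["cumulative_crf_restr"] <= merged["cumulative_crf_free"] + 1e-15).all()


def test_sf_restriction_to_absent_variant_zeroes_gene(caplog):
    bt = _burden_rows([["G1", "nfe", "P+LP", "AR", 0.01, 0.0198, 1e-4, 1e-4]])
    meta = _meta({"G1": ({"AR"}, {"eye"}, True, ["chr1:999:A:T"])})
    variants = pd.DataFrame({
        "chrom": ["chr1"], "pos": [1], "ref": ["A"], "alt": ["T"],
        "gene": ["G1"], "tier": ["P"], "filter": ["PASS"],
        "ac_nfe": [10], "an_nfe": [1000]})
    retained = {"nfe": pd.Series([True])}
    out = secondary_findings_summary(bt, meta, variants=variants, retained=retained)
    assert (out["cumulative_crf"] == 0).all()
    assert any("absent variant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# screening

def test_screening_boundary_is_strict():
    """CrF exactly 1/200 is excluded ("higher than")."""
    bt = _burden_rows([
        ["Gexact", "nfe", "P+LP", "AR", 0.0, 0.005, 0.0, 0.0],
        ["Gabove", "nfe", "P+LP", "AR", 0.0, 0.0051, 0.0, 0.0],
    ])
    res = screening_candidates(bt, threshold=1 / 200)
    assert res.per_ancestry["nfe"] == {"Gabove"}


def test_screening_shared_set(burdens):
    bt, _, _ = burdens
    res = screening_candidates(bt)
    shared = res.shared_across_ancestries
    for anc, genes in res.per_ancestry.items():
        assert shared <= genes
    # brute force per ancestry
    sub = bt[bt["tier_set"] == "P+LP"].drop_duplicates(subset=["gene", "ancestry"])
    for anc, genes in res.per_ancestry.items():
        brute = set(sub[(sub["ancestry"] == anc) & (sub["crf"] > 1 / 200)]["gene"])
        assert genes == brute


def test_screening_monotone_in_threshold(burdens):
    bt, _, _ = burdens
    loose = screening_candidates(bt, threshold=1 / 500)
    tight = screening_candidates(bt, threshold=1 / 200)
    for anc in tight.per_ancestry:
        assert tight.per_ancestry[anc] <= loose.per_ancestry[anc]


# ---------------------------------------------------------------------------
# constraint flags

def test_constraint_thresholds_are_strict():
    metrics = pd.DataFrame({
        "gene": ["A", "B", "C"],
        "pLI": [0.9, 0.91, None],
        "LOEUF": [0.6, 0.59, None],
        "s_het": [0.073, 0.074, None],
        "mis_z": [3.09, 3.10, None],
        "syn_z": [3.71, 3.72, None],
    })
    flags = constraint_flags(metrics).set_index(metrics["gene"])
    for col in ["pLI_constrained", "loeuf_constrained", "shet_constrained",
                "misZ_constrained", "synZ_constrained"]:
        assert flags.loc["A", col] == False  # noqa: E712 boundary not constrained
        assert flags.loc["B", col] == True  # noqa: E712
        assert pd.isna(flags.loc["C", col])


def test_constraint_flags_missing_metric_column():
    flags = constraint_flags(pd.DataFrame({"gene": ["A"], "pLI": [0.95]}))
    assert flags.loc[0, "pLI_constrained"] == True  # noqa: E712
    assert pd.isna(flags.loc[0, "loeuf_constrained"])


def test_constraint_flags_order_independent():
    metrics = pd.DataFrame({"gene": ["A", "B"], "pLI": [0.95, 0.1]})
    a = constraint_flags(metrics).sort_values("gene").reset_index(drop=True)
    b = (constraint_flags(metrics.iloc[::-1].reset_index(drop=True))
         .sort_values("gene").reset_index(drop=True))
    pd.testing.assert_frame_equal(a, b)
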