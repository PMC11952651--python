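"""Formula core: CAF, CrF, HomF, compound hets, prevalence dispatch."""

import math
from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from burdenkit.errors import (
    DispatchError,
    DomainError,
    UndefinedFrequencyError,
)
from burdenkit.hwe import (
    TierSet,
    allele_frequency,
    carrier_frequency,
    compound_het_frequency,
    cumulative_af,
    format_one_in_x,
    gene_burden,
    genetic_prevalence,
    homozygote_frequency,
    invert_crf,
    reported_crf,
)

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@pytest.mark.parametrize("ac,an,expected", [(0, 1000, 0.0), (1000, 1000, 1.0),
                                            (3, 400, 0.0075)])
def test_allele_frequency(ac, an, expected):
    assert allele_frequency(ac, an) == expected


def test_allele_frequency_undefined_vs_zero():
    """AN = 0 is an undefined frequency, not AF = 0."""
    with pytest.raises(UndefinedFrequencyError):
        allele_frequency(0, 0)
    with pytest.raises(DomainError):
        allele_frequency(5, 4)


@pytest.mark.parametrize("afs,expected", [([], 0.0), ([0.01, 0.02, 0.03], 0.06)])
def test_cumulative_af(afs, expected):
    assert cumulative_af(afs) == pytest.approx(expected)


def test_cumulative_af_cap():
    assert cumulative_af([0.7, 0.7]) == 1.0
    assert cumulative_af([0.7, 0.7], cap=False) == pytest.approx(1.4)


@pytest.mark.parametrize("caf,expected", [(0.0, 0.0), (0.5, 0.5)])
def test_carrier_frequency_basic(caf, expected):
    assert carrier_frequency(caf) == expected


@pytest.mark.parametrize("caf,expected", [(0.0, 0.0), (1.0, 1.0)])
def test_homozygote_frequency_basic(caf, expected):
    assert homozygote_frequency(caf) == expected


def test_homozygote_decomposes_into_hom_and_comphet():
    """CAF² for AFs {0.1, 0.2} = Σ af² + compound-het term."""
    caf = cumulative_af([0.1, 0.2])
    assert homozygote_frequency(caf) == pytest.approx(
        0.1**2 + 0.2**2 + compound_het_frequency(0.1, 0.2))
    assert homozygote_frequency(caf) == pytest.approx(0.09)


@pytest.mark.parametrize("a,b,expected", [(0.0, 0.3, 0.0), (0.1, 0.2, 0.04)])
def test_compound_het(a, b, expected):
    assert compound_het_frequency(a, b) == pytest.approx(expected)


def test_two_class_carriership_combination():
    """Combining the hypomorphic (1/21) and disease-causing (1/27) CFTR
    carrier classes through CAF space yields an overall 1-in-12 rate."""
    c = invert_crf(1 / 21) + invert_crf(1 / 27)
    assert c == pytest.approx(0.043280, abs=1e-5)
    combined = carrier_frequency(c)
    assert combined == pytest.approx(0.0828, abs=2e-4)
    assert round(1 / combined) == 12


@pytest.mark.parametrize("mode,expected_fn", [
    ("AD", carrier_frequency),
    ("AD/AR", carrier_frequency),
    ("pseudoautosomal-dominant", carrier_frequency),
    ("AR", homozygote_frequency),
    ("pseudoautosomal-recessive", homozygote_frequency),
])
@pytest.mark.parametrize("caf", [0.0, 0.01, 0.1, 0.5])
def test_prevalence_dispatch(mode, expected_fn, caf):
    assert genetic_prevalence(caf, mode) == expected_fn(caf)


def test_prevalence_x_linked():
    assert genetic_prevalence(1.0, "XLR") == 1.0
    for c in (0.1, 0.3):
        assert (genetic_prevalence(c, "XLD") - genetic_prevalence(c, "XLR")
                == pytest.approx(c * (1 - c)))


def test_prevalence_unknown_mode():
    with pytest.raises(DispatchError):
        genetic_prevalence(0.1, "Y-linked")


@pytest.mark.parametrize("rp,convention,expected", [
    (0.25, "as-printed", 0.375),
    (0.0001, "sqrt-prevalence", 2 * 0.01 * 0.99),
    (1e-12, "as-printed", pytest.approx(0.0, abs=1e-11)),
    (1e-12, "sqrt-prevalence", pytest.approx(0.0, abs=1e-5)),
])
def test_reported_crf(rp, convention, expected):
    assert reported_crf(rp, convention) == expected


@pytest.mark.parametrize("crf,expected", [(0.0, 0.0), (0.5, 0.5)])
def test_invert_crf_basic(crf, expected):
    assert invert_crf(crf) == expected


def test_invert_crf_domain():
    with pytest.raises(DomainError):
        invert_crf(0.6)


# ---------------------------------------------------------------------------
# properties

@given(unit)
def test_hardy_weinberg_partition(c):
    """(1−c)² + 2c(1−c) + c² = 1 to machine precision for all c."""
    total = (1 - c) ** 2 + carrier_frequency(c) + homozygote_frequency(c)
    assert abs(total - 1.0) < 1e-12


@given(st.lists(st.floats(min_value=0.0, max_value=0.1), max_size=8))
def test_comphet_decomposition(afs):
    """Brute-force pairwise enumeration: Σaf² + Σ 2·afᵢ·afⱼ = CAF²."""
    caf = cumulative_af(afs, cap=False)
    brute = math.fsum(a * a for a in afs) + math.fsum(
        compound_het_frequency(a, b) for a, b in combinations(afs, 2))
    assert brute == pytest.approx(caf * caf, rel=1e-9, abs=1e-15)


@given(unit)
def test_xld_minus_xlr_is_het_females(c):
    assert (genetic_prevalence(c, "XLD") - genetic_prevalence(c, "XLR")
            == pytest.approx(c * (1 - c), abs=1e-12))


@given(st.floats(min_value=0.0, max_value=0.5))
def test_invert_crf_left_inverse(c):
    """invert_crf ∘ carrier_frequency is the identity on [0, 0.5]."""
    assert invert_crf(carrier_frequency(c)) == pytest.approx(c, abs=1e-7)


@given(st.lists(st.tuples(st.sampled_from(["P", "LP", "VUS-H", "VUS-M", "B"]),
                          st.floats(min_value=0.0, max_value=0.01)),
                max_size=20))
def test_tier_set_nesting_monotone(pairs):
    """CAF is monotone over the nested tier sets P ⊂ P+LP ⊂ P+LP+VUS-H."""
    cafs = [gene_burden(pairs, lab, "AD").caf
            for lab in ("P", "P+LP", "P+LP+VUS-H")]
    assert cafs[0] <= cafs[1] <= cafs[2]


def test_gene_burden_empty_and_flags():
    gb = gene_burden([], "P", "AR")
    assert gb.caf == gb.crf == gb.gp == 0.0
    capped = gene_burden([("P", 0.8), ("P", 0.9)], "P", "AR")
    assert capped.caf == 1.0 and capped.caf_capped and capped.high_caf
    high = gene_burden([("P", 0.6)], "P", "AR")
    assert high.high_caf and not high.caf_capped


def test_tier_set_labels_nested():
    p = set(TierSet.from_label("P").members)
    plp = set(TierSet.from_label("P+LP").members)
    plpv = set(TierSet.from_label("P+LP+VUS-H").members)
    assert p < plp < plpv


@pytest.mark.parametrize("value,rendered", [
    (1 / 12, "1 in 12"),
    (1 / 22_000, "1 in 22K"),
    (1 / 2_200, "1 in 2.2K"),
    (1 / 23_000_000, "1 in 23M"),
    (0.0, "1 in inf"),
])
def test_one_in_x_rendering(value, rendered):
    assert format_one_in_x(value) == rendered
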