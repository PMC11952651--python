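import pytest
from hypothesis import HealthCheck, settings

from burdenkit import ingest
from burdenkit.hwe import burden_table
from burdenkit.simulate import SimConfig, simulate_cohort, write_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    """Small but structurally complete study: every inheritance mode class,
    SF genes with single-variant restrictions, common-variant outliers."""
    return SimConfig(
        n_genes=40,
        seed=3,
        sf_fraction=0.2,
        sf_single_variant_fraction=0.5,
        dual_phenotype_fraction=0.1,
        af_distribution={
            "name": "truncated-exponential", "scale": 0.002, "upper": 0.05,
            "common_fraction": 0.02, "common_range": (0.05, 0.3)},
    )


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def bundle(cohort, tmp_path_factory):
    """The cohort written to disk (TSV + VCF + metadata sidecars)."""
    out = tmp_path_factory.mktemp("bundle")
    return write_cohort(cohort, out)


@pytest.fixture(scope="session")
def burdens(cohort, sim_config):
    """In-memory gene burden table for the session cohort."""
    retained = ingest.qc_filter(cohort.variants,
                                sim_config.sample_size_per_ancestry)
    meta = ingest.gene_meta_records(cohort.gene_meta)
    return burden_table(cohort.variants, retained, meta), retained, meta
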