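import pytest

from rxvar import cohort, pipeline
from rxvar import synthetic_claims as sc

# ---------------------------------------------------------------- small world
# A modest synthetic world shared by module tests. Sizes keep each stage fast
# while leaving every drug with enough events to be informative.


@pytest.fixture(scope="session")
def small_catalog():
    return sc.generate_catalog(20, 6, class_overlap_rate=0.1, brand_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def small_world():
    return sc.generate_counties(20, 4, 2, seed=12, state_offset_sd=0.5)


@pytest.fixture(scope="session")
def small_claims(small_catalog, small_world):
    return sc.simulate_claims(small_catalog, small_world, 4000, (2003, 2010), seed=13)


@pytest.fixture(scope="session")
def small_cohort(small_claims, small_catalog):
    claims, _ = small_claims
    claims_f = claims[claims["sex"] == "F"]
    py = cohort.build_person_years(claims, sex="F")
    binned = cohort.assign_bins(py)
    fu = cohort.first_use_table(claims_f)
    rs = cohort.build_risk_sets(binned, fu, list(small_catalog["drug_id"]))
    return binned, fu, rs


# ------------------------------------------------------- full-scale pipelines
# The canonical study conditions: 50 counties, 60 drugs, 20,000 patients.


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default-condition pipeline run with all planted heterogeneity on."""
    cfg = pipeline.default_config()
    out = tmp_path_factory.mktemp("full_run")
    return pipeline.run_pipeline(cfg, out, seed=1)


@pytest.fixture(scope="session")
def offset_run(tmp_path_factory):
    """Controlled planted-offset experiment: 2x odds for each of the 10 most
    common drugs in its own disjoint county triple, all other county-level
    heterogeneity switched off, so the offset is the only systematic county
    signal."""
    cfg, cells = pipeline.offset_experiment_config(seed=2)
    out = tmp_path_factory.mktemp("offset_run")
    run = pipeline.run_pipeline(cfg, out, seed=2)
    return run, cells
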