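import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


from cmfootprint import CohortSpec, FeedingPrevalence, normalize_prevalence


@pytest.fixture
def china_baseline() -> CohortSpec:
    """China 2018 own-data cohort from the published example."""
    return CohortSpec(
        label="China 2018",
        annual_births=11_501_936,
        prevalence=normalize_prevalence(ebf_pbf=61.3, partial=32.2),
    )


@pytest.fixture
def china_counterfactual(china_baseline) -> CohortSpec:
    return china_baseline.with_prevalence(normalize_prevalence(90.0, 8.0))


@pytest.fixture
def canada_before() -> CohortSpec:
    return CohortSpec(
        label="Canada before 2008",
        annual_births=373_864,
        prevalence=normalize_prevalence(ebf_pbf=23.1, partial=51.3),
    )


@pytest.fixture
def canada_after(canada_before) -> CohortSpec:
    return canada_before.with_prevalence(normalize_prevalence(31.5, 45.7))


@pytest.fixture
def lmic_extinct() -> CohortSpec:
    return CohortSpec(
        label="All LMICs",
        annual_births=131_386_401,
        prevalence=FeedingPrevalence(0.0, 0.0, 100.0),
    )
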