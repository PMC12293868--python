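import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mcpkit import pipeline  # noqa: E402
from mcpkit.synthetic import CohortConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def default_bundle():
    """The reference synthetic cohort (seed 17, default study conditions)."""
    return generate_cohort(CohortConfig(seed=17))


@pytest.fixture(scope="session")
def core_results(default_bundle):
    """Burden fit, gene selection and predictor on the reference cohort."""
    return pipeline.run_core_analysis(default_bundle)


@pytest.fixture(scope="session")
def regulatory_results(default_bundle, core_results):
    return pipeline.run_regulatory_analysis(default_bundle, core_results)
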