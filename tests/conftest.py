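import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fx():
    """The deterministic worked-example bundle (built once per session)."""
    from irdx.fixture import study_fixture

    return study_fixture()


@pytest.fixture(scope="session")
def models(fx):
    return fx.gene_models


@pytest.fixture(scope="session")
def classified_ngs(fx):
    """NGS-arm classification of the whole fixture cohort."""
    from irdx.outcomes import classify_cohort

    return classify_cohort(fx.cohort, fx.gene_models, "ngs")
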