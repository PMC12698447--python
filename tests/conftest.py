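import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """One defect-free forward locus, generated once per session."""
    from tcrlocus import LocusConfig, generate_locus

    return generate_locus(LocusConfig(seed=101))


@pytest.fixture(scope="session")
def small_result(small_truth):
    from tcrlocus import annotate_locus

    return annotate_locus(small_truth.genome, small_truth.c_references(),
                          locus_label=small_truth.locus_label,
                          scaffold=small_truth.scaffold)
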