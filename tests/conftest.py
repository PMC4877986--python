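import pytest
from hypothesis import HealthCheck, settings

from pleacs.extraction import assess
from pleacs.synthetic import GeneratorConfig, GroupSpec, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_corpus():
    """500 clean-mode documents with labels and extractor assessments."""
    docs, labels = generate(GeneratorConfig(n_docs=500, seed=101))
    assessments = [assess(d) for d in docs]
    return docs, labels, assessments


@pytest.fixture(scope="session")
def noisy_corpus():
    docs, labels = generate(GeneratorConfig(n_docs=500, seed=202, noise_mode="noisy"))
    assessments = [assess(d) for d in docs]
    return docs, labels, assessments


@pytest.fixture(scope="session")
def neutral_group():
    return (GroupSpec(label="Neutral"),)
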