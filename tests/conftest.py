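import pytest
from hypothesis import settings

from uuoseq.model import PipelineConfig
from uuoseq.simulate import simulate_scenario

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def tiny_scenario():
    """Annotation, design, counts, truth, params for the tiny fixture."""
    return simulate_scenario("tiny", seed=7)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard synthetic study: 2000 genes, 40 lncRNAs, 4+3+3 samples."""
    return simulate_scenario("default", seed=7)


@pytest.fixture(scope="session")
def null_scenario():
    """Same geometry, no planted effects (type-I error suites)."""
    return simulate_scenario("null", seed=7)
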