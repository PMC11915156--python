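import pytest

from cysredox.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle shared by read-only tests."""
    return generate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def perfect_bundle():
    """Bundle with detection probability 1: recovery must be exact."""
    return generate(SimulationConfig(seed=5, detection_probability=1.0))


@pytest.fixture()
def tiny_db():
    return {
        "P001": "MACDEFKG",
        "P002": "ACCAKLMCRWAAAK",
        "P003": "AAAAAAACAAAAAAA",
    }
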