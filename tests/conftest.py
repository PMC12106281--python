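import numpy as np
import pytest

from hydrotraits.pipeline import default_species_params
from hydrotraits.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def species():
    """The six-species thicket community keyed by name."""
    return {p.name: p for p in default_species_params()}


@pytest.fixture
def cfg():
    return GeneratorConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
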