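import numpy as np
import pytest

from qepest.desirability import build_class_profile
from qepest.synthetic import default_spec, sample_population


@pytest.fixture(scope="session")
def class_populations():
    """One synthetic descriptor population per pesticide class."""
    return {
        label: sample_population(default_spec(label, 2000, 100 + i))
        for i, label in enumerate("HIF")
    }


@pytest.fixture(scope="session")
def fitted_profiles(class_populations):
    """Class profiles fitted on the session populations."""
    return {
        label: build_class_profile(pop, label, seed=0)
        for label, pop in class_populations.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
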