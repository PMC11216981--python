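import numpy as np
import pytest

from msiplus.classifier import train
from msiplus.panel import default_panel
from msiplus.synth import GeneratorParams, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def trained(panel):
    """Classifier trained on a small synthetic cohort (fast, shared)."""
    cohort, labels = simulate_cohort(20, 20, panel, seed=101)
    return train(cohort, labels, panel)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
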