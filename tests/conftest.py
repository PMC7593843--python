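import numpy as np
import pytest

from toxsae import load_panel, planted_scenario
from toxsae.dsae import NetworkSpec


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def small_net():
    """Full architecture but few epochs, for fast structural tests."""
    return NetworkSpec(input_width=43, epochs=40)


@pytest.fixture(scope="session")
def planted_cohort(panel):
    """One synthetic cohort with five planted risk SNPs (n=1400, 10%)."""
    gm, y, truth = planted_scenario(panel, n=1400, prevalence=0.10, seed=11)
    return gm, y, truth
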