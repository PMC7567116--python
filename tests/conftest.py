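import numpy as np
import pytest

from actnet import synthetic_data as synth
from actnet.synthetic_data import (
    generate_network,
    generate_timecourse,
    plant_module_effects,
)


@pytest.fixture(scope="session")
def small_network():
    """100-node network with two connected 10-node planted modules."""
    return generate_network(100, 4, 2, 10, 0.6, seed=1)


@pytest.fixture(scope="session")
def strong_truth(small_network):
    """Strong planted effects (terminal 2.0 log2FC at noise SD 0.25 = 8 SD)
    on module 0 for three of four drugs."""
    return plant_module_effects(
        small_network, {"DOX": [0], "EPI": [0], "IDA": [0]}, seed=7
    )


@pytest.fixture(scope="session")
def proteome_timecourse(small_network, strong_truth):
    return generate_timecourse(
        small_network, strong_truth, "DOX", "therapeutic", synth.PROTEOME, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
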