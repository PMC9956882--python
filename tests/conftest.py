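import numpy as np
import pandas as pd
import pytest

from cortexstack.config import GeometryConfig, ConnectivityConfig, SimConfig
from cortexstack.topology import place_neurons_2d, build_gaussian_layer


EMPTY_SYNAPSES = pd.DataFrame(
    {
        "pre_id": pd.array([], dtype="int64"),
        "post_id": pd.array([], dtype="int64"),
        "weight": pd.array([], dtype="float64"),
        "delay": pd.array([], dtype="float64"),
        "is_interlayer": pd.array([], dtype="bool"),
    }
)


@pytest.fixture(scope="session")
def tiny_geometry():
    """A 49-neuron layer: same pitch and jitter as the full model."""
    return GeometryConfig(area_um2=(7 * 26.0) ** 2, n_per_layer=49)


@pytest.fixture(scope="session")
def default_layer():
    """One full-size (1091-neuron) layer, shared across structural tests."""
    return place_neurons_2d(seed=42)


@pytest.fixture(scope="session")
def default_gaussian_synapses(default_layer):
    return build_gaussian_layer(default_layer, ConnectivityConfig(), seed=42)


def empty_synapses():
    return EMPTY_SYNAPSES.copy()
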