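import numpy as np
import pytest

from circuitkit import fixtures
from circuitkit.builder import ConnectionRule, EdgePropertySpec, NetworkBuilder


@pytest.fixture
def toy_net():
    """3+4-node two-population network with free-form edge columns."""
    return fixtures.make_toy_network(seed=0)


@pytest.fixture
def two_neuron_builder():
    """One driver and one follower LIF neuron, connectable in tests."""
    def make(weight=100.0, delay=2.0, **lif):
        b = NetworkBuilder(seed=0)
        b.add_nodes(2, "cells", model_type="point_process", **lif)
        b.add_edges("cells", "cells", ConnectionRule("one_to_one"),
                    EdgePropertySpec(syn_weight=weight, delay=delay),
                    source_filter=np.array([0]), target_filter=np.array([1]))
        return b.model
    return make


@pytest.fixture(scope="session")
def ei_scaled_run():
    """One 1/10-scale E/I example simulation, shared by regime tests."""
    from circuitkit.config import SimulationConfig
    from circuitkit.pointsim import simulate

    net = fixtures.make_ei_example(seed=1, scale=10)
    cfg = SimulationConfig(tstop=3000.0, dt=0.1, seed=1)
    inputs = fixtures.ei_example_inputs(seed=1, duration=cfg.tstop)
    spikes, _ = simulate(net, cfg, inputs=[inputs])
    return net, cfg, spikes
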