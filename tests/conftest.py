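import numpy as np
import pytest

from spikewin import Network, Population, connect
from spikewin.rules import STDPParams, STDPRule


@pytest.fixture
def lif_defaults():
    from spikewin.engine import LIFParams

    return LIFParams()


def single_synapse_network(delay=1, weight=1.0, plastic=False, rule=None, train=None):
    """One source neuron -> one LIF neuron through one synapse."""
    trains = [np.asarray(train if train is not None else [], dtype=np.int64)]
    src = Population("in", 1, kind="source", trains=trains)
    out = Population("out", 1, kind="lif", record_v=True)
    proj = connect("p", src, out, "one-to-one", weight=weight, delay=delay,
                   plastic=plastic, rule=rule)
    return Network([src, out], [proj]), proj


def unbounded_stdp_rule(a_plus=0.13, a_minus=0.11, tau_plus=17.0, tau_minus=23.0):
    return STDPRule(STDPParams(a_plus=a_plus, a_minus=a_minus, tau_plus=tau_plus,
                               tau_minus=tau_minus, w_min=-1e12, w_max=1e12))
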