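import pytest

import boxphi as bp
from boxphi.network import CandidateSystem


@pytest.fixture(scope="session")
def xor_delay():
    return bp.make_fixture("xor_delay")


@pytest.fixture(scope="session")
def nor_hierarchy():
    return bp.make_fixture("nor_hierarchy")


@pytest.fixture(scope="session")
def cell_cycle():
    return bp.make_fixture("cell_cycle")


@pytest.fixture(scope="session")
def xor_micro_model(xor_delay):
    return bp.build_transition_model(xor_delay.network)


@pytest.fixture(scope="session")
def xor_micro_calc(xor_micro_model):
    return bp.RepertoireCalculator(xor_micro_model, (0,) * 9)


@pytest.fixture(scope="session")
def xor_micro_system(xor_delay):
    net = xor_delay.network
    return CandidateSystem(net, net.node_labels, {}, (0,) * 9)


@pytest.fixture(scope="session")
def xor_macro(xor_delay):
    return bp.MacroSystem.from_micro_state(
        xor_delay.network, xor_delay.mappings["canonical"], xor_delay.state)
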