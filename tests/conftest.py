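import numpy as np
import pytest

from chpi import DescriptorTable, ThermoConstants, paper_scenarios


@pytest.fixture(scope="session")
def thermo():
    return ThermoConstants()


@pytest.fixture(scope="session")
def descriptors():
    return DescriptorTable.builtin()


@pytest.fixture(scope="session")
def scenarios():
    return paper_scenarios()


@pytest.fixture(scope="session")
def scenario_map(scenarios):
    return {(s.guest_id, s.host_id): s for s in scenarios}


def hexagon(radius=1.39, z=0.0, center=(0.0, 0.0, 0.0)):
    """Regular hexagon vertices in the xy-plane at height z."""
    t = np.arange(6) * np.pi / 3.0
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.full(6, z)])
    return pts + np.asarray(center)
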