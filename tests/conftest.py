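import pytest

from ppiscreen.simulate import SimulationConfig


@pytest.fixture
def cfg():
    return SimulationConfig(seed=7)


@pytest.fixture
def small_cfg():
    return SimulationConfig(seed=7, n_pairs=40, n_publications=15, L1=12, L2=15)
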