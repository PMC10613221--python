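import pytest
from hypothesis import settings

from dcfba import (
    RegulationSpec,
    SimConfig,
    build_three_cell_network,
    build_two_cell_network,
)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def two_cell_net():
    return build_two_cell_network()


@pytest.fixture
def three_cell_net():
    return build_three_cell_network()


@pytest.fixture
def regulated_pair_config():
    """Two-cell run at growth bias 0.05 with full regulation (epsilon=1);
    the initial composition is the analytic balanced state."""
    return SimConfig(
        horizon=200.0,
        mu=[0.2, 0.3],
        initial_B=[0.4, 0.6],
        regulation=RegulationSpec(mode="two_cell_regulated", epsilon=1.0),
    )


@pytest.fixture
def unregulated_pair_config():
    return SimConfig(horizon=200.0, mu=[0.2, 0.3], initial_B=[0.4, 0.6])


@pytest.fixture
def asocial_config():
    """Three-cell community with an asocial mutant (non-responsive and
    non-communicating), the tumor-like reference scenario."""
    return SimConfig(
        horizon=200.0,
        mu=[0.2, 0.3, 0.2],
        initial_B=[0.39, 0.59, 0.02],
        regulation=RegulationSpec(mode="three_cell_asocial", epsilon=1.0),
    )
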