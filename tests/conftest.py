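import numpy as np
import pytest

from hbridge import (BridgeDefinition, ModelPotentialParams,
                     SimulationSettings, Trajectory, embed_trajectory,
                     simulate_bridges)

try:
    from hypothesis import settings as _hyp_settings

    _hyp_settings.register_profile("suite", derandomize=True, max_examples=50)
    _hyp_settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def gas_params():
    return ModelPotentialParams.gas_phase()


@pytest.fixture(scope="session")
def solid_params():
    return ModelPotentialParams.solid_state()


@pytest.fixture(scope="session")
def low_barrier_params():
    return ModelPotentialParams.low_barrier()


@pytest.fixture(scope="session")
def short_run(gas_params):
    """2 ps gas-phase surrogate run (reduced coordinates)."""
    settings = SimulationSettings(seed=20250901, production_length=2.0,
                                  n_equilibration_steps=2000)
    return simulate_bridges(gas_params, settings)


@pytest.fixture(scope="session")
def short_traj(short_run):
    """The 2 ps run embedded as a 6-atom Cartesian trajectory."""
    return embed_trajectory(short_run)


@pytest.fixture(scope="session")
def bridge1():
    return BridgeDefinition(0, 1, 2, label="O8-HBP1...O1")


@pytest.fixture(scope="session")
def bridge2():
    return BridgeDefinition(3, 4, 5, label="O5-HBP2...O4")


def single_frame_trajectory(r: float, R: float) -> Trajectory:
    """One colinear O-H...O frame on the x axis (helper for NQE tests)."""
    pos = np.zeros((1, 3, 3))
    pos[0, 1, 0] = r
    pos[0, 2, 0] = R
    return Trajectory(labels=["O", "H", "O"], positions=pos, dt=1.0)
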