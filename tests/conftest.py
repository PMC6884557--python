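import numpy as np
import pytest

import poretrans as pt

#: conditions used by the reduced-scale stochastic checks (pull force 2,
#: i.e. the strong-force regime, where every event completes quickly)
REDUCED_CONDITIONS = [
    {"pore_radius": 1.5, "pore_epsilon": 1.0},
    {"pore_radius": 1.5, "pore_epsilon": 4.0},
    {"pore_radius": 1.5, "pore_epsilon": 8.0},
    {"pore_radius": 2.5, "pore_epsilon": 1.0},
    {"pore_radius": 2.5, "pore_epsilon": 8.0},
    {"pore_radius": 3.0, "pore_epsilon": 1.0},
]
REDUCED_EVENTS = 25
REDUCED_SEED = 2024


@pytest.fixture(scope="session")
def reduced_ensembles() -> dict:
    """25 completed events for each reduced-scale condition at f = 2.

    Shared across the stochastic tests so the ensemble is simulated once
    per session.  Keys are (pore_radius, pore_epsilon, pull_force).
    """
    params = pt.SimulationParameters(rng_seed=REDUCED_SEED, pull_force=2.0)
    events = pt.run_ensemble(params, REDUCED_CONDITIONS,
                             n_events=REDUCED_EVENTS, keep_snapshots=True)
    return pt.group_by_condition(events)


@pytest.fixture()
def default_params() -> pt.SimulationParameters:
    return pt.SimulationParameters()


@pytest.fixture()
def default_geom(default_params) -> pt.MembraneGeometry:
    return pt.MembraneGeometry.from_parameters(default_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
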