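"""Langevin integration of the bead-spring chain.

The equation of motion per bead is m r'' = F_c - xi v + F_R with F_c the
conservative force (WCA + FENE + membrane + pulling force) and F_R Gaussian
white noise.  The discretized random force has zero mean and per-component
variance 2 xi kT / dt, the fluctuation-dissipation closure that makes the
long-run kinetic temperature equal kT.  The update rule is a stochastic
velocity-Verlet scheme (see `_kernels.run_chunk`) that reduces exactly to
deterministic velocity Verlet when xi = 0 and the noise is switched off.

Randomness is organised as one `numpy.random.SeedSequence` substream per
translocation event, so events are reproducible independently of execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import PolymerState, _kernel_args, _raise_for_status
from .geometry import MembraneGeometry
from .parameters import SimulationParameters

#: steps integrated per kernel call; bounds the noise buffer at
#: chunk * N * 3 doubles
DEFAULT_CHUNK = 2000


@dataclass
class IntegratorConfig:
    """Numerical parameters of the Langevin velocity-Verlet integrator."""

    timestep: float = 0.005
    scheme_id: str = "langevin-velocity-verlet"
    rng_seed: int = 0
    rng_stream: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.timestep <= 0.01:
            raise ValueError("timestep must lie in (0, 0.01] t_LJ "
                             "(k = 30 bonds go unstable beyond that)")

    def rng(self, attempt: int = 0) -> np.random.Generator:
        """Generator for this event substream (attempt > 0 after retries)."""
        return np.random.default_rng(np.random.SeedSequence(
            self.rng_seed, spawn_key=(self.rng_stream, attempt)))

    @classmethod
    def from_parameters(cls, params: SimulationParameters,
                        stream: int = 0) -> "IntegratorConfig":
        return cls(timestep=params.timestep, rng_seed=params.rng_seed,
                   rng_stream=stream)


def noise_sigma(config: IntegratorConfig,
                params: SimulationParameters) -> float:
    """Standard deviation of each random-force component, sqrt(2 xi kT/dt)."""
    return float(np.sqrt(2.0 * params.friction * params.kT
                         / config.timestep))


def random_force_draw(config: IntegratorConfig, params: SimulationParameters,
                      rng: np.random.Generator) -> np.ndarray:
    """One (N, 3) draw of the discretized random force."""
    return noise_sigma(config, params) * rng.standard_normal(
        (params.n_monomers, 3))


def maxwell_velocities(n: int, params: SimulationParameters,
                       rng: np.random.Generator) -> np.ndarray:
    """(n, 3) velocities from the Maxwell distribution at temperature kT."""
    return rng.normal(scale=np.sqrt(params.kT / params.monomer_mass),
                      size=(n, 3))


class StepResult:
    """Outcome of an `advance` call."""

    __slots__ = ("status", "steps_done", "mean_sq_velocity")

    def __init__(self, status: int, steps_done: int,
                 mean_sq_velocity: np.ndarray):
        self.status = status
        self.steps_done = steps_done
        self.mean_sq_velocity = mean_sq_velocity  # (3,) <v_k^2> over run


def advance(state: PolymerState, geom: MembraneGeometry,
            params: SimulationParameters, config: IntegratorConfig,
            rng: np.random.Generator, n_steps: int, *,
            apply_external: bool = True,
            pinned: np.ndarray | None = None,
            thermostat: bool = True,
            with_noise: bool = True,
            record_exits: bool = False,
            exit_times: np.ndarray | None = None,
            snapshots: np.ndarray | None = None,
            raise_on_failure: bool = True,
            chunk: int = DEFAULT_CHUNK) -> StepResult:
    """Advance ``state`` in place by up to ``n_steps`` Langevin steps.

    With ``record_exits`` the run stops early on completion (status 3) or
    retraction (status 4); ``exit_times`` (length N+1, initialised to -1)
    and ``snapshots`` ((N+1, N, 3)) must then be supplied and are filled
    with absolute simulation times / configurations at each first passage.
    ``thermostat=False`` switches off both friction and noise (NVE);
    ``with_noise=False`` keeps the friction but drops the random force
    (pure exponential velocity damping).
    """
    n = state.n_beads
    dt = config.timestep
    friction = params.friction if thermostat else 0.0
    scale = noise_sigma(config, params) if (thermostat and with_noise) \
        else 0.0
    if pinned is None:
        pinned = np.zeros(n, dtype=np.bool_)
    if record_exits and (exit_times is None or snapshots is None):
        raise ValueError("record_exits requires exit_times and snapshots")
    if exit_times is None:
        exit_times = np.full(n + 1, -1.0)
    if snapshots is None:
        snapshots = np.zeros((1, n, 3))  # unused placeholder
    exited = np.zeros(n, dtype=np.bool_)
    if record_exits:
        # resume the monotone counter from any exits already recorded
        exited[:int(np.sum(exit_times[1:] >= 0.0))] = True
    err = np.zeros(2, dtype=np.int64)
    v2 = np.zeros(4)

    done = 0
    status = _kernels.STATUS_OK
    while done < n_steps:
        m = min(chunk, n_steps - done)
        if scale > 0.0:
            noise = rng.standard_normal((m, n, 3))
        else:
            noise = np.zeros((m, n, 3))
        status, steps, t_end = _kernels.run_chunk(
            state.positions, state.velocities, noise, scale, dt,
            params.monomer_mass, friction,
            *_kernel_args(params, geom),
            params.pull_force, apply_external, pinned,
            record_exits, exit_times, snapshots, exited, state.time,
            err, v2)
        state.time = t_end
        done += steps
        if status != _kernels.STATUS_OK:
            break
    if raise_on_failure:
        _raise_for_status(status, err)
    msv = v2[:3] / v2[3] if v2[3] > 0 else np.zeros(3)
    return StepResult(status, done, msv)


def step(state: PolymerState, geom: MembraneGeometry,
         params: SimulationParameters, config: IntegratorConfig,
         rng: np.random.Generator, **kwargs) -> PolymerState:
    """Single Langevin step; returns the advanced state (new object)."""
    out = state.copy()
    advance(out, geom, params, config, rng, 1, **kwargs)
    return out
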