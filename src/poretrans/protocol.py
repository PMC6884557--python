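"""Translocation protocol: initial threading, equilibration, event runs.

An event follows the three-stage protocol:

1. *Threading* — bead 1 is placed at the trans exit of the pore on the
   axis; the rest of the chain runs back through the bore and out the cis
   side at near-equilibrium bond spacing, with a small deterministic
   lateral ripple on the cis tail to break collinearity.
2. *Equilibration* — the beads initially inside the pore (plus bead 1) are
   pinned; the cis tail relaxes under full dynamics without the pulling
   force until the sliding-window range of its radius of gyration drops
   below 2 sigma.  Velocities are then resampled from the Maxwell
   distribution.
3. *Translocation* — pins are released, the pulling force inside the pore
   is switched on, and the first time at which s beads simultaneously sit
   past the trans plane is recorded for every s (a monotone first-passage
   counter, so back-and-forth motion never rewrites an earlier exit time).
   The event completes at s = N; if the whole chain backs out to the cis
   side it is discarded and re-run on a fresh random substream.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .forcefield import PolymerState
from .geometry import MembraneGeometry, in_pore_mask
from .integrator import IntegratorConfig, advance, maxwell_velocities
from .parameters import ConfigurationError, SimulationParameters

log = logging.getLogger(__name__)

STATUS_COMPLETED = "completed"
STATUS_RETRACTED = "retracted"
STATUS_NUMERICS = "numerics_failed"


class EquilibrationTimeout(RuntimeError):
    pass


@dataclass
class TranslocationEvent:
    """One recorded translocation with per-monomer first-exit times."""

    exit_times: np.ndarray      # (N,) times of s = 1..N, relative to release
    total_time: float           # exit_times[-1]
    status: str
    condition: dict             # pore_radius, pore_epsilon, pull_force
    seed_info: tuple[int, int]  # (seed, stream)
    snapshots: np.ndarray | None = None  # (N, N, 3) positions at each s
    n_discarded: int = 0
    equilibration_steps: int = 0
    translocation_steps: int = 0

    def __post_init__(self) -> None:
        if self.status == STATUS_COMPLETED:
            # non-decreasing: two monomers can clear the plane within the
            # same discrete timestep and then share a first-passage time
            if not np.all(np.diff(self.exit_times) >= 0):
                raise ValueError("exit times must be non-decreasing in s")
            if self.total_time <= 0:
                raise ValueError("total_time must be positive")


def equilibrium_bond_length(params: SimulationParameters) -> float:
    """Bond length where the FENE pull balances the WCA push (~0.96 sigma)."""
    s, k, r0 = params.sigma, params.fene_k, params.fene_r0

    def net(r: float) -> float:
        s6 = (s / r) ** 6
        wca = 24.0 * params.epsilon0 * s6 * (2.0 * s6 - 1.0) / r
        return wca - k * r / (1.0 - (r / r0) ** 2)

    return float(brentq(net, 0.5 * s, 2.0 ** (1.0 / 6.0) * s))


def condition_of(params: SimulationParameters) -> dict:
    return {"pore_radius": params.pore_radius,
            "pore_epsilon": params.pore_epsilon,
            "pull_force": params.pull_force}


def build_initial_configuration(params: SimulationParameters,
                                geom: MembraneGeometry) -> PolymerState:
    """Thread the chain through the pore with bead 1 at the trans exit."""
    if params.pore_radius <= params.sigma / 2:
        raise ConfigurationError("pore too narrow for a bead")
    n = params.n_monomers
    cx, cy, cz = geom.pore_center
    b = equilibrium_bond_length(params)
    pos = np.zeros((n, 3))
    pos[:, 0] = geom.trans_plane_x - b * np.arange(n)
    pos[:, 1] = cy
    pos[:, 2] = cz
    # deterministic lateral ripple on the free cis tail only; beads inside
    # (or near) the bore stay on the axis
    amp = 0.05 * params.sigma
    idx = np.arange(n)
    clear_of_pore = pos[:, 0] < geom.cis_plane_x - params.sigma
    pos[clear_of_pore, 1] += amp * np.sin(1.7 * idx[clear_of_pore])
    pos[clear_of_pore, 2] += amp * np.cos(2.3 * idx[clear_of_pore])
    state = PolymerState(pos, np.zeros((n, 3)), time=0.0)
    if np.any(state.bond_lengths() >= params.fene_r0):
        raise ConfigurationError("initial bonds exceed R0")
    return state


def pinned_mask(state: PolymerState, geom: MembraneGeometry) -> np.ndarray:
    """Beads held fixed during equilibration: those in the pore, plus bead 1."""
    mask = in_pore_mask(state.positions, geom)
    mask[0] = True
    return mask


def radius_of_gyration(positions: np.ndarray) -> float:
    centred = positions - positions.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum(axis=1).mean()))


def equilibrate(state: PolymerState, geom: MembraneGeometry,
                params: SimulationParameters, config: IntegratorConfig,
                rng: np.random.Generator, *,
                rg_threshold: float | None = None,
                sample_every: int = 50, window: int = 200,
                max_steps: int = 4_000_000) -> tuple[PolymerState, int]:
    """Relax the cis tail with the in-pore beads pinned; no pulling force.

    Terminates when the range (max - min) of the free-tail radius of
    gyration over the last ``window`` samples falls below ``rg_threshold``
    (default 2 sigma).  Returns (state, steps_used); velocities are
    resampled from the Maxwell distribution on exit.
    """
    if rg_threshold is None:
        rg_threshold = 2.0 * params.sigma
    pinned = pinned_mask(state, geom)
    free = ~pinned
    if free.sum() < 2:
        state.velocities = maxwell_velocities(state.n_beads, params, rng)
        return state, 0
    samples: list[float] = [radius_of_gyration(state.positions[free])]
    steps = 0
    while steps < max_steps:
        advance(state, geom, params, config, rng, sample_every,
                apply_external=False, pinned=pinned)
        steps += sample_every
        samples.append(radius_of_gyration(state.positions[free]))
        if len(samples) > window:
            samples.pop(0)
        if len(samples) == window \
                and max(samples) - min(samples) < rg_threshold:
            break
    else:
        raise EquilibrationTimeout(
            f"tail Rg range did not fall below {rg_threshold} sigma "
            f"within {max_steps} steps")
    state.velocities = maxwell_velocities(state.n_beads, params, rng)
    return state, steps


def run_event(params: SimulationParameters, geom: MembraneGeometry | None,
              config: IntegratorConfig | None = None, *,
              stream: int | None = None,
              keep_snapshots: bool = True,
              max_event_steps: int = 20_000_000,
              max_attempts: int = 20,
              equilibrate_kwargs: dict | None = None) -> TranslocationEvent:
    """Run one translocation event (retrying retractions on fresh streams)."""
    if geom is None:
        geom = MembraneGeometry.from_parameters(params)
    if config is None:
        config = IntegratorConfig.from_parameters(
            params, stream=stream if stream is not None else 0)
    elif stream is not None:
        config = IntegratorConfig(timestep=config.timestep,
                                  scheme_id=config.scheme_id,
                                  rng_seed=config.rng_seed,
                                  rng_stream=stream)
    n = params.n_monomers
    n_discarded = 0
    for attempt in range(max_attempts):
        rng = config.rng(attempt)
        state = build_initial_configuration(params, geom)
        try:
            state, eq_steps = equilibrate(state, geom, params, config, rng,
                                          **(equilibrate_kwargs or {}))
        except EquilibrationTimeout:
            log.warning("equilibration timeout (stream %d attempt %d)",
                        config.rng_stream, attempt)
            n_discarded += 1
            continue
        t_release = state.time
        exit_times = np.full(n + 1, -1.0)
        snapshots = np.zeros((n + 1, n, 3))
        result = advance(state, geom, params, config, rng, max_event_steps,
                         apply_external=True, record_exits=True,
                         exit_times=exit_times, snapshots=snapshots,
                         raise_on_failure=False)
        if result.status == _kernels.STATUS_COMPLETED:
            times = exit_times[1:] - t_release
            ev = TranslocationEvent(
                exit_times=times, total_time=float(times[-1]),
                status=STATUS_COMPLETED, condition=condition_of(params),
                seed_info=(config.rng_seed, config.rng_stream),
                snapshots=snapshots[1:].copy() if keep_snapshots else None,
                n_discarded=n_discarded, equilibration_steps=eq_steps,
                translocation_steps=result.steps_done)
            log.info("event stream=%d tau=%.1f discarded=%d",
                     config.rng_stream, ev.total_time, n_discarded)
            return ev
        kind = (STATUS_RETRACTED if result.status == _kernels.STATUS_RETRACTED
                else STATUS_NUMERICS)
        log.warning("event %s (stream %d attempt %d), re-running",
                    kind, config.rng_stream, attempt)
        n_discarded += 1
    raise RuntimeError(
        f"no completed event after {max_attempts} attempts on stream "
        f"{config.rng_stream}")


def run_ensemble(params: SimulationParameters,
                 conditions: list[dict] | None = None,
                 n_events: int | None = None, *,
                 base_seed: int | None = None,
                 out_dir: str | Path | None = None,
                 keep_snapshots: bool = True,
                 progress: bool = False,
                 on_event=None,
                 **event_kwargs) -> list[TranslocationEvent]:
    """Independent events for each condition, one RNG substream per event.

    ``conditions`` is a list of overrides (e.g. ``{"pore_epsilon": 8.0}``)
    applied to ``params``; with ``out_dir`` set, results stream to
    ``events.csv`` incrementally and completed (condition, stream) pairs
    found on disk are skipped, making reruns resumable no-ops.
    """
    if conditions is None:
        conditions = [{}]
    if n_events is None:
        n_events = params.n_events
    if base_seed is None:
        base_seed = params.rng_seed
    existing: set[tuple] = set()
    csv_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / "events.csv"
        if csv_path.exists():
            for row in read_event_rows(csv_path):
                existing.add((row["pore_radius"], row["pore_epsilon"],
                              row["pull_force"], int(row["stream"])))
    events: list[TranslocationEvent] = []
    for ci, cond in enumerate(conditions):
        p = params.replace(rng_seed=base_seed, **cond)
        for stream in range(ci * n_events, (ci + 1) * n_events):
            key = (p.pore_radius, p.pore_epsilon, p.pull_force, stream)
            if key in existing:
                continue
            try:
                ev = run_event(p, None, stream=stream,
                               keep_snapshots=keep_snapshots, **event_kwargs)
            except RuntimeError as exc:  # logged, not fatal
                log.error("condition %s stream %d failed: %s",
                          cond, stream, exc)
                continue
            events.append(ev)
            if csv_path is not None:
                append_event_row(csv_path, ev, p.n_monomers)
            if on_event is not None:
                on_event(ev)
            if progress:
                print(f"  condition {cond or 'base'} event "
                      f"{stream % n_events + 1}/{n_events} "
                      f"tau={ev.total_time:.1f}", flush=True)
    if out_dir is not None:
        manifest = {"parameters": params.to_dict(),
                    "conditions": conditions, "n_events": n_events,
                    "base_seed": base_seed}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return events


# ------------------------------------------------------------------- disk

def _event_header(n: int) -> list[str]:
    return (["pore_radius", "pore_epsilon", "pull_force", "seed", "stream",
             "status", "n_discarded", "total_time"]
            + [f"t_{s}" for s in range(1, n + 1)])


def append_event_row(path: Path, ev: TranslocationEvent, n: int) -> None:
    new = not Path(path).exists()
    with open(path, "a", newline="") as fh:
        w = csv.writer(fh)
        if new:
            w.writerow(_event_header(n))
        c = ev.condition
        w.writerow([c["pore_radius"], c["pore_epsilon"], c["pull_force"],
                    ev.seed_info[0], ev.seed_info[1], ev.status,
                    ev.n_discarded, repr(ev.total_time)]
                   + [repr(float(t)) for t in ev.exit_times])


def read_event_rows(path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = []
        for row in csv.DictReader(fh):
            out: dict = {k: row[k] for k in ("status",)}
            for k in ("pore_radius", "pore_epsilon", "pull_force",
                      "total_time"):
                out[k] = float(row[k])
            for k in ("seed", "stream", "n_discarded"):
                out[k] = int(row[k])
            n = sum(1 for k in row if k.startswith("t_"))
            out["exit_times"] = np.array(
                [float(row[f"t_{s}"]) for s in range(1, n + 1)])
            rows.append(out)
    return rows


def load_events(path) -> list[TranslocationEvent]:
    """Read events.csv back into TranslocationEvent objects (no snapshots)."""
    events = []
    for row in read_event_rows(path):
        events.append(TranslocationEvent(
            exit_times=row["exit_times"], total_time=row["total_time"],
            status=row["status"],
            condition={"pore_radius": row["pore_radius"],
                       "pore_epsilon": row["pore_epsilon"],
                       "pull_force": row["pull_force"]},
            seed_info=(row["seed"], row["stream"]),
            n_discarded=row["n_discarded"]))
    return events


def write_xyz(path, snapshots: np.ndarray, times=None,
              element: str = "C") -> None:
    """Write bead snapshots as a standard multi-frame XYZ trajectory."""
    snaps = np.atleast_3d(snapshots)
    with open(path, "w") as fh:
        for i, frame in enumerate(snaps):
            fh.write(f"{len(frame)}\n")
            t = times[i] if times is not None else i
            fh.write(f"t={t}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")
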