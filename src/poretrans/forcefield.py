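"""Potentials and forces of the bead-spring translocation model.

The model couples three interactions:

* excluded volume between all monomer pairs via the purely repulsive WCA
  potential (12-6 LJ truncated at its minimum 2^(1/6) sigma and shifted up
  by epsilon);
* connectivity between adjacent monomers via the FENE potential
  U = -1/2 k R0^2 ln(1 - r^2/R0^2), diverging at the maximum extension R0;
* the membrane: bead-to-surface WCA repulsion from the wall faces and a
  longer-ranged LJ (cutoff 2.5 sigma) between bead and pore bore surface
  whose well depth eps_pore sets the monomer-pore attraction;

plus the constant pulling force f x-hat applied only to beads inside the
pore bore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import MembraneGeometry
from .parameters import SimulationParameters


class OverlapError(RuntimeError):
    """A separation collapsed below the overlap guard (timestep too large)."""


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximal extension R0."""


@dataclass
class PolymerState:
    """Positions and velocities of the N-bead chain at one instant."""

    positions: np.ndarray  # (N, 3), sigma
    velocities: np.ndarray  # (N, 3), sigma / t_LJ
    time: float = 0.0  # t_LJ

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape \
                or self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions and velocities must both be (N, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "PolymerState":
        return PolymerState(self.positions.copy(), self.velocities.copy(),
                            self.time)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


@dataclass
class ForceReport:
    """Per-bead force breakdown and total potential energy."""

    wca_pair: np.ndarray
    fene: np.ndarray
    wall: np.ndarray
    pore: np.ndarray
    external: np.ndarray
    potential_energy: float

    @property
    def total_force(self) -> np.ndarray:
        return self.wca_pair + self.fene + self.wall + self.pore \
            + self.external

    def to_json(self, path) -> None:
        data = {name: getattr(self, name).tolist()
                for name in ("wca_pair", "fene", "wall", "pore", "external")}
        data["potential_energy"] = self.potential_energy
        with open(path, "w") as fh:
            json.dump(data, fh)


# ------------------------------------------------------------------ scalars

def wca_energy(r: float, eps: float, sigma: float = 1.0) -> float:
    """Purely repulsive WCA pair energy at separation r."""
    if r <= 0:
        raise OverlapError(f"non-positive separation r={r}")
    if r > 2.0 ** (1.0 / 6.0) * sigma:
        return 0.0
    s6 = (sigma / r) ** 6
    return 4.0 * eps * (s6 * s6 - s6) + eps


def pore_lj_energy(r: float, eps_pore: float, dialect: str = "shifted",
                   sigma: float = 1.0) -> float:
    """Monomer-pore LJ energy at bead-to-surface distance r.

    ``literal``: 4 eps [(s/r)^12 - (s/r)^6] + eps for r <= 2.5 sigma
    (discontinuous by ~0.984 eps at the cutoff).  ``shifted`` (default):
    truncated at 2.5 sigma and shifted so the energy is continuous there;
    the force is identical for both dialects.
    """
    if r <= 0:
        raise OverlapError(f"non-positive separation r={r}")
    cut = 2.5 * sigma
    if r > cut:
        return 0.0
    s6 = (sigma / r) ** 6
    u = 4.0 * eps_pore * (s6 * s6 - s6)
    if dialect == "literal":
        return u + eps_pore
    if dialect == "shifted":
        c6 = (sigma / cut) ** 6
        return u - 4.0 * eps_pore * (c6 * c6 - c6)
    raise ValueError(f"unknown dialect {dialect!r}")


def fene_energy(r: float, k: float = 30.0, r0: float = 1.5) -> float:
    """FENE bond energy; diverges as r approaches the maximum extension."""
    if r < 0:
        raise ValueError("negative bond length")
    if r >= r0:
        raise BondOverstretchError(f"bond length {r} >= R0 = {r0}")
    return -0.5 * k * r0 * r0 * np.log(1.0 - (r / r0) ** 2)


def fene_force_mag(r: float, k: float = 30.0, r0: float = 1.5) -> float:
    """Magnitude of the (attractive) FENE restoring force, k r/(1-r^2/R0^2)."""
    if r < 0:
        raise ValueError("negative bond length")
    if r >= r0:
        raise BondOverstretchError(f"bond length {r} >= R0 = {r0}")
    return k * r / (1.0 - (r / r0) ** 2)


def external_force(point, geom: MembraneGeometry, f: float) -> np.ndarray:
    """Pulling force f x-hat if the point lies inside the pore, else zero."""
    from .geometry import region_of, REGION_PORE
    if region_of(point, geom) == REGION_PORE:
        return np.array([f, 0.0, 0.0])
    return np.zeros(3)


# ------------------------------------------------------------------- system

def _kernel_args(params: SimulationParameters, geom: MembraneGeometry):
    return (params.sigma, params.epsilon0, params.cutoff_wca,
            params.fene_k, params.fene_r0,
            geom.cis_plane_x, geom.trans_plane_x,
            geom.pore_center[1], geom.pore_center[2], geom.pore_radius,
            params.pore_epsilon, params.cutoff_pore)


def _raise_for_status(status: int, err_idx: np.ndarray) -> None:
    if status == _kernels.STATUS_OVERLAP:
        raise OverlapError(f"overlap involving beads {tuple(err_idx)} "
                           "(negative indices denote membrane surfaces)")
    if status == _kernels.STATUS_OVERSTRETCH:
        raise BondOverstretchError(
            f"bond {err_idx[0]}-{err_idx[1]} overstretched")


def total_forces(state: PolymerState, geom: MembraneGeometry,
                 params: SimulationParameters,
                 apply_external: bool = True) -> ForceReport:
    """Evaluate all force components and the potential energy for a state."""
    n = state.n_beads
    comps = [np.zeros((n, 3)) for _ in range(5)]
    err = np.zeros(2, dtype=np.int64)
    status, pe = _kernels.compute_forces(
        state.positions, *_kernel_args(params, geom),
        params.pore_dialect == "shifted",
        params.pull_force, apply_external, True, *comps, err)
    _raise_for_status(status, err)
    return ForceReport(wca_pair=comps[0], fene=comps[1], wall=comps[2],
                       pore=comps[3], external=comps[4],
                       potential_energy=pe)


def system_potential_energy(positions: np.ndarray, geom: MembraneGeometry,
                            params: SimulationParameters) -> float:
    """Potential energy of a configuration (external force excluded)."""
    return float(_kernels.potential_energy(
        np.ascontiguousarray(positions, dtype=float),
        *_kernel_args(params, geom), params.pore_dialect == "shifted"))
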