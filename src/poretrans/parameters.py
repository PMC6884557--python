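"""Reduced Lennard-Jones unit system and simulation constants.

All internal computation is carried out in reduced units where the bead
diameter sigma, the base energy scale epsilon0 and the bead mass m are all 1,
so the intrinsic time unit t_LJ = sqrt(m sigma^2 / epsilon0) is also 1.
Physical (SI) values enter only through the optional mapping fields
(``sigma_nm``, ``monomer_mass_amu``, ``temperature_si``) used for reporting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

# CODATA values; precision far beyond anything the model resolves.
BOLTZMANN_J_PER_K = 1.380649e-23
AMU_KG = 1.66053906892e-27

#: default grid of pore well depths, in units of epsilon0 (nine values
#: spanning the weak-to-strong attraction range)
DEFAULT_EPSILON_GRID = (0.1, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)

#: default pore radii in sigma (pore diameters 3..6 sigma)
DEFAULT_PORE_RADII = (1.5, 2.0, 2.5, 3.0)

#: default pulling forces in epsilon0/sigma (medium and strong)
DEFAULT_FORCES = (1.0, 2.0)


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent simulation parameters."""


@dataclass
class SimulationParameters:
    """Physical and numerical constants of the translocation model.

    Lengths are in sigma, energies in epsilon0, masses in m and times in
    t_LJ unless a field name says otherwise.
    """

    n_monomers: int = 50
    sigma: float = 1.0
    monomer_mass: float = 1.0
    epsilon0: float = 1.0
    kT: float = 1.2
    friction: float = 0.7
    fene_k: float = 30.0
    fene_r0: float = 1.5
    pore_length: float = 6.0
    pore_radius: float = 1.5
    pore_epsilon: float = 1.0
    pull_force: float = 2.0
    timestep: float = 0.005
    rng_seed: int = 0
    n_events: int = 25
    pore_center: tuple[float, float, float] = (40.0, 38.0, 40.0)
    pore_dialect: str = "shifted"
    flory_nu: float = 0.588
    # SI mapping (reporting only)
    sigma_nm: float = 1.5
    monomer_mass_amu: float = 936.0
    temperature_si: float = 295.0

    def __post_init__(self) -> None:
        for name in ("sigma", "monomer_mass", "epsilon0", "kT", "friction",
                     "timestep"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.fene_r0 <= 0 or self.fene_k <= 0:
            raise ConfigurationError("FENE parameters must be positive")
        if self.pore_radius <= self.sigma / 2:
            raise ConfigurationError(
                "pore_radius must exceed sigma/2 so a bead fits in the bore")
        if self.pore_length <= 0:
            raise ConfigurationError("pore_length must be positive")
        if self.n_monomers < 2:
            raise ConfigurationError("need at least 2 monomers")
        if self.pore_dialect not in ("shifted", "literal"):
            raise ConfigurationError(
                f"unknown pore_dialect {self.pore_dialect!r}")
        if not 0 < self.flory_nu <= 1:
            raise ConfigurationError("flory_nu must lie in (0, 1]")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        self.pore_center = tuple(float(c) for c in self.pore_center)
        if len(self.pore_center) != 3:
            raise ConfigurationError("pore_center must be a 3-vector")

    @property
    def cutoff_wca(self) -> float:
        """WCA cutoff 2^(1/6) sigma — the minimum of the unshifted LJ."""
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def cutoff_pore(self) -> float:
        """Monomer-pore LJ cutoff, 2.5 sigma (repulsive + attractive)."""
        return 2.5 * self.sigma

    # ---------------------------------------------------------------- io

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pore_center"] = list(self.pore_center)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        if "pore_center" in data:
            data = dict(data)
            data["pore_center"] = tuple(data["pore_center"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError("configuration file must be a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "SimulationParameters":
        return dataclasses.replace(self, **kwargs)


def epsilon0_joules(params: SimulationParameters) -> float:
    """Energy scale epsilon0 in joules, from kT = (kT/eps0) * eps0.

    With the default mapping (T = 295 K, kT = 1.2 eps0) this gives
    eps0 = k_B * 295 / 1.2 ~= 3.39e-21 J.
    """
    if params.temperature_si <= 0:
        raise ConfigurationError("temperature_si must be positive for SI "
                                 "mapping")
    kT_over_eps0 = params.kT / params.epsilon0
    return BOLTZMANN_J_PER_K * params.temperature_si / kT_over_eps0


def lj_time_unit(params: SimulationParameters) -> float:
    """Intrinsic time unit t_LJ = sqrt(m sigma^2 / eps0) in picoseconds.

    Uses the SI mapping fields: sigma_nm, monomer_mass_amu, temperature_si.
    For sigma = 1.5 nm, m = 936 amu, T = 295 K and kT = 1.2 eps0 this is
    about 32.1 ps.
    """
    if params.sigma_nm <= 0 or params.monomer_mass_amu <= 0:
        raise ConfigurationError("SI mapping requires positive sigma_nm and "
                                 "monomer_mass_amu")
    eps0 = epsilon0_joules(params)
    m_kg = params.monomer_mass_amu * AMU_KG
    sigma_m = params.sigma_nm * 1e-9
    t_s = math.sqrt(m_kg * sigma_m ** 2 / eps0)
    return t_s * 1e12


def force_regime_bounds(params: SimulationParameters,
                        flory_nu: float | None = None
                        ) -> tuple[float, float]:
    """Bounds (kT/(sigma N^nu), kT/sigma) separating force regimes.

    A pulling force below the lower bound is weak (entropic barrier
    dominates), between the bounds medium, above the upper bound strong.
    Returned in reduced force units epsilon0/sigma.
    """
    nu = params.flory_nu if flory_nu is None else flory_nu
    if not 0 < nu <= 1:
        raise ConfigurationError("flory_nu must lie in (0, 1]")
    if params.n_monomers < 2 and params.n_monomers != 1:
        raise ConfigurationError("n_monomers must be >= 1")
    lower = params.kT / (params.sigma * params.n_monomers ** nu)
    upper = params.kT / params.sigma
    return lower, upper


def classify_force(params: SimulationParameters,
                   force: float | None = None) -> str:
    """Classify a pulling force as 'weak', 'medium' or 'strong'."""
    f = params.pull_force if force is None else force
    lower, upper = force_regime_bounds(params)
    if f < lower:
        return "weak"
    if f <= upper:
        return "medium"
    return "strong"
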