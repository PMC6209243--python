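"""Parameter containers and experiment presets.

Units used throughout the package: lengths in micrometres, times in seconds,
concentrations in mol/L (M).  Diffusivities are therefore in um^2/s
(2.5e-5 cm^2/s = 2.5e3 um^2/s).  All chemical potentials are dimensionless
(kBT units); the electric potential is in thermal-voltage units (RT/F).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

#: molarity of pure water, M
C_WATER = 55.5

#: cm^2/s -> um^2/s
CM2_TO_UM2 = 1.0e8


@dataclass(frozen=True)
class IonSpec:
    """Constants for one dissolved ionic species.

    Parameters
    ----------
    name : str
        Species identifier ("Na", "Ca", "Cl").
    z : int
        Valence (+1 sodium, +2 calcium, -1 chloride).
    D : float
        Diffusivity in the solvent, um^2/s.
    k_on : float
        Binding rate to network sites, 1/(M s).  Zero for anions.
    k_off : float
        Unbinding rate, 1/s.  Zero for anions.
    """

    name: str
    z: int
    D: float
    k_on: float = 0.0
    k_off: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusivity of {self.name} must be positive")
        if self.z < 0 and (self.k_on != 0 or self.k_off != 0):
            raise ValueError("anions do not bind to the network")
        if (self.k_on == 0) != (self.k_off == 0):
            raise ValueError("k_on and k_off must both be zero or both positive")

    @property
    def binds(self) -> bool:
        return self.k_on > 0

    @property
    def K(self) -> float:
        """Dissociation constant k_off/k_on (M); inf for non-binding species."""
        if not self.binds:
            return float("inf")
        return self.k_off / self.k_on


@dataclass(frozen=True)
class InteractionEnergies:
    """Mean-field interaction energies and network structural constants.

    eps1..eps4 are the pairwise interaction energies (kBT units) entering the
    crosslink-dependent interaction parameter I(alpha) and the network
    standard free energy.  N is the number of monomers per mucin chain,
    z_tilde the density of negative binding sites per litre of pure network
    (M).  With the shipped defaults I(alpha) interpolates from -45 (no
    crosslinks, strongly swelling) to 0 (fully crosslinked, neutral).
    """

    eps1: float = -45.0
    eps2: float = 25.0
    eps3: float = -0.5
    eps4: float = 0.0
    N: int = 6
    z_tilde: float = 0.1
    c_water: float = C_WATER
    mu_s0: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.c_water <= 0:
            raise ValueError("c_water must be positive")
        if self.z_tilde <= 0:
            raise ValueError("z_tilde must be positive")


@dataclass(frozen=True)
class MechanicalParams:
    """Viscosities, interphase drag and the potential-to-force scale.

    The momentum balance is homogeneous in (nu_n, nu_s, xi, potential_scale):
    scaling all four together leaves the velocities unchanged, so xi = 1 fixes
    the force unit.  potential_scale multiplies every chemical-potential
    gradient term; with xi = 1 it has units um^2/s and sets the permeation
    speed.  The defaults are calibrated (see docs/methods.md) so that the
    sparse-binding, sodium-preferred gel in a 0.02 M sodium bath swells with a
    front-decay rate of order 1/s.
    """

    nu_n: float = 0.25
    nu_s: float = 0.25
    xi: float = 1.0
    potential_scale: float = 12.0

    def __post_init__(self) -> None:
        for name in ("nu_n", "nu_s", "xi", "potential_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class KineticRates:
    """Binding/unbinding rate constants for the two cations."""

    k_Ca_on: float
    k_Ca_off: float
    k_Na_on: float
    k_Na_off: float

    @property
    def K_Ca(self) -> float:
        return self.k_Ca_off / self.k_Ca_on

    @property
    def K_Na(self) -> float:
        return self.k_Na_off / self.k_Na_on


#: diffusivity of every ion, um^2/s (2.5e-5 cm^2/s for all three species)
D_ION = 2.5e-5 * CM2_TO_UM2

#: the four experimental regimes: (rates, z_tilde, inner totals in M)
_PRESETS: dict[str, dict[str, Any]] = {
    "dense_Na_preferred": dict(
        rates=KineticRates(1e6, 1e3, 5e6, 5e2), z_tilde=1.0,
        T_Ca_inner=0.250, T_Na_inner=0.005),
    "sparse_Na_preferred": dict(
        rates=KineticRates(1e6, 1e3, 5e6, 5e2), z_tilde=0.1,
        T_Ca_inner=0.0253, T_Na_inner=0.001),
    "dense_Ca_preferred": dict(
        rates=KineticRates(1e7, 1e3, 5e5, 5e2), z_tilde=1.0,
        T_Ca_inner=0.250, T_Na_inner=0.005),
    "sparse_Ca_preferred": dict(
        rates=KineticRates(1e7, 1e3, 5e5, 5e2), z_tilde=0.1,
        T_Ca_inner=0.0253, T_Na_inner=0.001),
}

CASE_NAMES = tuple(_PRESETS)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one swelling experiment.

    Geometry: closed 1D container [0, L] with the dense gel initially at the
    left end (tanh transition centred at x0).  The inner region is a
    crosslinked gel at network fraction theta_n_inner equilibrated with the
    listed inner ion totals; the bath carries essentially no network and a
    prescribed sodium/calcium composition, chloride balancing the charge.
    """

    case: str = "sparse_Na_preferred"

    # geometry / grid
    L: float = 25.0             # domain length, um
    n_cells: int = 256
    x0: float = 5.0             # tanh centre, um
    tanh_width: float = 0.25    # tanh width w, um

    # composition
    theta_n_inner: float = 0.5
    theta_n_bath: float = 1.0e-9
    T_Na_inner: float = 0.001   # total inner sodium, M (per total volume)
    T_Ca_inner: float = 0.0253  # total inner calcium, M
    T_Na_bath: float = 0.02     # total bath sodium, M
    T_Ca_bath: float = 0.001    # total bath calcium, M

    # chemistry
    z_tilde: float = 0.1
    rates: KineticRates = KineticRates(1e6, 1e3, 5e6, 5e2)
    D_Na: float = D_ION
    D_Ca: float = D_ION
    D_Cl: float = D_ION

    # energetics
    energies: InteractionEnergies = InteractionEnergies()

    # mechanics
    mech: MechanicalParams = MechanicalParams()

    # time stepping
    t_end: float = 1.0
    cfl: float = 0.4
    dt_max: float = 1.0e-3
    dt_min: float = 1.0e-9
    advection_scheme: str = "upwind"   # or "muscl"
    charge_tol: float = 1.0e-10        # relative charge-flux closure tolerance
    reaction_tol: float = 1.0e-12

    # output
    metrics_dt: float = 0.01    # metric sampling cadence, s
    snapshot_dt: float = 0.1    # snapshot cadence, s (0 disables intermediates)
    front_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("n_cells must be at least 4")
        if not 0 < self.theta_n_inner < 1:
            raise ValueError("theta_n_inner must lie in (0, 1)")
        if self.advection_scheme not in ("upwind", "muscl"):
            raise ValueError("advection_scheme must be 'upwind' or 'muscl'")
        # z_tilde is shared between chemistry and energetics
        if self.energies.z_tilde != self.z_tilde:
            object.__setattr__(
                self, "energies",
                dataclasses.replace(self.energies, z_tilde=self.z_tilde))

    # -- derived ---------------------------------------------------------
    @property
    def h(self) -> float:
        return self.L / self.n_cells

    def ion_specs(self) -> dict[str, IonSpec]:
        r = self.rates
        return {
            "Na": IonSpec("Na", +1, self.D_Na, r.k_Na_on, r.k_Na_off),
            "Ca": IonSpec("Ca", +2, self.D_Ca, r.k_Ca_on, r.k_Ca_off),
            "Cl": IonSpec("Cl", -1, self.D_Cl),
        }

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "rates" in d and isinstance(d["rates"], dict):
            d["rates"] = KineticRates(**d["rates"])
        if "energies" in d and isinstance(d["energies"], dict):
            d["energies"] = InteractionEnergies(**d["energies"])
        if "mech" in d and isinstance(d["mech"], dict):
            d["mech"] = MechanicalParams(**d["mech"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def case_preset(name: str, **overrides: Any) -> SimulationConfig:
    """Build the configuration for one of the four named experiment regimes.

    ``dense``/``sparse`` refers to the density of network binding sites
    (z_tilde = 1 M vs 0.1 M); ``Na_preferred``/``Ca_preferred`` to which
    cation binds more tightly (K_Na < K_Ca vs K_Ca < K_Na).  Any config field
    may be overridden by keyword.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown case {name!r}; choose from {CASE_NAMES}")
    p = _PRESETS[name]
    base = dict(case=name, rates=p["rates"], z_tilde=p["z_tilde"],
                T_Ca_inner=p["T_Ca_inner"], T_Na_inner=p["T_Na_inner"])
    base.update(overrides)
    return SimulationConfig(**base)
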