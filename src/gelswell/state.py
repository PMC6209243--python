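"""The spatial state of the gel on a staggered 1D grid.

Scalars (volume fractions, concentrations, potentials, pressure) live at
cell centres; velocities and fluxes live at faces.  Face index f runs over
the n+1 faces of an n-cell grid; faces 0 and n are the container walls where
both phase velocities vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import energetics
from .params import SimulationConfig

__all__ = ["GelState", "Potentials"]


@dataclass
class Potentials:
    """Chemical potentials at cell centres (kBT units) plus helpers."""

    mu_s: np.ndarray
    mu_n: np.ndarray
    mu_Na: np.ndarray
    mu_Ca: np.ndarray
    mu_Cl: np.ndarray
    sigma_I: np.ndarray
    I: np.ndarray
    alpha: np.ndarray


@dataclass
class GelState:
    """Fields of the two-phase gel at one instant.

    c_* are dissolved concentrations per litre of solvent, b_* bound
    concentrations per litre of total volume, Psi the electric potential in
    thermal-voltage units (gauge: zero at the right wall).
    """

    config: SimulationConfig
    theta_n: np.ndarray
    c_Na: np.ndarray
    c_Ca: np.ndarray
    c_Cl: np.ndarray
    b_Na: np.ndarray
    b_Ca: np.ndarray
    b_C2: np.ndarray
    Psi: np.ndarray
    t: float = 0.0
    p: np.ndarray | None = None

    # -- geometry --------------------------------------------------------
    @property
    def n(self) -> int:
        return self.theta_n.size

    @property
    def h(self) -> float:
        return self.config.L / self.n

    @property
    def x(self) -> np.ndarray:
        """Cell-centre coordinates (um)."""
        return (np.arange(self.n) + 0.5) * self.h

    @property
    def x_face(self) -> np.ndarray:
        return np.arange(self.n + 1) * self.h

    # -- derived fields --------------------------------------------------
    @property
    def theta_s(self) -> np.ndarray:
        return 1.0 - self.theta_n

    @property
    def M_free(self) -> np.ndarray:
        """Unbound-site concentration from the site balance (per total vol)."""
        return (self.config.z_tilde * self.theta_n
                - self.b_Na - self.b_Ca - 2.0 * self.b_C2)

    @property
    def alpha(self) -> np.ndarray:
        zt = self.config.z_tilde
        a = 2.0 * self.b_C2 / np.maximum(zt * self.theta_n, 1e-300)
        return np.clip(a, 0.0, 1.0)

    def charge_density(self) -> np.ndarray:
        """Net charge per total volume (M of elementary charge):
        theta_s (c_Na + 2 c_Ca - c_Cl) - M_free + b_Ca.  Zero when
        electroneutral."""
        return (self.theta_s * (self.c_Na + 2.0 * self.c_Ca - self.c_Cl)
                - self.M_free + self.b_Ca)

    def potentials(self) -> Potentials:
        cfg = self.config
        e = cfg.energies
        cw = e.c_water
        phi_Na, phi_Ca, phi_Cl = (self.c_Na / cw, self.c_Ca / cw,
                                  self.c_Cl / cw)
        sigma = energetics.ionic_molality(phi_Na, phi_Ca, phi_Cl)
        alpha = self.alpha
        I = energetics.interaction_parameter(alpha, e)
        mu_n0 = energetics.network_standard_energy(alpha, e)
        mu_s = energetics.solvent_potential(self.theta_n, sigma, I, e)
        theta_pos = np.maximum(self.theta_n, 1e-300)
        mu_n = energetics.network_potential(theta_pos, I, mu_n0, self.Psi, e)
        floor = 1e-300
        mu_Na = energetics.ion_potential(np.maximum(phi_Na, floor), sigma,
                                         +1, self.Psi)
        mu_Ca = energetics.ion_potential(np.maximum(phi_Ca, floor), sigma,
                                         +2, self.Psi)
        mu_Cl = energetics.ion_potential(np.maximum(phi_Cl, floor), sigma,
                                         -1, self.Psi)
        return Potentials(mu_s=mu_s, mu_n=mu_n, mu_Na=mu_Na, mu_Ca=mu_Ca,
                          mu_Cl=mu_Cl, sigma_I=sigma, I=I, alpha=alpha)

    # -- bookkeeping -----------------------------------------------------
    def copy(self) -> "GelState":
        return GelState(
            config=self.config, theta_n=self.theta_n.copy(),
            c_Na=self.c_Na.copy(), c_Ca=self.c_Ca.copy(),
            c_Cl=self.c_Cl.copy(), b_Na=self.b_Na.copy(),
            b_Ca=self.b_Ca.copy(), b_C2=self.b_C2.copy(),
            Psi=self.Psi.copy(), t=self.t,
            p=None if self.p is None else self.p.copy())

    def totals(self) -> dict[str, float]:
        """Domain-integrated content of each conserved quantity (M um)."""
        h, ts = self.h, self.theta_s
        return {
            "theta_n": float(np.sum(self.theta_n) * h),
            "Na": float(np.sum(ts * self.c_Na + self.b_Na) * h),
            "Ca": float(np.sum(ts * self.c_Ca + self.b_Ca + self.b_C2) * h),
            "Cl": float(np.sum(ts * self.c_Cl) * h),
        }

    def check_invariants(self, charge_tol: float = 1e-6) -> None:
        """Raise if a structural invariant is violated beyond tolerance."""
        if np.any(self.theta_n < 0) or np.any(self.theta_n >= 1):
            raise AssertionError("theta_n outside [0, 1)")
        conc = np.concatenate([self.c_Na, self.c_Ca, self.c_Cl,
                               self.b_Na, self.b_Ca, self.b_C2])
        if conc.min() < -1e-10:
            raise AssertionError("negative concentration")
        if self.M_free.min() < -1e-9 * max(1.0, self.config.z_tilde):
            raise AssertionError("over-occupied binding sites")
        scale = max(float(np.max(np.abs(self.c_Na + self.c_Ca + self.c_Cl))),
                    1e-12)
        q = float(np.max(np.abs(self.charge_density())))
        if q > charge_tol * scale:
            raise AssertionError(f"electroneutrality violated: {q:.3e}")
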