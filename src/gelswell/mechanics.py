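"""Quasi-static force balance for the network and solvent phases.

Inertia is negligible at micron scales, so at every instant the phase
velocities solve a linear elliptic system: viscous stresses, interphase
drag, chemical-potential gradient forces on each phase (ionic forces are
transferred to the solvent), and a common pressure enforcing the
volume-averaged incompressibility constraint.

In 1D with zero wall velocities the incompressibility constraint integrates
to theta_n*u_n + theta_s*u_s = 0 at every face, which eliminates u_s, and
the combination theta_s*(network eq) - theta_n*(solvent eq) eliminates the
pressure.  What remains is a single tridiagonal system for u_n at interior
faces; u_s and p are recovered afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .params import MechanicalParams
from .state import GelState, Potentials

__all__ = ["VelocitySolution", "solve_velocities", "force_density"]


@dataclass
class VelocitySolution:
    """Phase velocities at faces (um/s) and pressure at cell centres."""

    u_n: np.ndarray          # length n+1, zero at walls
    u_s: np.ndarray          # length n+1, zero at walls
    p: np.ndarray            # length n, gauge p[0] = 0

    @property
    def max_speed(self) -> float:
        return float(max(np.max(np.abs(self.u_n)), np.max(np.abs(self.u_s))))


def _face_mean(a: np.ndarray) -> np.ndarray:
    """Arithmetic mean onto the n-1 interior faces."""
    return 0.5 * (a[:-1] + a[1:])


def potential_gradient_force(state: GelState, pots: Potentials):
    """Potential-gradient force densities at interior faces, excluding the
    pressure and the overall potential_scale factor.

    Returns ``(f_net, f_sol)`` with
    f_net = -theta_n * d(mu_n)/dx   and
    f_sol = -theta_s * d(mu_s)/dx - theta_s * sum_j phi_j d(mu_j)/dx.
    """
    h = state.h
    tn_f = _face_mean(state.theta_n)
    ts_f = _face_mean(state.theta_s)
    d_mu_n = np.diff(pots.mu_n) / h
    d_mu_s = np.diff(pots.mu_s) / h
    cw = state.config.energies.c_water
    ionic = np.zeros_like(d_mu_s)
    for c, mu in ((state.c_Na, pots.mu_Na), (state.c_Ca, pots.mu_Ca),
                  (state.c_Cl, pots.mu_Cl)):
        ionic += _face_mean(c / cw) * np.diff(mu) / h
    f_net = -tn_f * d_mu_n
    f_sol = -ts_f * d_mu_s - ts_f * ionic
    return f_net, f_sol


def force_density(state: GelState, pots: Potentials,
                  p: np.ndarray | None = None,
                  params: MechanicalParams | None = None):
    """Per-phase driving force densities at interior faces.

    network: -S*theta_n d(mu_n)/dx - theta_n dp/dx
    solvent: -S*theta_s d(mu_s)/dx - S*theta_s sum_j phi_j d(mu_j)/dx
             - theta_s dp/dx

    where S is the potential scale.  The drag force (which cancels exactly in
    the phase sum) is not included here; it belongs to the assembled
    operator.
    """
    params = params or state.config.mech
    S = params.potential_scale
    f_net, f_sol = potential_gradient_force(state, pots)
    f_net, f_sol = S * f_net, S * f_sol
    if p is not None:
        dp = np.diff(p) / state.h
        f_net = f_net - _face_mean(state.theta_n) * dp
        f_sol = f_sol - _face_mean(state.theta_s) * dp
    return f_net, f_sol


def solve_velocities(state: GelState, pots: Potentials | None = None,
                     params: MechanicalParams | None = None
                     ) -> VelocitySolution:
    """Solve the two-phase force balance on the staggered grid.

    Returns face velocities satisfying the zero-Dirichlet wall conditions
    exactly and theta_n*u_n + theta_s*u_s = 0 at every face by construction.
    """
    params = params or state.config.mech
    n, h = state.n, state.h
    tn, ts = state.theta_n, state.theta_s
    if np.any(ts <= 0.0):
        bad = np.flatnonzero(ts <= 0.0)
        raise RuntimeError(f"solvent fraction vanished in cells {bad[:5]}")
    pots = pots if pots is not None else state.potentials()
    nu_n, nu_s, xi, S = params.nu_n, params.nu_s, params.xi, params.potential_scale

    tn_f = _face_mean(tn)             # interior faces 1..n-1
    ts_f = _face_mean(ts)
    # ratio r_f = theta_n/theta_s at faces, walls forced to 0 (u=0 there)
    r = np.zeros(n + 1)
    r[1:n] = tn_f / ts_f

    f_net, f_sol = potential_gradient_force(state, pots)
    # theta_s*(net) - theta_n*(sol): pressure cancels, drag -> -xi*theta_n*u_n
    rhs = -S * (ts_f * f_net - tn_f * f_sol)

    inv_h2 = 1.0 / h**2
    lower = np.zeros(n - 1)
    diag = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    # face i (i = 1..n-1) couples un[i-1], un[i], un[i+1]
    i = np.arange(1, n)
    # network viscous term: theta_s_f * d/dx(theta_n nu_n d(un)/dx)
    diag += -ts_f * nu_n * (tn[i] + tn[i - 1]) * inv_h2
    upper += ts_f * nu_n * tn[i] * inv_h2          # coeff of un[i+1]
    lower += ts_f * nu_n * tn[i - 1] * inv_h2      # coeff of un[i-1]
    # solvent viscous term with us = -r*un: -theta_n_f d/dx(theta_s nu_s d(us)/dx)
    diag += -tn_f * nu_s * r[i] * (ts[i] + ts[i - 1]) * inv_h2
    upper += tn_f * nu_s * ts[i] * r[i + 1] * inv_h2
    lower += tn_f * nu_s * ts[i - 1] * r[i - 1] * inv_h2
    # drag
    diag += -xi * tn_f

    ab = np.zeros((3, n - 1))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    try:
        u_int = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise RuntimeError(f"force-balance solve failed: {err}") from err
    if not np.all(np.isfinite(u_int)):
        raise RuntimeError("force-balance solve produced non-finite velocities")

    u_n = np.zeros(n + 1)
    u_n[1:n] = u_int
    u_s = -r * u_n

    # pressure (diagnostic): integrate the total momentum balance
    G_n = tn * nu_n * np.diff(u_n) / h        # network viscous flux, cells
    G_s = ts * nu_s * np.diff(u_s) / h
    dpdx = (np.diff(G_n) + np.diff(G_s)) / h + S * (f_net + f_sol)
    p = np.concatenate([[0.0], np.cumsum(dpdx) * h])
    return VelocitySolution(u_n=u_n, u_s=u_s, p=p)
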