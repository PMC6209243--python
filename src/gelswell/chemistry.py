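"""Binding/unbinding chemistry between dissolved cations and network sites.

Sodium binds a single negative site; calcium, being divalent, binds first to
one site (singly bound, b_Ca) and may then capture a second site to form a
crosslink (doubly bound, b_C2).  Dissolved concentrations c_j are per litre
of *solvent*; bound concentrations b_j per litre of *total* volume.  The
unoccupied-site concentration M is tied to the network volume fraction by
the site balance  z_tilde * theta_n = M + b_Na + b_Ca + 2 b_C2.

Reaction rates follow the bound-ion evolution equations, taken per total
volume; the matching dissolved sinks are rate/theta_s so that the elemental
totals T_Na = theta_s c_Na + b_Na and T_Ca = theta_s c_Ca + b_Ca + b_C2 are
exactly invariant under pure reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import IonSpec, KineticRates

__all__ = [
    "WellMixedComposition", "IonTotals", "free_site_density",
    "crosslink_fraction", "reaction_rates", "solve_equilibrium",
    "integrate_kinetics", "electroneutral_chloride",
]


@dataclass(frozen=True)
class WellMixedComposition:
    """Dissolved + bound ion state at a point (or in a well-mixed box)."""

    theta_n: float
    c_Na: float
    c_Ca: float
    c_Cl: float
    b_Na: float
    b_Ca: float
    b_C2: float
    z_tilde: float

    @property
    def theta_s(self) -> float:
        return 1.0 - self.theta_n

    @property
    def M_free(self) -> float:
        return free_site_density(self.theta_n, self.b_Na, self.b_Ca,
                                 self.b_C2, self.z_tilde)

    @property
    def alpha(self) -> float:
        return crosslink_fraction(self.b_C2, self.theta_n, self.z_tilde)

    def totals(self) -> "IonTotals":
        ts = self.theta_s
        return IonTotals(T_Na=ts * self.c_Na + self.b_Na,
                         T_Ca=ts * self.c_Ca + self.b_Ca + self.b_C2,
                         T_Cl=ts * self.c_Cl)

    def validate(self, tol: float = 1e-9) -> None:
        if not 0.0 <= self.theta_n <= 1.0:
            raise ValueError("theta_n outside [0, 1]")
        fields = (self.c_Na, self.c_Ca, self.c_Cl,
                  self.b_Na, self.b_Ca, self.b_C2)
        if min(fields) < -tol:
            raise ValueError("negative concentration")
        if self.M_free < -tol * max(1.0, self.z_tilde):
            raise ValueError("over-occupied binding sites (M < 0)")


@dataclass(frozen=True)
class IonTotals:
    """Total (dissolved + bound) elemental content per litre of total volume."""

    T_Na: float
    T_Ca: float
    T_Cl: float = 0.0


def free_site_density(theta_n, b_Na, b_Ca, b_C2, z_tilde, *, strict=True):
    """Concentration M of unoccupied negative network sites (M, per total
    volume), from the site balance z_tilde*theta_n = M + b_Na + b_Ca + 2 b_C2.

    Accepts scalars or arrays.  With ``strict`` a meaningfully negative
    result (over-occupied sites) raises.
    """
    M = z_tilde * np.asarray(theta_n, float) - b_Na - b_Ca - 2.0 * b_C2
    if strict:
        floor = -1e-9 * max(1.0, float(np.max(z_tilde)))
        if np.any(M < floor):
            raise ValueError("inconsistent state: bound ions exceed available sites")
    return M if M.ndim else float(M)


def crosslink_fraction(b_C2, theta_n, z_tilde, *, tol=1e-6):
    """Crosslink fraction alpha = 2 b_C2 / (z_tilde theta_n) in [0, 1]:
    doubly-bound calcium relative to the maximum z_tilde*theta_n/2."""
    theta_n = np.asarray(theta_n, float)
    if np.any(theta_n <= 0.0):
        raise ValueError("degenerate network: theta_n must be positive")
    alpha = 2.0 * np.asarray(b_C2, float) / (z_tilde * theta_n)
    if np.any(alpha < -tol) or np.any(alpha > 1.0 + tol):
        raise ValueError("crosslink fraction outside [0, 1]")
    alpha = np.clip(alpha, 0.0, 1.0)
    return alpha if alpha.ndim else float(alpha)


def reaction_rates(comp: WellMixedComposition, ions: dict[str, IonSpec]):
    """Right-hand sides of the bound-ion kinetics, per total volume.

    Returns ``(db_Na, db_Ca, db_C2, dTc_Na, dTc_Ca)`` where the last two are
    the rates of change of the *dissolved content* theta_s*c_j, chosen as the
    exact negatives of the binding fluxes so the elemental totals are
    conserved.  d(c_j)/dt itself is dTc_j / theta_s.
    """
    ts, M = comp.theta_s, comp.M_free
    na, ca = ions["Na"], ions["Ca"]
    r_na = na.k_on * ts * M * comp.c_Na - na.k_off * ts**2 * comp.b_Na
    r_ca = ca.k_on * ts * M * comp.c_Ca - ca.k_off * ts**2 * comp.b_Ca
    r_x = 0.5 * ca.k_on * M * comp.b_Ca - 2.0 * ca.k_off * ts**2 * comp.b_C2
    db_Na = r_na
    db_Ca = r_ca - r_x
    db_C2 = r_x
    return db_Na, db_Ca, db_C2, -r_na, -r_ca


def electroneutral_chloride(T_Na, T_Ca, theta_n, z_tilde):
    """Total chloride T_Cl = T_Na + 2 T_Ca - z_tilde*theta_n that makes the
    composition (dissolved + bound + free network sites) charge neutral."""
    T_Cl = T_Na + 2.0 * T_Ca - z_tilde * theta_n
    if np.any(np.asarray(T_Cl) < 0.0):
        raise ValueError("infeasible composition: electroneutral chloride "
                         "would be negative")
    return T_Cl


def _composition_at_M(M, totals, theta_n, z_tilde, K_Na, K_Ca):
    """Dissolved/bound concentrations implied by a free-site concentration M
    via the per-reaction equilibrium relations and the elemental totals."""
    ts = 1.0 - theta_n
    c_Na = totals.T_Na / (ts + M / (K_Na * ts))
    b_Na = M * c_Na / (K_Na * ts)
    denom = ts + M / (K_Ca * ts) + M * M / (4.0 * K_Ca**2 * ts**3)
    c_Ca = totals.T_Ca / denom
    b_Ca = M * c_Ca / (K_Ca * ts)
    b_C2 = M * b_Ca / (4.0 * K_Ca * ts**2)
    return c_Na, b_Na, c_Ca, b_Ca, b_C2


def solve_equilibrium(totals: IonTotals, theta_n: float, z_tilde: float,
                      ions: dict[str, IonSpec] | KineticRates,
                      tol: float = 1e-12) -> WellMixedComposition:
    """Solve the well-mixed binding/unbinding equilibrium.

    Given elemental totals (per total volume), the network fraction and the
    site density, returns the composition at which every reaction is in
    detailed balance:  b_Na = M c_Na/(K_Na theta_s),
    b_Ca = M c_Ca/(K_Ca theta_s),  b_C2 = M b_Ca/(4 K_Ca theta_s^2),
    together with the
    site balance and the total-mass constraints.  The problem reduces to a
    single monotone root-find for M on [0, z_tilde*theta_n] (bracketed, so
    convergence is guaranteed).
    """
    if isinstance(ions, KineticRates):
        K_Na, K_Ca = ions.K_Na, ions.K_Ca
    else:
        K_Na, K_Ca = ions["Na"].K, ions["Ca"].K
    if min(totals.T_Na, totals.T_Ca, totals.T_Cl) < 0:
        raise ValueError("ion totals must be non-negative")
    if not 0.0 < theta_n < 1.0:
        raise ValueError("theta_n must lie in (0, 1)")
    ts = 1.0 - theta_n
    S = z_tilde * theta_n  # total site concentration

    def site_residual(M):
        _, b_Na, _, b_Ca, b_C2 = _composition_at_M(
            M, totals, theta_n, z_tilde, K_Na, K_Ca)
        return S - M - b_Na - b_Ca - 2.0 * b_C2

    # residual is strictly decreasing in M: residual(0) = S >= 0,
    # residual(S) <= 0, so the bracket [0, S] always contains the root.
    if site_residual(S) >= 0.0:
        M = S
    else:
        M = brentq(site_residual, 0.0, S, xtol=max(1e-30, tol * S),
                   rtol=8.9e-16, maxiter=200)
    c_Na, b_Na, c_Ca, b_Ca, b_C2 = _composition_at_M(
        M, totals, theta_n, z_tilde, K_Na, K_Ca)
    comp = WellMixedComposition(
        theta_n=theta_n, c_Na=c_Na, c_Ca=c_Ca, c_Cl=totals.T_Cl / ts,
        b_Na=b_Na, b_Ca=b_Ca, b_C2=b_C2, z_tilde=z_tilde)
    # residual measured as an error in M (the site balance can be extremely
    # steep when binding is tight, so the raw residual is slope-scaled)
    delta = max(1e-8 * S, 1e-300)
    slope = abs(site_residual(min(M + delta, S))
                - site_residual(max(M - delta, 0.0))) / (2.0 * delta)
    err_M = abs(site_residual(M)) / max(slope, 1.0)
    if err_M > 1e-10 * max(1.0, S):
        raise RuntimeError(
            f"equilibrium solver error in M {err_M:.3e} too large")
    return comp


def integrate_kinetics(initial: WellMixedComposition,
                       ions: dict[str, IonSpec], t_end: float,
                       rtol: float = 1e-10, atol: float = 1e-14):
    """Integrate the zero-gradient, zero-velocity reduction of the ion
    evolution (stiff ODE in the three bound states; dissolved concentrations
    eliminated through the conserved totals).

    Returns ``(trajectory times, list of WellMixedComposition)``.  Serves as
    the brute-force oracle for :func:`solve_equilibrium`.
    """
    initial.validate()
    tn, ts, zt = initial.theta_n, initial.theta_s, initial.z_tilde
    tot = initial.totals()

    def comp_of(b):
        b_Na, b_Ca, b_C2 = b
        return WellMixedComposition(
            theta_n=tn, z_tilde=zt,
            c_Na=(tot.T_Na - b_Na) / ts,
            c_Ca=(tot.T_Ca - b_Ca - b_C2) / ts,
            c_Cl=tot.T_Cl / ts,
            b_Na=b_Na, b_Ca=b_Ca, b_C2=b_C2)

    def rhs(_t, b):
        db_Na, db_Ca, db_C2, _, _ = reaction_rates(comp_of(b), ions)
        return [db_Na, db_Ca, db_C2]

    sol = solve_ivp(rhs, (0.0, t_end),
                    [initial.b_Na, initial.b_Ca, initial.b_C2],
                    method="LSODA", rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"stiff kinetics integration failed: {sol.message}; "
            "try loosening rtol/atol")
    comps = [comp_of(sol.y[:, k]) for k in range(sol.y.shape[1])]
    return sol.t, comps
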