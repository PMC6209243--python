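"""Electrodiffusive ion transport, the electroneutral potential closure,
and conservative advection on the staggered grid.

Dissolved species obey Nernst-Planck fluxes weighted by the solvent volume
fraction,  F_j = -D_j theta_s (dc_j/dx + z_j c_j dPsi/dx),  advect with the
solvent velocity, and exchange with the network-bound pools through the
mass-action chemistry.  No Poisson equation is solved: the gel is assumed
electroneutral at the bulk scale, and in a closed 1D container that
constraint fixes the potential gradient algebraically at every face — the
total charge flux (dissolved drift + diffusion + advection of dissolved and
bound charge, including the bare network sites) must vanish identically, so
time stepping cannot create local charge.

The diffusion+drift face flux uses Scharfetter-Gummel exponential fitting,
which is positivity-preserving at any cell Peclet number and reduces to
centred differencing as the potential gradient vanishes.
"""

from __future__ import annotations

import numpy as np

from .params import SimulationConfig
from .state import GelState

__all__ = [
    "CFLError", "advect_scalar", "upwind_flux", "electrodiffusive_flux",
    "solve_face_potential_gradient", "integrate_potential",
    "solve_electric_potential", "advance_ions", "implicit_reaction_step",
]


class CFLError(RuntimeError):
    """Raised when an explicit advection step violates the CFL condition."""


class StepRejected(RuntimeError):
    """Raised when a transport/reaction substep fails and dt must shrink."""


# ---------------------------------------------------------------------------
# Bernoulli function for exponential fitting
# ---------------------------------------------------------------------------

def bernoulli(x):
    """B(x) = x/(exp(x)-1), the exponential-fitting weight; B(0)=1."""
    x = np.clip(np.asarray(x, float), -500.0, 500.0)
    small = np.abs(x) < 1.0e-4
    xs = np.where(small, 0.0, x)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(small,
                       1.0 - x / 2.0 + x * x / 12.0,
                       xs / np.expm1(xs))
    return out


def bernoulli_prime(x):
    """Derivative of B(x); B'(0) = -1/2."""
    x = np.clip(np.asarray(x, float), -500.0, 500.0)
    small = np.abs(x) < 1.0e-4
    xs = np.where(small, 1.0, x)  # placeholder to avoid 0/0
    with np.errstate(over="ignore", invalid="ignore"):
        ex = np.exp(np.minimum(xs, 500.0))
        gen = (ex - 1.0 - xs * ex) / (ex - 1.0) ** 2
    return np.where(small, -0.5 + x / 6.0, gen)


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------

def _minmod(a, b):
    return np.where(a * b > 0.0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def upwind_flux(field, u, scheme: str = "upwind"):
    """Conservative advective face flux of a cell-centred field.

    ``u`` has length n+1 (wall faces included); returns fluxes of the same
    length with zero at the walls.  ``scheme`` is plain first-order upwind or
    minmod-limited MUSCL.
    """
    n = field.size
    F = np.zeros(n + 1)
    ui = u[1:n]
    if scheme == "upwind":
        face = np.where(ui >= 0.0, field[:-1], field[1:])
    elif scheme == "muscl":
        slope = np.zeros(n)
        slope[1:-1] = _minmod(field[1:-1] - field[:-2],
                              field[2:] - field[1:-1])
        left = field[:-1] + 0.5 * slope[:-1]
        right = field[1:] - 0.5 * slope[1:]
        face = np.where(ui >= 0.0, left, right)
    else:
        raise ValueError(f"unknown advection scheme {scheme!r}")
    F[1:n] = ui * face
    return F


def advect_scalar(field, u, dt, h, scheme: str = "upwind",
                  boundary: str = "wall"):
    """One conservative finite-volume advection step.

    With ``boundary='wall'`` the wall fluxes vanish and the integral of the
    field is preserved to round-off.  ``boundary='periodic'`` is a test
    harness mode (u then must also be periodic: u[0] == u[-1]).
    Raises :class:`CFLError` if max|u| dt/h > 1.
    """
    cfl = float(np.max(np.abs(u))) * dt / h
    if cfl > 1.0:
        raise CFLError(f"advective CFL {cfl:.3f} > 1; reduce dt")
    if boundary == "wall":
        F = upwind_flux(field, u, scheme)
    elif boundary == "periodic":
        ext = np.concatenate([field[-1:], field, field[:1]])
        Fe = upwind_flux(ext, np.concatenate([u[-2:-1], u, u[1:2]]), scheme)
        F = Fe[1:-1]
        F[0] = F[-1] = u[0] * (field[-1] if u[0] >= 0 else field[0])
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return field - (dt / h) * np.diff(F)


# ---------------------------------------------------------------------------
# Electrodiffusive fluxes
# ---------------------------------------------------------------------------

def electrodiffusive_flux(c, theta_s, Psi, D, z, h, scheme: str = "central"):
    """Nernst-Planck face flux -D theta_s (dc/dx + z c dPsi/dx).

    Returns fluxes at all n+1 faces with zero at the walls (no-flux
    boundaries).  ``scheme='central'`` evaluates the printed formula with
    centred differences and arithmetic face means; ``scheme='sg'`` uses the
    Scharfetter-Gummel exponentially fitted quadrature of the same flux.
    """
    n = c.size
    F = np.zeros(n + 1)
    ts_f = 0.5 * (theta_s[:-1] + theta_s[1:])
    dPsi = np.diff(Psi)
    if scheme == "central":
        c_f = 0.5 * (c[:-1] + c[1:])
        F[1:n] = -D * ts_f * (np.diff(c) / h + z * c_f * dPsi / h)
    elif scheme == "sg":
        s = z * dPsi
        F[1:n] = (D * ts_f / h) * (bernoulli(s) * c[:-1]
                                   - bernoulli(-s) * c[1:])
    else:
        raise ValueError(f"unknown flux scheme {scheme!r}")
    return F


# ---------------------------------------------------------------------------
# Electroneutral closure for the potential gradient
# ---------------------------------------------------------------------------

def _face_upwind(a, u):
    return np.where(u >= 0.0, a[:-1], a[1:])


def solve_face_potential_gradient(c_by_ion, z_by_ion, D_by_ion, theta_s,
                                  us, F_bound_charge, h, g0=None,
                                  rtol: float = 1.0e-10, maxiter: int = 100):
    """Solve, at every interior face, for the potential gradient g = dPsi/dx
    that makes the total charge flux vanish.

    The charge flux is the z-weighted sum of the Scharfetter-Gummel
    diffusion/drift fluxes plus the upwind advective dissolved fluxes, plus
    ``F_bound_charge`` (the advective flux of bound-plus-site charge, which
    does not depend on g).  The residual is strictly decreasing in g, so the
    root is unique; a vectorised Newton iteration with bisection fallback is
    used.  Returns ``(g, flux_scale)``.
    """
    n = theta_s.size
    ui = us[1:n]
    ts_mean = 0.5 * (theta_s[:-1] + theta_s[1:])
    ts_up = _face_upwind(theta_s, ui)

    # g-independent part: advection of dissolved charge + bound charge flux
    A = np.array(F_bound_charge, dtype=float, copy=True)
    scale = np.abs(F_bound_charge) + 1.0e-300
    for c, z, D in zip(c_by_ion, z_by_ion, D_by_ion):
        adv = ui * ts_up * _face_upwind(c, ui)
        A += z * adv
        scale += abs(z) * (np.abs(adv) + D * ts_mean * (c[:-1] + c[1:]) / h)

    def residual_and_slope(g):
        R = A.copy()
        dR = np.zeros_like(g)
        for c, z, D in zip(c_by_ion, z_by_ion, D_by_ion):
            s = z * g * h
            R += z * (D * ts_mean / h) * (bernoulli(s) * c[:-1]
                                          - bernoulli(-s) * c[1:])
            dR += z * z * D * ts_mean * (bernoulli_prime(s) * c[:-1]
                                         + bernoulli_prime(-s) * c[1:])
        return R, dR

    g = np.zeros(n - 1) if g0 is None else np.array(g0, float, copy=True)
    lo = np.full(n - 1, -np.inf)
    hi = np.full(n - 1, np.inf)
    for _ in range(maxiter):
        R, dR = residual_and_slope(g)
        done = np.abs(R) <= rtol * scale
        if done.all():
            return g, scale
        # residual decreasing in g: R > 0 means the root lies to the right
        lo = np.where(R > 0.0, np.maximum(lo, g), lo)
        hi = np.where(R < 0.0, np.minimum(hi, g), hi)
        step = np.where(done, 0.0, -R / np.minimum(dR, -1.0e-300))
        g_new = g + step
        # bisect where Newton leaves the bracket
        bad = (g_new <= lo) | (g_new >= hi)
        both = np.isfinite(lo) & np.isfinite(hi)
        mid = np.where(both, 0.5 * (np.where(both, lo, 0.0)
                               + np.where(both, hi, 0.0)),
                       g + np.sign(step) * 1.0)
        g = np.where(bad & ~done, mid, np.where(done, g, g_new))
    R, _ = residual_and_slope(g)
    if np.max(np.abs(R) / scale) > 100 * rtol:
        raise StepRejected("electroneutral closure failed to converge")
    return g, scale


def integrate_potential(g, h):
    """Potential at cell centres from interior-face gradients, with the
    gauge Psi = 0 in the rightmost cell."""
    n = g.size + 1
    Psi = np.zeros(n)
    Psi[:-1] = -np.cumsum((g * h)[::-1])[::-1]
    return Psi


def solve_electric_potential(state: GelState, u_n=None, u_s=None):
    """Electric potential field implied by the electroneutral closure.

    With no velocities supplied the closure balances drift against diffusion
    alone (the classical ambipolar constraint); otherwise the advective
    redistribution of dissolved and bound charge is included.
    """
    cfg = state.config
    n = state.n
    u_n = np.zeros(n + 1) if u_n is None else u_n
    u_s = np.zeros(n + 1) if u_s is None else u_s
    zt = cfg.z_tilde
    F_bc = (upwind_flux(state.b_Na, u_n)
            + 2.0 * upwind_flux(state.b_Ca, u_n)
            + 2.0 * upwind_flux(state.b_C2, u_n)
            - zt * upwind_flux(state.theta_n, u_n))[1:n]
    g, _ = solve_face_potential_gradient(
        (state.c_Na, state.c_Ca, state.c_Cl), (1, 2, -1),
        (cfg.D_Na, cfg.D_Ca, cfg.D_Cl), state.theta_s, u_s, F_bc, state.h,
        rtol=cfg.charge_tol)
    return integrate_potential(g, state.h)


# ---------------------------------------------------------------------------
# Implicit dissolved-species solve (given g)
# ---------------------------------------------------------------------------

def _implicit_dissolved_solve(c_old, W_old, theta_s_old, theta_s_new,
                              us, g, D, z, h, dt):
    """Backward-Euler solve of one dissolved species:

    theta_s_new c + (dt/h) div(F(c)) = W_old,  with implicit upwind
    advection and implicit Scharfetter-Gummel diffusion/drift at the frozen
    potential gradient g.  Tridiagonal; the operator is an M-matrix, so
    positivity is preserved unconditionally.
    """
    from scipy.linalg import solve_banded

    n = c_old.size
    ui = us[1:n]
    ts_mean = 0.5 * (theta_s_old[:-1] + theta_s_old[1:])
    ts_up = _face_upwind(theta_s_old, ui)
    s = z * g * h
    dcoef = D * ts_mean / h                      # interior faces
    Bp = bernoulli(s) * dcoef                    # multiplies left cell
    Bm = bernoulli(-s) * dcoef                   # multiplies right cell
    a_up = ui * ts_up                            # advective coefficient

    # face f (1..n-1): F_f = adv + Bp*c[f-1] - Bm*c[f]
    cL = np.where(ui >= 0.0, a_up, 0.0) + Bp     # coeff of c[f-1] in F_f
    cR = np.where(ui < 0.0, a_up, 0.0) - Bm      # coeff of c[f]   in F_f

    r = dt / h
    diag = theta_s_new.copy()
    diag[:-1] += r * cL                          # c_i coeff in F_{i+1}
    diag[1:] -= r * cR                           # c_i coeff in -F_i
    upper = r * cR                               # c_{i+1} coeff in F_{i+1}
    lower = -r * cL                              # c_{i-1} coeff in -F_i

    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    c_new = solve_banded((1, 1), ab, W_old)
    F = np.zeros(n + 1)
    F[1:n] = cL * c_new[:-1] + cR * c_new[1:]
    return c_new, F


# ---------------------------------------------------------------------------
# Implicit reaction step (vectorised backward-Euler Newton per cell)
# ---------------------------------------------------------------------------

def _reaction_newton(b_Na, b_Ca, b_C2, A_Na, A_Ca, theta_s, S_site,
                     rates, dt, tol, maxiter=40):
    """Vectorised damped Newton for one backward-Euler reaction step.

    Returns ``(u, v, w, converged)``.  Damping is per cell: the step
    fraction is first limited so every bound pool, the free sites and the
    dissolved contents stay non-negative, then halved per cell until the
    cell's residual does not increase.
    """
    kNon, kNoff = rates.k_Na_on, rates.k_Na_off
    kCon, kCoff = rates.k_Ca_on, rates.k_Ca_off
    ts2 = theta_s ** 2

    def residual(u, v, w):
        M = S_site - u - v - 2.0 * w
        P = A_Ca - v - w                      # theta_s * c_Ca
        Q = A_Na - u                          # theta_s * c_Na
        R_Na = kNon * M * Q - kNoff * ts2 * u
        Rb = kCon * M * P - kCoff * ts2 * v
        E2 = 0.5 * kCon * M * v - 2.0 * kCoff * ts2 * w
        F0 = u - b_Na - dt * R_Na
        F1 = v - b_Ca - dt * (Rb - E2)
        F2 = w - b_C2 - dt * E2
        return F0, F1, F2, M, P, Q

    scale = np.maximum.reduce([S_site, A_Na, A_Ca,
                               np.full_like(S_site, 1.0e-12)])
    u, v, w = b_Na.copy(), b_Ca.copy(), b_C2.copy()
    F0, F1, F2, M, P, Q = residual(u, v, w)
    norm = np.maximum.reduce([np.abs(F0), np.abs(F1), np.abs(F2)])
    atol = tol * scale + 1.0e-18
    for _ in range(maxiter):
        active = norm > atol
        if not active.any():
            return u, v, w, True
        J = np.zeros((u.size, 3, 3))
        J[:, 0, 0] = 1.0 - dt * (kNon * (-Q - M) - kNoff * ts2)
        J[:, 0, 1] = dt * kNon * Q
        J[:, 0, 2] = dt * 2.0 * kNon * Q
        dRb = (-kCon * P, kCon * (-P - M) - kCoff * ts2, kCon * (-2.0 * P - M))
        dE2 = (-0.5 * kCon * v, 0.5 * kCon * (M - v),
               -kCon * v - 2.0 * kCoff * ts2)
        J[:, 1, 0] = -dt * (dRb[0] - dE2[0])
        J[:, 1, 1] = 1.0 - dt * (dRb[1] - dE2[1])
        J[:, 1, 2] = -dt * (dRb[2] - dE2[2])
        J[:, 2, 0] = -dt * dE2[0]
        J[:, 2, 1] = -dt * dE2[1]
        J[:, 2, 2] = 1.0 - dt * dE2[2]
        rhs = -np.stack([F0, F1, F2], axis=-1)
        try:
            delta = np.linalg.solve(J, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return u, v, w, False
        du, dv, dw = delta[:, 0], delta[:, 1], delta[:, 2]
        du, dv, dw = (np.where(active, d, 0.0) for d in (du, dv, dw))
        # feasibility limit, per cell
        lam = np.ones_like(u)
        margin = 1.0e-14 * scale
        for q, dq in ((u, du), (v, dv), (w, dw),
                      (M, -(du + dv + 2.0 * dw)),
                      (P, -(dv + dw)), (Q, -du)):
            neg = dq < 0.0
            lam_q = np.where(neg, (np.maximum(q, 0.0) + margin)
                             / np.maximum(-dq, 1.0e-300), np.inf)
            lam = np.minimum(lam, lam_q)
        lam = np.minimum(lam, 1.0)
        # per-cell backtracking on the residual norm
        for _bt in range(30):
            u_t, v_t, w_t = u + lam * du, v + lam * dv, w + lam * dw
            F0t, F1t, F2t, Mt, Pt, Qt = residual(u_t, v_t, w_t)
            norm_t = np.maximum.reduce([np.abs(F0t), np.abs(F1t),
                                        np.abs(F2t)])
            worse = active & (norm_t > norm) & (lam > 1.0e-10)
            if not worse.any():
                break
            lam = np.where(worse, 0.5 * lam, lam)
        if not np.any(active & (norm_t < norm)):
            return u, v, w, False  # no active cell improved: stalled
        u, v, w = u_t, v_t, w_t
        F0, F1, F2, M, P, Q = F0t, F1t, F2t, Mt, Pt, Qt
        norm = norm_t
    return u, v, w, bool(np.all(norm <= atol))


def implicit_reaction_step(b_Na, b_Ca, b_C2, A_Na, A_Ca, theta_s, S_site,
                           cfg: SimulationConfig, dt):
    """Backward-Euler step of the stiff binding/unbinding kinetics in every
    cell simultaneously.

    Unknowns are the three bound pools; the dissolved concentrations are
    eliminated through the frozen elemental contents ``A_Na = theta_s c_Na +
    b_Na`` and ``A_Ca = theta_s c_Ca + b_Ca + b_C2`` so the step conserves
    both totals (and the local charge) exactly.  If the Newton iteration
    fails to converge over the full dt, the step is retried as a sequence of
    equal substeps, doubling their number up to 1024.
    """
    m = 1
    while m <= 1024:
        u, v, w = b_Na, b_Ca, b_C2
        ok = True
        for _ in range(m):
            u, v, w, ok = _reaction_newton(
                u, v, w, A_Na, A_Ca, theta_s, S_site, cfg.rates, dt / m,
                cfg.reaction_tol)
            if not ok:
                break
            # project round-off negatives away; the dissolved fields are
            # recomputed from the conserved contents afterwards, so this
            # perturbs neither the elemental totals nor the local charge
            u, v, w = (np.maximum(q, 0.0) for q in (u, v, w))
        if ok:
            return u, v, w
        m *= 2
    raise StepRejected("implicit reaction solve failed at minimum substep")


# ---------------------------------------------------------------------------
# Full ion update
# ---------------------------------------------------------------------------

def advance_ions(state: GelState, theta_n_new, F_theta, u_n, u_s, dt,
                 g_prev=None):
    """Advance all six ion fields over dt, given the already-advected network
    fraction and its face flux.

    Sequence: (i) bound species advect explicitly (upwind) with u_n;
    (ii) the face potential gradient is solved from the electroneutral
    closure at the incoming concentrations, the dissolved species advance
    implicitly (upwind advection with u_s plus Scharfetter-Gummel
    diffusion/drift at that frozen gradient), and the small closure error
    incurred by the implicit update is removed by a conservative corrective
    face flux distributed over the species in proportion to z_j D_j c_j —
    the weights z-sum to one, so the committed total charge flux vanishes
    identically at every face and pointwise electroneutrality is preserved
    to round-off; (iii) the stiff binding chemistry relaxes implicitly per
    cell.  Returns the updated field arrays plus the closure gradient.
    Raises :class:`StepRejected` on negative concentrations or
    non-convergence.
    """
    cfg = state.config
    n, h = state.n, state.h
    zt = cfg.z_tilde
    scheme = cfg.advection_scheme
    ts_old = state.theta_s
    ts_new = 1.0 - theta_n_new

    # (i) bound advection, and the g-independent bound+site charge flux
    F_bNa = upwind_flux(state.b_Na, u_n, scheme)
    F_bCa = upwind_flux(state.b_Ca, u_n, scheme)
    F_bC2 = upwind_flux(state.b_C2, u_n, scheme)
    b_Na = state.b_Na - (dt / h) * np.diff(F_bNa)
    b_Ca = state.b_Ca - (dt / h) * np.diff(F_bCa)
    b_C2 = state.b_C2 - (dt / h) * np.diff(F_bC2)
    if min(b_Na.min(), b_Ca.min(), b_C2.min()) < -1.0e-12:
        raise StepRejected("negative bound concentration after advection")
    # round-off-level negatives would deadlock the reaction feasibility
    # limiter; clipping them perturbs mass and charge at the 1e-16 level
    b_Na, b_Ca, b_C2 = (np.maximum(b, 0.0) for b in (b_Na, b_Ca, b_C2))
    F_bc = (F_bNa + 2.0 * F_bCa + 2.0 * F_bC2 - zt * F_theta)[1:n]

    # (ii) closure gradient at the incoming state, then implicit transport
    ions = ((state.c_Na, 1, cfg.D_Na), (state.c_Ca, 2, cfg.D_Ca),
            (state.c_Cl, -1, cfg.D_Cl))
    zs = (1, 2, -1)
    Ds = (cfg.D_Na, cfg.D_Ca, cfg.D_Cl)
    W_old = [ts_old * c for c, _, _ in ions]
    g, _ = solve_face_potential_gradient(
        tuple(c for c, _, _ in ions), zs, Ds, ts_old, u_s, F_bc, h,
        g0=g_prev, rtol=cfg.charge_tol)
    c_new, F_new = [], []
    for (c, z, D), W in zip(ions, W_old):
        cn, Fn = _implicit_dissolved_solve(
            c, W, ts_old, ts_new, u_s, g, D, z, h, dt)
        c_new.append(cn)
        F_new.append(Fn)

    # closure error of the committed fluxes, removed by a corrective face
    # flux split so that sum_j z_j * w_j = 1 exactly
    resid = F_bc.copy()
    for z, Fn in zip(zs, F_new):
        resid += z * Fn[1:n]
    ts_mean = 0.5 * (ts_old[:-1] + ts_old[1:])
    den = np.zeros(n - 1)
    for cn, z, D in zip(c_new, zs, Ds):
        den += z * z * D * ts_mean * 0.5 * (cn[:-1] + cn[1:])
    den = np.maximum(den, 1.0e-300)
    for k, (cn, z, D) in enumerate(zip(c_new, zs, Ds)):
        w = z * D * ts_mean * 0.5 * (cn[:-1] + cn[1:]) / den
        dF = np.zeros(n + 1)
        dF[1:n] = -w * resid
        c_new[k] = cn - (dt / h) * np.diff(dF) / ts_new

    c_Na, c_Ca, c_Cl = c_new
    floor = -1.0e-10 * max(float(np.max(np.abs(c))) for c in c_new)
    if min(float(np.min(c)) for c in c_new) < floor:
        raise StepRejected("negative dissolved concentration")
    if min(float(np.min(b)) for b in (b_Na, b_Ca, b_C2)) < -1.0e-12:
        raise StepRejected("negative bound concentration")

    # (iii) stiff chemistry, conserving local elemental content and charge
    A_Na = ts_new * c_Na + b_Na
    A_Ca = ts_new * c_Ca + b_Ca + b_C2
    S_site = zt * theta_n_new
    b_Na, b_Ca, b_C2 = implicit_reaction_step(
        b_Na, b_Ca, b_C2, A_Na, A_Ca, ts_new, S_site, cfg, dt)
    c_Na = (A_Na - b_Na) / ts_new
    c_Ca = (A_Ca - b_Ca - b_C2) / ts_new

    Psi = integrate_potential(g, h)
    return c_Na, c_Ca, c_Cl, b_Na, b_Ca, b_C2, Psi, g
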