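"""Electrodiffusion, advection, and the electroneutral potential closure."""

import dataclasses

import numpy as np
import pytest

import gelswell as gw
from gelswell.state import GelState
from gelswell.transport import (CFLError, advance_ions, advect_scalar,
                                electrodiffusive_flux,
                                solve_electric_potential, upwind_flux)


def salt_state(n, c_profile, D_Cl=None, c_Ca=0.0, L=25.0):
    """Network-free binary electrolyte state (c_Na = c_Cl + 2 c_Ca profile,
    theta_n at the bath floor) for pure-transport experiments."""
    over = {} if D_Cl is None else {"D_Cl": D_Cl}
    cfg = gw.case_preset("sparse_Na_preferred", n_cells=n, L=L, **over)
    x = (np.arange(n) + 0.5) * (L / n)
    c = c_profile(x)
    zeros = np.zeros(n)
    return GelState(
        config=cfg, theta_n=np.full(n, 1e-9), c_Na=c.copy(),
        c_Ca=np.full(n, c_Ca), c_Cl=c + 2 * c_Ca - 1e-10,
        b_Na=zeros.copy(), b_Ca=zeros.copy(), b_C2=zeros.copy(),
        Psi=zeros.copy())


def pure_transport_steps(state, dt, n_steps):
    """Advance the ions with zero phase velocities and frozen theta_n."""
    n = state.n
    zeros_f = np.zeros(n + 1)
    for _ in range(n_steps):
        out = advance_ions(state, state.theta_n, zeros_f, zeros_f, zeros_f,
                           dt, g_prev=np.diff(state.Psi) / state.h)
        (state.c_Na, state.c_Ca, state.c_Cl, state.b_Na, state.b_Ca,
         state.b_C2, state.Psi, _) = out
        state.t += dt
    return state


class TestElectrodiffusiveFlux:
    def test_uniform_fields_no_flux(self):
        n = 16
        c = np.full(n, 0.02)
        F = electrodiffusive_flux(c, np.ones(n), np.zeros(n), 2.5e3, 1, 1.0)
        assert np.max(np.abs(F)) == 0.0

    def test_neutral_species_is_fickian(self):
        n = 16
        c = np.linspace(0.01, 0.02, n)
        Psi = np.linspace(0.0, 1.0, n)
        h = 1.0
        F = electrodiffusive_flux(c, np.ones(n), Psi, 2.5e3, 0, h)
        assert np.allclose(F[1:n], -2.5e3 * np.diff(c) / h)

    def test_linear_ramps_closed_form(self):
        # c = 0.01 + 0.002 x, Psi = 0.05 x, theta_s = 1, z = +1:
        # flux = -D (dc/dx + z c dPsi/dx) with c at the face midpoint
        n, h = 10, 0.5
        x = (np.arange(n) + 0.5) * h
        c = 0.01 + 0.002 * x
        Psi = 0.05 * x
        D = 2.0e3
        F = electrodiffusive_flux(c, np.ones(n), Psi, D, 1, h)
        x_face = np.arange(1, n) * h
        c_face = 0.01 + 0.002 * x_face
        expected = -D * (0.002 + c_face * 0.05)
        assert np.allclose(F[1:n], expected, rtol=1e-12)

    def test_walls_are_no_flux(self):
        n = 8
        c = np.linspace(0.01, 0.05, n)
        for scheme in ("central", "sg"):
            F = electrodiffusive_flux(c, np.ones(n), np.zeros(n), 1e3, 1,
                                      1.0, scheme=scheme)
            assert F[0] == F[-1] == 0.0

    def test_sg_matches_central_at_small_drift(self):
        n = 12
        rng = np.random.default_rng(7)
        c = 0.02 + 0.005 * rng.random(n)
        Psi = 1e-6 * rng.random(n)
        ts = np.full(n, 0.8)
        Fc = electrodiffusive_flux(c, ts, Psi, 2.5e3, 2, 0.1, "central")
        Fs = electrodiffusive_flux(c, ts, Psi, 2.5e3, 2, 0.1, "sg")
        assert np.allclose(Fc, Fs, rtol=1e-5)


class TestAdvection:
    def test_zero_velocity_identity(self):
        f = np.linspace(0.0, 1.0, 20)
        out = advect_scalar(f, np.zeros(21), 0.1, 1.0)
        assert np.array_equal(out, f)

    def test_periodic_translation(self):
        """At unit CFL, upwind translates the profile by exactly one cell."""
        n = 32
        f = np.exp(-((np.arange(n) - 10.0) / 3.0) ** 2)
        u = np.full(n + 1, 2.0)
        out = advect_scalar(f, u, dt=0.5, h=1.0, boundary="periodic")
        assert np.allclose(out, np.roll(f, 1), atol=1e-14)

    def test_wall_conservation(self, rng):
        n = 40
        f = rng.random(n)
        u = np.zeros(n + 1)
        u[1:-1] = rng.standard_normal(n - 1)
        out = advect_scalar(f, u, dt=0.3, h=1.0)
        assert np.sum(out) == pytest.approx(np.sum(f), rel=1e-14)

    def test_cfl_violation_rejected(self):
        f = np.ones(10)
        with pytest.raises(CFLError):
            advect_scalar(f, np.full(11, 5.0), dt=1.0, h=1.0)

    def test_muscl_also_conservative_and_sharper(self):
        n = 100
        f = np.where(np.abs(np.arange(n) - 30) < 8, 1.0, 0.0)
        u = np.full(n + 1, 1.0)
        f1, f2 = f.copy(), f.copy()
        for _ in range(40):
            f1 = advect_scalar(f1, u, 0.5, 1.0, scheme="upwind")
            f2 = advect_scalar(f2, u, 0.5, 1.0, scheme="muscl")
        assert np.sum(f2) == pytest.approx(np.sum(f), rel=1e-12)
        exact = np.where(np.abs(np.arange(n) - 50) < 8, 1.0, 0.0)
        assert np.sum(np.abs(f2 - exact)) < np.sum(np.abs(f1 - exact))


class TestElectroneutralClosure:
    def test_uniform_state_has_constant_potential(self):
        st = salt_state(24, lambda x: np.full_like(x, 0.02))
        Psi = solve_electric_potential(st)
        assert np.max(np.abs(Psi)) < 1e-12

    def test_equal_diffusivities_give_zero_gradient(self):
        st = salt_state(24, lambda x: 0.02 + 0.005 * np.cos(np.pi * x / 25))
        Psi = solve_electric_potential(st)
        assert np.max(np.abs(np.diff(Psi))) < 1e-12

    def test_unequal_diffusivities_give_diffusion_potential(self):
        st = salt_state(24, lambda x: 0.02 + 0.005 * np.cos(np.pi * x / 25),
                        D_Cl=7.5e3)
        Psi = solve_electric_potential(st)
        # gradient sign: the faster anion runs ahead down-gradient, pulling
        # Psi down where the salt is depleted
        assert np.max(np.abs(np.diff(Psi))) > 1e-5

    def test_gauge_is_right_wall(self):
        st = salt_state(24, lambda x: 0.02 + 0.005 * np.cos(np.pi * x / 25),
                        D_Cl=7.5e3)
        Psi = solve_electric_potential(st)
        assert Psi[-1] == 0.0


class TestPureDiffusionOracle:
    """Single-salt transport against the separated cosine-mode solution
    c(x,t) = mean + A cos(pi x / L) exp(-D_eff (pi/L)^2 t) on a no-flux
    domain."""

    def _decay_error(self, n, D_Cl, D_eff, T=0.01, dt=2.0e-6):
        L = 25.0
        profile = lambda x: 0.02 + 0.004 * np.cos(np.pi * x / L)
        st = salt_state(n, profile, D_Cl=D_Cl)
        st = pure_transport_steps(st, dt, int(round(T / dt)))
        x = st.x
        exact = 0.02 + 0.004 * np.cos(np.pi * x / L) * np.exp(
            -D_eff * (np.pi / L) ** 2 * T)
        return float(np.sqrt(np.mean((st.c_Na - exact) ** 2))) / 0.004

    def test_equal_diffusivity_decay(self):
        err = self._decay_error(32, None, 2.5e3)
        assert err < 5e-3

    def test_ambipolar_effective_diffusivity(self):
        """With D_Cl = 3 D_Na the electroneutral pair diffuses with the
        ambipolar coefficient 2 D_Na D_Cl/(D_Na + D_Cl)."""
        D_Na, D_Cl = 2.5e3, 7.5e3
        D_amb = 2 * D_Na * D_Cl / (D_Na + D_Cl)
        err = self._decay_error(32, D_Cl, D_amb)
        assert err < 5e-3
        # and decisively not the bare cation or anion diffusivity
        assert self._decay_error(32, D_Cl, D_Na) > 5 * err
        assert self._decay_error(32, D_Cl, D_Cl) > 5 * err

    def test_error_vanishes_under_refinement(self):
        e32 = self._decay_error(32, 7.5e3, 3.75e3)
        e64 = self._decay_error(64, 7.5e3, 3.75e3)
        assert e64 < 0.6 * e32


class TestAdvanceIons:
    def test_conserves_each_total_without_network(self, rng):
        n = 32
        st = salt_state(n, lambda x: 0.02 + 0.004 * np.sin(np.pi * x / 25),
                        c_Ca=1e-3)
        h = st.h
        tot0 = st.totals()
        u = np.zeros(n + 1)
        u[1:-1] = 0.5 * np.sin(np.pi * np.arange(1, n) / n)
        for _ in range(50):
            out = advance_ions(st, st.theta_n, np.zeros(n + 1),
                               np.zeros(n + 1), u, 1e-4,
                               g_prev=np.diff(st.Psi) / h)
            (st.c_Na, st.c_Ca, st.c_Cl, st.b_Na, st.b_Ca, st.b_C2,
             st.Psi, _) = out
        tot1 = st.totals()
        for key in ("Na", "Ca", "Cl"):
            assert tot1[key] == pytest.approx(tot0[key], rel=1e-12)

    def test_electroneutrality_preserved_to_roundoff(self):
        st = salt_state(32, lambda x: 0.02 + 0.008 * np.cos(np.pi * x / 25),
                        D_Cl=7.5e3, c_Ca=1e-3)
        st = pure_transport_steps(st, 1e-4, 200)
        scale = float(np.max(st.c_Na + st.c_Ca + st.c_Cl))
        assert np.max(np.abs(st.charge_density())) < 1e-12 * scale

    def test_positivity_near_sharp_front(self):
        st = salt_state(48, lambda x: 0.001 + 0.05 * (x < 5.0))
        st = pure_transport_steps(st, 5e-5, 100)
        assert st.c_Na.min() > 0.0
        assert st.c_Cl.min() > 0.0
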