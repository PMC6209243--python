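"""Binding chemistry: site bookkeeping, equilibrium solver, kinetics oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gelswell as gw
from gelswell.chemistry import (IonTotals, WellMixedComposition,
                                crosslink_fraction, electroneutral_chloride,
                                free_site_density, integrate_kinetics,
                                reaction_rates, solve_equilibrium)


def make_comp(theta_n=0.5, z_tilde=0.1, **kw):
    base = dict(theta_n=theta_n, z_tilde=z_tilde, c_Na=0.01, c_Ca=0.005,
                c_Cl=0.02, b_Na=0.01, b_Ca=0.005, b_C2=0.01)
    base.update(kw)
    return WellMixedComposition(**base)


class TestSiteBookkeeping:
    @pytest.mark.parametrize("theta_n,z_tilde,b,expected", [
        (0.5, 1.0, (0.0, 0.0, 0.0), 0.5),        # empty network
        (0.5, 1.0, (0.0, 0.0, 0.25), 0.0),       # fully crosslinked
        (0.5, 0.1, (0.01, 0.005, 0.01), 0.015),  # mixed occupancy
    ])
    def test_free_sites(self, theta_n, z_tilde, b, expected):
        M = free_site_density(theta_n, *b, z_tilde)
        assert M == pytest.approx(expected, abs=1e-15)

    def test_over_occupied_sites_raise(self):
        with pytest.raises(ValueError, match="exceed"):
            free_site_density(0.1, 0.2, 0.0, 0.0, 0.1)

    @pytest.mark.parametrize("b_C2,expected", [
        (0.0, 0.0), (0.025, 1.0), (0.02, 0.8)])
    def test_crosslink_fraction(self, b_C2, expected):
        assert crosslink_fraction(b_C2, 0.5, 0.1) == pytest.approx(expected)

    def test_degenerate_network_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            crosslink_fraction(0.0, 0.0, 0.1)

    @given(theta_n=st.floats(0.01, 0.99), frac=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_alpha_bounded_when_sites_feasible(self, theta_n, frac):
        z_tilde = 0.1
        b_C2 = frac * z_tilde * theta_n / 2.0
        assert 0.0 <= crosslink_fraction(b_C2, theta_n, z_tilde) <= 1.0


class TestElectroneutralChloride:
    @pytest.mark.parametrize("T_Na,T_Ca,theta_n,z_tilde,expected", [
        (0.005, 0.250, 0.5, 1.0, 0.005),     # dense inner column
        (0.001, 0.0253, 0.5, 0.1, 0.0016),   # sparse inner column
    ])
    def test_inner_columns(self, T_Na, T_Ca, theta_n, z_tilde, expected):
        T_Cl = electroneutral_chloride(T_Na, T_Ca, theta_n, z_tilde)
        assert T_Cl == pytest.approx(expected, abs=1e-15)

    def test_bath_limit(self):
        T_Cl = electroneutral_chloride(0.200, 0.001, 1e-9, 0.1)
        assert T_Cl == pytest.approx(0.202, rel=1e-8)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            electroneutral_chloride(0.001, 0.001, 0.5, 1.0)


class TestReactionRates:
    def setup_method(self):
        self.ions = gw.case_preset("sparse_Na_preferred").ion_specs()

    def test_binding_starts_positive(self):
        comp = make_comp(b_Na=0.0, b_Ca=0.0, b_C2=0.0)
        db_Na, db_Ca, db_C2, dTc_Na, dTc_Ca = reaction_rates(comp, self.ions)
        assert db_Na > 0 and db_Ca > 0
        assert dTc_Na < 0 and dTc_Ca < 0

    def test_equilibrium_rates_vanish(self):
        tot = IonTotals(T_Na=0.001, T_Ca=0.0253, T_Cl=0.0016)
        comp = solve_equilibrium(tot, 0.5, 0.1, self.ions)
        rates = reaction_rates(comp, self.ions)
        scale = self.ions["Na"].k_on * 0.05 * 0.01
        assert all(abs(r) < 1e-9 * scale for r in rates)

    def test_elemental_conservation_identity(self, rng):
        for _ in range(20):
            comp = make_comp(
                c_Na=rng.uniform(0, 0.1), c_Ca=rng.uniform(0, 0.1),
                b_Na=rng.uniform(0, 0.01), b_Ca=rng.uniform(0, 0.01),
                b_C2=rng.uniform(0, 0.01))
            db_Na, db_Ca, db_C2, dTc_Na, dTc_Ca = reaction_rates(
                comp, self.ions)
            # d/dt(theta_s c_Na + b_Na) and d/dt(theta_s c_Ca + b_Ca + b_C2)
            assert dTc_Na + db_Na == pytest.approx(0.0, abs=1e-12)
            assert dTc_Ca + db_Ca + db_C2 == pytest.approx(0.0, abs=1e-12)


class TestEquilibriumSolver:
    def test_no_calcium_reduces_to_sodium_binding(self):
        rates = gw.case_preset("sparse_Na_preferred").rates
        tot = IonTotals(T_Na=0.01, T_Ca=0.0, T_Cl=0.0)
        comp = solve_equilibrium(tot, 0.5, 0.1, rates)
        assert comp.b_Ca == 0.0 and comp.b_C2 == 0.0 and comp.alpha == 0.0
        # remaining scalar balance: z~*theta_n = M + b_Na
        assert comp.M_free + comp.b_Na == pytest.approx(0.05, rel=1e-12)
        assert comp.theta_s * comp.c_Na + comp.b_Na == pytest.approx(
            0.01, rel=1e-12)

    @pytest.mark.parametrize("case", gw.CASE_NAMES)
    def test_inner_compositions_highly_crosslinked(self, case):
        cfg = gw.case_preset(case)
        T_Cl = electroneutral_chloride(cfg.T_Na_inner, cfg.T_Ca_inner,
                                       0.5, cfg.z_tilde)
        comp = solve_equilibrium(
            IonTotals(cfg.T_Na_inner, cfg.T_Ca_inner, T_Cl),
            0.5, cfg.z_tilde, cfg.rates)
        assert comp.alpha > 0.8
        tots = comp.totals()
        assert tots.T_Na == pytest.approx(cfg.T_Na_inner, rel=1e-10)
        assert tots.T_Ca == pytest.approx(cfg.T_Ca_inner, rel=1e-10)

    def test_agrees_with_kinetics_oracle_on_random_totals(self, rng):
        """Equilibrium solver vs brute-force stiff integration to steady
        state, over a grid of admissible random totals."""
        n_checked = 0
        for _ in range(50):
            case = rng.choice(gw.CASE_NAMES)
            cfg = gw.case_preset(case)
            ions = cfg.ion_specs()
            theta_n = rng.uniform(0.05, 0.6)
            S = cfg.z_tilde * theta_n
            tot = IonTotals(T_Na=S * rng.uniform(0.01, 2.0),
                            T_Ca=S * rng.uniform(0.01, 2.0),
                            T_Cl=0.0)
            eq = solve_equilibrium(tot, theta_n, cfg.z_tilde, ions)
            start = WellMixedComposition(
                theta_n=theta_n, z_tilde=cfg.z_tilde,
                c_Na=tot.T_Na / (1 - theta_n),
                c_Ca=tot.T_Ca / (1 - theta_n), c_Cl=0.0,
                b_Na=0.0, b_Ca=0.0, b_C2=0.0)
            _, traj = integrate_kinetics(start, ions, t_end=5.0)
            end = traj[-1]
            scale = max(S, tot.T_Na, tot.T_Ca)
            for attr in ("b_Na", "b_Ca", "b_C2"):
                assert getattr(end, attr) == pytest.approx(
                    getattr(eq, attr), rel=1e-6, abs=1e-6 * scale)
            n_checked += 1
        assert n_checked == 50

    def test_kinetics_conserves_totals_and_sites(self):
        cfg = gw.case_preset("dense_Ca_preferred")
        ions = cfg.ion_specs()
        start = make_comp(theta_n=0.4, z_tilde=1.0, c_Ca=0.3, b_C2=0.05)
        t, traj = integrate_kinetics(start, ions, t_end=1.0)
        T0 = start.totals()
        for comp in traj:
            T = comp.totals()
            assert T.T_Na == pytest.approx(T0.T_Na, rel=1e-10)
            assert T.T_Ca == pytest.approx(T0.T_Ca, rel=1e-10)
            # site balance maintained along the trajectory
            occupancy = comp.M_free + comp.b_Na + comp.b_Ca + 2 * comp.b_C2
            assert occupancy == pytest.approx(0.4, rel=1e-12)

    def test_kinetics_fixed_at_equilibrium(self):
        cfg = gw.case_preset("sparse_Na_preferred")
        ions = cfg.ion_specs()
        tot = IonTotals(T_Na=0.001, T_Ca=0.0253, T_Cl=0.0016)
        eq = solve_equilibrium(tot, 0.5, 0.1, ions)
        _, traj = integrate_kinetics(eq, ions, t_end=1.0)
        assert traj[-1].b_C2 == pytest.approx(eq.b_C2, rel=1e-8)

    def test_weaker_calcium_binding_never_increases_alpha(self):
        from gelswell.params import KineticRates
        tot = IonTotals(T_Na=0.002, T_Ca=0.03, T_Cl=0.0)
        alphas = []
        for K_Ca in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
            rates = KineticRates(k_Ca_on=1e3 / K_Ca, k_Ca_off=1e3,
                                 k_Na_on=5e6, k_Na_off=5e2)
            alphas.append(solve_equilibrium(tot, 0.5, 0.1, rates).alpha)
        assert all(a1 >= a2 - 1e-12 for a1, a2 in zip(alphas, alphas[1:]))

    @given(fNa=st.floats(0.01, 3.0), fCa=st.floats(0.01, 3.0),
           theta_n=st.floats(0.02, 0.7))
    @settings(max_examples=30, deadline=None)
    def test_solution_always_admissible(self, fNa, fCa, theta_n):
        rates = gw.case_preset("dense_Na_preferred").rates
        S = 1.0 * theta_n
        comp = solve_equilibrium(IonTotals(fNa * S, fCa * S, 0.0),
                                 theta_n, 1.0, rates)
        assert comp.M_free >= -1e-12
        assert min(comp.b_Na, comp.b_Ca, comp.b_C2,
                   comp.c_Na, comp.c_Ca) >= -1e-15
        assert 0.0 <= comp.alpha <= 1.0
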