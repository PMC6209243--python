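import numpy as np
import pytest
from hypothesis import settings

import gelswell as gw

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def energies():
    """Default interaction energies (eps1=-45, eps2=25, eps3=-0.5, N=6)."""
    return gw.InteractionEnergies()


@pytest.fixture(scope="session")
def exemplar_run():
    """The exemplar swelling experiment: sparse binding, sodium preferred,
    bath Na 0.02 M, integrated through the rate-fit window."""
    cfg = gw.case_preset("sparse_Na_preferred", n_cells=128, t_end=1.0)
    return gw.run(cfg)


@pytest.fixture(scope="session")
def long_run():
    """Coarse long-horizon run used for late-time/steady-state checks."""
    cfg = gw.case_preset("sparse_Na_preferred", n_cells=64, t_end=4.0)
    return gw.run(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def uniform_equilibrium_state(n=32, theta_n=0.1):
    """Spatially uniform state at binding equilibrium (an exact fixed point
    of the dynamics)."""
    from gelswell.chemistry import IonTotals, solve_equilibrium

    cfg = gw.case_preset("sparse_Na_preferred", n_cells=n)
    T_Na, T_Ca = 0.004, 0.005
    T_Cl = T_Na + 2 * T_Ca - cfg.z_tilde * theta_n
    comp = solve_equilibrium(IonTotals(T_Na, T_Ca, T_Cl), theta_n,
                             cfg.z_tilde, cfg.rates)
    ones = np.ones(n)
    return gw.GelState(
        config=cfg, theta_n=theta_n * ones, c_Na=comp.c_Na * ones,
        c_Ca=comp.c_Ca * ones, c_Cl=comp.c_Cl * ones,
        b_Na=comp.b_Na * ones, b_Ca=comp.b_Ca * ones,
        b_C2=comp.b_C2 * ones, Psi=np.zeros(n))
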