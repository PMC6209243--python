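"""Initial-condition construction and time integration of the gel model.

A run represents a closed 1D container: a dense, highly crosslinked globule
of network equilibrated with its inner ionic composition sits at the left
end; the rest of the domain is a network-free bath of prescribed sodium and
calcium content, chloride balancing the charge.  Profiles transition between
the two compositions through a sharp tanh centred at x0.

Each time step is a Lie split: (1) solve the quasi-static force balance for
the phase velocities; (2) advect the network fraction conservatively;
(3) advance the ions (bound advection, implicit electrodiffusion with the
electroneutral potential closure, implicit binding chemistry).  The step
size follows an advective CFL bound and is halved on rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, chemistry, transport
from .mechanics import VelocitySolution, solve_velocities
from .params import SimulationConfig
from .state import GelState

__all__ = ["Snapshot", "RunResult", "build_initial_condition", "step", "run"]


@dataclass
class Snapshot:
    """Full state plus the derived crosslink fields at one output time."""

    time: float
    state: GelState

    def to_frame(self):
        import pandas as pd

        s = self.state
        pots = s.potentials()
        return pd.DataFrame({
            "x_um": s.x, "theta_n": s.theta_n, "theta_s": s.theta_s,
            "c_Na_M": s.c_Na, "c_Ca_M": s.c_Ca, "c_Cl_M": s.c_Cl,
            "b_Na_M": s.b_Na, "b_Ca_M": s.b_Ca, "b_C2_M": s.b_C2,
            "Psi_thermal": s.Psi, "alpha": s.alpha, "M_free_M": s.M_free,
            "I": pots.I,
        })


@dataclass
class RunResult:
    """Everything one swelling experiment produces."""

    config: SimulationConfig
    snapshots: list[Snapshot]
    metrics: analysis.SwellingMetrics
    n_steps: int
    n_rejected: int
    drift: dict[str, float] = field(default_factory=dict)

    @property
    def final_state(self) -> GelState:
        return self.snapshots[-1].state


def _tanh_blend(x, inner, bath, x0, w):
    s = 0.5 * (1.0 - np.tanh((x - x0) / w))
    return bath + (inner - bath) * s


def build_initial_condition(config: SimulationConfig) -> GelState:
    """Equilibrate the inner and bath compositions separately, then blend.

    The conserved densities (theta_n, theta_s*c_j, b_j) are blended with the
    same tanh profile; because the net charge is linear in exactly those
    densities, and both end compositions are neutral, the blended state is
    pointwise electroneutral by construction.
    """
    zt = config.z_tilde
    rates = config.rates

    def equilibrate(T_Na, T_Ca, theta_n):
        T_Cl = chemistry.electroneutral_chloride(T_Na, T_Ca, theta_n, zt)
        tot = chemistry.IonTotals(T_Na=T_Na, T_Ca=T_Ca, T_Cl=T_Cl)
        return chemistry.solve_equilibrium(tot, theta_n, zt, rates)

    inner = equilibrate(config.T_Na_inner, config.T_Ca_inner,
                        config.theta_n_inner)
    bath = equilibrate(config.T_Na_bath, config.T_Ca_bath,
                       config.theta_n_bath)

    n = config.n_cells
    x = (np.arange(n) + 0.5) * config.h
    blend = lambda a, b: _tanh_blend(x, a, b, config.x0, config.tanh_width)

    theta_n = blend(inner.theta_n, bath.theta_n)
    theta_s = 1.0 - theta_n
    fields = {}
    for name in ("c_Na", "c_Ca", "c_Cl"):
        W = blend(inner.theta_s * getattr(inner, name),
                  bath.theta_s * getattr(bath, name))
        fields[name] = W / theta_s
    for name in ("b_Na", "b_Ca", "b_C2"):
        fields[name] = blend(getattr(inner, name), getattr(bath, name))

    state = GelState(config=config, theta_n=theta_n, Psi=np.zeros(n),
                     **fields)
    state.Psi = transport.solve_electric_potential(state)
    state.check_invariants()
    return state


def step(state: GelState, dt: float,
         vel: VelocitySolution | None = None) -> GelState:
    """One split time step of size dt.  Raises
    :class:`transport.StepRejected` or :class:`transport.CFLError` if the
    step cannot be completed at this dt."""
    cfg = state.config
    h, n = state.h, state.n
    if vel is None:
        vel = solve_velocities(state)
    if vel.max_speed * dt / h > 1.0:
        raise transport.CFLError(
            f"dt {dt:.3e} violates the advective CFL bound")

    F_theta = transport.upwind_flux(state.theta_n, vel.u_n,
                                    cfg.advection_scheme)
    theta_n_new = state.theta_n - (dt / h) * np.diff(F_theta)
    if np.any(theta_n_new <= 0.0) or np.any(theta_n_new >= 1.0):
        raise transport.StepRejected("network fraction left (0, 1)")

    g_prev = np.diff(state.Psi) / h
    c_Na, c_Ca, c_Cl, b_Na, b_Ca, b_C2, Psi, _g = transport.advance_ions(
        state, theta_n_new, F_theta, vel.u_n, vel.u_s, dt, g_prev=g_prev)

    return GelState(config=cfg, theta_n=theta_n_new, c_Na=c_Na, c_Ca=c_Ca,
                    c_Cl=c_Cl, b_Na=b_Na, b_Ca=b_Ca, b_C2=b_C2, Psi=Psi,
                    t=state.t + dt, p=vel.p)


def run(config: SimulationConfig, *, initial: GelState | None = None,
        progress=None) -> RunResult:
    """Integrate a swelling experiment to t_end.

    Emits snapshots at the configured cadence, samples the swelling metrics
    (peak network fraction, front location) every ``metrics_dt`` seconds,
    and fits the front-decay rate gamma over the configured window when
    enough of it is covered.  Conservation drift of network volume and of
    each ionic element over the whole run is reported in ``drift``.
    """
    state = initial if initial is not None else build_initial_condition(config)
    theta_ss = analysis.steady_state_fraction(state.theta_n)
    totals0 = state.totals()

    times = [state.t]
    th_max = [float(state.theta_n.max())]
    fronts = [analysis.front_location(state.x, state.theta_n,
                                      config.front_threshold)]
    snapshots = [Snapshot(state.t, state.copy())]
    next_metric = state.t + config.metrics_dt
    next_snap = (state.t + config.snapshot_dt if config.snapshot_dt > 0
                 else np.inf)

    n_steps = n_rejected = 0
    dt = config.dt_max
    while state.t < config.t_end - 1e-15:
        vel = solve_velocities(state)
        dt = min(config.dt_max,
                 config.cfl * state.h / max(vel.max_speed, 1e-30),
                 config.t_end - state.t)
        while True:
            try:
                new_state = step(state, dt, vel=vel)
                break
            except (transport.StepRejected, transport.CFLError) as err:
                n_rejected += 1
                dt *= 0.5
                if dt < config.dt_min:
                    raise RuntimeError(
                        f"time step collapsed below dt_min at t="
                        f"{state.t:.6f}s: {err}") from err
        state = new_state
        n_steps += 1

        if state.t >= next_metric - 1e-12:
            times.append(state.t)
            th_max.append(float(state.theta_n.max()))
            fronts.append(analysis.front_location(
                state.x, state.theta_n, config.front_threshold))
            next_metric += config.metrics_dt
        if state.t >= next_snap - 1e-12:
            snapshots.append(Snapshot(state.t, state.copy()))
            next_snap += config.snapshot_dt
        if progress is not None and n_steps % 1000 == 0:
            progress(state, n_steps)

    if snapshots[-1].time < state.t:
        snapshots.append(Snapshot(state.t, state.copy()))

    metrics = analysis.SwellingMetrics(
        times=np.array(times), theta_n_max=np.array(th_max),
        front_L=np.array(fronts), theta_n_ss=theta_ss, L=config.L)
    try:
        metrics.fit()
    except ValueError:
        pass  # window not covered (short runs); gamma stays NaN

    totals1 = state.totals()
    drift = {k: abs(totals1[k] - totals0[k]) / max(abs(totals0[k]), 1e-300)
             for k in totals0}
    return RunResult(config=config, snapshots=snapshots, metrics=metrics,
                     n_steps=n_steps, n_rejected=n_rejected, drift=drift)
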