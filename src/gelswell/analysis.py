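"""Swelling quantification: peak decay, front tracking and rate fitting.

The gel globule's expansion is tracked two ways: the decay of the excess
peak network fraction Delta-theta(t) = theta_n_max - theta_n_ss, and the
motion of the swelling front L*(t), the rightmost point where theta_n
crosses a small threshold (1% network by volume).  For a uniformly swelling
globule conservation of mass turns an exponential approach of the volume
fraction into an exponential decay of

    Delta-L-inv(t) = 1/L*(t) - 1/L  ~  exp(-gamma t),

so the early-time swelling rate gamma is read off as the (negative) slope of
a least-squares line through ln(Delta-L-inv) inside a fixed time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SwellingMetrics", "steady_state_fraction", "front_location",
    "delta_L_inv", "fit_decay_rate", "gamma_sweep", "FRONT_ABSENT",
]

#: sentinel returned when theta_n never crosses the front threshold
FRONT_ABSENT = float("nan")

#: default fit window (s): after the start-up transient, before the front
#: reaches the right wall
FIT_WINDOW = (0.2, 0.8)


def steady_state_fraction(theta_n, h=None, L=None) -> float:
    """Uniform-state network fraction implied by mass conservation: the
    domain average of theta_n (exact for a uniform grid)."""
    return float(np.mean(theta_n))


def front_location(x, theta_n, threshold: float = 0.01) -> float:
    """Rightmost location where theta_n crosses ``threshold``, by linear
    interpolation between adjacent cell centres.

    Returns :data:`FRONT_ABSENT` (NaN) if the profile never crosses.
    """
    t = np.asarray(theta_n, float)
    above = t >= threshold
    cross = np.flatnonzero(above[:-1] != above[1:])
    if cross.size == 0:
        return FRONT_ABSENT
    i = int(cross[-1])
    f = (threshold - t[i]) / (t[i + 1] - t[i])
    return float(x[i] + f * (x[i + 1] - x[i]))


def delta_L_inv(front_L, L: float):
    """Scaled front coordinate 1/L*(t) - 1/L; >= 0 while the front is inside
    the domain."""
    return 1.0 / np.asarray(front_L, float) - 1.0 / L


def fit_decay_rate(times, values, window=FIT_WINDOW):
    """Exponential decay rate of a positive time series.

    Ordinary least squares on (t, ln values) restricted to ``window``;
    returns ``(gamma, r_squared)`` with gamma = -slope.  Requires at least
    three positive samples inside the window.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    mask = (t >= window[0]) & (t <= window[1]) & (y > 0) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive samples in window {window}; got {mask.sum()}")
    tw, lw = t[mask], np.log(y[mask])
    slope, intercept = np.polyfit(tw, lw, 1)
    resid = lw - (slope * tw + intercept)
    ss_tot = float(np.sum((lw - lw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), r2


@dataclass
class SwellingMetrics:
    """Time series of the swelling diagnostics plus the fitted rate."""

    times: np.ndarray
    theta_n_max: np.ndarray
    front_L: np.ndarray
    theta_n_ss: float
    L: float
    fit_window: tuple[float, float] = FIT_WINDOW
    gamma: float = field(default=float("nan"))
    fit_r2: float = field(default=float("nan"))

    @property
    def delta_theta(self) -> np.ndarray:
        return self.theta_n_max - self.theta_n_ss

    @property
    def delta_L_inv(self) -> np.ndarray:
        return delta_L_inv(self.front_L, self.L)

    def fit(self) -> "SwellingMetrics":
        self.gamma, self.fit_r2 = fit_decay_rate(
            self.times, self.delta_L_inv, self.fit_window)
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.times,
            "theta_n_max": self.theta_n_max,
            "delta_theta": self.delta_theta,
            "front_L_um": self.front_L,
            "delta_L_inv_per_um": self.delta_L_inv,
        })


def gamma_sweep(case: str, bath_Na_list, *, config_overrides=None,
                progress=None) -> pd.DataFrame:
    """Run one swelling experiment per bath sodium molarity and fit gamma.

    Chloride in the bath is re-balanced for electroneutrality at every
    molarity.  Failed runs are recorded with NaN and the sweep continues.
    Returns a DataFrame with columns case, bath_Na_M, gamma_per_s, fit_r2.
    """
    from .params import case_preset
    from .simulation import run

    rows = []
    for bath_Na in bath_Na_list:
        over = dict(config_overrides or {})
        over["T_Na_bath"] = float(bath_Na)
        cfg = case_preset(case, **over)
        try:
            result = run(cfg)
            m = result.metrics
            rows.append(dict(case=case, bath_Na_M=float(bath_Na),
                             gamma_per_s=m.gamma, fit_r2=m.fit_r2))
        except Exception as err:  # record and continue
            rows.append(dict(case=case, bath_Na_M=float(bath_Na),
                             gamma_per_s=float("nan"),
                             fit_r2=float("nan"), error=str(err)))
        if progress is not None:
            progress(rows[-1])
    return pd.DataFrame(rows)
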