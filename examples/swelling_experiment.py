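"""One full swelling experiment: the exemplar case.

A sparse-binding, sodium-preferring gel globule (left fifth of a 25 um
closed container, network fraction 0.5, crosslink fraction 0.80) meets a
0.02 M sodium bath.  Sodium floods in, displaces the calcium bridges, the
interaction parameter I(alpha) swings from ~0 toward -45, and the network
spreads right toward the uniform state theta_n ~ 0.1.

The script prints the front trajectory L*(t) (where theta_n crosses 0.01)
and the fitted early-time swelling rate gamma: the exponential decay rate
of 1/L* - 1/L over the 0.2-0.8 s window.
"""

import numpy as np

import gelswell as gw

cfg = gw.case_preset("sparse_Na_preferred", n_cells=128, t_end=1.0,
                     T_Na_bath=0.02)
result = gw.run(cfg)
m = result.metrics

print(f"steps taken          : {result.n_steps}")
print(f"theta_n steady state : {m.theta_n_ss:.4f} (domain average)")
print(f"conservation drift   : "
      + ", ".join(f"{k}={v:.1e}" for k, v in result.drift.items()))
print("\n   t (s)   theta_n_max   L* (um)   1/L* - 1/L (1/um)")
for i in range(0, len(m.times), 10):
    print(f"  {m.times[i]:6.2f}   {m.theta_n_max[i]:11.4f}   "
          f"{m.front_L[i]:7.2f}   {m.delta_L_inv[i]:17.5f}")
print(f"\nfitted swelling rate gamma = {m.gamma:.3f} 1/s "
      f"(log-linear fit, R^2 = {m.fit_r2:.4f})")
print("The peak network fraction decays toward 0.1 while the front runs "
      "toward the\nfar wall; gamma summarises how fast the globule's "
      "inverse width relaxes.")
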