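# gelswell

A 1D simulator for the dynamic swelling of a two-phase polyelectrolyte gel
model of gastric mucus.

Gastric mucus is secreted as a densely packed, calcium-condensed polymer
globule that swells explosively on contact with the stomach's ionic milieu.
One proposed mechanism: divalent calcium ions bridge pairs of negative sites
on the mucin network ("crosslinks"), holding it condensed; monovalent sodium
from the environment displaces the calcium, the crosslinks vanish, the
mixing energy of the gel changes sign, and the network hydrates. `gelswell`
implements that mechanism as a continuum model and measures how fast the
resulting swelling front moves as a function of the gel's binding chemistry
and the bath's sodium content. It is aimed at modellers studying mucus
hydration, polyelectrolyte gel dynamics, or two-phase gel mechanics.

## The model

Two phases — network (volume fraction θₙ) and solvent (θₛ = 1 − θₙ) — each
carry a velocity obeying a quasi-static force balance (inertia is negligible
at micron scales):

    ∇·(θₙ σₙ) − ξ θₙθₛ(uₙ − uₛ) − θₙ∇μₙ − θₙ∇p = 0
    ∇·(θₛ σₛ) − ξ θₙθₛ(uₛ − uₙ) − θₛ∇μₛ − θₛ∇p − θₛ Σⱼ φⱼ∇μⱼ = 0

with viscous stresses σᵢ = νᵢ ∂ₓuᵢ, interphase drag ξ, and a common pressure
p enforcing ∇·(θₙuₙ + θₛuₛ) = 0. Dissolved Na⁺, Ca²⁺ and Cl⁻ follow
Nernst–Planck fluxes −Dⱼθₛ(∇cⱼ + zⱼcⱼ∇Ψ) with Ψ in thermal-voltage units,
closed by bulk electroneutrality rather than a Poisson equation. Cations
bind network sites by mass action; calcium can capture a second site to form
a crosslink (doubly bound concentration b_C2). The crosslink fraction

    α = 2 b_C2 / (z̃ θₙ)

rewires the gel's Flory-type interaction parameter, I(α) = 6(ε₁+ε₂) −
2(1−1/N)ε₁ − ε₁α, which interpolates linearly from I(1) = 0 (fully
crosslinked, no drive to swell) to I(0) = −45 (uncrosslinked, strongly
swelling) with the shipped energies. Swelling is quantified by the front
L*(t) where θₙ crosses 0.01: mass conservation turns exponential relaxation
of the volume fraction into exponential decay of ΔL⁻¹ = 1/L* − 1/L, and the
swelling rate γ is the slope of ln ΔL⁻¹ over the 0.2–0.8 s window.

Four named regimes cover dense (z̃ = 1 M) vs sparse (z̃ = 0.1 M) binding
sites crossed with sodium-preferred (K_Na < K_Ca) vs calcium-preferred
(K_Ca < K_Na) chemistry.

## Worked example

`python examples/swelling_experiment.py` runs the exemplar case — sparse
binding, sodium preferred, bath Na 0.02 M, 128 cells — and prints:

```
theta_n steady state : 0.1000 (domain average)
conservation drift   : theta_n=3.6e-16, Na=4.1e-13, Ca=2.9e-13, Cl=5.8e-13

   t (s)   theta_n_max   L* (um)   1/L* - 1/L (1/um)
    0.00        0.5000      5.52             0.14120
    0.20        0.2876     13.52             0.03398
    0.40        0.2291     16.74             0.01972
    0.60        0.1995     19.06             0.01246
    0.80        0.1806     20.93             0.00779
    1.00        0.1672     22.50             0.00444

fitted swelling rate gamma = 2.385 1/s (log-linear fit, R^2 = 0.9987)
```

The peak network fraction decays from 0.5 toward the conserved uniform value
0.1 while the 1%-network front sweeps from ~5.5 µm toward the far wall at
25 µm; γ ≈ 2.4 s⁻¹ summarises the early-time rate of that expansion.
`examples/equilibrium_chemistry.py` prints the initial crosslink fractions
(α = 0.80–0.97 across regimes) and `examples/sodium_sweep.py` shows the
non-monotone dependence of γ on bath sodium. A thin CLI wraps the same
machinery: `gelswell simulate --preset sparse_Na_preferred --out run/`,
plus `sweep`, `metrics` and `validate` subcommands.

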