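# Methods

## Model

`gelswell` treats mucus gel as a two-phase mixture on a closed 1D domain
[0, L]: a polymer network and a hydrating solvent, with volume fractions
θₙ + θₛ = 1, each moving with its own velocity. Momentum balance is
quasi-static (micron lengths, µm/s speeds — inertia is irrelevant): each
phase feels its viscous stress, interphase drag ξθₙθₛ(uₙ−uₛ), the gradient
of its chemical potential weighted by its volume fraction, and a shared
pressure that enforces the volume-averaged incompressibility constraint.
Dissolved ions are massless tracers in the solvent; the drag they exert is
bookkept as the force θₛΣφⱼ∇μⱼ acting on the solvent itself. In the solvent
momentum equation the pressure is weighted by θₛ, so the two phase equations
sum to a total balance containing a single full ∇p — the standard
mixture-theory convention.

Chemistry: Na⁺ occupies one negative network site; Ca²⁺ first binds one site
(b_Ca) and can then capture a second (b_C2, a crosslink). Site bookkeeping
is exact: z̃θₙ = M + b_Na + b_Ca + 2b_C2, with z̃ the site density per
network volume and M the free-site concentration. Reaction rates are mass
action, written per total volume:

    d b_Na/dt = k_Na_on θₛ M c_Na − k_Na_off θₛ² b_Na
    d b_Ca/dt = k_Ca_on θₛ M c_Ca − k_Ca_off θₛ² b_Ca − E₂
    d b_C2/dt = E₂ = ½ k_Ca_on M b_Ca − 2 k_Ca_off θₛ² b_C2

with the matching dissolved sinks equal to −(rate)/θₛ, so the elemental
totals θₛc_Na + b_Na and θₛc_Ca + b_Ca + b_C2 are invariants of pure
reaction. Every unbinding step carries the θₛ² volume-fraction weighting,
including the crosslink release: that convention is what makes the four
shipped inner compositions equilibrate at crosslink fractions α between
0.80 and 0.97, i.e. produces the highly condensed starting gels the model
is built to study (without the θₛ² on the crosslink step the sparse
sodium-preferred regime would start at α ≈ 0.66, not a condensed gel).

Energetics (all potentials in kBT units): the solvent and network
potentials are Flory–Huggins-type mixing terms plus an ionic osmotic term
σ_I = Σcⱼ/c_water, plus the electrostatic site term −z̃Ψ on the network.
The short-range interaction coefficient is not a constant: I(α) =
6(ε₁+ε₂) − 2(1−1/N)ε₁ − ε₁α. With the shipped energies (ε₁ = −45,
ε₂ = 25, N = 6) this is exactly −45(1−α): a fully crosslinked gel is
energetically indifferent to swelling, an uncrosslinked one swells hard.
The network standard free energy contributes only through its α-dependent
part (α/2)ε₃ (ε₃ = −0.5, kept small and negative to stay away from
phase-separating regimes); its constant part, and ε₄ entirely, produce no
gradient and therefore no force.

The electric potential Ψ (thermal-voltage units) is closed by bulk
electroneutrality, not a Poisson equation: Debye layers are far below the
grid scale. In 1D with no-flux walls the neutrality constraint is
algebraic — at every cell face the total charge flux (Nernst–Planck
diffusion + drift of the three dissolved species, advection of dissolved
charge with uₛ, and advection of bound-plus-bare-site charge with uₙ) must
vanish; this fixes ∂ₓΨ per face uniquely (the flux is strictly monotone in
the gradient). Ψ is integrated from the right wall, where it is gauged to
zero; all observables are gauge-invariant.

## Initial conditions

A run emulates a secretion event in a closed container: the left fifth of
the domain (tanh transition of width w = 0.25 µm centred at x₀ = 5 µm)
holds network at θₙ = 0.5 equilibrated with its inner ion totals; the rest
is bath (θₙ floored at 1e−9) with prescribed Na and Ca totals and chloride
balancing the charge. The two compositions are each solved for
binding/unbinding equilibrium (a bracketed 1D root-find in M on
[0, z̃θₙ] — guaranteed convergence; the solution error in M is kept below
1e−10 relative), then blended. The blend is applied to the *conserved*
densities (θₙ, θₛcⱼ, bⱼ): net charge is linear in exactly those variables,
so the blended profile is pointwise electroneutral by construction. The
domain-averaged θₙ of this profile, ≈ 0.1, is the exact uniform state the
run relaxes toward.

What this emulates — and what it does not: real secreted mucus is granular,
3D, polydisperse, and pH-coupled (hydrogen binding is excluded here); the
initial profile is an idealised sharp interface, and the "bath" is finite,
so bath composition evolves during a run (deliberately: total sodium
supply is part of the mechanism under study). Passing tests demonstrate
internal consistency of the model, not fidelity to any particular tissue.

## Numerics

Staggered uniform grid: scalars at cell centres, velocities and fluxes at
faces; default 256 cells on L = 25 µm. Concentrations in molar, lengths in
µm, time in s (diffusivities 2.5e−5 cm²/s → 2.5e3 µm²/s).

Each step is a Lie split, in order:

1. **Mechanics.** Eliminating uₛ via θₙuₙ + θₛuₛ = 0 (exact with wall
   Dirichlet values) and the pressure via the θₛ·(network) − θₙ·(solvent)
   combination leaves one tridiagonal system for uₙ at interior faces;
   drag reduces to −ξθₙuₙ. Incompressibility and wall conditions hold to
   machine precision by construction. Pressure is recovered diagnostically
   by integrating the total momentum balance.
2. **Network and bound advection.** Conservative first-order upwind with
   uₙ (an optional minmod-MUSCL variant is available in the config;
   upwind is the default for positivity at the sharp front).
3. **Dissolved transport.** Backward-Euler per species: implicit upwind
   advection with uₛ plus implicit Scharfetter–Gummel (exponentially
   fitted) diffusion/drift at the face potential gradient solved from the
   electroneutral closure of the incoming state. The SG flux is an
   M-matrix discretisation at any cell Péclet number, so concentrations
   stay positive unconditionally. The closure error incurred by the
   implicit update is then removed by a corrective face flux distributed
   over species with weights ∝ zⱼDⱼcⱼ (z-weighted sum ≡ 1), which is
   simultaneously conservative per species and exactly charge-free: in
   practice pointwise neutrality holds at the 1e−13 relative level over
   full runs against a 1e−6 requirement.
4. **Reactions.** Per-cell backward Euler on the three bound pools, with
   dissolved values eliminated through the frozen elemental contents (so
   totals and charge are conserved identically). A vectorised damped
   Newton iteration with per-cell feasibility line search (b ≥ 0, M ≥ 0,
   dissolved contents ≥ 0) converges to 1e−12 relative; on failure the
   substep is re-run as 2, 4, … equal pieces.

Time step: dt = min(dt_max, CFL·h/max|u|) with CFL = 0.4 and dt_max = 1 ms;
a step that produces a negative concentration or a non-convergent solve is
rejected and retried at dt/2 (aborting below dt_min = 1 ns with
diagnostics). The fitted rate γ changes by under 2% between 64- and
256-cell grids and under 0.2% between dt_max = 1 ms and 0.5 ms, so the
default resolution is comfortably converged for the shipped experiments;
runs take seconds on one core.

Degenerate regimes: the bath's θₙ floor (1e−9) keeps the momentum operator
nonsingular without extra regularisation (drag is evaluated as ξθₙθₛ);
α is reported as 2b_C2/(z̃θₙ) clipped to [0,1], which in the bath evaluates
on round-off-scale numerator and denominator and is effectively 0; logs of
volume fractions are guarded but in practice never hit the guard because
upwind advection preserves positivity under the CFL bound.

## Mechanical parameters and calibration

ν_n, ν_s, ξ and the energy-density scale S multiplying all potential
gradients are not fixed by published measurements. The momentum system is
homogeneous in (ν_n, ν_s, ξ, S) — a common rescaling leaves velocities
unchanged (asserted in the tests) — so ξ = 1 merely chooses the force
unit, leaving two physical ratios. ν/ξ = 0.25 µm² sets a viscous
smoothing length of 0.5 µm, enough to resolve the swelling front on the
default grid. S/ξ sets the permeation speed; it was calibrated once, by
scanning S against the exemplar experiment (sparse binding, sodium
preferred, bath Na 0.02 M) so that the front-decay rate lands in the
observed γ ≈ 2.4 s⁻¹ range, and frozen at S = 12. All other results —
the sweep shapes, orderings, and crossovers — are predictions at that
fixed setting, not separately tuned.

## Analysis conventions

θₙ^max is the grid maximum (interpolation changes it by less than the grid
tolerance). The front L* is the rightmost linear-interpolated crossing of
θₙ = 0.01; if the profile never crosses, the front is reported absent
(NaN) and such samples are excluded from fits. The rate fit is ordinary
least squares on (t, ln ΔL⁻¹) restricted to t ∈ [0.2, 0.8] s — after the
start-up transient, before the front reaches the wall — requiring at
least three positive samples; metrics are sampled every 10 ms. The window
is configurable (an alternative convention extends it to 1.0 s; the text
default is used).

## Known limitations

- Purely viscous constitutive law: no elasticity or viscoelastic memory,
  so the model cannot express strain-history effects of crosslinking on
  rheology.
- No hydrogen ion, hence no pH coupling; no competitive binding beyond
  the two cations; binding sites and charges in strict 1:1 ratio.
- Bulk electroneutrality everywhere: no space-charge layers; ion activity
  corrections enter only through the printed σ_I terms.
- 1D closed container: no secretion sources, no open boundaries, no
  lateral structure.
- First-order splitting and upwind transport: fronts are mildly smeared;
  the shipped experiments are grid-converged at the metrics level but
  profile-level accuracy near the front is first order.
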