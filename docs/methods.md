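# Methods

## Model

A linear chain of N = 50 identical beads (diameter σ, mass m) is driven
through a membrane by a constant force that acts only inside a narrow
cylindrical pore. All quantities are in reduced Lennard-Jones units
(σ = ε₀ = m = 1, time unit t_LJ = √(mσ²/ε₀)); with the DNA-like mapping
σ = 1.5 nm, m = 936 amu, T = 295 K and k_BT = 1.2 ε₀ one gets
ε₀ ≈ 3.39·10⁻²¹ J and t_LJ ≈ 32.1 ps.

Interactions:

* **Excluded volume** between all bead pairs (bonded pairs included):
  WCA potential, i.e. the 12-6 LJ truncated at its minimum 2^{1/6}σ and
  shifted up by ε, purely repulsive.
* **Connectivity**: FENE bonds,
  U = −½ k R₀² ln(1 − r²/R₀²), k = 30 ε₀/σ², R₀ = 1.5σ. The combined
  FENE + WCA bond has its minimum at r ≈ 0.961σ.
* **Membrane**: two laterally infinite wall faces pierced by a cylindrical
  bore of length 6σ and radius R_p ∈ {1.5, 2, 2.5, 3}σ, all treated as
  continuous surfaces. A bead interacts through the Euclidean distance
  from its centre to the nearest surface point. Wall faces are WCA
  (repulsive); the bore surface carries a full LJ with cutoff 2.5σ whose
  well depth ε_pore ∈ [0.1, 8] ε₀ is the monomer–pore attraction under
  study. Outside the axial span of the bore the surface distance
  continues smoothly onto the aperture rim circle, so the force field is
  continuous around the pore mouth (no integrator kicks at the edge).
* **Driving**: F = f x̂ with f ∈ {1, 2} ε₀/σ, applied to beads whose
  centre lies inside the bore. Relative to the bounds
  k_BT/(σN^ν) ≈ 0.12 and k_BT/σ = 1.2 (ν = 0.588), f = 1 is a medium
  and f = 2 a strong force.

Two dialects of the pore LJ are provided. The default truncates and
shifts the potential to zero at 2.5σ (continuous energy); the `literal`
dialect keeps the +ε offset, which leaves a ≈0.984ε energy discontinuity
at the cutoff. The force is identical in both; only energy diagnostics
differ, by under 2% of the well depth.

## Dynamics

Each bead obeys the Langevin equation m r̈ = F_c − ξv + F_R with
ξ = 0.7 m/t_LJ. The random force is Gaussian white noise with
per-component variance 2ξk_BT/Δt — the fluctuation–dissipation closure
that fixes the long-run kinetic temperature at k_BT. The update is a
stochastic velocity-Verlet scheme (friction evaluated with the available
velocity in each half-kick, one noise draw per step used in both), which
reduces exactly to deterministic velocity Verlet when ξ = 0. Δt = 0.005
t_LJ by default; the integrator refuses Δt > 0.01 because the k = 30
bonds go unstable there. Verified limits: NVE energy drift < 10⁻⁴ ε₀
over 10⁵ steps for a weakly excited bonded pair; free-particle speed
decays as e^{−ξt/m} to 0.5%; chain kinetic temperature matches 1.2 ε₀ to
2%.

Randomness is organised as one `SeedSequence(seed, spawn_key=(stream,
attempt))` generator per translocation event, so any event is
reproducible bit-for-bit in isolation and ensembles are order-independent.

## Protocol

1. **Threading.** Bead 1 is placed at the trans exit plane on the pore
   axis, the rest of the chain back through the bore and out the cis side
   at the equilibrium bond length; the free cis tail gets a deterministic
   0.05σ lateral ripple so it is not collinear.
2. **Equilibration.** Beads initially inside the bore (plus bead 1) are
   pinned; the tail relaxes without the driving force until the range of
   its radius of gyration over a sliding window (200 samples taken every
   50 steps, both configurable) falls below 2σ. Velocities are then
   resampled from the Maxwell distribution at k_BT. In the runs reported
   by the tests, equilibration takes on the order of 10⁴–10⁵ steps.
3. **Translocation.** Pins released, force on. For each s = 1..N the
   event records the first time at which s beads have crossed the trans
   plane at least once (per-bead first passage; a bead that re-enters the
   pore never rewinds the counter), together with a configuration
   snapshot at that instant. The event completes at s = N. If the whole
   chain retreats past the cis plane the event is discarded and re-run on
   a fresh substream (discards are counted and logged); at f ≥ 1
   retraction is rare.

The count-of-ever-exited definition matters at strong attraction in wide
pores: there, 10–15 beads stay adsorbed on the bore surface with frequent
re-entries, so demanding that all N beads sit past the plane
*simultaneously* leads to essentially unbounded times, while the
first-passage count terminates and reproduces the reported ordinal
behaviour.

## Observables

* Mean exit time ⟨t(s)⟩ over completed events; waiting time
  w(s) = ⟨t(s+1)⟩ − ⟨t(s)⟩ (difference of averages, telescoping exactly).
* Crossing index of two per-s curves: smallest s where sign(a−b) differs
  from its sign at s = 1; exact ties count as crossings.
* X_COM: mean x-coordinate of all beads, averaged over the per-s
  snapshots.
* Aspect ratio α = Δx/(2√(y²_max + z²_max)) over trans-side beads, with
  lateral maxima measured from the pore axis.
* Shape factor δ = R_g/R_h over **all** beads, with R_h the Kirkwood
  estimate R_h⁻¹ = N⁻² Σ_{i≠j} 1/r_ij. The estimator is isolated behind
  one function so it can be swapped. The compact end of the δ scale is
  anchored by the closed form √(3/5) ≈ 0.77 (uniform ball R_g over its
  geometric radius); note the bead-level Kirkwood δ of a dense ball is
  √(3/5)·6/5 ≈ 0.93, i.e. the printed anchors are scale references, not
  predictions of this estimator. Long rods sit at the high end (δ ≈ 4 for
  the continuum limit; the bead estimator grows with rod length).

## Numerical choices and degenerate inputs

* Pair forces by direct O(N²) loop (N = 50; neighbour lists would not
  pay), compiled with numba; a whole chunk of steps runs per call with
  pre-drawn noise.
* Pair separations below 0.25σ or bead-surface distances below 0.25σ
  abort the step as overlaps (timestep too large); FENE bonds at r ≥ R₀
  abort as overstretch. Both report the bead indices involved.
* On the pore axis the distance field to the bore surface has a conical
  kink; the radial force direction is undefined there and is set to zero
  (measure-zero configuration).
* Points inside the solid wall (reachable only transiently on integrator
  failure) get the depth below the nearer face, so the repulsion pushes
  them back out rather than vanishing.
* Two beads can cross the trans plane within one timestep; they then
  share an exit time, so per-event exit times are non-decreasing rather
  than strictly increasing.
* w(1) includes a start-up transient: the chain is released from pinned
  rest, so the second monomer's exit reflects acceleration from zero
  velocity, not steady-state passage. Shape assessments of w(s) therefore
  ignore the first two monomers.

## What the reduced-scale tests do and do not show

The test suite runs 25 events per condition at f = 2 (the acceptance
script, 60), against the ≥1500 events per condition of a production
sweep (`configs/production.yaml`). At this scale only ordinal statements are
assessed: τ grows with ε_pore and shrinks with pore diameter; w(s) is
bell-shaped at ε = 1 and develops an ascending tail at ε = 8, R_p = 1.5σ;
the strong-attraction cumulative curve starts below the weak-attraction
one and ends above it. The crossing location itself is noisy at tens of
events and depends on the timestep and thermostat discretisation, so its
numerical value is reported but not asserted. The generator emulates the
study conditions exactly as configured (geometry, forces, temperatures,
protocol); it does not emulate hydrodynamic interactions, electrostatics,
solvent structure, or sequence heterogeneity — conclusions transfer to
real polymer translocation only at the coarse-grained, free-draining
level of the model.

## Known limitations

* No overdamped (Brownian) limit and no alternative thermostats.
* The membrane is the only obstacle; space is open (no periodic box),
  appropriate for N = 50 where the chain never strays far.
* Retraction statistics at f < 1 are out of scope (events are discarded,
  not analysed).
* Parallelism is per-event at the process level only (the kernels are
  single-threaded).
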