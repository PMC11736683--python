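# Methods

This note documents the models implemented in `permeant`, their
assumptions, the defaults and why they were chosen, and what the
synthetic generators do and do not emulate.

## Units and conventions

Internal units are Å, ps, kJ/mol and K everywhere; conversions happen only
at the reporting boundary (permeability in cm/s via 1 Å/ps = 10⁴ cm/s,
densities in kg/m³). k_B = 0.008314462618 kJ/mol/K, which equals the molar
gas constant R on this energy scale. The membrane normal is the z axis,
the bilayer midplane sits at z = 0; trajectories from MD output are
recentred per frame on the mean z of the phosphate particles
(`center_membrane`). Boxes are orthorhombic; triclinic cells are out of
scope. O₂ density bookkeeping uses the molecular mass m = 32 g/mol (the
coarse-grained bead that represents O₂ carries a nominal 36 g/mol, but
mass densities describe the molecule, not the bead); m is a parameter
wherever it enters.

## Transfer free energies (solvation module)

In the Henry (ideal-dilute) regime the gas→solvent solvation free energy
on the mole-fraction scale is ΔG = −RT·ln x. The solvent→water transfer
free energy is the difference of the two gas-phase legs,
ΔG_transfer = ΔG_hydration(G→W) − ΔG_solvation(G→S) = RT·ln(x_S/x_W),
**positive** when the permeant prefers the organic solvent — the
convention that makes hydrophobic permeants come out positive, recorded
in every output header. No activity corrections are applied: mole-fraction
solubilities of sparingly soluble gases are far inside the dilute regime.

## Free-energy profiles (fep module)

F(z) = −k_BT·ln hist(z), with hist the normalized permeant z-histogram.
Defaults and choices:

* **Bin width 0.5 Å** — fine enough to resolve headgroup barriers a few Å
  wide, coarse enough that bins in the water phase hold thousands of
  samples in a typical run.
* **No symmetrization across z = 0.** Averaging the leaflets would hide
  exactly the sampling asymmetry the block errors are meant to expose.
* **Empty bins are missing (NaN), never clamped** to a large value, so
  downstream invariants (shift, conservation) remain testable.
* **Zero of energy**: the profile is shifted so the mean of F over a
  user-given water region (an |z| interval) is zero. When a membrane
  geometry is available the natural choice is |z| > h/2 + 5 Å, i.e.
  clearly beyond the dividing surfaces; there is no universal default
  without one, so the region is a required argument.
* **Errors**: 10 contiguous blocks; the profile is recomputed per block
  (each with its own water shift) and the per-bin standard error over
  blocks is reported. Bins defined in fewer than two blocks get NaN.

ΔG_m, the water→membrane-center free-energy difference, is read from the
bin containing z = 0 on the shifted profile and reported in k_BT units,
positive when the permeant prefers the membrane interior.

## Counting-method permeability (permeability module)

Dividing surfaces sit at ±h/2 with h/2 = ⟨|z_phosphate|⟩ + 8 Å — the
offset places the surfaces beyond the whole headgroup region so the full
membrane slab is counted. Frames are labeled A (z < −h/2), M (|z| ≤ h/2),
B (z > h/2); a crossing is complete when the most recent water label is
followed by the opposite one. Re-entries that return to the same side do
not count. Frame-to-frame water→water jumps with |Δz| > L_z/2 are periodic
wraps through the contiguous water phase (the two water slabs of a
single-bilayer box join across the boundary), not crossings.

The equilibrium normalization is

    P = n_crossings / (2 · A · t_sim · c_w),

the factor 2 because both directions are counted; c_w is the mean permeant
number density in |z| > h/2, measured over the whole water region with no
interfacial exclusion (the simplest defensible choice; an exclusion margin
can be emulated by passing a larger h/2). The error bar is Poisson,
P/√n — the event count dominates the uncertainty at desk scale. For 1D
surrogate systems the lateral box is 1 Å × 1 Å by construction, so A = 1
enters numerator and c_w consistently and P stays well-defined.

The inhomogeneous solubility–diffusivity (ISD) relation
1/P = ∫_{−h/2}^{h/2} e^{F(z)/k_BT}/D(z) dz (adaptive quadrature,
relative tolerance 1e-8) is implemented as an independent closed form: on
surrogate systems where F and D are inputs, counting and ISD must agree,
and the suite verifies they do (flat profile exactly D/h; a 5 kJ/mol
barrier within the counting statistics).

## Diffusion (diffusion module)

MSD uses the multiple-time-origin average over all permeants, computed
with the FFT autocorrelation algorithm (O(N log N) per particle), and
D = slope/(2d) by ordinary least squares over a fit window.

Window policy: 1–50 ns when the run is long enough that this window is a
small fraction of the data (≥200 ns); otherwise 5%–25% of the total time.
The relative standard deviation of an MSD estimate at lag τ from a run of
length T scales like √(τ/T) per particle, so windows that are a large
fraction of the run produce 10–20% scatter in the fitted D — the ~8%
error bars typical of production MD estimates arise exactly this way. For
the surrogate generators, whose dynamics are exactly Brownian at all
lags, the recovery tests use a short-lag window (1–250 ps of a 100 ns
ensemble), where the estimator is unbiased and precise to <2%.

Finite-size correction: self-diffusion in a periodic box is suppressed by
hydrodynamic self-interaction; the leading-order correction for a cubic
lattice of images is ΔD = k_BT·ξ/(6πηL), ξ = 2.837297, added to the
fitted D. The solvent viscosity η is a **required input** — there is no
defensible default, and published corrected values cannot be re-derived
without it. The stick/slip boundary flag and hydrodynamic radius R are
recorded as metadata; they enter only an optional next-order
Hasimoto-type term (−k_BT·4πR²/(18πηL³), off by default), which for a
small solute in a large box is orders of magnitude below the leading
term.

## Cavity binding (binding module)

The cavity center is the unweighted center of geometry of the labeled
cavity-residue particles per frame (protein-centered frames assumed;
superposition is out of scope). Distances are minimum-image. A bead is
bound when distance ≤ 6 Å — the boundary case counts as bound. Maximal
bound runs become events; two events of the same bead and cavity
separated by ≤ 60 ps (at 20 ps frames) merge into one, and the gap frames
are **reclassified as bound**, which keeps t = Σ durations and t̄ = t/n
self-consistent. Increasing the merge gap therefore never increases n and
never decreases t̄ (a tested invariant).

Summary statistics per cavity: event count n, total bound time t, mean
residence time t̄ = t/n with standard error sd/√n, occupancy
100·t/(n_beads·n_replicas·production). The packaged benchmark conditions
are 2 beads × 29 replicas × 2000 ns; this denominator is what reproduces
the published occupancies from the published bound times.

Binding free energy: ΔF_bind = −k_BT·ln(ρ_cavity/ρ_water) with
ρ_cavity = (per-bead occupancy fraction)·m/(N_A·V_sphere(6 Å)) and
ρ_water the permeant mass density in the water phase (0.283 kg/m³ for the
packaged benchmark, where it reproduces the published ΔF values to better
than 0.1 kJ/mol — the small residual is consistent with that density
being printed to three decimals). A number-density variant (identical for
a single species) serves the synthetic recovery tests. Zero occupancy
yields +inf with a warning, never a silent number.

Density maps histogram the permeant on a box-covering voxel grid (1 Å
default) anchored at −box/2, so counts conserve frames × beads exactly;
output is OpenDX via `gridData`.

## Surrogate generators (synthetic module)

The generators produce the statistical structure the estimators assume —
nothing more:

* `simulate_permeation_1d`: overdamped Langevin (Euler–Maruyama, Itô)
  update z ← z + [−D F′/k_BT + D′]dt + √(2 D dt)·𝒩(0,1), periodic in z.
  The spurious-drift term D′ makes the stationary law Boltzmann in F for
  any positive D(z), which is what the counting-vs-ISD and
  profile-recovery oracles require. Initial positions are drawn from the
  stationary law by inverse-CDF on a fine grid, so histograms are
  equilibrium samples from frame 0. Profiles supplied as tables (or as
  callables without derivatives) go through a periodic cubic spline whose
  analytic derivative drives the dynamics. A stability check rejects dt
  whose maximal drift step exceeds box/4. Euler–Maruyama has O(dt)
  stationary-law bias: at D = 0.5 Å²/ps on kJ/mol-scale profiles, dt =
  0.5 ps leaves residuals comparable to the block errors of a ~10⁶-sample
  run, while dt = 0.2 ps pushes them well below; the profile-recovery
  fixtures use dt = 0.2 ps for this reason.
* `simulate_binding_3d`: Metropolis walk (isotropic Gaussian proposals,
  acceptance e^{−ΔU/k_BT}) in a periodic box with non-overlapping
  spherical square wells of depth ε. Metropolis handles the discontinuous
  well exactly, so the stationary in/out density ratio is e^{ε/k_BT} —
  exact occupancy statistics at the price of only qualitatively diffusive
  kinetics. Residence-time *distributions* from this generator are
  therefore not quantitative targets; occupancy ratios and ΔF recovery
  are. A nominal dt per step supports the time bookkeeping downstream.
* `simulate_free_3d`: independent Gaussian increments, wrapped and
  unwrapped coordinates stored.

All generators take a single seed and draw from one
`numpy.random.Generator`; identical specs give bitwise-identical
trajectories.

What the surrogates do **not** emulate: inter-particle forces, membrane
structure, protein flexibility, momentum (no inertial/ballistic regime),
or hydrodynamic coupling to a solvent. Passing recovery tests therefore
demonstrates the *estimators* are correct under their stated assumptions,
not that any particular force field is accurate.

## Problem sizes in the test suite

Fixtures are sized so statistical tolerances sit near three standard
errors of the estimate: flat-profile permeability uses 10 particles ×
640k steps (~10³ crossings, Poisson ≈ 3%), the barrier run 10 × 300k
(~240 crossings against a 15% band), profile recovery 8 × 750k samples at
dt = 0.2 ps, square-well binding 8 × 400k Metropolis steps (ΔF to
±0.05 kJ/mol against a 0.2 band), and free diffusion 10 × 100k steps.
Each runs once per session as a shared fixture; the whole suite completes
in a couple of minutes on one core.

## Known limitations

* The counting estimator needs dozens of crossings before its Poisson
  error is meaningful; it is the wrong tool for high barriers at desk
  scale (use the ISD integral on an estimated profile instead).
* Block errors assume blocks much longer than the slowest relaxation in
  the data; 10 blocks of a short run can understate errors.
* `water_phase_density` and the occupancy denominators assume a constant
  box; NPT volume fluctuations are averaged, not propagated.
* The tabular trajectory dialect stores one box for the whole run; pass
  MD trajectories through the standard-format readers instead.
* Role labeling is by selection at read time; there is no topology
  chemistry beyond the labels.
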