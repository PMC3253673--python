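# Methods

This note records the model as implemented, the numerical and design
choices that were genuinely open, and what the synthetic generators and
scaled-down tests do and do not demonstrate.

## Model

**Filaments.** `N` polar chains of `M` monomers. Monomer 0 is the
[−]-end, monomer `M−1` the [+]-end; this index convention is fixed here
(it is arbitrary) and used everywhere — polarity vectors, motor stepping,
end-detachment. Energies per filament:

* bonds: `½ k_bond Σ (|r_{i+1}−r_i| − b)²`, `k_bond = 100 kBT/b²`;
* bending: `(κ/b) Σ (1 − t̂_i·t̂_{i+1})` over unit bond vectors. This
  discretisation gives a 3D worm-like chain with `ℓ_p = κ/kBT` exactly in
  the stiff limit (per-joint `⟨cos φ⟩ = coth(κ/b·β) − b/κβ ≈ 1 − b/ℓ_p`),
  which is why it was chosen over the angle-squared variant;
* excluded volume: WCA (truncated-shifted repulsive LJ), `ε = 5 kBT`,
  `σ = b`, cutoff `2^{1/6}σ`, between all monomer pairs except directly
  bonded neighbours (next-nearest intra-chain pairs do interact; at
  `ℓ_p = 200 b` they never come within range, so the choice is
  inconsequential but is stated for completeness).

**Motors.** Only doubly-bound motors are represented; the free-motor pool
is implicit and uniform, so the attachment rate `k_A` is the product of a
molecular rate and the free concentration and applies **per eligible
monomer pair per sweep** (pairs on different filaments within the capture
radius `2^{1/6}σ`). Both heads bind simultaneously to the two monomers of
the pair; several motors may share a monomer (no head–head exclusion —
unstated in the source problem, simplest consistent choice). Per kinetics
sweep of interval `Δt_k`:

* attachment with probability `1 − exp(−k_A Δt_k)` per eligible pair;
* stepping of each head (not at a [+]-end) one monomer towards the
  [+]-end with probability `min(1, k_M Δt_k e^{−ΔE/kBT})`, `ΔE` the trial
  spring-energy change. The probability is clipped at 1 and downhill
  moves are *not* accelerated beyond `k_M Δt_k`; for `k_M Δt_k ≪ 1` the
  clip is never active. Within one motor the two heads are processed in
  random order (heads of different motors are independent at frozen
  monomer positions, so the two-pass vectorised sweep is equivalent to
  any global interleaving);
* detachment of each head with probability `1 − exp(−k Δt_k)`, where
  `k = k_E` if that head sits at a [+]-end and `k = k_D` otherwise
  (`k_E` *replaces* `k_D` at ends; `k_E` defaults to `k_D`). Either head
  detaching removes the whole motor.

**Confinement.** Flat repulsive plates at `z = 0` and `z = Z = 5b` and a
side wall, both repelling monomers with the same WCA form (plate:
distance to the plane; side wall: 2D distance to the nearest point of the
wall polygon). The elastic wall is a closed polygon of `n_wall = 80`
nodes with reference spacing `ℓ_0` and reference discrete curvature
`κ_0 = 2π/(n_wall ℓ_0)`:

* stretch: `c_stretch · kBT · Z · δℓ²/ℓ_0³` per adjacent pair,
  `c_stretch = ½` (the coefficient is exposed in the configuration);
* bend: `c_bend · kBT · ℓ_0 · Z · δκ²` per node triplet,
  `c_bend = 10³`, with discrete curvature = (signed turning angle)/`ℓ_0`.
  This convention is exactly zero for straight segments and makes a
  uniform dilation cost stretch only (turning angles are
  scale-invariant).

Wall nodes carry no Brownian dynamics; they evolve by Metropolis MC (each
node once per sweep in random order, trial displacement uniform in
`[−δ_w, δ_w]²`, `δ_w = 0.1b`) against the wall elastic energy, the
wall–monomer repulsion and `P·V`, `V` = shoelace polygon area × `Z`. In
**fixed-volume mode** the wall is an analytic rigid circle following an
imposed radius schedule (piecewise-constant lookup) and no wall moves are
attempted.

**Dynamics.** Overdamped Euler–Maruyama step
`r ← r + M F dt + ξ`, with the per-monomer slender-body mobility
`M = t̂t̂/γ + (I − t̂t̂)/2γ` (tangent = normalised mean of adjacent bond
directions; degenerate tangents fall back to isotropic `1/2γ`) and
Gaussian noise of covariance `2 kBT M dt`. The 2:1 drag anisotropy is
verified in the tests via the centre-of-mass diffusion of free straight
filaments.

## Parameters and scheduling

Reduced units: `b` (length), `kBT` (energy), `γb²/kBT` (time);
`τ_b = Lbγ/4kBT = M/4` time units, `P_0 = ε/b³`, `ℓ_p = κ/kBT`.

The source problem leaves `dt`, the MC step size and the update
interleaving unspecified; here they are configuration-exposed with
defaults

* `dt = 5×10⁻⁴ γb²/kBT` — an order of magnitude below the stiffest-spring
  relaxation time `γ/2k_bond = 5×10⁻³`, the standard margin for an
  overdamped Euler integrator. The residual integrator bias is visible as
  a few-percent softening of the measured persistence length (the
  acceptance test recovers `ℓ_p ≈ 187 b` against the target `200 b ± 10%`);
* `kinetics_interval = wall_interval = 10` BD steps, so per-sweep event
  probabilities `k·Δt_k` stay `≪ 1` across the interesting rate ranges;
* `δ_w = 0.1b`, giving wall-MC acceptance near 50% at the default wall
  stiffnesses;
* neighbour list: k-d-tree pair list with a `0.5b` Verlet skin, rebuilt
  every kinetics sweep and shared by excluded volume and motor
  attachment. Per-step monomer RMS displacement is ≈ 0.04b, so the skin
  comfortably covers ten steps of drift.

Four independent RNG streams (initial condition, BD noise, motor
kinetics, wall MC) are spawned from one seed, so changing one subsystem's
draws cannot perturb the others.

**Initial condition.** A radial aster: straight filaments spanning radii
`[R_0 − L − 2b, R_0 − 2b]`, [+]-ends inward, distributed as evenly as
possible over three layers at `z = b, Z/2, Z − b`, azimuthal positions
regular within a layer plus a seeded jitter; the wall starts as a regular
`n_wall`-gon of radius `R_0 = 40b`, the motor roster empty. (The stated
"66–68 filaments per layer" of the source description is arithmetically
inconsistent with `N = 175` over 3 layers; the even split {59, 58, 58} is
used.)

## Numerical guards

* **Deep-overlap linearisation.** Below `0.9σ` the WCA potential is
  continued linearly (constant repulsive force equal to its value at
  `0.9σ`, energy continued C¹). Configurations that deep are suppressed
  by > 15 kBT, so equilibrium properties are untouched, but the cap is
  what keeps the integrator stable when the fixed-volume radius step
  suddenly strands monomers outside the rigid wall — the known
  instability of that protocol. Forces remain exact negative gradients of
  the (linearised) energy, which is what the finite-difference suite
  checks.
* **Wall-MC locality.** A node move re-evaluates the wall elastic energy
  of the two touched edges and three touched turning angles in closed
  form, the PV change from the local shoelace terms, and the wall–monomer
  energy over monomers within `ℓ_0 + cutoff + δ_w + 0.5b` of the node
  against the 12 segments around it. This is exact while the wall is
  locally star-shaped (remote segments further than the cutoff from the
  candidates), which holds for the stiff, near-circular walls the elastic
  constants enforce.
* **Contraction fit.** `curve_fit` from the stated initial guesses
  (min, half-range, steepest-descent time, span/10); a run is declared
  non-contracting — `t_cont` assigned the configured maximum time — when
  the fitted `|ΔR|` is below twice the residual SD, `t_cont` falls
  outside the observed span, or the fit fails.
* **Angle unwrapping** for the MSAD is per-filament cumulative with
  frame-to-frame increments in `(−π, π]`.

## Order-parameter estimation

`p̂(θ)` is estimated on `n_bins` equal angular bins about the wall-node
centroid as the plain mean polarity of the filaments in each bin — *not*
renormalised to unit length (a bin with opposing filaments contributes a
short vector, which is what the mode decomposition of the mean
orientation field requires) — with empty bins contributing zero, and the
coefficient integrals evaluated as Riemann sums over bin centres.
`n_bins = 40` suits `N = 175` (~4 filaments per bin); the simulation
recorder scales the default as `min(40, max(8, N/4))` because at small
`N` empty bins systematically depress every `Q_m`. The binned estimator
is exactly rotation-invariant for rotations by whole bins and invariant
to ~10⁻⁶ for arbitrary rotations of smooth full-circle fields; fields
with sharp support edges (semi-aster, spindle) shift by O(bin width) when
the support boundary straddles a bin, which is inherent to binning.

**Classification targets.** Two sets of ideal-state `(Q_0..Q_3)` vectors
ship:

| state | printed | derived (quadrature) |
|---|---|---|
| aster | (0, 1, 0, 0) | same |
| nematic | (0, 0, 0, 0) | same |
| spindle | (0, 2/π²+½, 0, 2/π²) | (0, ¼+1/π², 0, 1/π²) |
| semi-aster | (9/π², 9/4π², 333/**1715**π², 9/100π²) | (9/π², 9/4π², 333/**1225**π², 9/100π²) |

Direct quadrature of the stated ideal fields reproduces the aster,
nematic, and the semi-aster `Q_0, Q_1, Q_3` exactly, but gives **half**
the printed spindle `Q_1, Q_3` and a different semi-aster `Q_2`
denominator. The tests assert the quadrature values; classification
defaults to the printed set (which reproduces the published state-diagram
boundaries) with `source="derived"` available. The discrepancy is not
cosmetic: an ideal spindle field measured through the pipeline sits
almost exactly midway between the printed spindle tuple and the nematic
and classifies as nematic under the printed set, and correctly as spindle
under the derived one.

Ties in the nearest-target comparison break deterministically in the
order spindle, aster, nematic, semi-aster.

**Velocity scale.** Transverse velocities are reported in units of
`v = b/τ_b` (the characteristic velocity is otherwise left undefined);
finite differences are centred with the frame interval as the span,
one-sided at the series ends.

## Synthetic generators

The `fixtures` module emulates exactly the kinematic and statistical
signatures the analysis measures, so every estimator is testable without
the simulator:

* `gen_ideal_field` — points uniform over the field's angular support
  with the ideal polarity plus optional Gaussian angular noise. The
  nematic is realised as antiparallel pairs (each filament keeps unit
  polarity; the bin mean vanishes), matching how a physical nematic
  yields `p̂ = 0`.
* `gen_rotating_ring` — rigid rotation `ω` plus angular diffusion
  `D_θ`: the MSAD crossover (slope 1 → 2) and the transverse-velocity
  magnitude `ωr` in closed form.
* `gen_tanh_radius`, `gen_lifetime_sample` — the contraction-fit and
  goodness-of-fit inputs with known ground truth.

What these do **not** emulate: mechanics (bond lengths, excluded volume,
motor forces), density inhomogeneity, or the coupling of rotation to
contraction. Passing fixture-based tests therefore validates the
*estimators*, not the emergent physics; the scaled-down simulations below
are the (direction-only) check on the latter.

## Statistical tests

The Anderson–Darling statistic `A²` is computed against an exponential
with estimated mean or a normal with estimated mean and variance
(ddof = 1; the normal case is cross-checked against the independent
scipy implementation). Because parameters are estimated, p-values come
from a seeded parametric bootstrap (default 10⁴ resamples, parameters
re-estimated per resample); the calibration test confirms approximately
uniform p-values under the exponential null. Rotation-direction
symmetry uses the exact two-sided binomial test. Switching times are
intervals between sign changes of a boxcar-smoothed transverse-velocity
series; the smoothing window is exposed because the appropriate choice
depends on the frame rate.

## Scaled-down study conditions

Full state diagrams, vortex lifetime distributions (mean contraction time
≈ 1.7×10⁴ τ_b) and end-detachment sweeps require ~10⁴ τ_b runs with
`N = 175`, `M = 30` in replicate — cluster-scale. The package's
simulation checks instead use `N = 40`, `M = 10`, `R_0 = 16b`,
`P/P_0 = 0.03`, runs of 16–20 τ_b, with rates chosen so the motor
subsystem acts many times within the run (`k_D = 1`: motor lifetime one
time unit; `k_M = 10`: a head traverses a filament ~50 times per run;
`k_A/k_D = 20`: several motors per filament). Under these conditions the
assertions are direction-only, as befits the scale: late-run `Q_1` is
higher with motors than without (motor springs at [+]-ends hold the
initial aster together while the passive system decays by rotational
diffusion), and the [+]-end motor fraction on a frozen filament ladder
rises monotonically with `k_M/k_D`. Shorter filaments are known to lose
the vortex state entirely, so no vortex-formation assertion is made at
this scale.

## Known limitations

* No hydrodynamic coupling between filaments beyond the local anisotropic
  drag; no inertia; no filament growth, treadmilling or polydispersity.
* The Euler–Maruyama integrator softens stiff-mode fluctuations by
  O(dt/τ_mode); at the default `dt` this biases the measured `ℓ_p` by
  ≈ −6%. Halving `dt` halves the bias at twice the cost.
* The wall-MC locality window assumes a near-circular wall; strongly
  crumpled walls (soft `c_bend` together with monomers wedged between
  opposite wall sections closer than ~2ℓ_0) would need the full-polygon
  distance in the move energy.
* `V = |μ|/σ` is reported as `+inf` (with a flag) for a constant non-zero
  series; multi-run averaging should exclude such degenerate runs.
* In fixed-volume mode the monomer–wall interaction uses the analytic
  circle, so wall fluctuations are absent by construction; comparisons
  between the two ensembles should remember the fixed-volume wall is
  noiseless.
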