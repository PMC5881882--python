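# Methods

This note documents the models, conventions, defaults and limitations of
`alchemcycle`.  Energies are in kJ·mol⁻¹, lengths in nm, times in ps
throughout; λ = 0 is the pure A state and λ = 1 the pure B state.

## Thermodynamic integration

A run's free-energy change is ΔG = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ, evaluated by the
composite trapezoid rule over the run's λ schedule.  The trapezoid rule
(rather than Simpson or splines) is deliberate: refined schedules are
non-equidistant, and the piecewise-linear quadrature makes no smoothness
assumption beyond what the data support.  For equidistant spacing h the
discretization error is bounded by h²/12·max|g″|; the λ-refinement helper
flags interior points whose second divided difference exceeds a threshold
(default 100 kJ·mol⁻¹ per unit λ²) and proposes the midpoints of both
adjacent intervals, mirroring the practice of interspersing λ-points where
the mutation curve bends.

**Ensemble means.** Each λ-point's mean discards an initial equilibration
window (default 50 ps) and averages the remaining samples.  Sample times
are `first_time + i·interval`, so a discard equal to k intervals drops
exactly the first k samples.

**Uncertainties.** Per-λ standard errors come from block averaging: the
variance of block means is evaluated at geometrically growing block sizes
(down to ≥4 blocks), and the estimate at the plateau — the first size whose
value changes by <5% over two consecutive doublings — is taken, falling
back to the maximum observed estimate when no plateau is reached.  The
result is floored at the naive σ/√n, and requires ≥64 retained samples.
For an AR(1) process with coefficient φ the true error of the mean is
σ/√n·√((1+φ)/(1−φ)); the block estimator reproduces this within ~25% in
the test suite.  ΔG uncertainties propagate per-λ errors through the
trapezoid weights assuming independence between λ-points, which holds
because each λ-point is a separate simulation.

**Decomposition.** When ∂H/∂λ files carry per-interaction-group columns
(e.g. peptide–peptide / peptide–protein / peptide–solvent), the loader
enforces that groups partition the total within 1e-6 kJ·mol⁻¹ per sample;
quadrature is linear, so group ΔG values sum to the total exactly.
Convergence profiles re-integrate using only samples in (discard, t] for a
grid of times t, exposing slow drifts and their group attribution.

## Cycles, hysteresis and ΔΔG_bind

Every run-level ΔG is stored along the run's *executed* direction; nothing
downstream needs to guess signs.  Orientation onto a canonical direction
(lexicographic `state_from < state_to`) happens in the cycle engine:
reversed runs are negated (uncertainty preserved).  Hysteresis is the
absolute difference between a forward estimate and its sign-inverted
backward companion.  Replicate averages use the arithmetic mean with the
standard error of the mean for n ≥ 2 (a single estimate keeps its own
uncertainty); ΔΔG_bind = bound − solvent with root-sum-square uncertainty.
Cycle closure sums oriented edges along a closed path; the default
tolerance of 2.5 kJ·mol⁻¹ (≈ RT at 298 K, "thermal noise") is
configurable.  Closure is invariant under cyclic rotation of the path and
negates under reversal; the total closure is the bound closure minus the
solvent closure.

The bundled KXK/OppA worked example stores published per-run values.  One
bound-state entry (the second forward run of the S↔G transformation) is
printed with a sign inconsistent with the convention satisfied by every
other row; the fixture carries it with a `sign_corrected` flag and the
loader interprets its printed value as already oriented along the
canonical G→S direction.  The reported "average" uncertainties in the
source table cannot be reproduced by any single simple rule we tested;
this package reports the SEM of the oriented estimates and makes no claim
of matching the published ± values.

## Structural diagnostics

**Superposition** is a rigid-body least-squares (Kabsch) fit on a role-tag
selection (default backbone), with reflections excluded via the
determinant correction; it requires ≥3 non-collinear atoms.

**Dihedrals** use the standard signed-torsion convention (range
(−180°, 180°], cis = 0, trans = 180°); the implementation agrees with
mdtraj's `compute_dihedrals` to 1e-4°.  Note that the signed torsion is
*invariant* under full reversal of the atom order — gauche⁺ is gauche⁺
viewed from either end of the bond.  Histograms cover (−180°, 180°] with
right-inclusive bins and are normalized so the maximum bin equals 1, the
convention used for overlaying forward/backward distributions; a
two-sample chi-square (with small-count pooling) tests their agreement.

**Water-occupancy grids** assign each water oxygen inside an axis-aligned
region to its nearest grid node (default spacing 0.2 nm) per frame; exact
half-spacing ties go to the lexicographically smaller node index, and the
minimum-image convention is applied towards the region center when box
dimensions are known.  Node values are mean counts per frame (not binary
presence), so the sum over nodes equals the mean in-region water count
exactly, and the 30/50/90% classification operates on the node value
relative to the grid maximum (the maximum standing in for bulk-like
occupancy; absolute bulk densities are not defined for a toy region).

**Cavity water counts** report the per-frame in-region water count and its
integrated autocorrelation time (sum of the autocorrelation function from
lag 0 up to the first non-positive lag, times the frame interval).  White
noise gives ≈1 frame; a two-state exchange process with flip rate k per
frame gives ≈1/(2k) frames.  A constant series has undefined relaxation
time and is flagged as such.

## Toy alchemical simulator

The toy Hamiltonian couples end states linearly, H(λ) = (1−λ)H_A(λ) +
λH_B(λ), with softcore-regularized nonbonded end-state terms: the A terms
are softened proportionally to λ² and the B terms to (1−λ)², so softening
vanishes identically at both end states and end-state energies are
independent of the softness parameters.  The functional form is a
Beutler-style additive shift — r⁶ → r⁶ + α_vdw·λ_off²·(C12/C6) for
Lennard-Jones (the C12/C6 ratio taken per end state and per pair under
geometric combination; dummy particles use 0) and r² → r² + α_crf·λ_off²
(α_crf in nm²) for the Coulomb + reaction-field term

    V(r) = f·qᵢqⱼ·[ (r²+a)^−½ − C_rf(r²+a)/(2R_c³) − (1−C_rf/2)/R_c ],

with C_rf = 2(ε_rf−1)/(2ε_rf+1) (default ε_rf = 61, cutoff 1.4 nm, zero at
the cutoff).  This is a modeling choice for a desk-scale system, not a
reproduction of any production force field's softcore.  dE/dλ is analytic
and verified against central differences to 1e-4.

Sampling is Metropolis single-particle-translation Monte Carlo at constant
volume and temperature (default 298 K) in a rectangular periodic box with
minimum-image convention and a single cutoff; momenta cancel from λ-coupled
configurational averages for λ-independent masses, so no dynamics are
needed.  A recorded sample is assigned a nominal 0.5 ps so toy series flow
through the same TI analysis as file-based data; protocol runs discard
per-λ equilibration internally, so toy analyses use `discard=0`.  Forward
protocols visit λ ascending from the given configuration; backward
protocols visit λ descending starting from the forward run's final
configuration, and their TransformationRun is expressed in the executed
frame (λ′ = 1−λ, samples negated) so that integration yields ΔG(B→A)
directly.

**Oracles.** Three exact references validate the sampler end to end: the
harmonic mutation ΔG = (dims·RT/2)·ln(k_B/k_A); the partition sum of
discretized 1-D energy tables, −RT·ln(Σe^(−E_B/RT)/Σe^(−E_A/RT)), against
TI over a dense λ grid of exact Boltzmann-weighted means; and the confined
pair (below) by radial quadrature.

**Softness experiment.** The α-dependence of convergence is probed on a
deletion toy chosen deliberately hard: two particles with a deep pair well
(ε = 10 kJ·mol⁻¹ ≈ 4RT at 298 K, σ = 0.38 nm), both tethered identically
in A and B to a common anchor (k = 50 kJ·mol⁻¹·nm⁻²), with one particle's
interactions switched off in state B.  Because the tethers are
state-independent they cancel from ΔG, and center-of-mass/relative
separation decouple, giving an exact 1-D radial partition-sum oracle.
At this well depth the exact per-λ statistics show the TI curve's total
variation and the peak ∂H/∂λ standard deviation both roughly twice as
large for α = 0.5 as for α = 1.0 — the softer core smooths the mutation
curve while leaving the integrated ΔG unchanged.  Consequently, at fixed
short sampling (11 λ × 800 production steps, 10 seeds) the median
forward/backward hysteresis is systematically smaller at α = 1.0, while
longer runs on a denser schedule (21 λ × 3000 steps; the trapezoid
discretization bias is itself α-dependent, so the convergence comparison
needs the finer grid) agree between the two α values and with the exact
oracle within combined standard errors.  With a shallow, methane-like well
(ε ≈ 1.2 kJ·mol⁻¹) the α effect is buried in sampling noise — softness
only matters where cores genuinely clash.

## Synthetic ∂H/∂λ generator

`DhdlModel` produces x_t = g(λ) + s·b·e^(−t/τ_slow) + η_t: a polynomial
mean profile g with closed-form integral (the planted ΔG), an AR(1) noise
process η of stationary variance σ² (φ default 0.95 at 0.5 ps sampling —
the minimal autocorrelated model that justifies block averaging), and an
exponentially decaying transient of amplitude b and time constant τ_slow
whose sign is the same in each run's executed frame, so forward and
oriented-backward estimates are biased in *opposite* directions — the
minimal model of a water network lagging behind the alchemical change.
Mean bias over a production window (discard, T] is b·τ/(T−discard)·
(e^(−discard/τ) − e^(−T/τ)), so hysteresis ≈ twice that and shrinks
roughly as 1/T: the packaged prolongation experiment (b = 10, τ = 100 ps,
200 ps vs 2000 ps per λ-point) shows median hysteresis falling from ≈6 to
≈0.6 kJ·mol⁻¹ while replicate-averaged cycle closure stays within
tolerance (the bias is antisymmetric and cancels in forward/backward
averages).

Cycle datasets mirror the replication scheme of the study design — three
transformation pairs, two runs (1 forward + 1 backward) per pair in
solvent and four (2 + 2) in the bound environment, 11 equidistant λ — and
are written through the public TSV/manifest formats with a ground-truth
JSON alongside.  Edge truths must sum to zero around each environment's
cycle by construction.

Water scenes plant hotspot sites with two-state Markov presence dynamics
(stationary probability p, flip rates 2k·p and 2k(1−p), so the presence
autocorrelation integrates to ≈1/(2k) frames) plus diffusing bulk waters
and three static anchor atoms for superposition; absent waters are parked
in a reserved box corner outside any analysis region.  Dihedral fixtures
draw i.i.d. samples from von Mises mixtures — low concentration mimics a
glycine-like flat profile, high concentration the sharp peaks of a
side-chain-bearing residue.

### What the generators do and do not emulate

The generators reproduce the *statistical structure* the analysis relies
on: autocorrelated stationary noise, direction-dependent transients,
replicate scheme, file dialects, planted spatial hotspots with slow
exchange.  They do not emulate real force-field energetics, coupled
protein–water dynamics, pressure coupling, or correlations between
λ-points.  A passing suite therefore demonstrates that the estimators and
diagnostics are correct and calibrated under their stated assumptions —
not that any particular MD setup is converged.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp: 11–21 λ-points, 400–4000 MC steps or 200–2000
ps of synthetic sampling per λ-point, 10–20 seeds per stochastic claim,
8000–20000 frames for occupancy/relaxation estimates.  Stochastic
assertions use 3σ bounds (or 5σ for per-bin histogram checks) with
generator-derived σ, and all random streams are seed-derived.

## Known limitations

* TI with trapezoid quadrature only: no free-energy perturbation,
  Bennett/multistate reweighting, or spline integration.
* The block-error plateau heuristic can underestimate errors for
  relaxation times approaching the run length (the usual failure mode of
  block averaging); the floor at σ/√n bounds the damage from below only.
* The toy sampler is serial Metropolis MC with single-particle moves — fine
  for ≤ tens of particles, not a substitute for molecular dynamics.
* Rectangular boxes and a single cutoff only; no twin-range pairlist,
  thermostats, barostats or constraints.
* The occupancy grid's "bulk" reference is the observed grid maximum, so
  classifications are relative, not absolute densities.
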