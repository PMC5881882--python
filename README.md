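# alchemcycle

Thermodynamic-integration (TI) analysis for alchemical free-energy
calculations, built around the classic problem of **relative binding free
energies in a water-filled binding site**: the periplasmic
oligopeptide-binding protein A (OppA) binds lysine–X–lysine (KXK)
tripeptides whose side chains are solvated by conserved active-site waters,
so chemically similar ligands (X = glycine, alanine, serine) bind with
strikingly different affinities.  Estimating those differences by mutating
one ligand into another *in situ* stresses every convergence diagnostic an
alchemical workflow has — forward/backward hysteresis, thermodynamic-cycle
closure, free-energy decomposition, and direct inspection of the lagging
water network.

`alchemcycle` implements that workflow as a reusable library plus CLI:

* **TI engine** — per-λ ensemble means with equilibration discard,
  block-averaging standard errors for autocorrelated series, trapezoidal
  quadrature over arbitrary λ schedules with error propagation, λ-schedule
  refinement at high-curvature regions, convergence profiles as a function
  of simulation time, and per-interaction-group free-energy decomposition.
* **Cycle engine** — orientation of forward/backward runs onto canonical
  directions, hysteresis, replicate averaging, ΔΔG_bind, and cycle-closure
  tests against a thermal-noise tolerance.
* **Structural diagnostics** — Kabsch backbone superposition, signed
  dihedral angles (IUPAC convention, cross-checked against mdtraj),
  max-normalized angle histograms, water-occupancy grids with nearest-node
  assignment, relative-occupancy classification, and cavity water counts
  with integrated-autocorrelation relaxation times.
* **Toy alchemical simulator** — a λ-coupled softcore (Lennard-Jones +
  reaction-field) Metropolis Monte Carlo sampler that produces genuine
  ∂H/∂λ data with known limits, including exactly solvable harmonic and
  confined-pair systems.
* **Synthetic-data generators** — ∂H/∂λ series with AR(1) noise and a
  direction-dependent slow-relaxation bias, full thermodynamic-cycle
  datasets with planted ΔΔG, von Mises dihedral mixtures, and water scenes
  with planted hotspots.

## The central quantities

An alchemical mutation A→B is driven by a coupling parameter λ with
H(λ) = (1−λ)·H_A(λ) + λ·H_B(λ), and its free-energy change is obtained by
thermodynamic integration

    ΔG_mutate(A→B) = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ ,

sampled at discrete λ-points and integrated with the trapezoid rule.  The
relative binding free energy of two ligands follows from a thermodynamic
cycle:

    ΔΔG_bind(A→B) = ΔG_mutate,bound(A→B) − ΔG_mutate,solv(A→B) .

Because free energy is a state function, the sum around the closed cycle
A→G→S→A must vanish; deviations beyond thermal noise (≈ 2.5 kJ·mol⁻¹ ≈ RT
at 298 K) flag insufficient sampling, as does the hysteresis between a
forward run and its sign-inverted backward companion.

## Worked example

The package bundles the per-run TI results for the KGK/KAK/KSK–OppA series
(states labelled by the central residue: A = KAK, G = KGK, S = KSK; values
in kJ·mol⁻¹, stored along each run's executed direction):

```python
from alchemcycle import load_reference_runs, summary_table

summary = summary_table(load_reference_runs())
for pair, info in sorted(summary["pairs"].items()):
    solv, bound, ddg = info["average"]["solvent"], info["average"]["bound"], info["ddg"]
    print(f"{pair[0]}->{pair[1]}: dG_solv = {solv.value:+7.2f} ± {solv.uncertainty:.2f}   "
          f"dG_bound = {bound.value:+7.2f} ± {bound.uncertainty:.2f}   "
          f"ddG_bind = {ddg.value:+7.2f} ± {ddg.uncertainty:.2f}")
rep = summary["cycle"]
for env, (v, u) in sorted(rep.closures.items()):
    print(f"cycle closure [{env}]: {v:+.2f} ± {u:.2f} (tolerance {rep.tolerance})")
```

prints

```
A->G: dG_solv =   -4.05 ± 0.15   dG_bound =   +4.47 ± 1.11   ddG_bind =   +8.52 ± 1.12
A->S: dG_solv =  -26.25 ± 0.05   dG_bound =  -32.50 ± 0.83   ddG_bind =   -6.25 ± 0.83
G->S: dG_solv =  -22.45 ± 0.05   dG_bound =  -34.62 ± 1.25   ddG_bind =  -12.18 ± 1.25
cycle closure [bound]: +2.35 ± 1.86 (tolerance 2.5)
cycle closure [solvent]: -0.25 ± 0.17 (tolerance 2.5)
```

Reading: mutating alanine to glycine costs 8.5 kJ·mol⁻¹ of binding free
energy (KGK binds ~8.5 kJ·mol⁻¹ more weakly than KAK), serine binds
strongest, and both per-environment cycles close within the 2.5 kJ·mol⁻¹
thermal-noise tolerance — the internal-consistency criterion for converged
alchemical estimates.

The same pipeline runs from the shell:

```sh
alchemcycle synth --out ds --seed 1 --duration 500     # ground-truthed synthetic cycle
alchemcycle cycle --manifest ds/manifest.yaml --out results/
alchemcycle simulate --system sys.yaml --out sim/      # toy softcore MC protocol
alchemcycle analyze-traj --traj scene.pdb --region 0.5,0.5,0.5,1.5,1.5,1.5 --out traj/
```

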