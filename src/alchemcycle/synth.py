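"""Ground-truthed synthetic data: ∂H/∂λ series, full thermodynamic-cycle
datasets, dihedral samples and water-scene trajectories.

The ∂H/∂λ generator emulates the statistical structure the analysis
assumes about simulation output: a smooth mean profile g(λ) with a known
analytic integral, AR(1) autocorrelated stationary noise (the reason block
averaging is needed), and an optional slow-relaxation bias
s·b(λ)·e^(−t/τ_slow) whose sign flips between forward and backward runs —
the minimal model of a solvent network that lags behind the alchemical
change and produces direction-dependent hysteresis that shrinks as
sampling is prolonged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    DataValidationError,
    DhdlSeries,
    Trajectory,
    TransformationRun,
    UsageError,
    write_dhdl_file,
    write_run_manifest,
)
from .structure import DihedralSeries

logger = logging.getLogger("alchemcycle")

#: default AR(1) coefficient at 0.5 ps sampling (mimics slowly decorrelating
#: nonbonded energy derivatives stored every 0.5 ps)
DEFAULT_PHI = 0.95
#: default sampling interval (ps)
DEFAULT_INTERVAL = 0.5
#: default λ schedule: 11 equidistant points
DEFAULT_LAMBDAS = np.linspace(0.0, 1.0, 11)


@dataclass
class DhdlModel:
    """Generator model for one transformation's ∂H/∂λ data.

    ``mean_coeffs`` are polynomial coefficients of g(λ) in ascending powers;
    the exact TI ground truth is G* = Σ cᵢ/(i+1).  ``bias_amplitude`` b and
    ``tau_slow`` (ps) parameterize the slow-relaxation transient; the
    direction sign is supplied at generation time.
    """

    mean_coeffs: tuple[float, ...]
    sigma: float = 1.0
    phi: float = DEFAULT_PHI
    bias_amplitude: float = 0.0
    tau_slow: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.phi < 1.0:
            raise DataValidationError("AR(1) coefficient must satisfy |φ| < 1")
        if self.sigma < 0:
            raise DataValidationError("σ must be ≥ 0")
        if self.tau_slow <= 0:
            raise DataValidationError("τ_slow must be positive")

    def mean(self, lam: float) -> float:
        return float(np.polynomial.polynomial.polyval(lam, self.mean_coeffs))

    @property
    def ground_truth(self) -> float:
        """Analytic ∫₀¹ g(λ) dλ (kJ·mol⁻¹)."""
        return float(sum(c / (i + 1) for i, c in enumerate(self.mean_coeffs)))

    @property
    def stationary_sem_factor(self) -> float:
        """√((1+φ)/(1−φ)): inflation of the naive SEM under AR(1) noise."""
        return float(np.sqrt((1 + self.phi) / (1 - self.phi)))


def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    innovations = np.empty(n)
    innovations[0] = rng.normal(0.0, sigma)  # stationary start
    innovations[1:] = rng.normal(0.0, sigma * np.sqrt(1 - phi**2), n - 1)
    return lfilter([1.0], [1.0, -phi], innovations)


def gen_dhdl(
    model: DhdlModel,
    lam: float,
    duration: float,
    interval: float = DEFAULT_INTERVAL,
    direction_sign: int = 1,
    seed: int | None = None,
) -> DhdlSeries:
    """One λ-point's synthetic series:
    x_t = g(λ) + s·b·e^(−t/τ_slow) + η_t with AR(1) noise η of stationary
    variance σ².  Deterministic given the seed."""
    if duration < 2 * interval:
        raise DataValidationError("duration must cover at least 2 samples")
    if direction_sign not in (1, -1):
        raise UsageError("direction_sign must be ±1")
    n = int(round(duration / interval))
    times = interval * np.arange(1, n + 1)
    use_seed = model.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    bias = direction_sign * model.bias_amplitude * np.exp(-times / model.tau_slow)
    samples = model.mean(lam) + bias + _ar1(rng, n, model.sigma, model.phi)
    return DhdlSeries(
        lambda_value=lam,
        samples=samples,
        sample_interval=interval,
        origin=f"synthetic(seed={use_seed})",
    )


def gen_run(
    model: DhdlModel,
    direction: str = "forward",
    duration: float = 1000.0,
    interval: float = DEFAULT_INTERVAL,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    state_from: str = "A",
    state_to: str = "B",
    environment: str = "solvent",
    replicate_id: str = "r1",
    seed: int | None = None,
) -> TransformationRun:
    """A whole synthetic TransformationRun in its executed frame.

    A backward run is the reversed transformation: its mean profile is
    −g(1−λ'), and the slow-relaxation bias keeps the same sign in the
    executed frame, so that once oriented onto the canonical direction the
    forward and backward biases oppose each other (direction-dependent
    hysteresis ≈ 2·mean bias).
    """
    if direction not in ("forward", "backward"):
        raise UsageError(f"unknown direction {direction!r}")
    base_seed = model.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(lambdas))]
    series = []
    for k, lam in enumerate(np.sort(np.asarray(lambdas, dtype=float))):
        if direction == "forward":
            mean_at = model.mean(lam)
        else:
            mean_at = -model.mean(1.0 - lam)
        n = int(round(duration / interval))
        times = interval * np.arange(1, n + 1)
        rng = np.random.default_rng(child_seeds[k])
        bias = model.bias_amplitude * np.exp(-times / model.tau_slow)
        samples = mean_at + bias + _ar1(rng, n, model.sigma, model.phi)
        series.append(
            DhdlSeries(
                lambda_value=lam,
                samples=samples,
                sample_interval=interval,
                origin=f"synthetic-run(seed={base_seed},λ#{k})",
            )
        )
    if direction == "forward":
        sf, st = state_from, state_to
    else:
        sf, st = state_to, state_from
    return TransformationRun(
        state_from=sf,
        state_to=st,
        environment=environment,
        direction_tag=direction,
        replicate_id=replicate_id,
        series=series,
    )


# ---------------------------------------------------------------------------
# Cycle datasets
# ---------------------------------------------------------------------------

#: canonical transformation pairs of a three-state cycle {A, G, S}
CYCLE_PAIRS = (("A", "G"), ("G", "S"), ("A", "S"))
#: per-environment replicate scheme: solvent pairs run twice (1 fwd + 1 bwd),
#: bound pairs four times (2 fwd + 2 bwd)
REPLICATES = {"solvent": 1, "bound": 2}


def gen_cycle_dataset(
    out_dir: str | Path,
    edge_truths: dict[str, dict[tuple[str, str], float]],
    sigma: float = 2.0,
    phi: float = DEFAULT_PHI,
    bias_amplitude: float = 0.0,
    tau_slow: float = 100.0,
    duration: float = 1000.0,
    interval: float = DEFAULT_INTERVAL,
    lambdas: np.ndarray = DEFAULT_LAMBDAS,
    curvature: float = 0.0,
    seed: int = 0,
) -> Path:
    """Write a full synthetic cycle dataset (dhdl TSVs + manifest + truth).

    ``edge_truths[env][(a, b)]`` is the planted ΔG of mutating a→b in that
    environment; around the cycle A→G→S→A each environment's truths must
    sum to zero.  The mean profile is g(λ) = ΔG* + curvature·(6λ²−6λ+1)
    (the second term integrates to zero).  Returns the manifest path; the
    planted per-pair ΔΔG* values are recorded in ``truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for env, truths in edge_truths.items():
        closure = truths[("A", "G")] + truths[("G", "S")] - truths[("A", "S")]
        if abs(closure) > 1e-9:
            raise DataValidationError(
                f"{env} edge truths are inconsistent: cycle sum {closure:.3g} ≠ 0"
            )
    entries = []
    counter = 0
    for env, truths in edge_truths.items():
        for pair in CYCLE_PAIRS:
            if pair not in truths:
                raise DataValidationError(f"missing truth for pair {pair} in {env}")
            for rep in range(REPLICATES[env]):
                for direction in ("forward", "backward"):
                    counter += 1
                    model = DhdlModel(
                        mean_coeffs=(
                            truths[pair] + curvature,
                            -6.0 * curvature,
                            6.0 * curvature,
                        ),
                        sigma=sigma,
                        phi=phi,
                        bias_amplitude=bias_amplitude,
                        tau_slow=tau_slow,
                        seed=seed,
                    )
                    run = gen_run(
                        model,
                        direction=direction,
                        duration=duration,
                        interval=interval,
                        lambdas=lambdas,
                        state_from=pair[0],
                        state_to=pair[1],
                        environment=env,
                        replicate_id=f"{env[0]}{rep + 1}",
                        seed=seed * 100003 + counter * 613,
                    )
                    files = []
                    for s in run.series:
                        fname = (
                            f"{env}_{pair[0]}{pair[1]}_{direction}_r{rep + 1}"
                            f"_l{s.lambda_value:.3f}.tsv"
                        )
                        write_dhdl_file(s, out_dir / fname)
                        files.append(fname)
                    entries.append(
                        {
                            "state_from": run.state_from,
                            "state_to": run.state_to,
                            "environment": env,
                            "direction": direction,
                            "replicate": run.replicate_id,
                            "files": files,
                        }
                    )
    manifest = out_dir / "manifest.yaml"
    write_run_manifest(entries, manifest)
    truth = {
        "edges": {
            env: {f"{a}->{b}": v for (a, b), v in truths.items()}
            for env, truths in edge_truths.items()
        },
        "ddg_bind": {
            f"{a}->{b}": edge_truths["bound"][(a, b)] - edge_truths["solvent"][(a, b)]
            for (a, b) in CYCLE_PAIRS
        }
        if {"bound", "solvent"} <= set(edge_truths)
        else {},
        "bias_amplitude": bias_amplitude,
        "tau_slow": tau_slow,
        "sigma": sigma,
        "phi": phi,
        "duration": duration,
        "seed": seed,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Calibration experiments (generator truth vs pipeline estimate)
# ---------------------------------------------------------------------------


def recovery_experiment(
    n_models: int = 20,
    duration: float = 500.0,
    interval: float = DEFAULT_INTERVAL,
    discard: float = 50.0,
    seed: int = 0,
) -> dict:
    """Unbiased parameter recovery: random quadratic mean profiles with AR(1)
    noise, pipeline ΔG vs analytic ground truth.

    Returns the number of models whose 3σ interval (block-averaged,
    propagated through the quadrature) covers the truth, plus per-model
    details.
    """
    from . import ti

    rng = np.random.default_rng(seed)
    results = []
    covered = 0
    for i in range(n_models):
        coeffs = tuple(rng.uniform(-20, 20, 3))
        model = DhdlModel(
            mean_coeffs=coeffs,
            sigma=float(rng.uniform(0.5, 3.0)),
            phi=DEFAULT_PHI,
            seed=int(rng.integers(2**31 - 1)),
        )
        run = gen_run(model, duration=duration, interval=interval, seed=model.seed)
        est = ti.integrate_run(run, discard=discard)
        err = est.value - model.ground_truth
        ok = abs(err) <= 3 * est.uncertainty
        covered += ok
        results.append(
            {"truth": model.ground_truth, "estimate": est.value, "sigma": est.uncertainty, "covered": ok}
        )
    return {"n_models": n_models, "n_covered": covered, "results": results}


def prolongation_experiment(
    n_seeds: int = 10,
    short_duration: float = 200.0,
    long_duration: float = 2000.0,
    bias_amplitude: float = 10.0,
    tau_slow: float = 100.0,
    sigma: float = 1.0,
    discard: float = 50.0,
    seed: int = 0,
) -> dict:
    """Direction-dependent slow relaxation: hysteresis vs sampling length.

    For each seed a biased forward/backward pair is generated at a short and
    a 10× longer duration; the count of seeds whose hysteresis shrinks on
    prolongation is reported.  A full three-pair cycle at the long duration
    is then assembled and its closure checked against the thermal-noise
    tolerance.
    """
    from . import ti
    from .core import ThermoCycle
    from .cycles import combine, cycle_closure, hysteresis, orient

    truths = {("A", "G"): -4.05, ("G", "S"): -22.45, ("A", "S"): -26.5}
    hyst_short, hyst_long = [], []
    for s in range(n_seeds):
        model = DhdlModel(
            mean_coeffs=(truths[("A", "G")],),
            sigma=sigma,
            phi=DEFAULT_PHI,
            bias_amplitude=bias_amplitude,
            tau_slow=tau_slow,
        )
        per_dur = []
        for duration in (short_duration, long_duration):
            fwd = gen_run(model, "forward", duration, state_from="A", state_to="G", seed=seed * 7907 + 2 * s)
            bwd = gen_run(model, "backward", duration, state_from="A", state_to="G", seed=seed * 7907 + 2 * s + 1)
            per_dur.append(
                hysteresis(ti.integrate_run(fwd, discard), ti.integrate_run(bwd, discard))
            )
        hyst_short.append(per_dur[0])
        hyst_long.append(per_dur[1])
    n_decreased = sum(1 for a, b in zip(hyst_short, hyst_long) if b < a)

    cycle = ThermoCycle()
    for k, (pair, truth) in enumerate(truths.items()):
        model = DhdlModel(
            mean_coeffs=(truth,),
            sigma=sigma,
            phi=DEFAULT_PHI,
            bias_amplitude=bias_amplitude,
            tau_slow=tau_slow,
        )
        oriented = []
        for j, direction in enumerate(("forward", "backward")):
            run = gen_run(
                model, direction, long_duration,
                state_from=pair[0], state_to=pair[1],
                seed=seed * 6211 + 10 * k + j,
            )
            oriented.append(orient(ti.integrate_run(run, discard), pair))
        cycle.add_edge(combine(oriented), "solvent")
    report = cycle_closure(cycle, ["A", "G", "S", "A"])
    return {
        "hysteresis_short": hyst_short,
        "hysteresis_long": hyst_long,
        "n_decreased": n_decreased,
        "n_seeds": n_seeds,
        "closure_long": report.closures["solvent"],
        "closure_passed": report.passed["solvent"],
        "tolerance": report.tolerance,
    }


# ---------------------------------------------------------------------------
# Dihedral samples
# ---------------------------------------------------------------------------


def gen_dihedral_series(
    components: list[tuple[float, float, float]],
    n: int,
    seed: int = 0,
    name: str = "phi2",
) -> DihedralSeries:
    """i.i.d. draws from a von Mises mixture, degrees in (−180, 180].

    ``components`` are (center°, concentration κ, weight) triples; weights
    must sum to 1.  Low κ gives glycine-like broad sampling, high κ the
    sharp peaks of a side-chain-bearing residue.
    """
    if n < 1:
        raise UsageError("n must be ≥ 1")
    if not components:
        raise UsageError("mixture needs at least one component")
    weights = np.array([w for _, _, w in components], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise DataValidationError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    draws = []
    for (center, kappa, _), m in zip(components, counts):
        if m:
            draws.append(np.degrees(rng.vonmises(np.radians(center), kappa, m)))
    angles = np.concatenate(draws)
    rng.shuffle(angles)
    angles = ((angles + 180.0) % 360.0) - 180.0  # (−180, 180]
    angles[angles == -180.0] = 180.0
    return DihedralSeries(name=name, angles=angles)


# ---------------------------------------------------------------------------
# Water scenes
# ---------------------------------------------------------------------------


@dataclass
class WaterSceneModel:
    """A toy hydration scene: hotspot sites with two-state (present/absent)
    water dynamics plus freely diffusing bulk waters.

    ``site_probs`` are stationary presence probabilities; ``exchange_rate``
    k (frame⁻¹) sets the on/off relaxation so that the presence
    autocorrelation decays with integrated time ≈ 1/(2k) frames.  Absent
    hotspot waters are parked in a reserved corner of the box (outside any
    analysis region of interest).
    """

    box: np.ndarray
    site_positions: np.ndarray
    site_probs: np.ndarray
    exchange_rate: float = 0.05
    n_diffuse: int = 0
    seed: int = 0
    parking_corner: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.05, 0.05]))

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.site_positions = np.atleast_2d(np.asarray(self.site_positions, dtype=float))
        self.site_probs = np.atleast_1d(np.asarray(self.site_probs, dtype=float))
        if np.any((self.site_probs < 0) | (self.site_probs > 1)):
            raise DataValidationError("site probabilities must lie in [0, 1]")
        if self.site_positions.shape[0] != self.site_probs.size:
            raise DataValidationError("one probability per site required")
        if np.any(self.site_positions < 0) or np.any(self.site_positions > self.box):
            raise DataValidationError("sites must lie inside the box")
        if not 0 < self.exchange_rate <= 0.5:
            raise DataValidationError("exchange rate must be in (0, 0.5] per frame")


def gen_water_trajectory(model: WaterSceneModel, n_frames: int) -> Trajectory:
    """Generate a water trajectory with planted hotspots.

    Each hotspot water is present at its site (with a small positional
    jitter well below half the grid spacing) or parked in the reserved
    corner, switching by a two-state Markov chain with stationary
    probability p and flip rates 2k(1−p) / 2k·p.  Diffuse waters perform a
    reflected random walk.  Three static anchor atoms (N, CA, C) provide a
    backbone for superposition.
    """
    rng = np.random.default_rng(model.seed)
    n_sites = model.site_probs.size
    center = model.box / 2
    anchors = np.array([center + [0.0, 0.0, 0.0], center + [0.15, 0.0, 0.0], center + [0.15, 0.15, 0.0]])
    n_atoms = 3 + n_sites + model.n_diffuse
    coords = np.empty((n_frames, n_atoms, 3))
    state = rng.random(n_sites) < model.site_probs
    p_on = 2.0 * model.exchange_rate * model.site_probs  # off -> on
    p_off = 2.0 * model.exchange_rate * (1.0 - model.site_probs)  # on -> off
    diffuse = rng.uniform(0, 1, (model.n_diffuse, 3)) * model.box
    park = np.asarray(model.parking_corner, dtype=float)
    for f in range(n_frames):
        coords[f, :3] = anchors
        jitter = rng.normal(0.0, 0.01, (n_sites, 3))
        for s in range(n_sites):
            if state[s]:
                coords[f, 3 + s] = model.site_positions[s] + jitter[s]
            else:
                coords[f, 3 + s] = park + [0.0, 0.0, 0.02 * s]
        if model.n_diffuse:
            diffuse = diffuse + rng.normal(0.0, 0.05, diffuse.shape)
            diffuse = np.abs(diffuse)  # reflect at the walls
            over = diffuse > model.box
            diffuse[over] = (2 * model.box * np.ones_like(diffuse))[over] - diffuse[over]
            coords[f, 3 + n_sites :] = diffuse
        flips = rng.random(n_sites)
        next_state = state.copy()
        next_state[state & (flips < p_off)] = False
        next_state[~state & (flips < p_on)] = True
        state = next_state
    atom_names = ["N", "CA", "C"] + ["OW"] * (n_sites + model.n_diffuse)
    res_names = ["ALA"] * 3 + ["SOL"] * (n_sites + model.n_diffuse)
    res_ids = [1, 1, 1] + list(range(2, 2 + n_sites + model.n_diffuse))
    roles = np.array(
        ["backbone"] * 3 + ["water-oxygen"] * (n_sites + model.n_diffuse), dtype=object
    )
    box = np.tile(model.box, (n_frames, 1))
    return Trajectory(
        coords=coords,
        atom_names=atom_names,
        residue_names=res_names,
        residue_indices=res_ids,
        roles=roles,
        box=box,
        frame_interval=1.0,
    )
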