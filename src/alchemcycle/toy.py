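"""A minimal λ-coupled alchemical Monte Carlo simulator.

The Hamiltonian is coupled linearly between end states,

    H(λ) = (1 − λ)·H_A(λ) + λ·H_B(λ),

where the end-state nonbonded terms are softcore-regularized so that
creation/annihilation of particles never produces singular energies at
intermediate λ: the A-state terms are softened proportionally to λ² and the
B-state terms to (1 − λ)², so the softening vanishes exactly at each end
state and H(0)/H(1) are the unmodified A/B Hamiltonians regardless of the
softness parameters.

The functional form is a Beutler-style additive softening: the
Lennard-Jones r⁶ is shifted by α_vdw·λ_off²·(C12/C6) (the ratio taken per
end state; zero-parameter particles use 0), and the Coulomb/reaction-field
r² by α_crf·λ_off² (α_crf in nm²).  This is a modeling choice for a toy
system, not a reproduction of any production force field's softcore.

Sampling is Metropolis single-particle-translation Monte Carlo at constant
volume; momenta drop out of Eq.-style λ-coupling for λ-independent masses,
so configurational sampling suffices for ⟨∂H/∂λ⟩.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    DataValidationError,
    DhdlSeries,
    SoftcoreParams,
    TransformationRun,
    UsageError,
)

logger = logging.getLogger("alchemcycle")

#: molar gas constant (kJ·mol⁻¹·K⁻¹)
R_GAS = 0.008314462
#: Coulomb prefactor 1/(4πε₀) in kJ·mol⁻¹·nm·e⁻²
F_COULOMB = 138.935458
#: default simulation temperature (K)
DEFAULT_TEMPERATURE = 298.0
#: default nonbonded cutoff (nm) and reaction-field permittivity
DEFAULT_CUTOFF = 1.4
DEFAULT_EPS_RF = 61.0


# ---------------------------------------------------------------------------
# System definition
# ---------------------------------------------------------------------------


@dataclass
class ToySystem:
    """Particles in a rectangular periodic box with A/B-state parameters.

    ``c12_*`` (kJ·mol⁻¹·nm¹²), ``c6_*`` (kJ·mol⁻¹·nm⁶) and ``q_*`` (e) give
    each particle's Lennard-Jones and charge parameters in states A and B.
    Optional per-particle harmonic tethers (``tether_k_*`` in
    kJ·mol⁻¹·nm⁻², anchored at ``tether_centers``) provide exactly solvable
    reference modes.
    """

    positions: np.ndarray
    box: np.ndarray
    c12_a: np.ndarray
    c6_a: np.ndarray
    q_a: np.ndarray
    c12_b: np.ndarray
    c6_b: np.ndarray
    q_b: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    cutoff: float = DEFAULT_CUTOFF
    eps_rf: float = DEFAULT_EPS_RF
    softcore: SoftcoreParams = field(default_factory=SoftcoreParams)
    tether_k_a: np.ndarray | None = None
    tether_k_b: np.ndarray | None = None
    tether_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        n = self.positions.shape[0]
        for name in ("c12_a", "c6_a", "q_a", "c12_b", "c6_b", "q_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape == ():
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise DataValidationError(f"{name} must have one entry per particle")
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"{name} must be finite")
            setattr(self, name, arr)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise DataValidationError("box must be three positive edge lengths")
        half_min = float(self.box.min()) / 2
        if self.cutoff > half_min:
            logger.warning(
                "cutoff %.3g nm exceeds half the smallest box edge; truncated to %.3g nm",
                self.cutoff,
                half_min,
            )
            self.cutoff = half_min
        if self.tether_k_a is not None or self.tether_k_b is not None:
            self.tether_k_a = np.asarray(
                self.tether_k_a if self.tether_k_a is not None else np.zeros(n), dtype=float
            )
            self.tether_k_b = np.asarray(
                self.tether_k_b if self.tether_k_b is not None else np.zeros(n), dtype=float
            )
            if self.tether_centers is None:
                self.tether_centers = self.positions.copy()
            else:
                self.tether_centers = np.asarray(self.tether_centers, dtype=float)

        # cached geometric-combination pair parameters and interaction flags
        self._c12a_mat = np.sqrt(np.outer(self.c12_a, self.c12_a))
        self._c6a_mat = np.sqrt(np.outer(self.c6_a, self.c6_a))
        self._c12b_mat = np.sqrt(np.outer(self.c12_b, self.c12_b))
        self._c6b_mat = np.sqrt(np.outer(self.c6_b, self.c6_b))
        self._qqa_mat = np.outer(self.q_a, self.q_a)
        self._qqb_mat = np.outer(self.q_b, self.q_b)
        self._has_lj = bool(self._c12a_mat.any() or self._c12b_mat.any() or self._c6a_mat.any() or self._c6b_mat.any())
        self._has_charges = bool(self._qqa_mat.any() or self._qqb_mat.any())

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def kt(self) -> float:
        return R_GAS * self.temperature


# ---------------------------------------------------------------------------
# Softcore pair interactions
# ---------------------------------------------------------------------------


def _ratio(c12, c6):
    c12 = np.asarray(c12, dtype=float)
    c6 = np.asarray(c6, dtype=float)
    return np.where(c6 > 0, c12 / np.where(c6 > 0, c6, 1.0), 0.0)


def softcore_pair_vdw(r, lam: float, c12_a, c6_a, c12_b, c6_b, alpha_vdw: float):
    """Softcore Lennard-Jones pair energy and its exact dE/dλ.

    The A term is softened by λ (vanishing at λ=0), the B term by 1−λ:
    r⁶ → r⁶ + α·λ_off²·(C12/C6), with the C12/C6 ratio of that end state.
    Accepts scalars or broadcastable arrays; r must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise UsageError("pair distance must be positive")
    r6 = r**6
    ra, rb = _ratio(c12_a, c6_a), _ratio(c12_b, c6_b)
    da = r6 + alpha_vdw * lam**2 * ra
    db = r6 + alpha_vdw * (1.0 - lam) ** 2 * rb
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        va = np.where(da > 0, c12_a / da**2 - c6_a / da, np.inf)
        vb = np.where(db > 0, c12_b / db**2 - c6_b / db, np.inf)
        dva = np.where(da > 0, (-2.0 * c12_a / da**3 + c6_a / da**2), 0.0) * (
            2.0 * alpha_vdw * lam * ra
        )
        dvb = np.where(db > 0, (-2.0 * c12_b / db**3 + c6_b / db**2), 0.0) * (
            -2.0 * alpha_vdw * (1.0 - lam) * rb
        )
    energy = (1.0 - lam) * va + lam * vb
    dedl = -va + vb + (1.0 - lam) * dva + lam * dvb
    return energy, dedl


def crf_constant(eps_rf: float) -> float:
    """Reaction-field constant C_rf = 2(ε−1)/(2ε+1)."""
    return 2.0 * (eps_rf - 1.0) / (2.0 * eps_rf + 1.0)


def softcore_pair_rf(
    r, lam: float, qq_a, qq_b, alpha_crf: float, eps_rf: float, cutoff: float
):
    """Softcore Coulomb + reaction-field pair energy and exact dE/dλ.

    ``qq_a``/``qq_b`` are the products of the pair's charges in each end
    state.  Within each end-state term, r² → r² + α_crf·λ_off² in both the
    direct 1/r part and the reaction-field crown term

        V(r) = f·qq·[ (r²+a)^−½ − C_rf·(r²+a)/(2R_c³) − (1 − C_rf/2)/R_c ],

    which vanishes at the cutoff for a = 0.  Beyond the cutoff both energy
    and derivative are zero.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise UsageError("pair distance must be positive")
    crf = crf_constant(eps_rf)
    rc3 = cutoff**3
    const = (1.0 - crf / 2.0) / cutoff
    r2 = r**2

    def v_and_dvda(qq, a):
        s2 = r2 + a
        with np.errstate(divide="ignore", over="ignore"):
            v = F_COULOMB * qq * (1.0 / np.sqrt(s2) - crf * s2 / (2.0 * rc3) - const)
            dvda = F_COULOMB * qq * (-0.5 * s2**-1.5 - crf / (2.0 * rc3))
        return v, dvda

    aa = alpha_crf * lam**2
    ab = alpha_crf * (1.0 - lam) ** 2
    va, dva_da = v_and_dvda(np.asarray(qq_a, dtype=float), aa)
    vb, dvb_da = v_and_dvda(np.asarray(qq_b, dtype=float), ab)
    dva = dva_da * (2.0 * alpha_crf * lam)
    dvb = dvb_da * (-2.0 * alpha_crf * (1.0 - lam))
    energy = (1.0 - lam) * va + lam * vb
    dedl = -va + vb + (1.0 - lam) * dva + lam * dvb
    outside = r > cutoff
    energy = np.where(outside, 0.0, energy)
    dedl = np.where(outside, 0.0, dedl)
    return energy, dedl


# ---------------------------------------------------------------------------
# System energies
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _particle_terms(
    system: ToySystem, positions: np.ndarray, i: int, xi: np.ndarray, lam: float
) -> tuple[float, float]:
    """Energy and dH/dλ of particle i at position xi with all other particles
    (plus its tether), under minimum image and the cutoff."""
    n = system.n_particles
    e_total = 0.0
    de_total = 0.0
    if n > 1:
        others = np.arange(n) != i
        d = _min_image(positions[others] - xi, system.box)
        r = np.sqrt(np.sum(d**2, axis=1))
        within = r <= system.cutoff
        if np.any(within):
            rw = r[within]
            sel = np.flatnonzero(others)[within]
            if system._has_lj:
                e_vdw, de_vdw = softcore_pair_vdw(
                    rw,
                    lam,
                    system._c12a_mat[i, sel],
                    system._c6a_mat[i, sel],
                    system._c12b_mat[i, sel],
                    system._c6b_mat[i, sel],
                    system.softcore.alpha_vdw,
                )
                e_total += float(np.sum(e_vdw))
                de_total += float(np.sum(de_vdw))
            if system._has_charges:
                e_rf, de_rf = softcore_pair_rf(
                    rw,
                    lam,
                    system._qqa_mat[i, sel],
                    system._qqb_mat[i, sel],
                    system.softcore.alpha_crf,
                    system.eps_rf,
                    system.cutoff,
                )
                e_total += float(np.sum(e_rf))
                de_total += float(np.sum(de_rf))
    if system.tether_k_a is not None:
        dr2 = float(np.sum((xi - system.tether_centers[i]) ** 2))
        ka, kb = system.tether_k_a[i], system.tether_k_b[i]
        e_total += 0.5 * ((1.0 - lam) * ka + lam * kb) * dr2
        de_total += 0.5 * (kb - ka) * dr2
    return e_total, de_total


def total_hamiltonian(system: ToySystem, lam: float, positions: np.ndarray | None = None):
    """Total coupled energy and dH/dλ (pairwise with minimum image inside
    the cutoff, plus harmonic tethers).  Raises on non-finite energies
    (e.g. exactly overlapping particles with zero softness)."""
    pos = system.positions if positions is None else positions
    n = system.n_particles
    e = de = 0.0
    if n > 1:
        ii, jj = np.triu_indices(n, k=1)
        d = _min_image(pos[jj] - pos[ii], system.box)
        r = np.sqrt(np.sum(d**2, axis=1))
        within = r <= system.cutoff
        if np.any(within):
            i, j, rw = ii[within], jj[within], r[within]
            if system._has_lj:
                e_vdw, de_vdw = softcore_pair_vdw(
                    rw,
                    lam,
                    system._c12a_mat[i, j],
                    system._c6a_mat[i, j],
                    system._c12b_mat[i, j],
                    system._c6b_mat[i, j],
                    system.softcore.alpha_vdw,
                )
                e += float(np.sum(e_vdw))
                de += float(np.sum(de_vdw))
            if system._has_charges:
                e_rf, de_rf = softcore_pair_rf(
                    rw,
                    lam,
                    system._qqa_mat[i, j],
                    system._qqb_mat[i, j],
                    system.softcore.alpha_crf,
                    system.eps_rf,
                    system.cutoff,
                )
                e += float(np.sum(e_rf))
                de += float(np.sum(de_rf))
    if system.tether_k_a is not None:
        dr2 = np.sum((pos - system.tether_centers) ** 2, axis=1)
        e += float(np.sum(0.5 * ((1.0 - lam) * system.tether_k_a + lam * system.tether_k_b) * dr2))
        de += float(np.sum(0.5 * (system.tether_k_b - system.tether_k_a) * dr2))
    if not (np.isfinite(e) and np.isfinite(de)):
        raise DataValidationError(
            "non-finite energy: overlapping particles with zero softness?"
        )
    return e, de


# ---------------------------------------------------------------------------
# Monte Carlo sampling
# ---------------------------------------------------------------------------


@dataclass
class MCResult:
    """Output of one fixed-λ Monte Carlo run."""

    series: DhdlSeries
    final_positions: np.ndarray
    acceptance_rate: float


def run_mc(
    system: ToySystem,
    lam: float,
    n_steps: int,
    max_displacement: float = 0.05,
    seed: int = 0,
    record_interval: int = 10,
    sample_interval: float = 0.5,
    start_positions: np.ndarray | None = None,
) -> MCResult:
    """Metropolis single-particle-translation MC at fixed λ.

    Records dH/dλ every ``record_interval`` steps; ``sample_interval`` is the
    nominal time (ps) assigned per recorded sample so the series can flow
    through the TI analysis.  Identical seeds give identical output.
    """
    if n_steps < 1:
        raise UsageError("n_steps must be ≥ 1")
    rng = np.random.default_rng(seed)
    pos = np.array(system.positions if start_positions is None else start_positions, dtype=float)
    kt = system.kt
    n = system.n_particles
    samples = []
    accepted = 0
    for step in range(1, n_steps + 1):
        i = int(rng.integers(n))
        move = rng.uniform(-max_displacement, max_displacement, 3)
        old_e, _ = _particle_terms(system, pos, i, pos[i], lam)
        new_xi = (pos[i] + move) % system.box
        new_e, _ = _particle_terms(system, pos, i, new_xi, lam)
        delta = new_e - old_e
        if delta <= 0 or rng.random() < np.exp(-delta / kt):
            pos[i] = new_xi
            accepted += 1
        if step % record_interval == 0:
            _, dhdl = total_hamiltonian(system, lam, pos)
            samples.append(dhdl)
    if not samples:
        _, dhdl = total_hamiltonian(system, lam, pos)
        samples.append(dhdl)
    rate = accepted / n_steps
    logger.debug("MC λ=%.3f: acceptance %.2f", lam, rate)
    series = DhdlSeries(
        lambda_value=lam,
        samples=np.array(samples),
        sample_interval=sample_interval,
        origin=f"toy-mc(seed={seed})",
    )
    return MCResult(series=series, final_positions=pos, acceptance_rate=rate)


@dataclass
class ProtocolResult:
    run: TransformationRun
    final_positions: np.ndarray


def run_protocol(
    system: ToySystem,
    schedule: np.ndarray,
    direction: str = "forward",
    production_steps: int = 2000,
    equilibration_steps: int = 500,
    seed: int = 0,
    max_displacement: float = 0.05,
    record_interval: int = 10,
    sample_interval: float = 0.5,
    start_positions: np.ndarray | None = None,
    state_from: str = "A",
    state_to: str = "B",
    replicate_id: str = "r1",
    environment: str = "solvent",
) -> ProtocolResult:
    """Run the full λ schedule in one direction, chaining configurations.

    A forward run visits the schedule in ascending order starting from the
    given configuration; a backward run visits it in descending order (its
    natural starting configuration is a forward run's final one).  Per-λ
    equilibration steps are discarded before production sampling.

    The returned TransformationRun is expressed in the run's *executed*
    frame: for a backward run, λ' = 1 − λ and the recorded ∂H/∂λ samples are
    negated, so integrating it yields ΔG(B→A) directly.
    """
    schedule = np.sort(np.asarray(schedule, dtype=float))
    if schedule[0] > 1e-9 or schedule[-1] < 1 - 1e-9:
        raise UsageError("λ schedule must cover [0, 1]")
    if direction not in ("forward", "backward"):
        raise UsageError(f"unknown direction {direction!r}")
    visit = schedule if direction == "forward" else schedule[::-1]
    pos = np.array(system.positions if start_positions is None else start_positions, dtype=float)
    series: list[DhdlSeries] = []
    for k, lam in enumerate(visit):
        sub_seed = (seed * 1009 + k * 97 + (0 if direction == "forward" else 31)) % (2**31 - 1)
        if equilibration_steps:
            eq = run_mc(
                system,
                lam,
                equilibration_steps,
                max_displacement,
                seed=sub_seed,
                record_interval=max(equilibration_steps, 1),
                sample_interval=sample_interval,
                start_positions=pos,
            )
            pos = eq.final_positions
        prod = run_mc(
            system,
            lam,
            production_steps,
            max_displacement,
            seed=sub_seed + 1,
            record_interval=record_interval,
            sample_interval=sample_interval,
            start_positions=pos,
        )
        pos = prod.final_positions
        if direction == "forward":
            series.append(prod.series)
        else:
            series.append(
                DhdlSeries(
                    lambda_value=round(1.0 - lam, 12),
                    samples=-prod.series.samples,
                    sample_interval=sample_interval,
                    origin=prod.series.origin,
                )
            )
    series.sort(key=lambda s: s.lambda_value)
    if direction == "forward":
        sf, st = state_from, state_to
    else:
        sf, st = state_to, state_from
    run = TransformationRun(
        state_from=sf,
        state_to=st,
        environment=environment,
        direction_tag=direction,
        replicate_id=replicate_id,
        series=series,
    )
    return ProtocolResult(run=run, final_positions=pos)


def forward_backward(
    system: ToySystem, schedule: np.ndarray, seed: int = 0, **kwargs
) -> tuple[ProtocolResult, ProtocolResult]:
    """Forward protocol followed by a backward protocol seeded from the
    forward run's final configuration (the hysteresis-diagnostic pairing)."""
    fwd = run_protocol(system, schedule, direction="forward", seed=seed, **kwargs)
    bwd = run_protocol(
        system,
        schedule,
        direction="backward",
        seed=seed + 1,
        start_positions=fwd.final_positions,
        **kwargs,
    )
    return fwd, bwd


# ---------------------------------------------------------------------------
# Closed-form / brute-force oracles
# ---------------------------------------------------------------------------


def analytic_dg_harmonic(
    k_a: float, k_b: float, temperature: float = DEFAULT_TEMPERATURE, dims: int = 3
) -> float:
    """Exact ΔG (kJ·mol⁻¹) of mutating a harmonic well k_A → k_B:
    (dims·R·T/2)·ln(k_B/k_A)."""
    if k_a <= 0 or k_b <= 0:
        raise UsageError("spring constants must be positive")
    return dims * R_GAS * temperature / 2.0 * np.log(k_b / k_a)


def enumerate_dg(e_a: np.ndarray, e_b: np.ndarray, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Exact ΔG of a discretized 1-D system from partition sums:
    −RT·ln(Σ e^(−E_B/RT) / Σ e^(−E_A/RT))."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if e_a.size == 0 or e_a.shape != e_b.shape:
        raise UsageError("energy tables must be non-empty and congruent")
    rt = R_GAS * temperature
    return float(-rt * (logsumexp(-e_b / rt) - logsumexp(-e_a / rt)))


def ti_reference_means(
    e_a: np.ndarray, e_b: np.ndarray, lambdas: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Exact ⟨∂H/∂λ⟩_λ = ⟨E_B − E_A⟩_λ for the linearly interpolated
    Hamiltonian on a discretized 1-D system (Boltzmann-weighted average over
    the grid), for TI-vs-partition-sum oracle comparisons."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    rt = R_GAS * temperature
    means = []
    for lam in np.asarray(lambdas, dtype=float):
        h = (1.0 - lam) * e_a + lam * e_b
        logw = -h / rt - logsumexp(-h / rt)
        means.append(float(np.sum(np.exp(logw) * (e_b - e_a))))
    return np.array(means)


# ---------------------------------------------------------------------------
# Reference toy systems
# ---------------------------------------------------------------------------


def harmonic_system(
    k_a: float,
    k_b: float,
    temperature: float = DEFAULT_TEMPERATURE,
    box_edge: float = 10.0,
) -> ToySystem:
    """A single tethered, non-interacting particle: the exactly solvable
    harmonic mutation k_A → k_B (3 dimensions)."""
    center = np.full((1, 3), box_edge / 2)
    return ToySystem(
        positions=center.copy(),
        box=np.full(3, box_edge),
        c12_a=0.0,
        c6_a=0.0,
        q_a=0.0,
        c12_b=0.0,
        c6_b=0.0,
        q_b=0.0,
        temperature=temperature,
        cutoff=0.5,
        tether_k_a=np.array([k_a]),
        tether_k_b=np.array([k_b]),
        tether_centers=center.copy(),
    )


def confined_pair_system(
    alpha_vdw: float = 1.0,
    alpha_crf: float = 1.0,
    eps_pair: float = 10.0,
    sigma: float = 0.38,
    k_confine: float = 50.0,
    box_edge: float = 3.0,
    separation: float = 0.44,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ToySystem:
    """Deletion of one particle of a deep-well LJ pair confined by tethers.

    Both particles are tethered (identically in states A and B, so the
    tethers contribute nothing to ΔG) to a common center; state B switches
    off one particle's LJ parameters.  The pair well is deep relative to RT
    (default ε = 10 kJ·mol⁻¹ ≈ 4RT at 298 K), which makes the deletion a
    genuinely hard alchemical problem at desk scale: the TI curve is steep
    and the ∂H/∂λ variance large where the particles overlap, with both
    effects visibly reduced by softer cores.  This is the packaged
    softness/hysteresis test case, and it has an exact partition-sum oracle
    (:func:`exact_dg_confined_pair`).
    """
    s6 = sigma**6
    c6 = 4.0 * eps_pair * s6
    c12 = 4.0 * eps_pair * s6 * s6
    c = np.full(3, box_edge / 2)
    pos = np.array([c - [separation / 2, 0, 0], c + [separation / 2, 0, 0]])
    return ToySystem(
        positions=pos,
        box=np.full(3, box_edge),
        c12_a=np.array([c12, c12]),
        c6_a=np.array([c6, c6]),
        q_a=np.zeros(2),
        c12_b=np.array([0.0, c12]),
        c6_b=np.array([0.0, c6]),
        q_b=np.zeros(2),
        temperature=temperature,
        cutoff=1.4,
        softcore=SoftcoreParams(alpha_vdw=alpha_vdw, alpha_crf=alpha_crf),
        tether_k_a=np.full(2, k_confine),
        tether_k_b=np.full(2, k_confine),
        tether_centers=np.array([c, c]),
    )


def exact_dg_confined_pair(system: ToySystem, r_max: float | None = None, n_grid: int = 200001) -> float:
    """Exact ΔG of :func:`confined_pair_system` by radial quadrature.

    With both tethers anchored at the same point with equal spring constant
    k in both states, center-of-mass and relative coordinates separate; the
    CM part cancels between A and B and the relative separation s feels
    (k/4)s² plus the pair potential, so

        ΔG = −RT·ln( ∫ s²e^(−β[(k/4)s² + V_B(s)]) ds /
                     ∫ s²e^(−β[(k/4)s² + V_A(s)]) ds ).

    End-state potentials are softcore-free by construction.
    """
    if system.n_particles != 2 or system.tether_k_a is None:
        raise UsageError("exact oracle requires the two-particle tethered system")
    k = float(system.tether_k_a[0])
    if not (
        np.allclose(system.tether_k_a, k)
        and np.allclose(system.tether_k_b, k)
        and np.allclose(system.tether_centers[0], system.tether_centers[1])
    ):
        raise UsageError("tethers must be equal in both states and share one anchor")
    rt = system.kt
    if r_max is None:
        r_max = min(float(system.box.min()) / 2, system.cutoff)
    s = np.linspace(1e-6, r_max, n_grid)

    def z(c12_i, c6_i, c12_j, c6_j, qq):
        v = np.zeros_like(s)
        c12p = np.sqrt(c12_i * c12_j)
        c6p = np.sqrt(c6_i * c6_j)
        if c12p or c6p:
            v = v + c12p / s**12 - c6p / s**6
        if qq:
            crf = crf_constant(system.eps_rf)
            v = v + F_COULOMB * qq * (
                1.0 / s - crf * s**2 / (2 * system.cutoff**3) - (1 - crf / 2) / system.cutoff
            )
        w = s**2 * np.exp(-np.clip((k / 4) * s**2 + v, -500 * rt, 500 * rt) / rt)
        return np.trapezoid(w, s)

    za = z(system.c12_a[0], system.c6_a[0], system.c12_a[1], system.c6_a[1], system.q_a[0] * system.q_a[1])
    zb = z(system.c12_b[0], system.c6_b[0], system.c12_b[1], system.c6_b[1], system.q_b[0] * system.q_b[1])
    return float(-rt * np.log(zb / za))


@dataclass
class SoftnessResult:
    """Per-α outcome of the softness/hysteresis experiment."""

    hysteresis: dict[float, list[float]]
    combined_dg: dict[float, tuple[float, float]]  # alpha -> (mean, SEM)
    exact_dg: float


def _protocol_estimates(alpha, schedule, seed, steps, equil, disp, rec):
    from . import ti as _ti
    from .cycles import hysteresis as _hyst

    system = confined_pair_system(alpha_vdw=alpha, alpha_crf=alpha)
    fwd, bwd = forward_backward(
        system,
        schedule,
        seed=seed,
        production_steps=steps,
        equilibration_steps=equil,
        max_displacement=disp,
        record_interval=rec,
    )
    f = _ti.integrate_run(fwd.run, discard=0.0)
    b = _ti.integrate_run(bwd.run, discard=0.0)
    return f, b, _hyst(f, b)


def softness_experiment(
    alphas: tuple[float, ...] = (0.5, 1.0),
    n_seeds: int = 10,
    production_steps: int = 800,
    equilibration_steps: int = 100,
    n_lambdas: int = 11,
    converged_steps: int = 3000,
    converged_lambdas: int = 21,
    converged_seeds: int = 3,
    max_displacement: float = 0.04,
    record_interval: int = 2,
    base_seed: int = 0,
) -> SoftnessResult:
    """Hysteresis vs softness on the confined deep-well pair.

    Phase 1 (fixed short sampling, ``n_seeds`` forward/backward protocol
    pairs per α on ``n_lambdas`` equidistant λ): per-seed hysteresis.  A
    softer core flattens the TI curve and tames the overlap-region ∂H/∂λ
    variance, so the median hysteresis at α = 1.0 should not exceed that at
    α = 0.5.

    Phase 2 (convergence check, longer sampling on a denser schedule —
    discretization bias of the trapezoid rule is itself α-dependent, so the
    comparison needs the finer grid): per-α combined ΔG ± SEM pooled over
    forward and sign-inverted backward estimates; the integrated
    free-energy difference is α-independent, so the combined values should
    agree with each other and with the exact partition-sum oracle.
    """
    short_schedule = np.linspace(0, 1, n_lambdas)
    long_schedule = np.linspace(0, 1, converged_lambdas)
    hyst: dict[float, list[float]] = {}
    combined: dict[float, tuple[float, float]] = {}
    exact = exact_dg_confined_pair(confined_pair_system())
    for alpha in alphas:
        hs: list[float] = []
        for seed in range(n_seeds):
            _, _, h = _protocol_estimates(
                alpha,
                short_schedule,
                base_seed * 7919 + seed,
                production_steps,
                equilibration_steps,
                max_displacement,
                record_interval,
            )
            hs.append(h)
        hyst[alpha] = hs
        dgs: list[float] = []
        for seed in range(converged_seeds):
            f, b, _ = _protocol_estimates(
                alpha,
                long_schedule,
                base_seed * 7919 + 500 + seed,
                converged_steps,
                equilibration_steps,
                max_displacement,
                record_interval,
            )
            dgs.extend([f.value, -b.value])
        arr = np.array(dgs)
        combined[alpha] = (float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size)))
    return SoftnessResult(hysteresis=hyst, combined_dg=combined, exact_dg=exact)


def lj_deletion_system(
    n_solvent: int = 8,
    box_edge: float = 1.6,
    c12: float = 4.35e-5,
    c6: float = 1.45e-2,
    alpha_vdw: float = 1.0,
    alpha_crf: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> ToySystem:
    """A solute Lennard-Jones particle deleted (A → dummy) in a small bath
    of identical LJ particles; the standard softness/hysteresis test case.
    Default C12/C6 are methane-like GROMOS-scale values."""
    rng = np.random.default_rng(seed)
    n = n_solvent + 1
    # start from a jittered cubic lattice to avoid initial overlaps
    per_edge = int(np.ceil(n ** (1 / 3)))
    grid = np.array(
        [
            (i, j, k)
            for i in range(per_edge)
            for j in range(per_edge)
            for k in range(per_edge)
        ][:n],
        dtype=float,
    )
    pos = (grid + 0.5) / per_edge * box_edge + rng.normal(0, 0.02, (n, 3))
    pos %= box_edge
    c12_arr = np.full(n, c12)
    c6_arr = np.full(n, c6)
    c12_b = c12_arr.copy()
    c6_b = c6_arr.copy()
    c12_b[0] = 0.0  # solute becomes a dummy in state B
    c6_b[0] = 0.0
    return ToySystem(
        positions=pos,
        box=np.full(3, box_edge),
        c12_a=c12_arr,
        c6_a=c6_arr,
        q_a=np.zeros(n),
        c12_b=c12_b,
        c6_b=c6_b,
        q_b=np.zeros(n),
        temperature=temperature,
        cutoff=0.8,
        softcore=SoftcoreParams(alpha_vdw=alpha_vdw, alpha_crf=alpha_crf),
    )
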