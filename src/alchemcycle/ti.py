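"""Thermodynamic integration over per-λ ⟨∂H/∂λ⟩ series.

ΔG(A→B) = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ, evaluated by trapezoidal quadrature over the
(possibly non-equidistant) λ schedule.  Per-λ ensemble means discard an
initial equilibration window (default 50 ps); their standard errors come
from block averaging, which accounts for the autocorrelation typical of
molecular-simulation time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DhdlSeries,
    FreeEnergyEstimate,
    InsufficientDataError,
    RangeError,
    DataValidationError,
    TransformationRun,
)

logger = logging.getLogger("alchemcycle")

#: default equilibration discard per λ-point (ps)
DEFAULT_DISCARD = 50.0
#: default curvature threshold for λ-schedule refinement (kJ·mol⁻¹ per λ²)
DEFAULT_CURVATURE_THRESHOLD = 100.0
#: minimum retained samples for a block-average error estimate
MIN_BLOCK_SAMPLES = 64
#: relative change defining the block-error plateau over two doublings
PLATEAU_RTOL = 0.05


@dataclass
class TICurve:
    """⟨∂H/∂λ⟩ as a function of λ, with standard errors.

    ``sampling_times`` records the per-λ production time actually used (ps).
    Optional ``state_from``/``state_to`` labels propagate into estimates.
    """

    lambdas: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    sampling_times: np.ndarray | None = None
    state_from: str = "A"
    state_to: str = "B"

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sems = np.asarray(self.sems, dtype=float)
        if not (self.lambdas.shape == self.means.shape == self.sems.shape):
            raise DataValidationError("lambdas/means/sems must have equal shapes")
        if np.any(np.diff(self.lambdas) <= 0):
            raise DataValidationError("λ values must be strictly increasing")
        if np.any(self.sems < 0):
            raise DataValidationError("standard errors must be ≥ 0")
        if self.sampling_times is not None:
            self.sampling_times = np.asarray(self.sampling_times, dtype=float)

    @property
    def n_points(self) -> int:
        return self.lambdas.size


@dataclass
class ConvergenceProfile:
    """ΔG re-estimated from truncated data, per simulation time per λ-point."""

    times: np.ndarray
    dg: np.ndarray
    group_dg: dict[str, np.ndarray] | None = None


def _retained(series: DhdlSeries, discard: float) -> np.ndarray:
    if discard < 0:
        raise DataValidationError("discard must be ≥ 0")
    if discard >= series.total_time:
        raise InsufficientDataError(
            f"discard {discard} ps leaves no samples (series ends at "
            f"{series.total_time} ps)"
        )
    return series.samples[series.times > discard]


def ensemble_mean(series: DhdlSeries, discard: float = DEFAULT_DISCARD) -> tuple[float, int]:
    """Arithmetic mean of ∂H/∂λ samples with time > ``discard`` (ps).

    Returns (mean, number of samples used).
    """
    kept = _retained(series, discard)
    if kept.size < 2:
        raise InsufficientDataError("fewer than 2 samples after discard")
    return float(np.mean(kept)), int(kept.size)


def block_error(series: DhdlSeries, discard: float = DEFAULT_DISCARD) -> float:
    """Block-averaging standard error of the mean ∂H/∂λ.

    The variance of block means is evaluated at geometrically growing block
    sizes; the estimate at the plateau (first size whose error changes by
    <5% over two consecutive doublings) is returned, falling back to the
    maximum observed estimate when no plateau is reached.  The result is
    never smaller than the naive independent-sample error σ/√n.
    """
    kept = _retained(series, discard)
    return _block_error_samples(kept)


def _block_error_samples(kept: np.ndarray) -> float:
    n = kept.size
    if n < MIN_BLOCK_SAMPLES:
        raise InsufficientDataError(
            f"block averaging needs ≥{MIN_BLOCK_SAMPLES} samples, got {n}"
        )
    naive = float(np.std(kept, ddof=1) / np.sqrt(n))
    if naive == 0.0:
        return 0.0
    estimates = []
    size = 1
    while n // size >= 4:  # need enough blocks for a variance of block means
        nb = n // size
        means = kept[: nb * size].reshape(nb, size).mean(axis=1)
        estimates.append(float(np.std(means, ddof=1) / np.sqrt(nb)))
        size *= 2
    plateau = max(estimates)
    for i in range(len(estimates) - 2):
        a, b, c = estimates[i : i + 3]
        if a > 0 and abs(b - a) / a < PLATEAU_RTOL and abs(c - b) / b < PLATEAU_RTOL:
            plateau = c
            break
    return max(plateau, naive)


def curve_from_run(
    run: TransformationRun,
    discard: float = DEFAULT_DISCARD,
    group: str | None = None,
    max_time: float | None = None,
) -> TICurve:
    """Build a TI curve from a run's series (optionally one group column,
    optionally truncating each series at ``max_time`` ps)."""
    lams, means, sems, times = [], [], [], []
    for s in run.series:
        if group is not None:
            if not s.group_samples or group not in s.group_samples:
                raise DataValidationError(
                    f"group {group!r} missing at λ={s.lambda_value}"
                )
            s = DhdlSeries(
                lambda_value=s.lambda_value,
                samples=s.group_samples[group],
                sample_interval=s.sample_interval,
                first_time=s.first_time,
                origin=s.origin,
            )
        samples, stimes = s.samples, s.times
        if max_time is not None:
            if max_time > s.total_time + 1e-9:
                raise RangeError(
                    f"requested time {max_time} ps exceeds sampled "
                    f"{s.total_time} ps at λ={s.lambda_value}"
                )
            keep = stimes <= max_time + 1e-9
            samples, stimes = samples[keep], stimes[keep]
        kept = samples[stimes > discard]
        if kept.size < 2:
            raise InsufficientDataError(
                f"λ={s.lambda_value}: fewer than 2 samples after discard"
            )
        lams.append(s.lambda_value)
        means.append(float(np.mean(kept)))
        if kept.size >= MIN_BLOCK_SAMPLES:
            sems.append(_block_error_samples(kept))
        else:
            sems.append(float(np.std(kept, ddof=1) / np.sqrt(kept.size)))
        times.append(float(stimes[-1]))
    return TICurve(
        lambdas=np.array(lams),
        means=np.array(means),
        sems=np.array(sems),
        sampling_times=np.array(times),
        state_from=run.state_from,
        state_to=run.state_to,
    )


def trapezoid_weights(lambdas: np.ndarray) -> np.ndarray:
    """Per-point quadrature weights of the composite trapezoid rule."""
    w = np.zeros_like(lambdas)
    d = np.diff(lambdas)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def integrate(curve: TICurve) -> FreeEnergyEstimate:
    """Trapezoidal TI over the curve.

    The uncertainty propagates per-λ standard errors assuming independence
    between λ-points (each comes from a separate simulation):
    σ² = Σ (wᵢ σᵢ)² with wᵢ the trapezoid weights.  If the curve does not
    span [0, 1] the covered interval is integrated and the estimate's method
    string is flagged ``partial``; no extrapolation is attempted.
    """
    if curve.n_points < 2:
        raise InsufficientDataError("TI needs at least 2 λ-points")
    method = "TI-trapezoid"
    if curve.lambdas[0] > 1e-9 or curve.lambdas[-1] < 1 - 1e-9:
        logger.warning(
            "TI curve covers only [%g, %g]; integrating the covered interval",
            curve.lambdas[0],
            curve.lambdas[-1],
        )
        method += f"-partial[{curve.lambdas[0]:g},{curve.lambdas[-1]:g}]"
    w = trapezoid_weights(curve.lambdas)
    value = float(np.dot(w, curve.means))
    unc = float(np.sqrt(np.sum((w * curve.sems) ** 2)))
    return FreeEnergyEstimate(
        value=value,
        uncertainty=unc,
        state_from=curve.state_from,
        state_to=curve.state_to,
        method=method,
    )


def integrate_run(
    run: TransformationRun, discard: float = DEFAULT_DISCARD
) -> FreeEnergyEstimate:
    """TI estimate of a run along its executed direction."""
    return integrate(curve_from_run(run, discard))


def suggest_lambdas(
    curve: TICurve, curvature_threshold: float = DEFAULT_CURVATURE_THRESHOLD
) -> list[float]:
    """Propose new λ-points where the curve bends sharply.

    For each interior point whose second divided difference
    f[λᵢ₋₁, λᵢ, λᵢ₊₁] exceeds ``curvature_threshold`` in magnitude
    (kJ·mol⁻¹ per λ²), the midpoints of both adjacent intervals are
    proposed; duplicates and existing λ values are removed.
    """
    if curve.n_points < 3:
        raise InsufficientDataError("refinement needs ≥3 λ-points")
    lam, y = curve.lambdas, curve.means
    proposals: set[float] = set()
    for i in range(1, curve.n_points - 1):
        s1 = (y[i] - y[i - 1]) / (lam[i] - lam[i - 1])
        s2 = (y[i + 1] - y[i]) / (lam[i + 1] - lam[i])
        dd = (s2 - s1) / (lam[i + 1] - lam[i - 1])
        if abs(dd) > curvature_threshold:
            proposals.add(round((lam[i - 1] + lam[i]) / 2, 12))
            proposals.add(round((lam[i] + lam[i + 1]) / 2, 12))
    existing = set(np.round(lam, 12))
    return sorted(p for p in proposals if p not in existing)


def convergence_profile(
    run: TransformationRun,
    time_grid: np.ndarray,
    discard: float = DEFAULT_DISCARD,
) -> ConvergenceProfile:
    """ΔG as a function of simulation time per λ-point.

    For each grid time t the TI estimate is recomputed using only samples in
    (discard, t] at every λ-point.  When group columns are present, per-group
    profiles are produced as well; their sum equals the total profile.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0 or np.any(np.diff(time_grid) <= 0):
        raise DataValidationError("time grid must be non-empty and strictly increasing")
    shortest = min(s.total_time for s in run.series)
    if time_grid[-1] > shortest + 1e-9:
        raise RangeError(
            f"grid extends to {time_grid[-1]} ps but shortest λ-point has "
            f"{shortest} ps"
        )
    dg = np.array(
        [integrate(curve_from_run(run, discard, max_time=t)).value for t in time_grid]
    )
    groups = run.group_names
    group_dg = None
    if groups:
        group_dg = {
            g: np.array(
                [
                    integrate(curve_from_run(run, discard, group=g, max_time=t)).value
                    for t in time_grid
                ]
            )
            for g in groups
        }
    return ConvergenceProfile(times=time_grid, dg=dg, group_dg=group_dg)


def decompose(
    run: TransformationRun, discard: float = DEFAULT_DISCARD
) -> dict[str, FreeEnergyEstimate]:
    """Per-interaction-group TI estimates (e.g. peptide-peptide /
    peptide-protein / peptide-solvent).  Group values sum to the total
    estimate because quadrature is linear and the group columns partition
    the total at load time."""
    groups = run.group_names  # raises on inconsistency
    if not groups:
        raise DataValidationError("run carries no group columns")
    return {g: integrate(curve_from_run(run, discard, group=g)) for g in groups}
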