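"""Combining run-level TI estimates: orientation, hysteresis, averages,
thermodynamic-cycle closure, and relative binding free energies.

Sign convention: every run-level ΔG is stored along the run's *executed*
direction; orientation onto a canonical direction (lexicographic
``state_from < state_to``) happens only here.  The relative binding free
energy of mutating ligand A into B is

    ΔΔG_bind(A→B) = ΔG_mutate,bound(A→B) − ΔG_mutate,solv(A→B),

and around any closed path of states the oriented edge values must sum to
zero (free energy is a state function); deviations beyond thermal noise
(default tolerance 2.5 kJ·mol⁻¹ ≈ RT at 298 K) indicate insufficient
sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import (
    CLOSURE_TOLERANCE,
    FreeEnergyEstimate,
    GraphError,
    ThermoCycle,
    TransformationRun,
    UsageError,
)
from . import ti

logger = logging.getLogger("alchemcycle")

#: ITC-derived reference ΔΔG_bind values (kJ·mol⁻¹) for the OppA KXK ligand
#: series, keyed by canonical mutation direction of the central residue.
EXPERIMENTAL_DDG = {("A", "G"): 7.5, ("G", "S"): -8.4, ("A", "S"): -0.9}


@dataclass(frozen=True)
class OrientedEstimate:
    """A run-level ΔG expressed along a canonical state pair."""

    state_from: str
    state_to: str
    value: float
    uncertainty: float
    source: str = ""
    was_inverted: bool = False


@dataclass
class RunEstimate:
    """One run's ΔG along its executed direction, with bookkeeping labels."""

    pair_from: str
    pair_to: str
    environment: str
    direction_tag: str
    replicate_id: str
    executed_from: str
    executed_to: str
    value: float
    uncertainty: float

    @property
    def estimate(self) -> FreeEnergyEstimate:
        return FreeEnergyEstimate(
            value=self.value,
            uncertainty=self.uncertainty,
            state_from=self.executed_from,
            state_to=self.executed_to,
        )


@dataclass
class CycleReport:
    """Closure of a thermodynamic cycle, per environment and in total."""

    path: tuple[str, ...]
    closures: dict[str, tuple[float, float]]  # env -> (value, uncertainty)
    total: tuple[float, float] | None
    tolerance: float
    passed: dict[str, bool]
    total_passed: bool | None


def orient(
    estimate: FreeEnergyEstimate, canonical: tuple[str, str], source: str = ""
) -> OrientedEstimate:
    """Express a run's ΔG along the canonical direction, negating if the run
    was executed in reverse."""
    a, b = canonical
    if (estimate.state_from, estimate.state_to) == (a, b):
        return OrientedEstimate(a, b, estimate.value, estimate.uncertainty, source, False)
    if (estimate.state_from, estimate.state_to) == (b, a):
        return OrientedEstimate(a, b, -estimate.value, estimate.uncertainty, source, True)
    raise UsageError(
        f"run direction {estimate.state_from}→{estimate.state_to} does not match "
        f"canonical pair {a}→{b}"
    )


def hysteresis(forward: FreeEnergyEstimate, backward: FreeEnergyEstimate) -> float:
    """|forward − sign-inverted backward| for one forward/backward run pair.

    Near-zero hysteresis indicates that both directions sample the same
    ensembles (converged transformation).
    """
    canonical = (forward.state_from, forward.state_to)
    if {backward.state_from, backward.state_to} != set(canonical):
        raise UsageError(
            f"hysteresis requires a matching pair, got "
            f"{forward.state_from}↔{forward.state_to} vs "
            f"{backward.state_from}↔{backward.state_to}"
        )
    return abs(orient(forward, canonical).value - orient(backward, canonical).value)


def combine(estimates: list[OrientedEstimate]) -> FreeEnergyEstimate:
    """Average oriented estimates of one transformation.

    The value is the arithmetic mean; the uncertainty is the standard error
    of the mean for n ≥ 2, else the single estimate's own uncertainty.
    """
    if not estimates:
        raise UsageError("combine needs at least one estimate")
    pairs = {(e.state_from, e.state_to) for e in estimates}
    if len(pairs) > 1:
        raise UsageError(f"estimates oriented to different directions: {pairs}")
    values = np.array([e.value for e in estimates])
    if values.size >= 2:
        unc = float(np.std(values, ddof=1) / np.sqrt(values.size))
    else:
        unc = estimates[0].uncertainty
    a, b = estimates[0].state_from, estimates[0].state_to
    return FreeEnergyEstimate(
        value=float(np.mean(values)),
        uncertainty=unc,
        state_from=a,
        state_to=b,
        method=f"mean-of-{values.size}",
    )


def ddg_bind(
    bound: FreeEnergyEstimate, solvent: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """Relative binding free energy: bound-state mutation ΔG minus
    solvent-state mutation ΔG, with root-sum-square uncertainty."""
    if (bound.state_from, bound.state_to) != (solvent.state_from, solvent.state_to):
        raise UsageError(
            f"direction mismatch: bound {bound.state_from}→{bound.state_to} vs "
            f"solvent {solvent.state_from}→{solvent.state_to}"
        )
    return FreeEnergyEstimate(
        value=bound.value - solvent.value,
        uncertainty=float(np.hypot(bound.uncertainty, solvent.uncertainty)),
        state_from=bound.state_from,
        state_to=bound.state_to,
        method="ddG-bind",
    )


def cycle_closure(cycle: ThermoCycle, path: list[str]) -> CycleReport:
    """Sum oriented edges along a closed path, per environment.

    The total closure (bound − solvent) is reported when both environments
    are present.  A closure passes when |value| ≤ the cycle's tolerance.
    """
    if len(path) < 3 or path[0] != path[-1]:
        raise UsageError("path must return to its starting state")
    closures: dict[str, tuple[float, float]] = {}
    passed: dict[str, bool] = {}
    for env in cycle.environments:
        total = 0.0
        var = 0.0
        for a, b in zip(path, path[1:]):
            edge = cycle.get_edge(a, b, env)  # GraphError if absent
            total += edge.value
            var += edge.uncertainty**2
        closures[env] = (total, float(np.sqrt(var)))
        passed[env] = abs(total) <= cycle.closure_tolerance
    total_closure = None
    total_passed = None
    if "bound" in closures and "solvent" in closures:
        tv = closures["bound"][0] - closures["solvent"][0]
        tu = float(np.hypot(closures["bound"][1], closures["solvent"][1]))
        total_closure = (tv, tu)
        total_passed = abs(tv) <= cycle.closure_tolerance
    return CycleReport(
        path=tuple(path),
        closures=closures,
        total=total_closure,
        tolerance=cycle.closure_tolerance,
        passed=passed,
        total_passed=total_passed,
    )


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------


def estimates_from_runs(
    runs: list[TransformationRun], discard: float = ti.DEFAULT_DISCARD
) -> list[RunEstimate]:
    """Integrate every run and wrap the results as RunEstimate records."""
    records = []
    for run in runs:
        est = ti.integrate_run(run, discard)
        a, b = run.pair
        records.append(
            RunEstimate(
                pair_from=a,
                pair_to=b,
                environment=run.environment,
                direction_tag=run.direction_tag,
                replicate_id=run.replicate_id,
                executed_from=run.state_from,
                executed_to=run.state_to,
                value=est.value,
                uncertainty=est.uncertainty,
            )
        )
    return records


def summary_table(
    records: list[RunEstimate],
    closure_tolerance: float = CLOSURE_TOLERANCE,
    experimental: dict[tuple[str, str], float] | None = None,
) -> dict:
    """Build the full per-transformation summary.

    For every canonical transformation pair: the individual oriented
    estimates, per-environment averages, ΔΔG_bind (when both environments
    are present), and per-replicate hysteresis.  When all three pairs of a
    triangle are present in an environment, the cycle-closure row is added.

    Returns a dict with keys ``pairs`` (per-pair summaries), ``cycle``
    (a CycleReport or None) and ``frame`` (a tidy DataFrame mirroring the
    per-run / average / ΔΔG table layout).
    """
    pairs = sorted({(r.pair_from, r.pair_to) for r in records})
    result: dict = {"pairs": {}, "cycle": None}
    rows: list[dict] = []
    cycle = ThermoCycle(closure_tolerance=closure_tolerance)
    for pair in pairs:
        per_env: dict[str, FreeEnergyEstimate] = {}
        pair_info: dict = {"oriented": {}, "average": {}, "hysteresis": {}, "ddg": None}
        for env in ("solvent", "bound"):
            recs = [r for r in records if (r.pair_from, r.pair_to) == pair and r.environment == env]
            if not recs:
                continue
            oriented = [
                orient(r.estimate, pair, source=f"{env}:{r.replicate_id}:{r.direction_tag}")
                for r in recs
            ]
            avg = combine(oriented)
            per_env[env] = avg
            cycle.add_edge(avg, env)
            pair_info["oriented"][env] = oriented
            pair_info["average"][env] = avg
            for r in recs:
                rows.append(
                    {
                        "transformation": f"{pair[0]}->{pair[1]}",
                        "environment": env,
                        "row": f"{r.executed_from}->{r.executed_to} ({r.direction_tag} {r.replicate_id})",
                        "value": r.value,
                        "uncertainty": r.uncertainty,
                    }
                )
            # hysteresis per forward/backward replicate pairing
            by_rep: dict[str, dict[str, RunEstimate]] = {}
            for r in recs:
                by_rep.setdefault(r.replicate_id, {})[r.direction_tag] = r
            hyst = {
                rep: hysteresis(d["forward"].estimate, d["backward"].estimate)
                for rep, d in by_rep.items()
                if "forward" in d and "backward" in d
            }
            pair_info["hysteresis"][env] = hyst
            rows.append(
                {
                    "transformation": f"{pair[0]}->{pair[1]}",
                    "environment": env,
                    "row": "average",
                    "value": avg.value,
                    "uncertainty": avg.uncertainty,
                }
            )
        if "bound" in per_env and "solvent" in per_env:
            ddg = ddg_bind(per_env["bound"], per_env["solvent"])
            pair_info["ddg"] = ddg
            row = {
                "transformation": f"{pair[0]}->{pair[1]}",
                "environment": "both",
                "row": "ddG_bind",
                "value": ddg.value,
                "uncertainty": ddg.uncertainty,
            }
            if experimental and pair in experimental:
                row["experimental"] = experimental[pair]
            rows.append(row)
        else:
            missing = {"solvent", "bound"} - set(per_env)
            logger.warning("pair %s lacks %s runs; ΔΔG not available", pair, missing)
        result["pairs"][pair] = pair_info
    states = sorted({s for p in pairs for s in p})
    if len(states) == 3 and len(pairs) == 3:
        path = [states[0], states[1], states[2], states[0]]
        try:
            report = cycle_closure(cycle, path)
        except GraphError:
            report = None
        result["cycle"] = report
        if report is not None:
            for env, (val, unc) in report.closures.items():
                rows.append(
                    {
                        "transformation": "cycle",
                        "environment": env,
                        "row": "closure",
                        "value": val,
                        "uncertainty": unc,
                    }
                )
            if report.total is not None:
                rows.append(
                    {
                        "transformation": "cycle",
                        "environment": "both",
                        "row": "closure",
                        "value": report.total[0],
                        "uncertainty": report.total[1],
                    }
                )
    result["frame"] = pd.DataFrame(rows)
    return result


# ---------------------------------------------------------------------------
# Bundled worked example
# ---------------------------------------------------------------------------


def load_reference_runs() -> list[RunEstimate]:
    """Run-level TI results for the OppA KXK tripeptide series (worked example).

    States are labelled by the central residue of the KXK ligand (A = KAK,
    G = KGK, S = KSK).  Values are stored along each run's executed
    direction.  One bound-state entry (forward S→G) is published with a sign
    inconsistent with the convention satisfied by every other row; it is
    flagged ``sign_corrected`` in the bundled CSV, and the loader interprets
    its printed value as already oriented along the canonical G→S direction.
    """
    with resources.files("alchemcycle.data").joinpath("oppa_kxk_runs.csv").open() as fh:
        frame = pd.read_csv(fh)
    records = []
    for row in frame.itertuples():
        value = float(row.value)
        if bool(row.sign_corrected):
            value = -value  # printed value was already canonical-oriented
        records.append(
            RunEstimate(
                pair_from=str(row.pair_from),
                pair_to=str(row.pair_to),
                environment=str(row.environment),
                direction_tag=str(row.direction),
                replicate_id=str(row.replicate),
                executed_from=str(row.executed_from),
                executed_to=str(row.executed_to),
                value=value,
                uncertainty=float(row.uncertainty),
            )
        )
    return records
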