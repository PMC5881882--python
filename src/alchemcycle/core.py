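"""Domain types and file I/O for alchemical free-energy analysis.

Conventions used throughout the package: energies in kJ·mol⁻¹, lengths in
nm, times in ps.  λ is the alchemical coupling parameter on [0, 1], with
λ = 0 the pure A state and λ = 1 the pure B state.

The ∂H/∂λ file dialect is a plain TSV with one metadata comment line
``# lambda=<value>`` followed by a tab-separated column header (time column
in ps, a total ∂H/∂λ column, and optional per-interaction-group columns
whose per-row sum must equal the total).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("alchemcycle")

#: tolerance (kJ·mol⁻¹) for the group-columns-partition-the-total check
GROUP_SUM_TOL = 1e-6
#: tolerance (ps) for the uniform-time-step check
TIME_STEP_TOL = 1e-6
#: default cycle-closure tolerance, ≈ RT at 298 K (kJ·mol⁻¹)
CLOSURE_TOLERANCE = 2.5

WATER_RESIDUE_NAMES = frozenset({"SOL", "HOH", "WAT"})
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})


class AlchemcycleError(Exception):
    """Base class for all errors raised by this package."""


class FileFormatError(AlchemcycleError):
    """A file does not conform to the expected dialect."""


class DataValidationError(AlchemcycleError):
    """Data violates a domain invariant (e.g. group sums, λ ordering)."""


class ManifestError(AlchemcycleError):
    """A run manifest is inconsistent (duplicates, bad schema)."""


class InsufficientDataError(AlchemcycleError):
    """Not enough samples/points for the requested estimate."""


class UsageError(AlchemcycleError):
    """An operation was called with incompatible arguments."""


class RangeError(AlchemcycleError):
    """A requested grid/time range exceeds the available data."""


class GraphError(AlchemcycleError):
    """A thermodynamic-cycle path references a missing edge."""


class NumericalDegeneracyError(AlchemcycleError):
    """Geometry too degenerate for a well-defined result."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DhdlSeries:
    """One λ-point's ∂H/∂λ samples.

    Parameters
    ----------
    lambda_value : float
        Coupling parameter of the simulation that produced the samples.
    samples : ndarray
        Total ∂H/∂λ per stored frame (kJ·mol⁻¹).
    sample_interval : float
        Spacing between stored frames (ps).
    first_time : float
        Time stamp of the first sample (ps); defaults to one interval.
    group_samples : dict[str, ndarray], optional
        Per-interaction-group decomposition of the total (e.g.
        "peptide-peptide", "peptide-protein", "peptide-solvent").
    origin : str
        File path or generator id the series came from.
    """

    lambda_value: float
    samples: np.ndarray
    sample_interval: float
    first_time: float | None = None
    group_samples: dict[str, np.ndarray] | None = None
    origin: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0.0 <= self.lambda_value <= 1.0:
            raise DataValidationError(
                f"lambda_value {self.lambda_value} outside [0, 1]"
            )
        if self.samples.ndim != 1:
            raise DataValidationError("samples must be one-dimensional")
        if self.sample_interval <= 0:
            raise DataValidationError("sample_interval must be positive")
        if self.first_time is None:
            self.first_time = self.sample_interval
        if self.group_samples is not None:
            groups = {k: np.asarray(v, dtype=float) for k, v in self.group_samples.items()}
            for name, values in groups.items():
                if values.shape != self.samples.shape:
                    raise DataValidationError(
                        f"group column {name!r} length {values.size} != total length "
                        f"{self.samples.size}"
                    )
            total = np.sum(list(groups.values()), axis=0)
            worst = float(np.max(np.abs(total - self.samples))) if self.samples.size else 0.0
            if worst > GROUP_SUM_TOL:
                raise DataValidationError(
                    f"group columns do not partition the total: max deviation "
                    f"{worst:.3g} kJ/mol exceeds {GROUP_SUM_TOL:g}"
                )
            self.group_samples = groups

    @property
    def times(self) -> np.ndarray:
        """Time stamp per sample (ps)."""
        return self.first_time + self.sample_interval * np.arange(self.samples.size)

    @property
    def total_time(self) -> float:
        """Time stamp of the last sample (ps)."""
        return float(self.times[-1]) if self.samples.size else 0.0

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.group_samples)) if self.group_samples else ()


@dataclass
class TransformationRun:
    """An ordered set of per-λ series for one alchemical transformation.

    ``state_from``/``state_to`` are the executed direction of the run: for a
    backward run they name the reversed transformation, and the series are
    expressed in the run's own λ frame (λ = 0 is the run's start state).
    """

    state_from: str
    state_to: str
    environment: str
    direction_tag: str
    replicate_id: str
    series: list[DhdlSeries]
    seeded_from: str | None = None

    def __post_init__(self) -> None:
        if self.state_from == self.state_to:
            raise DataValidationError("state_from and state_to must differ")
        if self.environment not in ("solvent", "bound"):
            raise DataValidationError(f"unknown environment {self.environment!r}")
        if self.direction_tag not in ("forward", "backward"):
            raise DataValidationError(f"unknown direction_tag {self.direction_tag!r}")
        lams = [s.lambda_value for s in self.series]
        if len(lams) < 2:
            raise DataValidationError("a run needs at least 2 λ-points")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise DataValidationError("λ values must be strictly increasing")

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([s.lambda_value for s in self.series])

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered transformation pair, lexicographically sorted."""
        return tuple(sorted((self.state_from, self.state_to)))  # type: ignore[return-value]

    @property
    def group_names(self) -> tuple[str, ...]:
        names = {s.group_names for s in self.series}
        if len(names) > 1:
            raise DataValidationError("inconsistent group names across λ-points")
        return names.pop()


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG value with uncertainty, directed from ``state_from`` to ``state_to``."""

    value: float
    uncertainty: float
    state_from: str = "A"
    state_to: str = "B"
    method: str = "TI-trapezoid"

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise DataValidationError("uncertainty must be ≥ 0")

    def reversed(self) -> "FreeEnergyEstimate":
        """The same estimate along the opposite direction (negated value)."""
        return replace(
            self, value=-self.value, state_from=self.state_to, state_to=self.state_from
        )

    def __neg__(self) -> "FreeEnergyEstimate":
        return self.reversed()


@dataclass
class ThermoCycle:
    """States plus directed, per-environment free-energy edges.

    Edges are keyed ``(state_from, state_to, environment)``; querying the
    reverse of a stored edge returns its negation (state-function identity).
    """

    edges: dict[tuple[str, str, str], FreeEnergyEstimate] = field(default_factory=dict)
    closure_tolerance: float = CLOSURE_TOLERANCE

    @property
    def states(self) -> frozenset[str]:
        return frozenset(s for a, b, _ in self.edges for s in (a, b))

    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(sorted({env for _, _, env in self.edges}))

    def add_edge(self, estimate: FreeEnergyEstimate, environment: str) -> None:
        self.edges[(estimate.state_from, estimate.state_to, environment)] = estimate

    def get_edge(self, state_from: str, state_to: str, environment: str) -> FreeEnergyEstimate:
        key = (state_from, state_to, environment)
        if key in self.edges:
            return self.edges[key]
        rkey = (state_to, state_from, environment)
        if rkey in self.edges:
            return self.edges[rkey].reversed()
        raise GraphError(f"no edge {state_from}→{state_to} in environment {environment!r}")


@dataclass
class Trajectory:
    """Coordinate frames with atom metadata and per-frame rectangular boxes.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm.  ``roles`` assigns each
    atom one of ``backbone`` / ``side-chain`` / ``water-oxygen`` / ``other``.
    ``box`` is (n_frames, 3) edge lengths in nm, or None when unknown.
    """

    coords: np.ndarray
    atom_names: list[str]
    residue_names: list[str]
    residue_indices: list[int]
    roles: np.ndarray
    box: np.ndarray | None = None
    frame_interval: float = 1.0  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataValidationError("coords must have shape (frames, atoms, 3)")
        n_atoms = self.coords.shape[1]
        for name, seq in (
            ("atom_names", self.atom_names),
            ("residue_names", self.residue_names),
            ("residue_indices", self.residue_indices),
        ):
            if len(seq) != n_atoms:
                raise DataValidationError(f"{name} length != atom count")
        self.roles = np.asarray(self.roles, dtype=object)
        if self.roles.shape != (n_atoms,):
            raise DataValidationError("roles length != atom count")
        if not np.all(np.isfinite(self.coords)):
            raise DataValidationError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise DataValidationError("box must have shape (frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, role: str) -> np.ndarray:
        """Indices of atoms carrying the given role tag."""
        return np.flatnonzero(self.roles == role)


@dataclass(frozen=True)
class SoftcoreParams:
    """Softness parameters of the softcore nonbonded interactions.

    ``alpha_vdw`` is dimensionless, ``alpha_crf`` is in nm².  The defaults are
    the increased values needed for acceptable convergence of side-chain
    creation/annihilation in the KXK tripeptide transformations.
    """

    alpha_vdw: float = 1.0
    alpha_crf: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha_vdw) and math.isfinite(self.alpha_crf)):
            raise DataValidationError("softcore parameters must be finite")
        if self.alpha_vdw < 0 or self.alpha_crf < 0:
            raise DataValidationError("softcore parameters must be ≥ 0")


# ---------------------------------------------------------------------------
# ∂H/∂λ files
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = {"time": "time", "total": "dhdl"}


def assign_role(atom_name: str, residue_name: str) -> str:
    """Role tag from atom/residue naming conventions."""
    if residue_name.upper() in WATER_RESIDUE_NAMES:
        return "water-oxygen" if atom_name.upper().startswith("O") else "other"
    if atom_name.upper() in BACKBONE_ATOM_NAMES:
        return "backbone"
    return "side-chain"


def read_dhdl_file(path: str | Path, dialect: Mapping[str, str] | None = None) -> DhdlSeries:
    """Read one λ-point's ∂H/∂λ TSV file.

    The file starts with ``# lambda=<value>``, then a tab-separated header
    naming the time column and total column (per ``dialect``, defaults
    ``time``/``dhdl``); any remaining columns are interaction groups and must
    sum row-wise to the total within 1e-6 kJ·mol⁻¹.
    """
    path = Path(path)
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "lambda" not in first:
        raise FileFormatError(f"{path}: missing '# lambda=<value>' header line")
    try:
        lam = float(first.split("=", 1)[1])
    except (IndexError, ValueError) as exc:
        raise FileFormatError(f"{path}: cannot parse λ from header {first!r}") from exc

    frame = pd.read_csv(path, sep="\t", skiprows=1)
    for key in ("time", "total"):
        if dia[key] not in frame.columns:
            raise FileFormatError(f"{path}: missing required column {dia[key]!r}")
    times = frame[dia["time"]].to_numpy(dtype=float)
    if times.size < 2:
        raise FileFormatError(f"{path}: need at least 2 rows")
    steps = np.diff(times)
    bad = np.flatnonzero(np.abs(steps - steps[0]) > TIME_STEP_TOL)
    if bad.size:
        raise FileFormatError(
            f"{path}: non-uniform time step at data row {int(bad[0]) + 2} "
            f"(Δt={steps[bad[0]]:.6g} vs {steps[0]:.6g} ps)"
        )
    group_cols = [c for c in frame.columns if c not in (dia["time"], dia["total"])]
    groups = (
        {c: frame[c].to_numpy(dtype=float) for c in group_cols} if group_cols else None
    )
    return DhdlSeries(
        lambda_value=lam,
        samples=frame[dia["total"]].to_numpy(dtype=float),
        sample_interval=float(steps[0]),
        first_time=float(times[0]),
        group_samples=groups,
        origin=str(path),
    )


def write_dhdl_file(
    series: DhdlSeries, path: str | Path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write a DhdlSeries in the TSV dialect that :func:`read_dhdl_file` reads."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    columns: dict[str, np.ndarray] = {dia["time"]: series.times, dia["total"]: series.samples}
    if series.group_samples:
        columns.update(series.group_samples)
    frame = pd.DataFrame(columns)
    with open(path, "w") as fh:
        fh.write(f"# lambda={float(series.lambda_value)!r}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def read_run_manifest(path: str | Path) -> list[TransformationRun]:
    """Load a YAML/JSON manifest of transformation runs and their dhdl files.

    Each entry carries state labels, environment, direction, replicate id and
    the per-λ file paths (relative paths are resolved against the manifest's
    directory).  Duplicate (pair, environment, direction, replicate)
    combinations are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or not doc.get("runs"):
        logger.warning("manifest %s lists no runs", path)
        return []
    runs: list[TransformationRun] = []
    seen: set[tuple] = set()
    for entry in doc["runs"]:
        try:
            files = entry["files"]
            run_meta = dict(
                state_from=str(entry["state_from"]),
                state_to=str(entry["state_to"]),
                environment=str(entry["environment"]),
                direction_tag=str(entry["direction"]),
                replicate_id=str(entry["replicate"]),
                seeded_from=entry.get("seeded_from"),
            )
        except KeyError as exc:
            raise ManifestError(f"{path}: run entry missing key {exc}") from exc
        key = (
            tuple(sorted((run_meta["state_from"], run_meta["state_to"]))),
            run_meta["environment"],
            run_meta["direction_tag"],
            run_meta["replicate_id"],
        )
        if key in seen:
            raise ManifestError(f"{path}: duplicate run {key}")
        seen.add(key)
        series = []
        for rel in files:
            fpath = Path(rel)
            if not fpath.is_absolute():
                fpath = path.parent / fpath
            if not fpath.exists():
                raise IOError(f"{path}: referenced dhdl file {fpath} does not exist")
            series.append(read_dhdl_file(fpath))
        series.sort(key=lambda s: s.lambda_value)
        runs.append(TransformationRun(series=series, **run_meta))
    return runs


def write_run_manifest(
    entries: Sequence[Mapping], path: str | Path
) -> None:
    """Write a manifest consumable by :func:`read_run_manifest`.

    Each entry is a mapping with keys ``state_from``, ``state_to``,
    ``environment``, ``direction``, ``replicate``, ``files`` and optionally
    ``seeded_from``.
    """
    doc = {"runs": [dict(e) for e in entries]}
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a multi-frame trajectory (``pdb-frames`` or ``xyz-frames``).

    PDB coordinates (Å) are converted to nm.  Role tags are assigned from
    residue/atom names: the oxygen of a SOL/HOH/WAT residue is a water
    oxygen; N, CA, C, O of non-water residues are backbone.
    """
    path = Path(path)
    if format is None:
        format = "pdb-frames" if path.suffix.lower() == ".pdb" else "xyz-frames"
    if format == "pdb-frames":
        return _read_pdb_frames(path)
    if format == "xyz-frames":
        return _read_xyz_frames(path)
    raise UsageError(f"unknown trajectory format {format!r}")


def _read_pdb_frames(path: Path) -> Trajectory:
    import mdtraj

    try:
        traj = mdtraj.load_pdb(str(path), standard_names=False)
    except Exception as exc:  # mdtraj raises assorted types on malformed input
        raise FileFormatError(f"{path}: cannot parse multi-MODEL PDB ({exc})") from exc
    top = traj.topology
    atom_names = [a.name for a in top.atoms]
    res_names = [a.residue.name for a in top.atoms]
    res_ids = [a.residue.resSeq for a in top.atoms]
    roles = np.array(
        [assign_role(n, r) for n, r in zip(atom_names, res_names)], dtype=object
    )
    box = traj.unitcell_lengths  # already nm, (frames, 3) or None
    return Trajectory(
        coords=traj.xyz.astype(float),  # mdtraj stores nm
        atom_names=atom_names,
        residue_names=res_names,
        residue_indices=res_ids,
        roles=roles,
        box=None if box is None else np.asarray(box, dtype=float),
    )


def _read_xyz_frames(path: Path) -> Trajectory:
    """Repeated-block XYZ: natoms line, comment (optionally ``box=x,y,z``),
    then ``name x y z`` rows in nm.  Waters are atoms named OW."""
    frames: list[np.ndarray] = []
    names: list[str] = []
    boxes: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FileFormatError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        if "box=" in comment:
            box = np.array([float(v) for v in comment.split("box=")[1].split(",")])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FileFormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        frame_names = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FileFormatError(f"{path}: bad atom row at line {i + 3 + j}")
            frame_names.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        if not names:
            names = frame_names
        elif frame_names != names:
            raise FileFormatError(f"{path}: inconsistent atom names/count across frames")
        frames.append(coords)
        boxes.append(box if box is not None else np.full(3, np.nan))
        i += 2 + n
    if not frames:
        raise FileFormatError(f"{path}: no frames found")
    box_arr: np.ndarray | None = np.array(boxes)
    if np.any(np.isnan(box_arr)):
        box_arr = None
    roles = np.array(
        ["water-oxygen" if nm.upper() == "OW" else "other" for nm in names], dtype=object
    )
    res_names = ["SOL" if r == "water-oxygen" else "UNK" for r in roles]
    return Trajectory(
        coords=np.array(frames),
        atom_names=names,
        residue_names=res_names,
        residue_indices=list(range(1, len(names) + 1)),
        roles=roles,
        box=box_arr,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Serialize structured results to JSON (17 significant digits, round-trip
    safe) or CSV (row-oriented; results must be a DataFrame or list of dicts)."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2)
    elif format == "csv":
        frame = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
        frame.to_csv(path, index=False)
    else:
        raise UsageError(f"unknown report format {format!r}")


def read_report(path: str | Path):
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
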