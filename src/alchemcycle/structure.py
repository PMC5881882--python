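"""Structural diagnostics on trajectories: superposition, dihedral
distributions, water-occupancy grids and cavity water counts.

These analyses target the slow-solvent-relaxation diagnosis in a
water-filled binding site: dihedral distributions compare conformational
sampling along forward vs backward transformations, and the occupancy grid
visualizes where water resides (and fails to return) around the mutated
side chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    DataValidationError,
    InsufficientDataError,
    NumericalDegeneracyError,
    Trajectory,
    UsageError,
)

logger = logging.getLogger("alchemcycle")

#: default occupancy-grid spacing (nm)
DEFAULT_GRID_SPACING = 0.2
#: default relative-occupancy classification levels
DEFAULT_LEVELS = (0.3, 0.5, 0.9)


@dataclass
class DihedralSeries:
    """Per-frame values of one named dihedral angle (degrees, (−180, 180])."""

    name: str
    angles: np.ndarray
    atom_indices: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            np.any(self.angles <= -180.0) or np.any(self.angles > 180.0)
        ):
            raise DataValidationError("angles must lie in (−180, 180]")


@dataclass
class OccupancyGrid:
    """Mean water count per frame on a regular 3-D grid.

    ``counts`` has shape (nx, ny, nz); node (i, j, k) sits at
    ``origin + spacing * (i, j, k)``.  Relative occupancy is
    ``counts / counts.max()``.
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    region: tuple[np.ndarray, np.ndarray]

    @property
    def max_value(self) -> float:
        return float(self.counts.max()) if self.counts.size else 0.0

    @property
    def relative(self) -> np.ndarray:
        m = self.max_value
        if m <= 0:
            raise UsageError("grid has no occupancy; relative scale undefined")
        return self.counts / m

    def node_position(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)


@dataclass
class CavityWaterSeries:
    """Per-frame water count in a region, with its relaxation time.

    ``relaxation_time`` is the integrated autocorrelation time of the count
    series in ps (sum of the autocorrelation function from lag 0 up to, but
    excluding, the first non-positive lag, times the frame interval).  It is
    None for a constant series (zero variance: undefined).
    """

    counts: np.ndarray
    frame_interval: float
    relaxation_time: float | None


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translations aligning mobile onto
    reference in the least-squares sense (reflections excluded)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    return rot, mc, rc


def superpose(traj: Trajectory, reference_frame: int = 0, selection: str = "backbone") -> Trajectory:
    """Rigid-body least-squares fit of every frame onto a reference frame.

    Each frame is rotated/translated so the RMSD of the selected atoms (by
    role tag) to the reference frame is minimal; the transformation is
    applied to all atoms.  Requires ≥3 non-collinear selected atoms.
    """
    idx = traj.select(selection)
    if idx.size < 3:
        raise UsageError(f"selection {selection!r} matches {idx.size} atoms; need ≥3")
    ref = traj.coords[reference_frame, idx]
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise UsageError("selected atoms are collinear; superposition is underdetermined")
    fitted = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, mc, rc = _kabsch(traj.coords[f, idx], ref)
        fitted[f] = (traj.coords[f] - mc) @ rot + rc
    return Trajectory(
        coords=fitted,
        atom_names=list(traj.atom_names),
        residue_names=list(traj.residue_names),
        residue_indices=list(traj.residue_indices),
        roles=traj.roles.copy(),
        box=None if traj.box is None else traj.box.copy(),
        frame_interval=traj.frame_interval,
    )


def selection_rmsd(traj: Trajectory, reference_frame: int, selection: str) -> np.ndarray:
    """Per-frame RMSD (nm) of the selected atoms to the reference frame,
    without fitting."""
    idx = traj.select(selection)
    diff = traj.coords[:, idx] - traj.coords[reference_frame, idx]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, IUPAC convention) of four points.

    Zero for a planar cis arrangement, 180° for trans; positive for a
    clockwise rotation of the far bond viewed along p2→p3.  Result lies in
    (−180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-12:
            raise NumericalDegeneracyError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise NumericalDegeneracyError("collinear points: torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def dihedral_series(
    traj: Trajectory, indices: tuple[int, int, int, int], name: str = ""
) -> DihedralSeries:
    """Evaluate one dihedral over all frames of a trajectory."""
    i, j, k, l = indices
    angles = np.array(
        [
            dihedral_angle(traj.coords[f, i], traj.coords[f, j], traj.coords[f, k], traj.coords[f, l])
            for f in range(traj.n_frames)
        ]
    )
    return DihedralSeries(name=name or f"dihedral[{i},{j},{k},{l}]", angles=angles, atom_indices=indices)


def angle_histogram(series: DihedralSeries, bin_width: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a dihedral series over (−180, 180], normalized so the
    maximum bin equals 1 (the "n.occ." normalization used for distribution
    overlays).

    Returns (bin_edges, normalized_counts); ``bin_width`` must divide 360.
    """
    if series.angles.size == 0:
        raise UsageError("cannot histogram an empty series")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise UsageError(f"bin width {bin_width} does not divide 360")
    n_bins = int(round(n_bins))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    # right-inclusive binning so the domain is (−180, 180]
    idx = np.digitize(series.angles, edges, right=True) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return edges, counts / counts.max()


def histogram_chi2(
    a: DihedralSeries, b: DihedralSeries, bin_width: float = 10.0
) -> tuple[float, float]:
    """Two-sample chi-square comparison of dihedral distributions.

    Pools bins with small expected counts; returns (statistic, p-value).
    Used to test that forward and backward transformation runs sample the
    same dihedral distribution.
    """
    from scipy import stats

    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    ca = np.bincount(
        np.clip(np.digitize(a.angles, edges, right=True) - 1, 0, n_bins - 1), minlength=n_bins
    )
    cb = np.bincount(
        np.clip(np.digitize(b.angles, edges, right=True) - 1, 0, n_bins - 1), minlength=n_bins
    )
    keep = (ca + cb) >= 5
    obs = np.array([np.append(ca[keep], ca[~keep].sum()), np.append(cb[keep], cb[~keep].sum())])
    obs = obs[:, obs.sum(axis=0) > 0]
    stat, p, _, _ = stats.chi2_contingency(obs)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Water occupancy
# ---------------------------------------------------------------------------


def _wrap_to_region(coords: np.ndarray, center: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image shift of coordinates towards the region center."""
    if box is None:
        return coords
    return coords - box * np.round((coords - center) / box)


def _region_arrays(region) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if lo.shape != (3,) or hi.shape != (3,) or np.any(hi <= lo):
        raise UsageError("region must be ((x0,y0,z0), (x1,y1,z1)) with hi > lo")
    return lo, hi


def occupancy_grid(
    traj: Trajectory, region, spacing: float = DEFAULT_GRID_SPACING
) -> OccupancyGrid:
    """Average water occurrence on a regular grid over a superposed trajectory.

    Every water oxygen inside the axis-aligned ``region`` is assigned to its
    nearest grid node per frame (Euclidean; exact ties go to the
    lexicographically smallest node index); node values are mean counts per
    frame.  The minimum-image convention is applied towards the region
    center before assignment when box dimensions are available.
    """
    if spacing <= 0:
        raise UsageError("grid spacing must be positive")
    lo, hi = _region_arrays(region)
    shape = np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1
    counts = np.zeros(shape)
    waters = traj.select("water-oxygen")
    center = (lo + hi) / 2
    for f in range(traj.n_frames):
        pos = traj.coords[f, waters]
        box = traj.box[f] if traj.box is not None else None
        pos = _wrap_to_region(pos, center, box)
        inside = np.all((pos >= lo - 1e-9) & (pos <= hi + 1e-9), axis=1)
        if not np.any(inside):
            continue
        frac = (pos[inside] - lo) / spacing
        # nearest node with .5 ties resolved towards the lower index
        idx = np.ceil(frac - 0.5).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        np.add.at(counts, tuple(idx.T), 1.0)
    if not waters.size:
        logger.warning("trajectory contains no water oxygens; grid is empty")
    return OccupancyGrid(
        origin=lo,
        spacing=spacing,
        counts=counts / traj.n_frames,
        n_frames=traj.n_frames,
        region=(lo, hi),
    )


def classify_grid(
    grid: OccupancyGrid, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> dict[float, list[tuple[int, int, int]]]:
    """Label grid nodes by the highest relative-occupancy level they meet.

    Relative occupancy is node value / grid maximum (the maximum
    corresponding to bulk-water-like occupancy).  Nodes below the lowest
    level are unclassified and omitted.
    """
    rel = grid.relative  # raises UsageError on an all-zero grid
    levels = tuple(sorted(levels))
    out: dict[float, list[tuple[int, int, int]]] = {lv: [] for lv in levels}
    it = np.ndindex(*rel.shape)
    for node in it:
        r = rel[node]
        best = None
        for lv in levels:
            if r >= lv:
                best = lv
        if best is not None:
            out[best].append(node)
    return out


def grid_to_text(grid: OccupancyGrid) -> str:
    """Plain-text density-map export: origin, spacing, dimensions, values."""
    lines = [
        f"origin\t{grid.origin[0]:.6g}\t{grid.origin[1]:.6g}\t{grid.origin[2]:.6g}",
        f"spacing\t{grid.spacing:.6g}",
        "shape\t" + "\t".join(str(s) for s in grid.counts.shape),
        f"frames\t{grid.n_frames}",
    ]
    for node in np.ndindex(*grid.counts.shape):
        v = grid.counts[node]
        if v > 0:
            lines.append(f"{node[0]}\t{node[1]}\t{node[2]}\t{v:.10g}")
    return "\n".join(lines) + "\n"


def cavity_water_count(traj: Trajectory, region) -> CavityWaterSeries:
    """Per-frame water-oxygen count inside a region, with relaxation time.

    Fluctuations in this count occurring on a timescale comparable to or
    longer than the sampled time signal slow water-network relaxation.
    Needs ≥10 frames; a constant series has undefined relaxation time.
    """
    if traj.n_frames < 10:
        raise InsufficientDataError("cavity water analysis needs ≥10 frames")
    lo, hi = _region_arrays(region)
    waters = traj.select("water-oxygen")
    center = (lo + hi) / 2
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        pos = traj.coords[f, waters]
        box = traj.box[f] if traj.box is not None else None
        pos = _wrap_to_region(pos, center, box)
        counts[f] = int(np.sum(np.all((pos >= lo - 1e-9) & (pos <= hi + 1e-9), axis=1)))
    x = counts.astype(float)
    var = np.var(x)
    if var == 0:
        return CavityWaterSeries(counts=counts, frame_interval=traj.frame_interval, relaxation_time=None)
    xc = x - x.mean()
    n = x.size
    tau = 0.0
    for lag in range(n - 1):
        rho = float(np.dot(xc[: n - lag], xc[lag:]) / ((n - lag) * var))
        if rho <= 0:
            break
        tau += rho
    return CavityWaterSeries(
        counts=counts,
        frame_interval=traj.frame_interval,
        relaxation_time=tau * traj.frame_interval,
    )
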