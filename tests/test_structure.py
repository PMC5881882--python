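"""Superposition, dihedrals, occupancy grids and cavity water counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alchemcycle import (
    InsufficientDataError,
    NumericalDegeneracyError,
    Trajectory,
    UsageError,
    angle_histogram,
    cavity_water_count,
    classify_grid,
    dihedral_angle,
    occupancy_grid,
    superpose,
)
from alchemcycle.structure import DihedralSeries, selection_rmsd
from alchemcycle.synth import WaterSceneModel, gen_dihedral_series, gen_water_trajectory


def _traj_from_frames(frames, roles=None, box=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    if roles is None:
        roles = ["backbone"] * n
    return Trajectory(
        coords=frames,
        atom_names=[f"A{i}" for i in range(n)],
        residue_names=["UNK"] * n,
        residue_indices=list(range(n)),
        roles=np.array(roles, dtype=object),
        box=box,
    )


class TestSuperpose:
    BASE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1.0]])

    def test_translation_removed(self):
        traj = _traj_from_frames([self.BASE, self.BASE + [1.0, 0, 0]])
        fitted = superpose(traj)
        assert selection_rmsd(fitted, 0, "backbone")[1] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_removed(self):
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90° about z
        traj = _traj_from_frames([self.BASE, self.BASE @ rot.T])
        fitted = superpose(traj)
        assert selection_rmsd(fitted, 0, "backbone")[1] == pytest.approx(0.0, abs=1e-12)

    def test_fit_never_worse_than_no_fit(self):
        rng = np.random.default_rng(0)
        frames = [self.BASE] + [self.BASE + rng.normal(0, 0.1, self.BASE.shape) for _ in range(5)]
        traj = _traj_from_frames(frames)
        fitted = superpose(traj)
        assert np.all(
            selection_rmsd(fitted, 0, "backbone") <= selection_rmsd(traj, 0, "backbone") + 1e-12
        )

    def test_too_few_selected_atoms(self):
        traj = _traj_from_frames([self.BASE], roles=["backbone", "backbone", "other", "other"])
        with pytest.raises(UsageError):
            superpose(traj)

    def test_collinear_selection_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(UsageError, match="collinear"):
            superpose(_traj_from_frames([line]))


def _rotate_about(p, axis, angle_deg):
    a = np.radians(angle_deg)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return (np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * k @ k) @ p


class TestDihedral:
    P1, P2, P3 = np.array([1.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0])
    CIS = np.array([1.0, 0.0, 0.0])  # same side as p1: planar cis

    def test_planar_cis_zero(self):
        assert dihedral_angle(self.P1, self.P2, self.P3, self.CIS) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_180(self):
        trans = np.array([-1.0, 0.0, 0.0])
        assert dihedral_angle(self.P1, self.P2, self.P3, trans) == pytest.approx(180.0)

    @pytest.mark.parametrize("angle", [60.0, -60.0, 90.0, 150.0])
    def test_rotation_about_bond_axis_gives_angle(self, angle):
        # right-hand rotation of the cis-placed fourth point about the
        # p2→p3 bond axis; the constructed gauche arrangement reads +60°
        p4 = _rotate_about(self.CIS, self.P3 - self.P2, angle)
        assert dihedral_angle(self.P1, self.P2, self.P3, p4) == pytest.approx(angle, abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_reversal_symmetry(self, seed):
        # the signed torsion is invariant under full reversal of the atom
        # order (IUPAC convention): gauche+ is gauche+ seen from either end
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (4, 3))
        try:
            fwd = dihedral_angle(*pts)
            rev = dihedral_angle(*pts[::-1])
        except NumericalDegeneracyError:
            return
        assert rev == pytest.approx(fwd, abs=1e-9)

    def test_matches_mdtraj_oracle(self):
        import mdtraj
        import mdtraj.core.element as elem

        top = mdtraj.Topology()
        res = top.add_residue("UNK", top.add_chain())
        for i in range(4):
            top.add_atom(f"C{i}", elem.carbon, res)
        rng = np.random.default_rng(12)
        for _ in range(5):
            pts = rng.normal(0, 1, (4, 3))
            ref = float(
                np.degrees(
                    mdtraj.compute_dihedrals(
                        mdtraj.Trajectory(pts.reshape(1, 4, 3), top), [[0, 1, 2, 3]]
                    )
                )[0, 0]
            )
            assert dihedral_angle(*pts) == pytest.approx(ref, abs=1e-4)

    def test_degenerate_geometry(self):
        with pytest.raises(NumericalDegeneracyError):
            dihedral_angle(self.P1, self.P1, self.P3, self.CIS)


class TestAngleHistogram:
    def test_single_value_single_bin(self):
        edges, hist = angle_histogram(DihedralSeries("x", np.full(50, 10.0)), 10.0)
        assert hist.max() == 1.0
        assert np.count_nonzero(hist) == 1
        assert edges[np.argmax(hist)] == pytest.approx(0.0)  # bin (0, 10]

    def test_uniform_angles_flat(self):
        rng = np.random.default_rng(7)
        angles = rng.uniform(-179.99, 180.0, 40_000)
        _, hist = angle_histogram(DihedralSeries("x", angles), 10.0)
        n, bins = 40_000, 36
        p = 1.0 / bins
        sigma = np.sqrt(n * p * (1 - p))
        raw_max = np.histogram(angles, np.arange(-180, 181, 10))[0].max()
        raw = hist * raw_max  # hist is normalized to its maximum bin
        assert hist.max() == 1.0
        assert np.all(np.abs(raw - n * p) < 5 * sigma)

    def test_bimodal_modes_recovered(self):
        series = gen_dihedral_series([(-90.0, 20.0, 0.5), (90.0, 20.0, 0.5)], 10_000, seed=3)
        edges, hist = angle_histogram(series, 10.0)
        top2 = np.sort(np.argsort(hist)[-2:])
        centers = edges[top2] + 5.0
        assert abs(centers[0] + 90.0) <= 10.0
        assert abs(centers[1] - 90.0) <= 10.0

    def test_bin_width_must_divide_360(self):
        with pytest.raises(UsageError):
            angle_histogram(DihedralSeries("x", np.array([0.0])), 7.0)

    def test_empty_series_rejected(self):
        with pytest.raises(UsageError):
            angle_histogram(DihedralSeries("x", np.array([])), 10.0)


def _water_traj(positions_per_frame, box=None):
    """Trajectory whose atoms are all water oxygens at given positions."""
    frames = np.asarray(positions_per_frame, dtype=float)
    n = frames.shape[1]
    return Trajectory(
        coords=frames,
        atom_names=["OW"] * n,
        residue_names=["SOL"] * n,
        residue_indices=list(range(n)),
        roles=np.array(["water-oxygen"] * n, dtype=object),
        box=box,
    )


REGION = (np.zeros(3), np.full(3, 1.0))


class TestOccupancyGrid:
    def test_static_water_node_one(self):
        pos = np.tile([[0.4, 0.4, 0.4]], (20, 1, 1))
        grid = occupancy_grid(_water_traj(pos), REGION, 0.2)
        assert grid.counts[2, 2, 2] == 1.0
        assert grid.counts.sum() == 1.0

    def test_intermittent_water_fractional_occupancy(self):
        rng = np.random.default_rng(11)
        frames = []
        present = rng.random(1000) < 0.7
        for p in present:
            frames.append([[0.4, 0.4, 0.4]] if p else [[5.0, 5.0, 5.0]])
        grid = occupancy_grid(_water_traj(np.array(frames)), REGION, 0.2)
        # oracle: direct count of present frames
        assert grid.counts[2, 2, 2] == pytest.approx(present.mean())

    def test_midpoint_tie_goes_to_smaller_index(self):
        pos = np.tile([[0.1, 0.0, 0.0]], (5, 1, 1))  # exactly between nodes 0 and 1 in x
        grid = occupancy_grid(_water_traj(pos), REGION, 0.2)
        assert grid.counts[0, 0, 0] == 1.0
        assert grid.counts[1, 0, 0] == 0.0

    def test_node_sums_conserve_in_region_mean_count(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-0.2, 1.2, (50, 30, 3))
        traj = _water_traj(pos)
        grid = occupancy_grid(traj, REGION, 0.2)
        inside = np.all((pos >= 0.0) & (pos <= 1.0), axis=2)
        assert grid.counts.sum() == pytest.approx(inside.sum(1).mean())

    def test_translation_invariance_with_region(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 1, (20, 10, 3))
        shift = np.array([3.0, -2.0, 7.0])
        g1 = occupancy_grid(_water_traj(pos), REGION, 0.2)
        g2 = occupancy_grid(_water_traj(pos + shift), (REGION[0] + shift, REGION[1] + shift), 0.2)
        assert np.allclose(g1.counts, g2.counts)

    def test_minimum_image_wrapping(self):
        box = np.tile([2.0, 2.0, 2.0], (5, 1))
        pos = np.tile([[1.9, 0.5, 0.5]], (5, 1, 1))  # image at −0.1 is nearer the region
        region = (np.array([-0.5, 0, 0]), np.array([0.5, 1, 1]))
        grid = occupancy_grid(_water_traj(pos, box=box), region, 0.2)
        assert grid.counts.sum() == pytest.approx(1.0)

    def test_bad_spacing(self):
        with pytest.raises(UsageError):
            occupancy_grid(_water_traj(np.zeros((2, 1, 3))), REGION, 0.0)


class TestClassifyGrid:
    def test_levels_and_boundaries(self):
        frames = []
        # node A present always, node B 95%, node C 29%
        for i in range(100):
            frame = [[0.2, 0.2, 0.2]]
            if i < 95:
                frame.append([0.6, 0.6, 0.6])
            else:
                frame.append([5.0, 5.0, 5.0])
            if i < 29:
                frame.append([0.8, 0.2, 0.2])
            else:
                frame.append([5.0, 5.0, 5.0])
            frames.append(frame)
        grid = occupancy_grid(_water_traj(np.array(frames)), REGION, 0.2)
        classified = classify_grid(grid)
        assert (1, 1, 1) in classified[0.9]
        assert (3, 3, 3) in classified[0.9]  # 0.95 of max meets the 0.9 level
        assert all((4, 1, 1) not in nodes for nodes in classified.values())  # 0.29 < 0.3

    def test_planted_hotspots_classified(self):
        model = WaterSceneModel(
            box=np.full(3, 2.0),
            site_positions=np.array([[0.9, 0.9, 0.9], [1.3, 0.9, 0.9]]),
            site_probs=np.array([1.0, 0.6]),
            exchange_rate=0.5,
            seed=4,
        )
        traj = gen_water_trajectory(model, 2000)
        grid = occupancy_grid(traj, (np.full(3, 0.5), np.full(3, 1.5)), 0.2)
        classified = classify_grid(grid)
        at_least_half = set(classified[0.5]) | set(classified[0.9])
        assert at_least_half == {(2, 2, 2), (4, 2, 2)}

    def test_all_zero_grid_rejected(self):
        grid = occupancy_grid(_water_traj(np.full((5, 1, 3), 9.0)), REGION, 0.2)
        with pytest.raises(UsageError):
            classify_grid(grid)


class TestCavityWater:
    def test_constant_count_undefined_relaxation(self):
        pos = np.tile([[0.5, 0.5, 0.5]], (50, 1, 1))
        res = cavity_water_count(_water_traj(pos), REGION)
        assert np.all(res.counts == 1)
        assert res.relaxation_time is None

    def test_white_noise_relaxation_about_one_frame(self):
        rng = np.random.default_rng(9)
        frames = [[[0.5, 0.5, 0.5]] if p else [[5.0, 5.0, 5.0]] for p in rng.random(4000) < 0.5]
        res = cavity_water_count(_water_traj(np.array(frames)), REGION)
        assert res.relaxation_time == pytest.approx(1.0, rel=0.3)

    def test_telegraph_relaxation_matches_closed_form(self):
        k = 0.05
        model = WaterSceneModel(
            box=np.full(3, 2.0),
            site_positions=np.array([[1.0, 1.0, 1.0]]),
            site_probs=np.array([0.5]),
            exchange_rate=k,
            seed=21,
        )
        traj = gen_water_trajectory(model, 20_000)
        res = cavity_water_count(traj, (np.full(3, 0.5), np.full(3, 1.5)))
        assert res.relaxation_time == pytest.approx(1.0 / (2 * k), rel=0.3)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            cavity_water_count(_water_traj(np.zeros((5, 1, 3))), REGION)
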