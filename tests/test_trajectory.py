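"""Superposition geometry and the RMSF protocol."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from kinoflex.synthetic import TrajectorySpec, gen_trajectory
from kinoflex.trajectory import (
    Trajectory,
    compute_rmsf,
    kabsch_superpose,
    read_coordinate_table,
    read_pdb_trajectory,
    write_pdb_trajectory,
)
from tests.conftest import random_rotation


class TestKabsch:
    def test_identity_case(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.standard_normal((12, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ Rz.T + np.array([5.0, 0.0, 0.0])
        R, t, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd < 1e-10
        assert np.allclose(mobile @ R.T + t, ref, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_minimization_oracle(self):
        # Independent oracle: numerically minimize RMSD over rotations
        # parametrized by rotation vectors, with multiple restarts.
        rng = np.random.default_rng(2)
        ref = rng.standard_normal((50, 3)) * 3
        mobile = (ref + rng.standard_normal((50, 3)) * 0.1) @ random_rotation(rng).T

        _, _, rmsd = kabsch_superpose(mobile, ref)

        P0 = mobile - mobile.mean(axis=0)
        Q0 = ref - ref.mean(axis=0)

        def cost(rotvec):
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((P0 @ Rm.T - Q0) ** 2).sum() / len(P0))

        best = np.inf
        for _ in range(12):
            res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
            best = min(best, res.fun)
        assert abs(rmsd - best) < 1e-6

    def test_proper_rotation_under_reflection_pressure(self):
        # A near-planar cloud vs its mirror image must still yield det(R)=+1.
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((20, 3))
        ref[:, 2] *= 0.01
        mobile = ref * np.array([1.0, 1.0, -1.0])
        R, _, _ = kabsch_superpose(mobile, ref)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_too_few_atoms_rejected(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(X, X)

    def test_collinear_atoms_rejected(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(X, X)


def _simple_meta(n_res, atoms_per_res=4):
    import pandas as pd

    names = ["N", "CA", "C", "O"]
    rows = [
        {"residue_id": r + 1, "residue_name": "ALA", "atom_name": names[a],
         "is_backbone": True}
        for r in range(n_res)
        for a in range(atoms_per_res)
    ]
    return pd.DataFrame(rows)


class TestComputeRMSF:
    def test_rigid_trajectory_gives_exact_zero(self):
        spec = TrajectorySpec(
            n_frames=6, residues=[(1, 0.0, [0, 0, 0]), (2, 0.0, [4, 0, 0])], seed=0
        )
        profile = compute_rmsf(gen_trajectory(spec), discard=0)
        assert np.all(profile.rmsf == 0.0)

    def test_two_point_displacement(self):
        # A large rigid scaffold pins the fit; one extra atom flips between
        # +d and -d along x, so its RMSF is d (up to the tiny centroid shift
        # the moving atom itself induces, ~1/n_atoms).
        rng = np.random.default_rng(4)
        d = 0.8
        scaffold = rng.standard_normal((400, 3)) * 10
        frames = np.stack([scaffold, scaffold])
        mover = np.array([[d, 0, 0], [-d, 0, 0]])
        coords = np.concatenate([frames, mover[:, None, :]], axis=1)
        import pandas as pd

        meta = pd.DataFrame(
            {
                "residue_id": [1] * 400 + [2],
                "residue_name": "ALA",
                "atom_name": ["CA"] * 401,
                "is_backbone": True,
            }
        )
        profile = compute_rmsf(Trajectory(coordinates=coords, atom_meta=meta), discard=0)
        assert profile.value_at(2) == pytest.approx(d, rel=0.02)

    def test_gaussian_closed_form(self):
        # sigma = 0.5 A: per-residue RMSF ~ sigma*sqrt(3) = 0.866 A within 2 %.
        sigma = 0.5
        spec = TrajectorySpec(
            n_frames=4000,
            residues=[(i + 1, sigma, [3.8 * i, 0.0, 0.0]) for i in range(30)],
            seed=1,
        )
        profile = compute_rmsf(gen_trajectory(spec), discard=0)
        expected = sigma * np.sqrt(3)
        assert np.abs(profile.rmsf.mean() - expected) / expected < 0.02

    def test_superposition_invariance_under_rigid_motion(self):
        spec = TrajectorySpec(
            n_frames=40,
            residues=[(i + 1, 0.4, [3.8 * i, 0.0, 0.0]) for i in range(5)],
            seed=2,
        )
        traj = gen_trajectory(spec)
        base = compute_rmsf(traj, discard=0)

        rng = np.random.default_rng(9)
        R = random_rotation(rng)
        shift = np.array([10.0, -3.0, 7.0])
        moved = Trajectory(
            coordinates=traj.coordinates @ R.T + shift, atom_meta=traj.atom_meta
        )
        again = compute_rmsf(moved, discard=0)
        assert np.allclose(base.rmsf, again.rmsf, atol=1e-8)

    def test_mean_structure_fixed_point(self):
        # One extra (fit -> recompute mean) iteration past convergence
        # changes the per-residue RMSF by less than 1e-6 A.
        from kinoflex.trajectory import _fit_frames, _iterate_fit

        spec = TrajectorySpec(
            n_frames=200,
            residues=[(i + 1, 0.5, [3.8 * i, 0.0, 0.0]) for i in range(6)],
            seed=3,
        )
        traj = gen_trajectory(spec)
        mask = traj.atom_mask("backbone")
        fitted, mean = _iterate_fit(traj.coordinates, mask)
        refit = _fit_frames(fitted, mean, mask)
        remean = refit.mean(axis=0)

        def residue_rmsf(f, m):
            sq = ((f - m[None]) ** 2).sum(axis=2).mean(axis=0)
            resids = traj.atom_meta["residue_id"].to_numpy()
            return np.array(
                [np.sqrt(sq[resids == r].mean()) for r in sorted(set(resids))]
            )

        assert np.allclose(
            residue_rmsf(fitted, mean), residue_rmsf(refit, remean), atol=1e-6
        )
        assert np.allclose(compute_rmsf(traj, discard=0).rmsf,
                           residue_rmsf(fitted, mean), atol=1e-12)

    def test_discard_too_large_rejected(self, gaussian_trajectory):
        with pytest.raises(ValueError, match="discard"):
            compute_rmsf(gaussian_trajectory, discard=25)

    def test_empty_selection_rejected(self, gaussian_trajectory):
        with pytest.raises(ValueError, match="no atoms"):
            compute_rmsf(gaussian_trajectory, selection=["ZZ"], discard=0)


class TestTrajectoryIO:
    def test_pdb_round_trip(self, gaussian_trajectory, tmp_path):
        path = tmp_path / "traj.pdb"
        write_pdb_trajectory(gaussian_trajectory, path)
        back = read_pdb_trajectory(path)
        assert back.n_frames == gaussian_trajectory.n_frames
        # PDB stores 3 decimals
        assert np.allclose(back.coordinates, gaussian_trajectory.coordinates, atol=1e-3)
        assert list(back.atom_meta["atom_name"]) == list(
            gaussian_trajectory.atom_meta["atom_name"]
        )

    def test_coordinate_table_round_trip(self, gaussian_trajectory, tmp_path):
        import pandas as pd

        traj = gaussian_trajectory
        rows = [
            {"frame": f, "atom_index": a, "x": traj.coordinates[f, a, 0],
             "y": traj.coordinates[f, a, 1], "z": traj.coordinates[f, a, 2]}
            for f in range(traj.n_frames)
            for a in range(traj.n_atoms)
        ]
        path = tmp_path / "coords.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        back = read_coordinate_table(path, traj.atom_meta)
        assert np.allclose(back.coordinates, traj.coordinates)

    def test_incomplete_table_rejected(self, gaussian_trajectory, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"frame": [0], "atom_index": [0], "x": [0.0], "y": [0.0], "z": [0.0]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="cover"):
            read_coordinate_table(path, gaussian_trajectory.atom_meta)
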