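"""Superposition, RMSD/RMSF, dihedral and distance metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from asickin.structure import (
    Selection,
    StructureFrame,
    Trajectory,
    atom_distance_series,
    chi_dihedrals,
    dihedral_angle,
    kabsch_superpose,
    read_pdb,
    read_trajectory_pdb,
    rmsd_series,
    rmsf,
    state_plane,
    write_pdb,
)


def make_frame(coords, res_name="GLY", atom_names=None, chain="A", res_start=1):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atom_names = atom_names or [f"C{i}" for i in range(n)]
    return StructureFrame(
        chain_id=np.array([chain] * n),
        res_id=np.arange(res_start, res_start + n),
        res_name=np.array([res_name] * n),
        atom_name=np.array(atom_names),
        element=np.array(["C"] * n),
        coord=coords,
    )


def random_cloud(rng, n=10):
    return rng.normal(0, 5, (n, 3))


def gln_frame(coords):
    """A glutamine residue with the seven atoms needed for chi1-chi3."""
    names = ["N", "CA", "CB", "CG", "CD", "OE1", "NE2"]
    return StructureFrame(
        chain_id=np.array(["A"] * 7),
        res_id=np.full(7, 277),
        res_name=np.array(["GLN"] * 7),
        atom_name=np.array(names),
        element=np.array(["N", "C", "C", "C", "C", "O", "N"]),
        coord=np.asarray(coords, dtype=float),
    )


class TestKabsch:
    def test_identity_on_self(self, rng):
        X = random_cloud(rng)
        R, t, r = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_recovered_exactly(self, rng):
        X = random_cloud(rng)
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        Y = X @ rot.T + np.array([5.0, -3.0, 2.0])
        _, _, r = kabsch_superpose(Y, X)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_rotation_optimizer(self, rng):
        """RMSD after Kabsch equals a numerical minimum over rotation vectors."""
        X = random_cloud(rng)
        Y = X + rng.normal(0, 0.5, X.shape)
        _, _, r_kabsch = kabsch_superpose(Y, X)

        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((Yc @ R.T - Xc) ** 2, axis=1)))

        best = min(
            (minimize(objective, v0, method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}).fun
             for v0 in [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 2.0, 1.0])]),
        )
        assert r_kabsch == pytest.approx(best, abs=1e-6)

    def test_reflection_excluded(self, rng):
        X = random_cloud(rng)
        Y = X.copy()
        Y[:, 0] *= -1  # mirror image
        R, _, _ = kabsch_superpose(Y, X)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_set_rejected(self):
        X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(X, X)

    def test_aligned_rmsd_never_exceeds_unaligned(self, rng):
        for _ in range(20):
            X = random_cloud(rng)
            Y = random_cloud(rng)
            _, _, aligned = kabsch_superpose(Y, X)
            unaligned = np.sqrt(np.mean(np.sum((Y - X) ** 2, axis=1)))
            assert aligned <= unaligned + 1e-12


class TestPdbIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        frame = make_frame(np.round(random_cloud(rng, 8), 3))
        p = tmp_path / "f.pdb"
        write_pdb(frame, p)
        back = read_pdb(p)
        np.testing.assert_allclose(back.coord, frame.coord, atol=1e-3)
        assert list(back.atom_name) == list(frame.atom_name)

    def test_minimal_three_atom_fixture(self, tmp_path):
        text = (
            "ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N\n"
            "ATOM      2  CA  GLY A   1       2.000   3.000   4.000  1.00  0.00           C\n"
            "ATOM      3  C   GLY A   1       3.500   4.500   5.500  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        frame = read_pdb(p)
        assert frame.n_atoms == 3
        np.testing.assert_allclose(frame.coord[2], [3.5, 4.5, 5.5])

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        text = (
            "ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N\n"
            "ATOM      2  CA AGLY A   1       2.000   3.000   4.000  0.60  0.00           C\n"
            "ATOM      3  CA BGLY A   1       9.000   9.000   9.000  0.40  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        frame = read_pdb(p)
        ca = frame.coord[frame.atom_name == "CA"]
        assert ca.shape[0] == 1
        np.testing.assert_allclose(ca[0], [2.0, 3.0, 4.0])

    def test_malformed_atom_line_errors(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM  not a valid line\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_multi_model_trajectory(self, tmp_path, rng):
        f1 = make_frame(np.round(random_cloud(rng, 5), 3))
        f2 = make_frame(f1.coord + 1.0)
        p = tmp_path / "traj.pdb"
        lines = []
        for k, fr in enumerate((f1, f2), start=1):
            lines.append(f"MODEL     {k:>4}")
            for j in range(fr.n_atoms):
                x, y, z = fr.coord[j]
                lines.append(
                    f"ATOM  {j+1:>5}  {fr.atom_name[j]:<3} GLY A{fr.res_id[j]:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        p.write_text("\n".join(lines) + "\n")
        traj = read_trajectory_pdb(p)
        assert traj.n_frames == 2
        np.testing.assert_allclose(traj.frames[1].coord - traj.frames[0].coord, 1.0, atol=1e-3)


class TestRmsdSeries:
    def test_identical_frames_give_zeros(self, rng):
        ref = make_frame(random_cloud(rng, 12))
        traj = Trajectory(frames=[ref, ref, ref])
        sel = Selection(atom_names=tuple(ref.atom_name))
        np.testing.assert_allclose(rmsd_series(traj, ref, sel), 0.0, atol=1e-12)

    def test_uniform_displacement_outside_fit_region(self, rng):
        """Displace only the measured atoms by d after alignment on others."""
        coords = random_cloud(rng, 12)
        ref = make_frame(coords)
        d = 2.5
        moved = coords.copy()
        moved[8:, 0] += d  # displace atoms with res_id 9..12
        fr = make_frame(moved)
        traj = Trajectory(frames=[fr])
        fit = Selection(res_range=(1, 8))
        measure = Selection(res_range=(9, 12))
        out = rmsd_series(traj, ref, fit, measure)
        assert out[0] == pytest.approx(d, rel=1e-9)

    def test_two_state_trajectory_has_two_rmsd_levels(self, rng):
        coords = random_cloud(rng, 12)
        ref = make_frame(coords)
        rot = Rotation.from_euler("y", 25, degrees=True).as_matrix()
        state_b = coords @ rot.T + 3.0  # rigid copy: rmsd 0 to ref
        state_b[5] += np.array([4.0, 0.0, 0.0])  # plus a local deformation
        frames = [make_frame(coords if k % 2 == 0 else state_b) for k in range(10)]
        traj = Trajectory(frames=frames)
        sel = Selection()
        out = rmsd_series(traj, ref, sel)
        assert np.allclose(out[::2], 0.0, atol=1e-9)
        assert np.allclose(out[1::2], out[1], atol=1e-9) and out[1] > 0.5

    def test_rigid_motion_invariance(self, rng):
        coords = random_cloud(rng, 12)
        ref = make_frame(coords)
        fr = make_frame(coords + rng.normal(0, 0.3, coords.shape))
        sel = Selection()
        base = rmsd_series(Trajectory(frames=[fr]), ref, sel)[0]
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = make_frame(fr.coord @ rot.T + np.array([10.0, -4.0, 2.0]))
        after = rmsd_series(Trajectory(frames=[moved]), ref, sel)[0]
        assert after == pytest.approx(base, abs=1e-9)


class TestRmsf:
    def test_static_trajectory_is_zero(self, rng):
        fr = make_frame(random_cloud(rng, 6), atom_names=["CA"] * 0 or None)
        traj = Trajectory(frames=[fr, fr, fr])
        out = rmsf(traj, Selection())
        np.testing.assert_allclose(out["per_atom"], 0.0, atol=1e-12)

    def test_two_point_alternation_gives_amplitude(self, rng):
        # one atom alternates +/- a along x about its mean; alignment disabled
        coords = random_cloud(rng, 8)
        a = 0.8
        up, down = coords.copy(), coords.copy()
        up[3, 0] += a
        down[3, 0] -= a
        frames = [make_frame(up if k % 2 == 0 else down) for k in range(10)]
        out = rmsf(Trajectory(frames=frames), Selection(), superpose=False)
        assert out["per_atom"][3] == pytest.approx(a, rel=1e-9)
        np.testing.assert_allclose(np.delete(out["per_atom"], 3), 0.0, atol=1e-12)

    def test_matches_naive_two_pass_recomputation(self, rng):
        frames = [make_frame(random_cloud(rng, 7) * 0.2 + np.arange(21).reshape(7, 3))
                  for _ in range(6)]
        traj = Trajectory(frames=frames)
        out = rmsf(traj, Selection(), superpose=False)["per_atom"]
        stack = np.stack([fr.coord for fr in frames])
        naive = np.sqrt(((stack - stack.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(out, naive, atol=1e-9)

    def test_single_frame_rejected(self, rng):
        traj = Trajectory(frames=[make_frame(random_cloud(rng, 5))])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj, Selection())

    def test_per_residue_uses_ca(self, rng):
        coords = random_cloud(rng, 4)
        fr = make_frame(coords, atom_names=["N", "CA", "C", "O"])
        fr2 = make_frame(coords + 0.1, atom_names=["N", "CA", "C", "O"])
        out = rmsf(Trajectory(frames=[fr, fr2]), Selection(), superpose=False)
        assert set(out["per_residue"]) == {("A", 2)}  # the CA atom's residue


class TestStatePlane:
    def test_frames_at_reference_a(self, rng):
        a = make_frame(random_cloud(rng, 10))
        b = make_frame(a.coord + rng.normal(0, 1.0, a.coord.shape))
        sel = Selection()
        _, _, d_ab = kabsch_superpose(a.coord, b.coord)
        plane = state_plane(Trajectory(frames=[a, a]), a, b, sel)
        np.testing.assert_allclose(plane[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(plane[:, 1], d_ab, atol=1e-9)

    def test_interpolation_traces_monotone_path(self, rng):
        a = make_frame(random_cloud(rng, 10))
        b = make_frame(a.coord + rng.normal(0, 2.0, a.coord.shape))
        frames = [make_frame((1 - w) * a.coord + w * b.coord) for w in np.linspace(0, 1, 9)]
        plane = state_plane(Trajectory(frames=frames), a, b, Selection())
        assert np.all(np.diff(plane[:, 0]) > -1e-9)  # away from a
        assert np.all(np.diff(plane[:, 1]) < 1e-9)  # toward b


class TestDihedrals:
    def test_anti_configuration_is_180(self):
        p = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        assert dihedral_angle(*map(np.array, p)) == pytest.approx(180.0)

    def test_eclipsed_configuration_is_zero(self):
        p = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert dihedral_angle(*map(np.array, p)) == pytest.approx(0.0, abs=1e-12)

    def test_positive_gauche_sign_convention(self):
        # +60 degree rotation of the distal atom: IUPAC positive (clockwise
        # looking from atom 2 to atom 3)
        ang = np.radians(60.0)
        p4 = (1.0, np.cos(ang), np.sin(ang))
        val = dihedral_angle(
            np.array([0, 1, 0]), np.array([0, 0, 0]), np.array([1, 0, 0]), np.array(p4)
        )
        assert val == pytest.approx(60.0, abs=1e-9)

    def test_matches_independent_oracles_on_random_geometries(self, rng):
        """Agreement with a projection-formula oracle (float64, 1e-9 deg) and
        with biotite (which computes in float32, hence the looser band)."""
        from biotite.structure import dihedral as biotite_dihedral

        def projection_oracle(p1, p2, p3, p4):
            b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
            b2u = b2 / np.linalg.norm(b2)
            v = -b1 - (-b1 @ b2u) * b2u
            w = b3 - (b3 @ b2u) * b2u
            return np.degrees(np.arctan2(np.cross(b2u, v) @ w, v @ w))

        for _ in range(1000):
            pts = rng.normal(0, 3, (4, 3))
            mine = dihedral_angle(*pts)
            oracle = projection_oracle(*pts)
            assert abs((mine - oracle + 180) % 360 - 180) < 1e-9
            theirs = np.degrees(float(biotite_dihedral(*pts)))
            assert abs((mine - theirs + 180) % 360 - 180) < 1e-3

    def test_gln_chi_angles_on_constructed_side_chain(self):
        # all-anti (extended) side chain: every chi = 180
        coords = [
            (0.0, 1.0, 0.0),   # N
            (0.0, 0.0, 0.0),   # CA
            (1.4, 0.0, 0.0),   # CB  (chi1 axis CA-CB)
            (1.4, -1.4, 0.0),  # CG
            (2.8, -1.4, 0.0),  # CD  -> wait, keep a genuine zig-zag
            (2.8, -2.8, 0.0),  # OE1
            (3.9, -0.9, 0.0),  # NE2
        ]
        fr = gln_frame(coords)
        chi = chi_dihedrals(fr, "A", 277)
        assert len(chi) == 3
        for c in chi:
            assert abs(abs(c) - 180.0) < 1e-6 or abs(c) < 1e-6  # planar construction

    def test_missing_atom_named_in_error(self):
        fr = gln_frame(np.arange(21).reshape(7, 3) * 1.0)
        # remove CD by renaming it
        fr.atom_name[4] = "XX"
        with pytest.raises(ValueError, match="CD"):
            chi_dihedrals(fr, "A", 277)

    def test_dihedral_invariant_under_rigid_motion(self, rng):
        pts = rng.normal(0, 3, (4, 3))
        base = dihedral_angle(*pts)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 7.0])
        assert dihedral_angle(*moved) == pytest.approx(base, abs=1e-9)


class TestDistances:
    def _two_atom_traj(self, positions_b):
        frames = []
        for pb in positions_b:
            frames.append(StructureFrame(
                chain_id=np.array(["A", "B"]),
                res_id=np.array([277, 414]),
                res_name=np.array(["GLN", "LEU"]),
                atom_name=np.array(["NE2", "O"]),
                element=np.array(["N", "O"]),
                coord=np.array([[0.0, 0.0, 0.0], list(pb)]),
            ))
        return Trajectory(frames=frames)

    def test_pythagorean_distance(self):
        traj = self._two_atom_traj([(3.0, 4.0, 0.0)])
        out = atom_distance_series(traj, ("A", 277, "NE2"), ("B", 414, "O"))
        assert out["distance"][0] == pytest.approx(5.0)

    def test_coincident_atoms(self):
        traj = self._two_atom_traj([(0.0, 0.0, 0.0)])
        out = atom_distance_series(traj, ("A", 277, "NE2"), ("B", 414, "O"))
        assert out["distance"][0] == 0.0

    def test_threshold_fraction(self):
        traj = self._two_atom_traj([(3.0, 0, 0), (4.0, 0, 0)] * 5)
        out = atom_distance_series(traj, ("A", 277, "NE2"), ("B", 414, "O"), cutoff=3.5)
        assert out["fraction_within_cutoff"] == pytest.approx(0.5)

    def test_missing_atom_reports_frame(self):
        traj = self._two_atom_traj([(1.0, 0, 0)])
        with pytest.raises(KeyError, match="frame 0"):
            atom_distance_series(traj, ("A", 277, "NE2"), ("C", 1, "CA"))
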