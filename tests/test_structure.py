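"""Structure I/O, selection language and geometry primitives."""

import numpy as np
import pytest

from enzloop.structure import (
    SelectionSyntaxError,
    StructureError,
    StructureParseError,
    Trajectory,
    make_topology,
    measure,
    read_frames,
    select_atoms,
    write_frames,
)

from conftest import build_trajectory, pose_frame_coords


def _pdb_text(n_models, n_atoms, drop_atom_in_model=None):
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL {m:8d}")
        for a in range(1, n_atoms + 1):
            if m == drop_atom_in_model and a == n_atoms:
                continue
            x, y, z = 1.0 * a, 2.0 * a + m, 0.5 * m
            lines.append(
                f"ATOM  {a:5d}  CA  GLY A{a:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestReadFrames:
    def test_multi_model_pdb_counts(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(_pdb_text(3, 20))
        traj = read_frames(p, "pdb_models")
        assert traj.n_frames == 3
        assert traj.n_atoms == 20

    def test_single_block_xyz(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text("2\nframe 0\nC 0.0 0.0 0.0\nO 1.0 0.0 0.0\n")
        traj = read_frames(p, "xyz")
        assert traj.n_frames == 1
        assert traj[0].frame_index == 0
        assert traj.n_atoms == 2

    def test_dropped_atom_names_the_frame(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(_pdb_text(3, 5, drop_atom_in_model=2))
        with pytest.raises(StructureParseError, match="frame 2"):
            read_frames(p, "pdb_models")

    def test_unparseable_line_reports_line_number(self, tmp_path):
        text = _pdb_text(1, 3).splitlines()
        text[2] = "ATOM  garbage line that cannot be parsed"
        p = tmp_path / "bad.pdb"
        p.write_text("\n".join(text) + "\n")
        with pytest.raises(StructureParseError, match="line 3"):
            read_frames(p, "pdb_models")


class TestWriteFrames:
    def test_pdb_round_trip_to_3_decimals(self, tmp_path):
        rng = np.random.default_rng(0)
        entries = [("CA", "GLY", "A", i + 1) for i in range(7)]
        traj = build_trajectory(entries, rng.uniform(-50, 50, (2, 7, 3)))
        p = tmp_path / "rt.pdb"
        write_frames(traj, p, "pdb_models")
        back = read_frames(p, "pdb_models")
        assert back.n_frames == 2
        np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-3)

    def test_xyz_round_trip_exact_at_printed_precision(self, tmp_path):
        entries = [("C", "UNK", "A", 1), ("O", "UNK", "A", 1)]
        traj = build_trajectory(entries, [[[0.123456, -1.5, 2.0], [3.0, 4.0, 5.0]]])
        p = tmp_path / "rt.xyz"
        write_frames(traj, p, "xyz")
        back = read_frames(p, "xyz")
        np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-6)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(make_topology([("CA", "GLY", "A", 1)]), np.empty((0, 1, 3)))

    def test_written_pdb_readable_by_mdanalysis(self, tmp_path):
        """Independent oracle: MDAnalysis re-reads our PDB identically."""
        mda = pytest.importorskip("MDAnalysis")
        rng = np.random.default_rng(1)
        entries = [("CA", "GLY", "A", i + 1) for i in range(5)]
        traj = build_trajectory(entries, rng.uniform(-20, 20, (3, 5, 3)))
        p = tmp_path / "mda.pdb"
        write_frames(traj, p, "pdb_models")
        u = mda.Universe(str(p))
        assert len(u.trajectory) == 3
        for i, _ in enumerate(u.trajectory):
            np.testing.assert_allclose(
                u.atoms.positions, traj.coordinates[i], atol=2e-3
            )


class TestSelectAtoms:
    def test_loop_heavy_atoms(self, loop_fixture):
        sel = select_atoms(loop_fixture, "resid 39-47 and not element H")
        assert len(sel) == 36

    def test_single_named_atom(self, pose_topology_entries):
        traj = build_trajectory(
            pose_topology_entries, [pose_frame_coords(3.5, 3.2, 85.0)]
        )
        sel = select_atoms(traj, "name OH and resid 165")
        assert len(sel) == 1

    def test_absent_residue_is_empty_with_warning(self, loop_fixture):
        with pytest.warns(UserWarning, match="matched no atoms"):
            sel = select_atoms(loop_fixture, "resid 999")
        assert len(sel) == 0

    def test_syntax_error(self, loop_fixture):
        with pytest.raises(SelectionSyntaxError):
            select_atoms(loop_fixture, "resid 39-47 frobnicate")

    def test_idempotent_and_sorted(self, loop_fixture):
        a = select_atoms(loop_fixture, "resid 39-47 and not element H")
        b = select_atoms(loop_fixture, "resid 39-47 and not element H")
        assert a.resolved_indices == b.resolved_indices
        assert list(a.resolved_indices) == sorted(set(a.resolved_indices))


class TestMeasure:
    def test_distance_345_triangle(self):
        traj = build_trajectory(
            [("C1", "UNK", "A", 1), ("C2", "UNK", "A", 1)],
            [[[0, 0, 0], [3, 4, 0]]],
        )
        assert measure(traj[0], "distance", (0, 1)) == pytest.approx(5.0)

    def test_right_angle(self):
        traj = build_trajectory(
            [("A1", "UNK", "A", 1), ("A2", "UNK", "A", 1), ("A3", "UNK", "A", 1)],
            [[[1, 0, 0], [0, 0, 0], [0, 1, 0]]],
        )
        assert measure(traj[0], "angle", (0, 1, 2)) == pytest.approx(90.0)

    def test_distance_symmetry(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(-10, 10, (1, 6, 3))
        traj = build_trajectory(
            [("C", "UNK", "A", 1)] * 6, coords
        )
        f = traj[0]
        for i in range(6):
            for j in range(i + 1, 6):
                assert measure(f, "distance", (i, j)) == pytest.approx(
                    measure(f, "distance", (j, i))
                )

    def test_coincident_angle_rejected(self):
        traj = build_trajectory(
            [("A", "UNK", "A", 1), ("B", "UNK", "A", 1), ("C", "UNK", "A", 1)],
            [[[0, 0, 0], [0, 0, 0], [1, 0, 0]]],
        )
        with pytest.raises(StructureError, match="coincident"):
            measure(traj[0], "angle", (0, 1, 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        """Distances and angles are invariant under rotation + translation."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        coords = rng.uniform(-10, 10, (5, 3))
        q = rng.normal(size=4)
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        shift = rng.uniform(-100, 100, 3)
        moved = coords @ rot.T + shift
        t1 = build_trajectory([("C", "UNK", "A", 1)] * 5, [coords])
        t2 = build_trajectory([("C", "UNK", "A", 1)] * 5, [moved])
        d1 = measure(t1[0], "distance", (0, 3))
        d2 = measure(t2[0], "distance", (0, 3))
        assert d2 == pytest.approx(d1, rel=1e-9)
        a1 = measure(t1[0], "angle", (0, 1, 2))
        a2 = measure(t2[0], "angle", (0, 1, 2))
        assert a2 == pytest.approx(a1, rel=1e-9)
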