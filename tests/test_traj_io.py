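import numpy as np
import pytest

from semirigid import (
    AtomRecord,
    EmptyInputError,
    FormatError,
    SecondaryStructureTable,
    Trajectory,
    UsageError,
    load_packaged_sstable,
    read_multimodel_pdb,
    read_xtc,
    select_atoms,
    trim_frames,
    write_multimodel_pdb,
    write_xtc,
)
from semirigid.traj_io import (
    backbone_in_secondary_predicate,
    calpha_predicate,
    frames_for_duration,
    write_gro,
)


def make_traj(n_frames=2, n_atoms=5, dt=20.0, names=None, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.random((n_frames, n_atoms, 3))
    names = names or ["CA"] * n_atoms
    atoms = tuple(AtomRecord(i, names[i], i + 1, i + 1, "A") for i in range(n_atoms))
    return Trajectory(coords, dt, atoms)


class TestPDB:
    def test_model_count_and_unit_conversion(self, tmp_path):
        path = tmp_path / "two.pdb"
        lines = []
        for model in (1, 2):
            lines.append(f"MODEL     {model:4d}")
            for i in range(5):
                x = 10.0 if i == 0 else float(i)
                lines.append(
                    f"ATOM  {i+1:5d}  CA  GLY A{i+1:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        traj = read_multimodel_pdb(path)
        assert traj.n_frames == 2
        assert traj.n_atoms == 5
        # 10.0 Angstrom in the file -> 1.0 nm internally
        assert traj.coords[0, 0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_within_pdb_precision(self, tmp_path):
        traj = make_traj(n_frames=3, n_atoms=7, seed=4)
        path = tmp_path / "rt.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path, dt_frame=traj.dt_frame)
        assert back.n_frames == traj.n_frames
        assert np.abs(back.coords - traj.coords).max() < 1e-3

    def test_metadata_round_trip(self, tmp_path):
        traj = make_traj(n_atoms=4)
        path = tmp_path / "meta.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert [a.atom_name for a in back.atoms] == ["CA"] * 4
        assert [a.residue_number for a in back.atoms] == [1, 2, 3, 4]
        assert [a.residue_id for a in back.atoms] == [1, 2, 3, 4]

    def test_inconsistent_model_sizes_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(FormatError):
            read_multimodel_pdb(path)

    def test_zero_models_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyInputError):
            read_multimodel_pdb(path)

    def test_altloc_rejected(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(FormatError):
            read_multimodel_pdb(path)


class TestXTC:
    def test_round_trip(self, tmp_path):
        traj = make_traj(n_frames=10, n_atoms=6, seed=8)
        xtc, gro = tmp_path / "t.xtc", tmp_path / "t.gro"
        write_xtc(traj, xtc)
        write_gro(traj, gro)
        back = read_xtc(xtc, gro)
        assert back.n_frames == 10
        assert np.abs(back.coords - traj.coords).max() < 1e-3
        assert back.dt_frame == pytest.approx(traj.dt_frame)

    def test_empty_xtc_rejected(self, tmp_path):
        traj = make_traj()
        gro = tmp_path / "t.gro"
        write_gro(traj, gro)
        empty = tmp_path / "empty.xtc"
        empty.touch()
        with pytest.raises(EmptyInputError):
            read_xtc(empty, gro)

    def test_atom_count_mismatch_rejected(self, tmp_path):
        traj = make_traj(n_atoms=6)
        other = make_traj(n_atoms=4)
        xtc, gro = tmp_path / "t.xtc", tmp_path / "o.gro"
        write_xtc(traj, xtc)
        write_gro(other, gro)
        with pytest.raises((FormatError, EmptyInputError)):
            read_xtc(xtc, gro)


class TestTrim:
    def test_paper_bookkeeping(self):
        traj = make_traj(n_frames=30000, n_atoms=2, dt=20.0)
        trimmed = trim_frames(traj, 100_000.0)  # 100 ns in ps
        assert trimmed.n_frames == 25000

    def test_zero_discard_is_identity(self):
        traj = make_traj(n_frames=10)
        out = trim_frames(traj, 0.0)
        assert np.array_equal(out.coords, traj.coords)

    def test_floor_formula(self):
        traj = make_traj(n_frames=10, dt=20.0)
        assert trim_frames(traj, 100.0).n_frames == 5

    def test_discard_beyond_duration_rejected(self):
        traj = make_traj(n_frames=10, dt=20.0)
        with pytest.raises(UsageError):
            trim_frames(traj, 200.0)

    @pytest.mark.parametrize("discard,expected", [(20.0, 9), (30.0, 8), (150.0, 2)])
    def test_floor_counts(self, discard, expected):
        traj = make_traj(n_frames=10, dt=20.0)
        assert trim_frames(traj, discard).n_frames == expected


class TestSelection:
    def test_calpha_only(self):
        names = ["N", "CA", "C"] * 3
        atoms = tuple(AtomRecord(i, names[i], i // 3 + 1, i // 3 + 1, "A") for i in range(9))
        traj = Trajectory(np.zeros((2, 9, 3)), 20.0, atoms)
        assert select_atoms(traj, calpha_predicate) == [1, 4, 7]

    def test_backbone_in_strand(self):
        names = ["N", "CA", "C"] * 6
        atoms = tuple(AtomRecord(i, names[i], i // 3 + 1, i // 3 + 1, "A") for i in range(18))
        traj = Trajectory(np.zeros((2, 18, 3)), 20.0, atoms)
        from semirigid.traj_io import SSEntry

        table = SecondaryStructureTable((
            SSEntry("s1", 1, 5, "strand"),
            SSEntry("l1", 6, 6, "loop"),
        ))
        sel = select_atoms(traj, backbone_in_secondary_predicate(table))
        assert len(sel) == 15  # N, CA, C for each of 5 strand residues

    def test_empty_selection_rejected(self):
        traj = make_traj()
        with pytest.raises(UsageError):
            select_atoms(traj, lambda a: a.atom_name == "ZZ")


class TestSSTable:
    def test_packaged_fixture_shapes(self):
        pdl1 = load_packaged_sstable("pdl1")
        pd1 = load_packaged_sstable("pd1")
        assert (pdl1.res_start, pdl1.res_end) == (1, 115)
        assert (pd1.res_start, pd1.res_end) == (116, 240)
        both = load_packaged_sstable("complex")
        assert both.n_residues() == 240

    def test_kind_partition(self):
        table = load_packaged_sstable("complex")
        strand = table.residues_of_kind(["strand"])
        helix = table.residues_of_kind(["helix"])
        loop = table.residues_of_kind(["loop"])
        assert strand | helix | loop == set(range(1, 241))
        assert not strand & helix and not strand & loop and not helix & loop
        # helices exist only on the ligand side
        assert helix and max(helix) <= 115

    def test_gap_rejected(self):
        from semirigid.traj_io import SSEntry

        with pytest.raises(FormatError):
            SecondaryStructureTable((SSEntry("a", 1, 5, "strand"), SSEntry("b", 7, 9, "loop")))

    def test_tsv_round_trip(self, tmp_path):
        table = load_packaged_sstable("pdl1")
        path = tmp_path / "ss.tsv"
        with open(path, "w") as fh:
            fh.write("domain\tres_start\tres_end\tkind\n")
            for e in table.entries:
                fh.write(f"{e.domain_name}\t{e.res_start}\t{e.res_end}\t{e.kind}\n")
        back = SecondaryStructureTable.from_tsv(path)
        assert back.entries == table.entries


def test_frames_for_duration():
    assert frames_for_duration(600_000.0, 20.0) == 30000
    with pytest.raises(UsageError):
        frames_for_duration(100.0, 0.0)


def test_trajectory_invariants():
    atoms = (AtomRecord(0, "CA", 1, 1, "A"),)
    with pytest.raises(UsageError):
        Trajectory(np.zeros((1, 1, 3)), 20.0, atoms)  # < 2 frames
    with pytest.raises(UsageError):
        Trajectory(np.full((2, 1, 3), np.nan), 20.0, atoms)
    with pytest.raises(UsageError):
        Trajectory(np.zeros((2, 1, 3)), -1.0, atoms)
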