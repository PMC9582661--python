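"""Trajectory and annotation I/O.

Coordinates are stored in nm internally (GROMACS convention); PDB files,
which use Angstrom, are converted on read and write.  Atom indexing is
0-based internally, while residue numbers are 1-based and continuous over
the whole complex, in reading order of the atom list.

Readers are backed by MDAnalysis; writers for the plain-text formats
(multi-model PDB, GRO) are implemented here so that round trips stay under
our control at fixed-width precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, FormatError, UsageError

ANGSTROM_PER_NM = 10.0

BACKBONE_NAMES = ("N", "CA", "C")
"""Amide N, alpha carbon and carbonyl C of each residue."""

SS_KINDS = ("strand", "helix", "loop")


@dataclass(frozen=True)
class AtomRecord:
    """Metadata for one atom of the (frame-invariant) atom list."""

    atom_index: int
    atom_name: str
    residue_number: int  # continuous 1-based numbering over the complex
    residue_id: int  # author-assigned PDB ResID
    chain_id: str = ""


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates in nm with per-atom metadata."""

    coords: np.ndarray
    dt_frame: float  # ps
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise UsageError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 2:
            raise UsageError("a trajectory needs at least 2 frames")
        if self.coords.shape[1] != len(self.atoms):
            raise UsageError("coords atom dimension does not match atom list")
        if not np.all(np.isfinite(self.coords)):
            raise UsageError("coordinates must be finite")
        if self.dt_frame <= 0:
            raise UsageError("dt_frame must be positive")
        idx = [a.atom_index for a in self.atoms]
        if idx != list(range(len(self.atoms))):
            raise UsageError("atom_index must be unique and contiguous from 0")
        resnums = [a.residue_number for a in self.atoms]
        if any(b < a for a, b in zip(resnums, resnums[1:])):
            raise UsageError("residue_number must be non-decreasing along the atom list")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration(self) -> float:
        """Total sampled time in ps (each frame accounts for dt_frame)."""
        return self.n_frames * self.dt_frame

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in ps; frame 0 is at t = 0."""
        return np.arange(self.n_frames) * self.dt_frame

    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)


@dataclass(frozen=True)
class SSEntry:
    domain_name: str
    res_start: int
    res_end: int
    kind: str


@dataclass
class SecondaryStructureTable:
    """Per-residue secondary structure as contiguous, non-overlapping ranges."""

    entries: tuple[SSEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = None
        for e in self.entries:
            if e.kind not in SS_KINDS:
                raise FormatError(f"unknown secondary-structure kind {e.kind!r}")
            if e.res_start > e.res_end:
                raise FormatError(f"range start {e.res_start} > end {e.res_end} in {e.domain_name!r}")
            if prev_end is not None and e.res_start != prev_end + 1:
                raise FormatError(
                    f"entries must cover a contiguous residue range: gap/overlap at "
                    f"{e.domain_name!r} (starts {e.res_start}, previous ended {prev_end})"
                )
            prev_end = e.res_end

    @property
    def res_start(self) -> int:
        return self.entries[0].res_start

    @property
    def res_end(self) -> int:
        return self.entries[-1].res_end

    def n_residues(self) -> int:
        return self.res_end - self.res_start + 1

    def residues_of_kind(self, kinds: Iterable[str]) -> set[int]:
        kinds = set(kinds)
        out: set[int] = set()
        for e in self.entries:
            if e.kind in kinds:
                out.update(range(e.res_start, e.res_end + 1))
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SecondaryStructureTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"domain", "res_start", "res_end", "kind"}
        if not required.issubset(df.columns):
            raise FormatError(f"secondary-structure TSV needs columns {sorted(required)}")
        entries = tuple(
            SSEntry(str(r.domain), int(r.res_start), int(r.res_end), str(r.kind))
            for r in df.itertuples()
        )
        return cls(entries)

    @classmethod
    def concatenate(cls, *tables: "SecondaryStructureTable") -> "SecondaryStructureTable":
        entries: list[SSEntry] = []
        for t in tables:
            entries.extend(t.entries)
        return cls(tuple(entries))


def load_packaged_sstable(which: str = "complex") -> SecondaryStructureTable:
    """Load the packaged ligand/receptor annotation fixtures.

    ``which`` is one of ``"pdl1"`` (residues 1-115), ``"pd1"`` (116-240) or
    ``"complex"`` (both concatenated, 1-240).
    """
    data = resources.files("semirigid") / "data"
    tables = {
        "pdl1": "pdl1_secondary_structure.tsv",
        "pd1": "pd1_secondary_structure.tsv",
    }
    if which == "complex":
        return SecondaryStructureTable.concatenate(
            load_packaged_sstable("pdl1"), load_packaged_sstable("pd1")
        )
    if which not in tables:
        raise UsageError(f"unknown fixture {which!r}; choose pdl1, pd1 or complex")
    with resources.as_file(data / tables[which]) as p:
        return SecondaryStructureTable.from_tsv(p)


# ---------------------------------------------------------------------------
# reading


def _continuous_residue_numbers(resids: Sequence[int], chains: Sequence[str]) -> list[int]:
    """Assign 1-based continuous residue numbers in atom-list order."""
    numbers: list[int] = []
    current = 0
    prev = None
    for rid, ch in zip(resids, chains):
        key = (ch, rid)
        if key != prev:
            current += 1
            prev = key
        numbers.append(current)
    return numbers


def _prescan_pdb(path: Path) -> int:
    """Validate MODEL structure; returns the model count.

    Rejects altloc/insertion codes and inconsistent atom counts across
    models before handing the file to the actual parser.
    """
    counts: list[int] = []
    in_model = False
    n_atoms = 0
    saw_model_record = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                in_model = True
                n_atoms = 0
            elif rec == "ENDMDL":
                in_model = False
                counts.append(n_atoms)
            elif rec in ("ATOM  ", "HETATM"):
                if len(line) > 16 and line[16] not in (" ", ""):
                    raise FormatError(f"alternate locations are not supported ({path})")
                if len(line) > 26 and line[26] not in (" ", "", "\n"):
                    raise FormatError(f"insertion codes are not supported ({path})")
                n_atoms += 1
    if in_model:  # MODEL without ENDMDL
        counts.append(n_atoms)
    if not saw_model_record:
        if n_atoms == 0:
            raise EmptyInputError(f"no models / atoms in {path}")
        counts = [n_atoms]
    if not counts or all(c == 0 for c in counts):
        raise EmptyInputError(f"no models / atoms in {path}")
    if len(set(counts)) != 1:
        raise FormatError(f"inconsistent atom counts across models in {path}: {sorted(set(counts))}")
    return len(counts)


def _universe(*paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*map(str, paths))


def _atoms_from_universe(u) -> tuple[AtomRecord, ...]:
    names = [str(n) for n in u.atoms.names]
    resids = [int(r) for r in u.atoms.resids]
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except Exception:
        chains = [str(s) for s in u.atoms.segids]
    resnums = _continuous_residue_numbers(resids, chains)
    return tuple(
        AtomRecord(i, names[i], resnums[i], resids[i], chains[i].strip())
        for i in range(len(names))
    )


def read_multimodel_pdb(path: str | Path, dt_frame: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB file; one frame per MODEL, Angstrom -> nm.

    PDB carries no timestamps, so ``dt_frame`` (ps) must be supplied by the
    caller; it defaults to 1 ps.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    _prescan_pdb(path)
    u = _universe(path)
    atoms = _atoms_from_universe(u)
    coords = np.array([u.atoms.positions / ANGSTROM_PER_NM for _ in u.trajectory])
    return Trajectory(coords=coords, dt_frame=dt_frame, atoms=atoms)


def read_xtc(xtc_path: str | Path, atoms_path: str | Path) -> Trajectory:
    """Read a GROMACS XTC with atom metadata from a GRO or single-model PDB.

    dt_frame is taken from the XTC timestamps.
    """
    xtc_path, atoms_path = Path(xtc_path), Path(atoms_path)
    for p in (xtc_path, atoms_path):
        if not p.exists():
            raise UsageError(f"no such file: {p}")
    if xtc_path.stat().st_size == 0:
        raise EmptyInputError(f"empty XTC file: {xtc_path}")
    try:
        u = _universe(atoms_path, xtc_path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read {xtc_path} with atoms from {atoms_path}: {exc}") from exc
    if u.trajectory.n_frames == 0:
        raise EmptyInputError(f"no frames in {xtc_path}")
    atoms = _atoms_from_universe(u)
    dt = float(u.trajectory.dt)
    coords = np.array([u.atoms.positions / ANGSTROM_PER_NM for _ in u.trajectory])
    return Trajectory(coords=coords, dt_frame=dt, atoms=atoms)


# ---------------------------------------------------------------------------
# writing


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write one MODEL per frame, nm -> Angstrom, fixed 3-decimal precision."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in traj.atoms:
                x, y, z = traj.coords[f, a.atom_index] * ANGSTROM_PER_NM
                name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
                chain = (a.chain_id or "A")[0]
                fh.write(
                    f"ATOM  {a.atom_index + 1:5d} {name:<4s} GLY {chain}{a.residue_id:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.atom_name[:1]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_gro(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write a single frame as a GRO file (atom metadata carrier for XTC)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("generated by semirigid\n")
        fh.write(f"{traj.n_atoms:5d}\n")
        for a in traj.atoms:
            x, y, z = traj.coords[frame, a.atom_index]
            fh.write(
                f"{a.residue_id % 100000:5d}{'GLY':<5s}{a.atom_name:>5s}"
                f"{(a.atom_index + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        box = traj.coords[frame].max(axis=0) - traj.coords[frame].min(axis=0) + 2.0
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


def write_xtc(traj: Trajectory, path: str | Path) -> None:
    """Write all frames to a GROMACS XTC (binary, lossy at 1e-3 nm)."""
    from MDAnalysis.coordinates.XTC import XTCWriter

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with XTCWriter(str(path), n_atoms=traj.n_atoms) as w:
            import MDAnalysis as mda

            u = mda.Universe.empty(traj.n_atoms, trajectory=True)
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f] * ANGSTROM_PER_NM
                u.trajectory.ts.frame = f
                u.trajectory.ts.time = f * traj.dt_frame
                u.trajectory.ts.dt = traj.dt_frame
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# trimming / selection / bookkeeping


def trim_frames(traj: Trajectory, discard_time: float) -> Trajectory:
    """Drop all frames with timestamp < ``discard_time`` (ps).

    The remaining frame count is floor((duration - discard_time) / dt).
    """
    if discard_time < 0:
        raise UsageError("discard_time must be >= 0")
    if discard_time == 0:
        return Trajectory(traj.coords.copy(), traj.dt_frame, traj.atoms)
    if discard_time >= traj.duration:
        raise UsageError(
            f"discard_time {discard_time} ps >= trajectory duration {traj.duration} ps"
        )
    keep = traj.times >= discard_time
    return Trajectory(traj.coords[keep].copy(), traj.dt_frame, traj.atoms)


def select_atoms(traj: Trajectory, predicate: Callable[[AtomRecord], bool]) -> list[int]:
    """Indices (sorted, unique, 0-based) of atoms matching a predicate."""
    idx = sorted({a.atom_index for a in traj.atoms if predicate(a)})
    if not idx:
        raise UsageError("atom selection is empty")
    return idx


def calpha_predicate(atom: AtomRecord) -> bool:
    return atom.atom_name == "CA"


def backbone_in_secondary_predicate(
    sstable: SecondaryStructureTable, kinds: Iterable[str] = ("strand", "helix")
) -> Callable[[AtomRecord], bool]:
    """Predicate matching backbone atoms (N, CA, C) in the given SS kinds."""
    residues = sstable.residues_of_kind(kinds)

    def predicate(atom: AtomRecord) -> bool:
        return atom.atom_name in BACKBONE_NAMES and atom.residue_number in residues

    return predicate


def frames_for_duration(duration_ps: float, dt_ps: float) -> int:
    """Frame count implied by sampling ``duration_ps`` every ``dt_ps``."""
    if dt_ps <= 0:
        raise UsageError("dt must be positive")
    n = duration_ps / dt_ps
    if not math.isclose(n, round(n), rel_tol=0, abs_tol=1e-9 * max(1.0, n)):
        raise UsageError(f"duration {duration_ps} ps is not a multiple of dt {dt_ps} ps")
    return int(round(n))
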