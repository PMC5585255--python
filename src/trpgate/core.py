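"""Structural domain model and file I/O.

The package represents a channel system as a :class:`Topology` (atoms grouped
into subunits, a ligand and free waters) plus a :class:`Trajectory` (ordered
frames of Cartesian coordinates).  Units are Å for coordinates and ns for time
throughout; frames are 0-indexed.

Multi-model PDB is the on-disk dialect for structures and trajectories; CSV
(via :func:`write_table`) for all tabular series.  PDB parsing and writing are
delegated to biotite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, QueryError

#: Residue names mapped to the water role.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: Default residue name of the lipid agonist in fixtures.
DEFAULT_LIGAND_RESNAME = "EET"


class Role(str, enum.Enum):
    """Coarse classification of an atom by the residue it belongs to."""

    PROTEIN = "protein"
    LIGAND = "ligand"
    WATER = "water"


def role_from_residue_name(residue_name: str, ligand_resname: str = DEFAULT_LIGAND_RESNAME) -> Role:
    if residue_name in WATER_RESNAMES:
        return Role.WATER
    if residue_name == ligand_resname:
        return Role.LIGAND
    return Role.PROTEIN


@dataclass(frozen=True, slots=True)
class Atom:
    """One atom (or pseudo-atom) of the system."""

    atom_id: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    subunit: str
    role: Role


class Topology:
    """Ordered atom list with fast (subunit, residue, atom-name) lookup."""

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise FormatError("atom_id values must be unique within a topology")
        self.atoms: list[Atom] = atoms
        self._index: dict[tuple[str, int, str], int] = {
            (a.subunit, a.residue_number, a.name): i for i, a in enumerate(atoms)
        }

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def subunit_labels(self) -> list[str]:
        """Distinct protein subunit labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            if a.role is Role.PROTEIN and a.subunit not in seen:
                seen[a.subunit] = None
        return list(seen)

    def index_of(self, subunit: str, residue_number: int, atom_name: str) -> int:
        return self._index[(subunit, residue_number, atom_name)]


_SELECT_FIELDS = frozenset({"subunit", "residue_number", "residue_name", "atom_name", "role"})


def select(topology: Topology, **query) -> np.ndarray:
    """Select atom indices by AND-combined field filters.

    Recognised filters: ``subunit``, ``residue_number``, ``residue_name``,
    ``atom_name``, ``role`` (a :class:`Role` or its string value).  Each may be
    a scalar or a collection of admissible values.  Returns indices in storage
    order; an empty selection is allowed.
    """
    unknown = set(query) - _SELECT_FIELDS
    if unknown:
        raise QueryError(f"unknown selection field(s): {sorted(unknown)}")

    def as_set(value, coerce=lambda v: v):
        if isinstance(value, (str, int, Role)):
            return {coerce(value)}
        try:
            return {coerce(v) for v in value}
        except TypeError:
            raise QueryError(f"malformed selection value: {value!r}") from None

    checks = []
    if "subunit" in query:
        allowed = as_set(query["subunit"], str)
        checks.append(lambda a: a.subunit in allowed)
    if "residue_number" in query:
        allowed_rn = as_set(query["residue_number"], int)
        checks.append(lambda a: a.residue_number in allowed_rn)
    if "residue_name" in query:
        allowed_rname = as_set(query["residue_name"], str)
        checks.append(lambda a: a.residue_name in allowed_rname)
    if "atom_name" in query:
        allowed_an = as_set(query["atom_name"], str)
        checks.append(lambda a: a.name in allowed_an)
    if "role" in query:
        allowed_role = as_set(query["role"], Role)
        checks.append(lambda a: a.role in allowed_role)

    idx = [i for i, a in enumerate(topology.atoms) if all(c(a) for c in checks)]
    return np.asarray(idx, dtype=np.intp)


@dataclass(frozen=True)
class Frame:
    """Coordinates of every atom at one time point (Å)."""

    coordinates: np.ndarray  # (n_atoms, 3)
    frame_index: int
    time_ns: float

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ConsistencyError(f"coordinates must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ConsistencyError("non-finite coordinates in frame")
        object.__setattr__(self, "coordinates", coords)


class Trajectory:
    """Ordered frames over a fixed topology.

    Coordinates are stored as one contiguous ``(n_frames, n_atoms, 3)`` array;
    :class:`Frame` views are built on demand.
    """

    def __init__(self, topology: Topology, coords: np.ndarray, frame_interval_ns: float = 1.0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ConsistencyError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ConsistencyError("a trajectory needs at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ConsistencyError(
                f"coordinate atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise ConsistencyError("non-finite coordinates in trajectory")
        if frame_interval_ns <= 0:
            raise ConsistencyError("frame_interval_ns must be > 0")
        self.topology = topology
        self.coords = coords
        self.frame_interval_ns = float(frame_interval_ns)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        if i < 0:
            i += self.n_frames
        return Frame(self.coords[i], i, i * self.frame_interval_ns)

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self[i]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _read_pdb_stack(path):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
    except OSError:
        raise
    if not any(line.startswith(("ATOM", "HETATM")) for line in pdb.lines):
        raise FormatError(f"no atom records in {path}")
    try:
        stack = pdb.get_structure()
    except Exception as exc:  # biotite raises InvalidFileError on model mismatch
        raise ConsistencyError(f"could not assemble models from {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"no atoms found in {path}")
    return stack


def read_topology(path, ligand_resname: str = DEFAULT_LIGAND_RESNAME) -> Topology:
    """Read a Topology from a (possibly multi-model) PDB file.

    Only the first model is consulted; roles are assigned from residue names
    (waters: HOH/WAT/TIP3/SOL; ligand: *ligand_resname*; everything else
    protein).
    """
    stack = _read_pdb_stack(path)
    first = stack[0] if stack.stack_depth() >= 1 else stack
    atoms = []
    for i in range(first.array_length()):
        res_name = str(first.res_name[i])
        atoms.append(
            Atom(
                atom_id=i,
                name=str(first.atom_name[i]),
                element=str(first.element[i]),
                residue_number=int(first.res_id[i]),
                residue_name=res_name,
                subunit=str(first.chain_id[i]),
                role=role_from_residue_name(res_name, ligand_resname),
            )
        )
    return Topology(atoms)


def read_trajectory(path, topology: Topology, frame_interval_ns: float = 1.0) -> Trajectory:
    """Read all models of a PDB file as frames over *topology*."""
    stack = _read_pdb_stack(path)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise ConsistencyError(
            f"models have {coords.shape[1]} atoms but topology has {topology.n_atoms}"
        )
    return Trajectory(topology, coords, frame_interval_ns)


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB fixture."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.topology.n_atoms
    arr = struc.AtomArray(n)
    top = traj.topology
    arr.chain_id[:] = [a.subunit for a in top.atoms]
    arr.res_id[:] = [a.residue_number for a in top.atoms]
    arr.res_name[:] = [a.residue_name for a in top.atoms]
    arr.atom_name[:] = [a.name for a in top.atoms]
    arr.element[:] = [a.element for a in top.atoms]
    arr.hetero[:] = [a.role is not Role.PROTEIN for a in top.atoms]
    frames = []
    for i in range(traj.n_frames):
        model = arr.copy()
        model.coord = traj.coords[i]
        frames.append(model)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(frames))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(records, path, columns: Sequence[str] | None = None) -> None:
    """Write tabular records as CSV with a header and ≥ 6 significant digits.

    *records* may be a DataFrame, a list of dicts sharing a schema, or a
    mapping of column name to sequence.  Column order is the DataFrame order,
    or *columns* if given.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records) if not isinstance(records, Mapping) else records)
    if columns is not None:
        df = df[list(columns)]
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError:
        raise


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
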