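import numpy as np
import pytest

from trpgate.core import Atom, Role, Topology, Trajectory


def make_topology(spec):
    """Build a Topology from tuples (name, element, resnum, resname, subunit)."""
    atoms = []
    for i, (name, element, resnum, resname, subunit) in enumerate(spec):
        from trpgate.core import role_from_residue_name

        atoms.append(
            Atom(i, name, element, resnum, resname, subunit, role_from_residue_name(resname))
        )
    return Topology(atoms)


def make_trajectory(topology, frames, frame_interval_ns=1.0):
    """Trajectory from a list/array of (n_atoms, 3) coordinate sets."""
    return Trajectory(topology, np.asarray(frames, dtype=float), frame_interval_ns)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gate_water_topology():
    """4 gate Cα + 4 cytosolic protein anchors (for axis orientation) + 2 waters."""
    spec = [("CA", "C", 715, "ILE", s) for s in "ABCD"]
    spec += [("CA", "C", 733, "TRP", s) for s in "ABCD"]
    spec += [("OW", "O", 9001 + i, "HOH", "W") for i in range(2)]
    return make_topology(spec)


def gate_water_coords(n_frames, side, water_z, anchor_z=-12.0):
    """Canonical coordinates for gate_water_topology.

    *water_z*: array (n_frames, n_waters) of axial water positions; the gate
    square of side *side* sits in the z = 0 plane.
    """
    water_z = np.atleast_2d(np.asarray(water_z, dtype=float))
    n_waters = water_z.shape[1]
    coords = np.zeros((n_frames, 8 + n_waters, 3))
    r = side / np.sqrt(2.0)
    angles = np.radians([45, 135, 225, 315])
    for j, a in enumerate(angles):
        coords[:, j, 0] = r * np.cos(a)
        coords[:, j, 1] = r * np.sin(a)
    for j, a in enumerate(angles):  # cytosolic anchors below the gate
        coords[:, 4 + j, 0] = 14 * np.cos(a)
        coords[:, 4 + j, 1] = 14 * np.sin(a)
        coords[:, 4 + j, 2] = anchor_z
    for w in range(n_waters):
        coords[:, 8 + w, 2] = water_z[:, w]
    return coords
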