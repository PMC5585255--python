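"""Ligand-contact occupancy and salt-bridge persistence.

Contact occupancy is the fraction of trajectory frames in which a residue's
minimum heavy-atom distance to the ligand is at or below a cutoff (default
3.5 Å).  The binding site is the set of residues whose occupancy exceeds a
persistence threshold (default 60%, strict inequality).  A wider 5 Å shell —
the convention used to summarise docking poses — is available as
:data:`DOCKING_SHELL_CUTOFF_A`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Frame, Role, Trajectory
from .errors import SelectionError

#: Default contact shell for trajectory occupancy.
DEFAULT_CONTACT_CUTOFF_A = 3.5

#: Wider shell used when summarising docking-pose contacts.
DOCKING_SHELL_CUTOFF_A = 5.0

#: Conventional N–O salt-bridge cutoff (Lys NZ to Asp carboxylate O).
DEFAULT_SALT_BRIDGE_CUTOFF_A = 4.0


@dataclass(frozen=True)
class ContactRecord:
    subunit: str
    residue_number: int
    residue_name: str
    occupancy: float
    mean_min_distance_A: float


@dataclass(frozen=True)
class ContactProfile:
    """Per-residue ligand-contact occupancy over a trajectory."""

    records: tuple[ContactRecord, ...]
    cutoff_A: float
    n_frames: int

    def occupancy(self, subunit: str, residue_number: int) -> float:
        for r in self.records:
            if r.subunit == subunit and r.residue_number == residue_number:
                return r.occupancy
        raise KeyError((subunit, residue_number))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subunit": [r.subunit for r in self.records],
                "resnum": [r.residue_number for r in self.records],
                "resname": [r.residue_name for r in self.records],
                "occupancy": [r.occupancy for r in self.records],
                "mean_min_dist_A": [r.mean_min_distance_A for r in self.records],
            }
        )


@dataclass(frozen=True)
class SaltBridgeSeries:
    """Per-frame bridged state and donor–acceptor minimum distance."""

    bridged: np.ndarray  # bool, (n_frames,)
    distance_A: np.ndarray  # (n_frames,)
    cutoff_A: float

    @property
    def persistence(self) -> float:
        return float(np.mean(self.bridged))


def min_residue_ligand_distance(frame: Frame, residue_indices, ligand_indices) -> float:
    """Minimum pairwise Euclidean distance between two atom sets (Å)."""
    residue_indices = np.asarray(residue_indices, dtype=np.intp)
    ligand_indices = np.asarray(ligand_indices, dtype=np.intp)
    if residue_indices.size == 0 or ligand_indices.size == 0:
        raise SelectionError("empty atom set in distance computation")
    d = cdist(frame.coordinates[residue_indices], frame.coordinates[ligand_indices])
    return float(d.min())


def _protein_residue_groups(topology):
    """Ordered mapping (subunit, resnum) -> (resname, atom index array)."""
    groups: dict[tuple[str, int], list[int]] = {}
    names: dict[tuple[str, int], str] = {}
    for i, a in enumerate(topology.atoms):
        if a.role is not Role.PROTEIN:
            continue
        key = (a.subunit, a.residue_number)
        groups.setdefault(key, []).append(i)
        names.setdefault(key, a.residue_name)
    return {k: (names[k], np.asarray(v, dtype=np.intp)) for k, v in groups.items()}


def contact_occupancy_profile(
    traj: Trajectory,
    ligand_indices,
    cutoff_A: float = DEFAULT_CONTACT_CUTOFF_A,
    start_frame: int = 0,
) -> ContactProfile:
    """Per-residue fraction of frames with min distance to the ligand ≤ cutoff.

    Every protein residue in the topology gets a record (per subunit, no
    pooling across the tetramer).  ``start_frame`` discards an initial
    equilibration window before counting.
    """
    ligand_indices = np.asarray(ligand_indices, dtype=np.intp)
    if ligand_indices.size == 0:
        raise SelectionError("no ligand atoms selected")
    groups = _protein_residue_groups(traj.topology)
    coords = traj.coords[start_frame:]
    n_frames = coords.shape[0]
    if n_frames == 0:
        raise SelectionError("start_frame leaves no frames to analyse")

    lig = coords[:, ligand_indices, :]  # (F, L, 3)
    records = []
    for (subunit, resnum), (resname, idx) in groups.items():
        res = coords[:, idx, :]  # (F, R, 3)
        # pairwise distances per frame: (F, R, L)
        diff = res[:, :, None, :] - lig[:, None, :, :]
        dmin = np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=(1, 2))
        occ = float(np.mean(dmin <= cutoff_A))
        records.append(ContactRecord(subunit, resnum, resname, occ, float(dmin.mean())))
    return ContactProfile(tuple(records), float(cutoff_A), n_frames)


def detect_binding_site(profile: ContactProfile, threshold: float = 0.6):
    """Residues whose occupancy strictly exceeds *threshold*.

    Returns ``[(subunit, residue_number), ...]`` ordered by subunit then
    residue number.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    site = [
        (r.subunit, r.residue_number)
        for r in profile.records
        if r.occupancy > threshold
    ]
    return sorted(site)


def salt_bridge_persistence(
    traj: Trajectory,
    donor_index: int,
    acceptor_indices,
    cutoff_A: float = DEFAULT_SALT_BRIDGE_CUTOFF_A,
) -> SaltBridgeSeries:
    """Per-frame salt-bridge state between a donor atom and acceptor set."""
    acceptor_indices = np.asarray(acceptor_indices, dtype=np.intp)
    if acceptor_indices.size == 0:
        raise SelectionError("empty acceptor set")
    donor = traj.coords[:, int(donor_index), :]  # (F, 3)
    acc = traj.coords[:, acceptor_indices, :]  # (F, A, 3)
    d = np.linalg.norm(acc - donor[:, None, :], axis=-1).min(axis=1)
    return SaltBridgeSeries(bridged=d <= cutoff_A, distance_A=d, cutoff_A=float(cutoff_A))
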