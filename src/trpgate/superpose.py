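"""Rigid-body superposition and replicate RMSD statistics.

RMSD between conformations is the least-squares residual after optimal rigid
alignment (Kabsch superposition, proper rotations only).  Replicate summaries
follow the "mean ± S.D., n" convention: each replicate is reduced to its time
mean first, then mean and sample SD (n−1) are taken across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Frame, Role, Trajectory, select
from .errors import ConfigurationError, DegenerateGeometryError


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation 3×3, translation Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class RMSDSeries:
    rmsd_A: np.ndarray
    selection: np.ndarray

    @property
    def time_mean_A(self) -> float:
        return float(np.mean(self.rmsd_A))


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float  # sample SD (n−1)
    n: int
    replicate_means: tuple[float, ...]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper-rotation superposition of *mobile* onto *reference*.

    Returns ``(RigidTransform, rmsd_A)`` where the transform maps mobile
    coordinates onto the reference and the RMSD is the minimized value.
    Reflections are excluded, so mirror-image point sets keep a positive
    residual.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError("point sets must share shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise DegenerateGeometryError("collinear or coincident point configuration")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    resid = mob_c @ R.T - ref_c  # residual recomputed for full precision
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return RigidTransform(R, t), rmsd


def rmsd_to_reference(
    traj: Trajectory, reference: Frame | np.ndarray | None = None, selection=None
) -> RMSDSeries:
    """Per-frame minimized RMSD of a trajectory against a reference frame.

    Default selection: all protein Cα (pseudo-)atoms.  Default reference:
    frame 0.  Superposition and measurement use the same selection.
    """
    if selection is None:
        selection = select(traj.topology, atom_name="CA", role=Role.PROTEIN)
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size < 3:
        raise DegenerateGeometryError("RMSD selection needs at least 3 atoms")
    if reference is None:
        ref = traj.coords[0][selection]
    elif isinstance(reference, Frame):
        ref = reference.coordinates[selection]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == traj.topology.n_atoms:
            ref = ref[selection]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = kabsch_superpose(traj.coords[i][selection], ref)
    return RMSDSeries(rmsd_A=out, selection=selection)


def aggregate_replicates(series) -> ReplicateSummary:
    """Across-replicate mean ± sample SD of per-replicate time means.

    *series* is a list of :class:`RMSDSeries` and/or scalars (a scalar is a
    replicate already reduced to its summary value).
    """
    if not series:
        raise ConfigurationError("no replicates to aggregate")
    means = []
    for s in series:
        if isinstance(s, RMSDSeries):
            means.append(s.time_mean_A)
        else:
            means.append(float(np.mean(np.asarray(s, dtype=float))))
    arr = np.asarray(means)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return ReplicateSummary(float(arr.mean()), sd, int(n), tuple(means))
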