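"""Lower-gate geometry and water permeation.

The gate of a tetrameric channel is tracked through the quadrilateral formed
by the four pore-lining Cα atoms (I715 in TRPV4).  Per frame we fit a plane
to the four corners, project them onto it, and report the shoelace area of
the azimuthally ordered polygon — well defined even when the corners are not
exactly coplanar, and invariant to corner ordering and rigid motion.

Permeation is counted with a two-plane hysteresis: a water completes an
up-crossing only when it passes from below ``-d`` to above ``+d`` along the
pore axis without first retreating below ``-d`` (mirror definition for
down-crossings).  Boundary flicker at a single plane therefore never
double-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Role, Trajectory
from .errors import ConfigurationError, DegenerateGeometryError, SelectionError

_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class GateGeometrySeries:
    """Per-frame gate area with summary statistics (population SD)."""

    area_A2: np.ndarray
    mean_A2: float
    sd_A2: float
    max_out_of_plane_A: np.ndarray  # per-frame non-planarity diagnostic
    segment_summaries: tuple[tuple[str, float, float], ...] = ()


@dataclass(frozen=True)
class PairDistanceSeries:
    label: str
    distance_A: np.ndarray
    mean_A: float
    sd_A: float


@dataclass(frozen=True)
class PermeationEvent:
    water_id: int
    entry_frame: int
    exit_frame: int
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class PermeationEventLog:
    events: tuple[PermeationEvent, ...]
    plane_offset_A: float

    @property
    def n_up(self) -> int:
        return sum(1 for e in self.events if e.direction == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for e in self.events if e.direction == "down")


@dataclass(frozen=True)
class WaterDensitySeries:
    counts: np.ndarray  # int per frame
    radius_A: float


def _gate_corners(frame_coords: np.ndarray, gate_indices) -> np.ndarray:
    gate_indices = np.asarray(gate_indices, dtype=np.intp)
    if gate_indices.size != 4:
        raise SelectionError(f"gate selection must resolve to 4 atoms, got {gate_indices.size}")
    return frame_coords[gate_indices]


def _plane_fit(corners: np.ndarray):
    """Total-least-squares plane through points: (center, unit normal)."""
    center = corners.mean(axis=0)
    centered = corners - center
    # SVD: smallest right singular vector is the plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= _DEGENERACY_TOL * max(1.0, s[0]):
        raise DegenerateGeometryError("gate corners are collinear or coincident")
    return center, vt[2]


def estimate_pore_axis(frame: Frame, gate_indices, orient_toward=None):
    """Pore axis (unit vector) and gate center from four gate Cα atoms.

    The axis is the normal of the best-fit plane through the corners.  Its
    sign is chosen toward ``orient_toward`` (a reference point or point set on
    the extracellular side) when given; otherwise the sign is canonical but
    arbitrary.
    """
    corners = _gate_corners(frame.coordinates, gate_indices)
    center, normal = _plane_fit(corners)
    if orient_toward is not None:
        ref = np.atleast_2d(np.asarray(orient_toward, dtype=float)).mean(axis=0)
        if np.dot(normal, ref - center) < 0:
            normal = -normal
    else:
        # deterministic sign: make the largest-magnitude component positive
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
    return normal, center


def _projected_polygon_area(corners: np.ndarray) -> tuple[float, float]:
    """(shoelace area of azimuth-ordered projection, max out-of-plane dev)."""
    center, normal = _plane_fit(corners)
    rel = corners - center
    out = rel @ normal
    in_plane = rel - np.outer(out, normal)
    # orthonormal basis of the plane
    u = in_plane[int(np.argmax(np.linalg.norm(in_plane, axis=1)))]
    nu = np.linalg.norm(u)
    if nu <= _DEGENERACY_TOL:
        raise DegenerateGeometryError("gate corners coincide with the centroid")
    u = u / nu
    v = np.cross(normal, u)
    x, y = in_plane @ u, in_plane @ v
    order = np.argsort(np.arctan2(y, x))
    x, y = x[order], y[order]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area), float(np.max(np.abs(out)))


def gate_area(frame: Frame, gate_indices) -> float:
    """Area (Å²) of the gate quadrilateral; s² exactly for a square of side s."""
    corners = _gate_corners(frame.coordinates, gate_indices)
    area, _ = _projected_polygon_area(corners)
    return area


def gate_area_series(
    traj: Trajectory,
    gate_indices,
    window: tuple[int, int] | None = None,
    segments: dict[str, tuple[int, int]] | None = None,
) -> GateGeometrySeries:
    """Per-frame gate area with mean ± SD over *window* (default all frames).

    *segments* maps labels to ``(start, stop)`` frame ranges for separate
    summaries, e.g. first/last thirds of a closed→open schedule.
    """
    areas = np.empty(traj.n_frames)
    oop = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        corners = _gate_corners(traj.coords[i], gate_indices)
        areas[i], oop[i] = _projected_polygon_area(corners)
    lo, hi = window if window is not None else (0, traj.n_frames)
    win = areas[lo:hi]
    if win.size == 0:
        raise ConfigurationError("summary window contains no frames")
    seg_summaries = tuple(
        (label, float(areas[a:b].mean()), float(areas[a:b].std()))
        for label, (a, b) in (segments or {}).items()
    )
    return GateGeometrySeries(
        area_A2=areas,
        mean_A2=float(win.mean()),
        sd_A2=float(win.std()),
        max_out_of_plane_A=oop,
        segment_summaries=seg_summaries,
    )


def ca_pair_distance_series(
    traj: Trajectory, index_a: int, index_b: int, label: str = ""
) -> PairDistanceSeries:
    """Per-frame distance between two atoms, with mean ± SD (Å)."""
    try:
        a = traj.coords[:, int(index_a), :]
        b = traj.coords[:, int(index_b), :]
    except IndexError as exc:
        raise SelectionError(f"atom index out of range: {exc}") from exc
    d = np.linalg.norm(a - b, axis=1)
    return PairDistanceSeries(label, d, float(d.mean()), float(d.std()))


def _default_orientation_reference(traj: Trajectory, gate_indices) -> np.ndarray:
    """Centroid of non-gate protein atoms, per frame (F, 3).

    In TRP-channel architecture the cytosolic domains dominate the protein
    mass below the lower gate, so the axis oriented *away* from this centroid
    points extracellularly.
    """
    gate = set(int(i) for i in np.asarray(gate_indices).ravel())
    idx = [
        i
        for i, a in enumerate(traj.topology.atoms)
        if a.role is Role.PROTEIN and i not in gate
    ]
    if not idx:
        raise SelectionError("no non-gate protein atoms to orient the pore axis")
    return traj.coords[:, idx, :].mean(axis=1)


def axial_water_coordinates(
    traj: Trajectory, water_indices, gate_indices, orient_toward=None
) -> np.ndarray:
    """Signed axial coordinate of each water relative to the gate center.

    Shape ``(n_frames, n_waters)``.  Positive = extracellular side.  The axis
    is refit per frame; its sign points away from the cytosolic protein mass
    unless *orient_toward* supplies explicit extracellular reference points
    (an array of shape (3,), (k, 3) or (n_frames, 3)).
    """
    water_indices = np.asarray(water_indices, dtype=np.intp)
    z = np.empty((traj.n_frames, water_indices.size))
    if orient_toward is None:
        anti_ref = _default_orientation_reference(traj, gate_indices)
    for i in range(traj.n_frames):
        corners = _gate_corners(traj.coords[i], gate_indices)
        center, normal = _plane_fit(corners)
        if orient_toward is None:
            if np.dot(normal, anti_ref[i] - center) > 0:
                normal = -normal
        else:
            ref = np.asarray(orient_toward, dtype=float)
            if ref.ndim == 2 and ref.shape[0] == traj.n_frames:
                ref_pt = ref[i]
            else:
                ref_pt = np.atleast_2d(ref).mean(axis=0)
            if np.dot(normal, ref_pt - center) < 0:
                normal = -normal
        z[i] = (traj.coords[i, water_indices, :] - center) @ normal
    return z


def count_water_crossings(
    traj: Trajectory,
    water_indices,
    gate_indices,
    plane_offset_A: float = 5.0,
    orient_toward=None,
) -> PermeationEventLog:
    """Count completed water permeation events through the gate slab.

    Two planes at ±``plane_offset_A`` along the pore axis define a slab; an
    up-crossing is a passage from below the lower plane to above the upper
    plane without retreating below the lower plane while inside the slab
    (and symmetrically for down).  Waters that never leave the slab on the
    far side contribute nothing.
    """
    if plane_offset_A <= 0:
        raise ConfigurationError("plane_offset_A must be > 0")
    if traj.n_frames < 2:
        raise ConfigurationError("crossing detection needs at least 2 frames")
    water_indices = np.asarray(water_indices, dtype=np.intp)
    events: list[PermeationEvent] = []
    if water_indices.size:
        z = axial_water_coordinates(traj, water_indices, gate_indices, orient_toward)
        d = float(plane_offset_A)
        for w in range(water_indices.size):
            side = None  # last compartment occupied outside the slab
            entry = None  # frame the current slab excursion started
            for t in range(traj.n_frames):
                zt = z[t, w]
                if zt < -d:
                    if side == "above":
                        events.append(
                            PermeationEvent(
                                int(water_indices[w]),
                                entry if entry is not None else t,
                                t,
                                "down",
                            )
                        )
                    side, entry = "below", None
                elif zt > d:
                    if side == "below":
                        events.append(
                            PermeationEvent(
                                int(water_indices[w]),
                                entry if entry is not None else t,
                                t,
                                "up",
                            )
                        )
                    side, entry = "above", None
                else:
                    if entry is None:
                        entry = t
    events.sort(key=lambda e: (e.exit_frame, e.water_id))
    return PermeationEventLog(tuple(events), float(plane_offset_A))


def water_presence_series(
    traj: Trajectory, water_indices, gate_indices, radius_A: float = 6.0
) -> WaterDensitySeries:
    """Per-frame count of waters within *radius_A* of the gate centroid."""
    if radius_A <= 0:
        raise ConfigurationError("radius_A must be > 0")
    water_indices = np.asarray(water_indices, dtype=np.intp)
    counts = np.zeros(traj.n_frames, dtype=int)
    if water_indices.size:
        gate_indices = np.asarray(gate_indices, dtype=np.intp)
        centers = traj.coords[:, gate_indices, :].mean(axis=1)  # (F, 3)
        d = np.linalg.norm(
            traj.coords[:, water_indices, :] - centers[:, None, :], axis=-1
        )
        counts = (d <= radius_A).sum(axis=1)
    return WaterDensitySeries(counts=counts, radius_A=float(radius_A))
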