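"""Seeded synthetic channel trajectories and assay recordings.

These generators emulate the *statistical* structure the analysis layer
assumes — nothing here is physical dynamics.  A coarse tetramer is built from
one Cα pseudo-atom per residue of interest (plus a side-chain pseudo-atom
where an analysis needs one: Lys535 NZ and Asp743 OD1), a four-atom ligand
with a carboxylate head, and free waters.  Every ground-truth parameter in
the configs (contact fractions, gate-area schedule, crossing counts,
salt-bridge persistence, Kd, AUC, current density, NPo) is recoverable by the
corresponding analysis operation; the generators and analyzers are tested as
closed round trips.

All outputs are fully determined by the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .assays import (
    CalciumTrace,
    GapFreeRecording,
    MSTTrace,
    RampRecording,
    TitrationCurve,
    mass_action_bound_fraction,
)
from .core import Atom, Role, Topology, Trajectory
from .errors import ConfigurationError

#: Residues of interest carried by every subunit of the pseudo-tetramer.
PSEUDO_RESIDUES: dict[int, str] = {
    535: "LYS",
    549: "PHE",
    550: "GLN",
    556: "TYR",
    591: "TYR",
    594: "ARG",
    596: "LEU",
    715: "ILE",
    733: "TRP",
    743: "ASP",
}

SUBUNITS = ("A", "B", "C", "D")

#: Distance at which "contact" frames place the pocket pseudo-atom from the
#: ligand head — strictly inside the 3.5 Å analysis cutoff so that small
#: positional noise cannot flip the contact state.
CONTACT_PLACEMENT_A = 2.5
NONCONTACT_PLACEMENT_A = 8.0
BRIDGE_PLACEMENT_A = 3.0
NONBRIDGE_PLACEMENT_A = 8.0


@dataclass
class GateSegment:
    """Square-side statistics for one stretch of frames (closed or open)."""

    side_mean_A: float
    side_sd_A: float
    n_frames: int | None = None  # None → equal share of remaining frames


@dataclass
class ChannelSimConfig:
    n_frames: int = 600
    frame_interval_ns: float = 0.2  # 120 ns / 600 frames
    noise_sigma_A: float = 0.1
    contact_schedule: dict[int, float] = field(default_factory=dict)
    gate_segments: list[GateSegment] = field(
        default_factory=lambda: [GateSegment(7.45, 0.19)]
    )
    n_waters: int = 20
    crossings_up: int = 0
    crossings_down: int = 0
    salt_bridge_fraction: float = 1.0
    pocket_subunit: str = "A"
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be ≥ 1")
        if self.frame_interval_ns <= 0:
            raise ConfigurationError("frame_interval_ns must be > 0")
        for res, frac in self.contact_schedule.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"contact fraction for {res} outside [0, 1]")
        if not 0.0 <= self.salt_bridge_fraction <= 1.0:
            raise ConfigurationError("salt_bridge_fraction outside [0, 1]")
        for seg in self.gate_segments:
            if seg.side_mean_A <= 0:
                raise ConfigurationError("gate side mean must be > 0")
            if seg.side_sd_A < 0:
                raise ConfigurationError("gate side SD must be ≥ 0")
        if self.crossings_up < 0 or self.crossings_down < 0:
            raise ConfigurationError("crossing counts must be ≥ 0")
        if self.n_waters < 0:
            raise ConfigurationError("n_waters must be ≥ 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChannelSimConfig":
        raw = json.loads(text)
        raw["gate_segments"] = [GateSegment(**g) for g in raw.get("gate_segments", [])]
        raw["contact_schedule"] = {
            int(k): float(v) for k, v in raw.get("contact_schedule", {}).items()
        }
        return cls(**raw)


@dataclass
class AssaySimConfig:
    kd_uM: float = 12.8
    amplitude: float = -0.03  # ΔF_norm span at saturation (thermophoretic depletion)
    protein_conc_nM: float = 20.0
    concentrations_uM: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.027, 225.0, 16)
    )
    noise_frac: float = 0.05
    auc_target: float = 60.0  # normalized-ratio · s
    current_density_target_pA_pF: float = 10.0
    capacitance_pF: float = 20.0
    npo_target: float = 0.5
    single_channel_pA: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ConfigurationError("concentrations must be positive and strictly increasing")
        if self.kd_uM <= 0:
            raise ConfigurationError("kd_uM must be > 0")
        if self.npo_target < 0:
            raise ConfigurationError("npo_target must be ≥ 0")
        if self.single_channel_pA == 0:
            raise ConfigurationError("single_channel_pA must be nonzero")


def gate_sides_for_area(area_mean_A2: float, area_sd_A2: float) -> tuple[float, float]:
    """Square-side (mean, SD) whose area s² has the requested mean and SD.

    With s ~ N(m, σ): E[s²] = m² + σ² and Var[s²] = 4m²σ² + 2σ⁴, which this
    inverts in closed form.
    """
    A, S = float(area_mean_A2), float(area_sd_A2)
    if A <= 0 or S < 0:
        raise ConfigurationError("area mean must be > 0 and SD ≥ 0")
    disc = A * A - S * S / 2.0
    if disc <= 0:
        raise ConfigurationError("area SD too large for a Gaussian-side square")
    u = A - math.sqrt(disc)  # σ²
    return math.sqrt(A - u), math.sqrt(u)


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def build_tetramer_topology(config: ChannelSimConfig) -> Topology:
    """Coarse four-fold tetramer: 12 pseudo-atoms per subunit, a 4-atom
    ligand and ``n_waters`` water oxygens."""
    config.validate()
    atoms: list[Atom] = []
    aid = 0
    for sub in SUBUNITS:
        for res, resname in PSEUDO_RESIDUES.items():
            atoms.append(Atom(aid, "CA", "C", res, resname, sub, Role.PROTEIN))
            aid += 1
            if res == 535:
                atoms.append(Atom(aid, "NZ", "N", res, resname, sub, Role.PROTEIN))
                aid += 1
            elif res == 743:
                atoms.append(Atom(aid, "OD1", "O", res, resname, sub, Role.PROTEIN))
                aid += 1
    for name in ("C1", "C2", "C3", "C4"):  # C1 carries the carboxylate head
        atoms.append(Atom(aid, name, "C", 900, "EET", "L", Role.LIGAND))
        aid += 1
    for w in range(config.n_waters):
        atoms.append(Atom(aid, "OW", "O", 9001 + w, "HOH", "W", Role.WATER))
        aid += 1
    return Topology(atoms)


def _base_coordinates(topology: Topology) -> np.ndarray:
    """Static scaffold positions (Å) in the canonical frame: gate plane at
    z = 0, cytosolic domains below, ligand pocket near subunit A."""
    coords = np.zeros((topology.n_atoms, 3))
    # residue-group depths below the gate (cytosolic side is z < 0)
    depth = {535: -16.0, 549: -16.0, 550: -16.0, 556: -15.0, 591: -10.0,
             594: -8.0, 596: -8.0, 715: 0.0, 733: -12.0, 743: -12.0}
    sub_angle = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
    res_angle = {res: 8.0 * k for k, res in enumerate(PSEUDO_RESIDUES)}
    for i, a in enumerate(topology.atoms):
        if a.role is Role.PROTEIN:
            if a.residue_number == 715 and a.name == "CA":
                # gate corners are rewritten per frame; placeholder square
                ang = math.radians(sub_angle[a.subunit] + 45.0)
                coords[i] = [7.45 / math.sqrt(2) * math.cos(ang),
                             7.45 / math.sqrt(2) * math.sin(ang), 0.0]
            else:
                ang = math.radians(sub_angle[a.subunit] + res_angle[a.residue_number])
                r = 14.0
                z = depth[a.residue_number]
                base = np.array([r * math.cos(ang), r * math.sin(ang), z])
                if a.name == "NZ":  # Lys535 side chain reaches toward the TRP box
                    base = base + np.array([0.0, 0.0, 2.0])
                elif a.name == "OD1":
                    base = base + np.array([1.0, 1.0, 1.0])
                coords[i] = base
        elif a.role is Role.LIGAND:
            k = {"C1": 0, "C2": 1, "C3": 2, "C4": 3}[a.name]
            coords[i] = np.array([22.0 + 1.4 * k, 3.0, -14.0])
        else:  # waters are rewritten per frame; park below the gate
            coords[i] = np.array([0.0, 0.0, -9.0])
    return coords


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _segment_lengths(config: ChannelSimConfig) -> list[int]:
    fixed = sum(s.n_frames for s in config.gate_segments if s.n_frames is not None)
    free = [s for s in config.gate_segments if s.n_frames is None]
    remaining = config.n_frames - fixed
    if remaining < 0 or (free and remaining < len(free)):
        raise ConfigurationError("gate segments request more frames than n_frames")
    if not free and remaining != 0:
        raise ConfigurationError("gate segment frame counts must sum to n_frames")
    lengths = []
    share = remaining // len(free) if free else 0
    extra = remaining - share * len(free) if free else 0
    it_free = iter(range(len(free)))
    for s in config.gate_segments:
        if s.n_frames is not None:
            lengths.append(s.n_frames)
        else:
            k = next(it_free)
            lengths.append(share + (1 if k < extra else 0))
    return lengths


def _allocate_crossings(config: ChannelSimConfig) -> list[list[str]]:
    """Split requested up/down crossings into per-water alternating event
    sequences; raises if the schedule cannot fit the water/frame budget."""
    total = config.crossings_up + config.crossings_down
    if total == 0:
        return []
    if config.n_waters == 0:
        raise ConfigurationError("crossings requested but n_waters is 0")
    cap = max(1, math.ceil(total / config.n_waters))
    u, d = config.crossings_up, config.crossings_down
    seqs: list[list[str]] = []
    while u > 0 or d > 0:
        seq: list[str] = []
        side = "below" if u >= d else "above"
        while len(seq) < cap and (u > 0 or d > 0):
            if side == "below" and u > 0:
                seq.append("up")
                u -= 1
                side = "above"
            elif side == "above" and d > 0:
                seq.append("down")
                d -= 1
                side = "below"
            else:
                break
        seqs.append(seq)
    if len(seqs) > config.n_waters:
        raise ConfigurationError("not enough waters for the requested crossings")
    per_water_frames = max(len(s) for s in seqs) * 3 + 1
    if per_water_frames > config.n_frames:
        raise ConfigurationError("n_frames too small for the requested crossings")
    return seqs


def _water_z_path(seq: list[str], n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-linear axial path realizing the event sequence exactly.

    Travel legs run ±8 → ∓8 (3 Å beyond the ±5 Å hysteresis planes); waters
    with no events make "touch and retreat" excursions into the slab so the
    counter's state machine is exercised without producing events.
    """
    z = np.empty(n_frames)
    if not seq:
        # decoy: oscillate from −8 up to a peak below +5 and back
        peak = float(rng.uniform(-1.0, 3.5))
        period = max(6, n_frames // max(1, int(rng.integers(1, 4))))
        for t in range(n_frames):
            phase = (t % period) / period
            tri = 1.0 - abs(2.0 * phase - 1.0)  # 0→1→0
            z[t] = -8.0 + (peak + 8.0) * tri
        return z
    start = -8.0 if seq[0] == "up" else 8.0
    n_legs = len(seq)
    leg_len = n_frames // n_legs
    pos = start
    t = 0
    for k, ev in enumerate(seq):
        end = 8.0 if ev == "up" else -8.0
        stop = n_frames if k == n_legs - 1 else t + leg_len
        span = stop - t
        # linear travel with a mid-leg hesitation inside the slab
        for j in range(span):
            frac = (j + 1) / span
            z[t + j] = pos + (end - pos) * frac
        pos = end
        t = stop
    return z


def simulate_channel_trajectory(topology: Topology, config: ChannelSimConfig) -> Trajectory:
    """Simulate a coarse trajectory with known analysis ground truths.

    Per frame: gate corners form a square whose side is drawn from the active
    :class:`GateSegment`; scheduled pocket residues touch the ligand head
    (2.5 Å) in an exact-count random subset of frames; water axial paths
    realize the requested crossing counts exactly; the Lys535–Asp743 pair is
    bridged in the scheduled fraction of frames; the whole frame is then
    rigidly rotated/translated at random and iid Gaussian noise is added.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_frames, n_atoms = config.n_frames, topology.n_atoms
    base = _base_coordinates(topology)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    sub = config.pocket_subunit
    idx = topology.index_of

    # --- gate squares ---------------------------------------------------
    gate_idx = [idx(s, 715, "CA") for s in SUBUNITS]
    lengths = _segment_lengths(config)
    sides = np.empty(n_frames)
    t0 = 0
    for seg, L in zip(config.gate_segments, lengths):
        sides[t0:t0 + L] = rng.normal(seg.side_mean_A, seg.side_sd_A, size=L)
        t0 += L
    sides = np.abs(sides)
    corner_angles = np.radians([45.0, 135.0, 225.0, 315.0])
    for j, gi in enumerate(gate_idx):
        coords[:, gi, 0] = sides / math.sqrt(2) * math.cos(corner_angles[j])
        coords[:, gi, 1] = sides / math.sqrt(2) * math.sin(corner_angles[j])
        coords[:, gi, 2] = 0.0

    # --- ligand contacts (exact-count frame subsets) --------------------
    lig_head = base[idx("L", 900, "C1")]
    for k, (res, frac) in enumerate(sorted(config.contact_schedule.items())):
        ai = idx(sub, res, "CA")
        n_contact = round(frac * n_frames)
        chosen = rng.choice(n_frames, size=n_contact, replace=False)
        # fixed approach direction per residue, away from the other ligand atoms
        theta = 2.0 * math.pi * (k + 1) / (len(config.contact_schedule) + 2)
        unit = np.array([-math.cos(theta * 0.3), math.sin(theta * 0.3), math.cos(theta)])
        unit /= np.linalg.norm(unit)
        near = lig_head + CONTACT_PLACEMENT_A * unit
        far = lig_head + NONCONTACT_PLACEMENT_A * unit
        coords[:, ai, :] = far
        coords[chosen, ai, :] = near

    # --- salt bridge ----------------------------------------------------
    nz, od1 = idx(sub, 535, "NZ"), idx(sub, 743, "OD1")
    n_bridge = round(config.salt_bridge_fraction * n_frames)
    bridged = rng.choice(n_frames, size=n_bridge, replace=False)
    direction = np.array([0.0, 0.0, 1.0])
    coords[:, nz, :] = base[od1] + NONBRIDGE_PLACEMENT_A * direction
    coords[bridged, nz, :] = base[od1] + BRIDGE_PLACEMENT_A * direction

    # --- waters ---------------------------------------------------------
    water_idx = [i for i, a in enumerate(topology.atoms) if a.role is Role.WATER]
    seqs = _allocate_crossings(config)
    for w, wi in enumerate(water_idx):
        seq = seqs[w] if w < len(seqs) else []
        z = _water_z_path(seq, n_frames, rng)
        r = rng.uniform(0.0, 1.5)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        coords[:, wi, 0] = r * math.cos(phi)
        coords[:, wi, 1] = r * math.sin(phi)
        coords[:, wi, 2] = z

    # --- per-frame rigid transform + noise ------------------------------
    quats = rng.normal(size=(n_frames, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    shifts = rng.uniform(-20.0, 20.0, size=(n_frames, 3))
    for t in range(n_frames):
        R = Rotation.from_quat(quats[t]).as_matrix()
        coords[t] = coords[t] @ R.T + shifts[t]
    if config.noise_sigma_A > 0:
        coords += rng.normal(0.0, config.noise_sigma_A, size=(n_frames, n_atoms, 3))
    return Trajectory(topology, coords, config.frame_interval_ns)


# ---------------------------------------------------------------------------
# Replicate RMSD generators
# ---------------------------------------------------------------------------

def reference_ca_structure(n_atoms: int = 400, seed: int = 0) -> tuple[Topology, np.ndarray]:
    """A featureless Cα cloud (uniform in a 40 Å box) used as RMSD reference."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(i, "CA", "C", i + 1, "GLY", "A", Role.PROTEIN) for i in range(n_atoms)
    ]
    return Topology(atoms), rng.uniform(-20.0, 20.0, size=(n_atoms, 3))


def simulate_noisy_replicate(
    topology: Topology,
    reference_coords: np.ndarray,
    sigma_A: float,
    n_frames: int,
    seed: int,
    frame_interval_ns: float = 0.2,
) -> Trajectory:
    """Frames = reference + iid Gaussian noise (σ per coordinate), each frame
    additionally carried through a random rigid motion.

    For many atoms the minimized RMSD of such frames concentrates at σ·√3,
    so σ = target_RMSD/√3 calibrates a replicate to a wanted RMSD level.
    """
    if sigma_A < 0:
        raise ConfigurationError("sigma_A must be ≥ 0")
    rng = np.random.default_rng(seed)
    ref = np.asarray(reference_coords, dtype=float)
    coords = np.empty((n_frames, ref.shape[0], 3))
    for t in range(n_frames):
        frame = ref + rng.normal(0.0, sigma_A, size=ref.shape)
        quat = rng.normal(size=4)
        R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        coords[t] = frame @ R.T + rng.uniform(-15.0, 15.0, size=3)
    return Trajectory(topology, coords, frame_interval_ns)


# ---------------------------------------------------------------------------
# Assay generators
# ---------------------------------------------------------------------------

def simulate_mst_titration(config: AssaySimConfig) -> TitrationCurve:
    """ΔF_norm(c) = amplitude · bound_fraction(c) · (1 + ε), ε ~ N(0, noise_frac).

    The bound fraction uses exact 1:1 mass action (quadratic form) with the
    stated total protein concentration, so ligand depletion is represented
    even though it is negligible at 20 nM protein.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations_uM, dtype=float)
    fb = mass_action_bound_fraction(conc, config.kd_uM, config.protein_conc_nM / 1000.0)
    eps = rng.normal(0.0, config.noise_frac, size=conc.size) if config.noise_frac > 0 else 0.0
    response = config.amplitude * fb * (1.0 + eps)
    return TitrationCurve(
        concentration_uM=conc,
        delta_fnorm=np.asarray(response, dtype=float),
        replicate=np.zeros(conc.size, dtype=int),
        protein_conc_nM=config.protein_conc_nM,
    )


def simulate_mst_traces(
    config: AssaySimConfig,
    cold_level: float = 1000.0,
    baseline_depletion: float = 0.10,
) -> list[MSTTrace]:
    """Raw fluorescence time traces whose window-normalized ΔF_norm follows
    the titration isotherm (for exercising the trace-processing path)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations_uM, dtype=float)
    fb = mass_action_bound_fraction(conc, config.kd_uM, config.protein_conc_nM / 1000.0)
    time = np.arange(0.0, 45.0, 0.1)
    ir_on, ir_off = 5.0, 35.0
    traces = []
    for c, f in zip(conc, fb):
        eps = rng.normal(0.0, config.noise_frac) if config.noise_frac > 0 else 0.0
        f_norm = (1.0 - baseline_depletion) + config.amplitude * f * (1.0 + eps)
        hot_level = cold_level * f_norm
        fluor = np.full_like(time, cold_level)
        heating = (time >= ir_on) & (time < ir_on + 10.0)
        fluor[heating] = cold_level + (hot_level - cold_level) * (
            (time[heating] - ir_on) / 10.0
        )
        fluor[time >= ir_on + 10.0] = hot_level
        fluor[time >= ir_off] = cold_level  # back-diffusion after IR off (idealized)
        traces.append(
            MSTTrace(
                time_s=time.copy(),
                fluorescence=fluor,
                ir_on_s=ir_on,
                ir_off_s=ir_off,
                concentration_uM=float(c),
                replicate=0,
            )
        )
    return traces


def simulate_calcium_trace(config: AssaySimConfig) -> CalciumTrace:
    """Baseline-1 normalized fura-2 ratio with a triangular response pulse
    whose integral above baseline equals ``auc_target`` exactly when
    noiseless."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    time = np.arange(0.0, 120.0, 0.1)
    stim_on, peak_t, decay_end = 30.0, 40.0, 90.0
    # triangular pulse area = h * (rise + decay) / 2 = 30 h
    h = config.auc_target / 30.0
    ratio = np.ones_like(time)
    rise = (time >= stim_on) & (time <= peak_t)
    ratio[rise] += h * (time[rise] - stim_on) / (peak_t - stim_on)
    fall = (time > peak_t) & (time <= decay_end)
    ratio[fall] += h * (decay_end - time[fall]) / (decay_end - peak_t)
    if config.noise_frac > 0:
        ratio += rng.normal(0.0, config.noise_frac * max(h, 1e-12), size=time.size)
    return CalciumTrace(time_s=time, ratio=ratio, stimulus_window=(stim_on, decay_end))


def simulate_ramp_recording(config: AssaySimConfig) -> RampRecording:
    """Voltage-ramp (−100 → +100 mV over 400 ms) current with a mildly
    outwardly rectifying I–V whose density at +100 mV is the target."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    v = np.linspace(-100.0, 100.0, 401)
    i100 = config.current_density_target_pA_pF * config.capacitance_pF
    c3 = 0.3 * i100 / 100.0**3  # cubic rectification, 30% of the +100 mV current
    c1 = 0.7 * i100 / 100.0
    current = c1 * v + c3 * v**3
    if config.noise_frac > 0:
        current += rng.normal(0.0, config.noise_frac * abs(i100), size=v.size)
        current[-1] = i100  # endpoint anchored: density target is a ground truth
    return RampRecording(voltage_mV=v, current_pA=current, capacitance_pF=config.capacitance_pF)


def simulate_gapfree_recording(
    config: AssaySimConfig,
    duration_s: float = 15.0,
    sample_rate_hz: float = 5000.0,
    n_channels: int | None = None,
) -> GapFreeRecording:
    """Idealized multi-level single-channel record at +80 mV whose dwell
    fractions give exactly ``npo_target`` when noiseless.

    By default enough independent channels are superposed to keep the
    per-channel open probability at or below 0.5, so the all-closed level
    stays visible for baseline idealization.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_s * sample_rate_hz))
    if n_channels is None:
        n_channels = max(1, math.ceil(config.npo_target / 0.5))
    if n_channels < 1 or config.npo_target > n_channels:
        raise ConfigurationError("npo_target exceeds the channel count")
    po = config.npo_target / n_channels
    level = np.zeros(n, dtype=int)
    for _ in range(n_channels):
        open_samples = round(po * n)
        state = np.zeros(n, dtype=int)
        n_bursts = 40
        cuts = np.sort(rng.integers(0, open_samples + 1, size=n_bursts - 1))
        burst_sizes = np.diff(np.concatenate(([0], cuts, [open_samples])))
        block = n // n_bursts
        deficit = 0
        for b, size in enumerate(burst_sizes):
            size += deficit
            deficit = 0
            start_lo = b * block
            room = min(block, n - start_lo)
            if size > room:
                deficit = size - room
                size = room
            if size <= 0:
                continue
            off = int(rng.integers(0, room - size + 1))
            state[start_lo + off : start_lo + off + size] = 1
        # any residual deficit goes at the very end
        if deficit > 0:
            closed = np.flatnonzero(state == 0)
            state[closed[-deficit:]] = 1
        level += state
    current = level * config.single_channel_pA
    if config.noise_frac > 0:
        current = current + rng.normal(
            0.0, config.noise_frac * abs(config.single_channel_pA), size=n
        )
    return GapFreeRecording(
        time_s=np.arange(n) / sample_rate_hz,
        current_pA=np.asarray(current, dtype=float),
        single_channel_pA=config.single_channel_pA,
    )
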