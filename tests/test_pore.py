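import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trpgate.core import Role, select
from trpgate.errors import ConfigurationError, DegenerateGeometryError, SelectionError
from trpgate.pore import (
    ca_pair_distance_series,
    count_water_crossings,
    estimate_pore_axis,
    gate_area,
    gate_area_series,
    water_presence_series,
)
from trpgate.synthetic import (
    ChannelSimConfig,
    build_tetramer_topology,
    simulate_channel_trajectory,
)

from conftest import gate_water_coords, make_topology, make_trajectory


def square_corners(side, z=0.0):
    r = side / np.sqrt(2.0)
    a = np.radians([45, 135, 225, 315])
    return np.stack([r * np.cos(a), r * np.sin(a), np.full(4, z)], axis=1)


def frame_from(corners):
    top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABCD"])
    return make_trajectory(top, [corners])[0]


def random_rigid(rng):
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    return R, t


class TestPoreAxis:
    def test_planar_corners_give_z_axis(self):
        axis, center = estimate_pore_axis(frame_from(square_corners(7.0)), range(4))
        np.testing.assert_allclose(np.abs(axis), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(center, 0, atol=1e-12)

    def test_equivariance_under_rotation(self, rng):
        corners = square_corners(7.0)
        axis0, _ = estimate_pore_axis(frame_from(corners), range(4))
        for _ in range(5):
            R, t = random_rigid(rng)
            axis, _ = estimate_pore_axis(frame_from(corners @ R.T + t), range(4))
            dot = abs(np.dot(axis, R @ axis0))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_orientation_follows_reference(self):
        f = frame_from(square_corners(7.0))
        axis, _ = estimate_pore_axis(f, range(4), orient_toward=[0, 0, 50.0])
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)
        axis, _ = estimate_pore_axis(f, range(4), orient_toward=[0, 0, -50.0])
        np.testing.assert_allclose(axis, [0, 0, -1], atol=1e-12)

    def test_matches_svd_plane_normal_on_noisy_corners(self, rng):
        corners = square_corners(7.45) + rng.normal(0, 0.05, size=(4, 3))
        axis, _ = estimate_pore_axis(frame_from(corners), range(4))
        centered = corners - corners.mean(axis=0)
        normal = np.linalg.svd(centered)[2][2]  # total-least-squares oracle
        assert abs(abs(np.dot(axis, normal)) - 1.0) < 1e-9

    def test_collinear_corners_are_degenerate(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            estimate_pore_axis(frame_from(corners), range(4))


class TestGateArea:
    def test_square_side_squared(self):
        assert gate_area(frame_from(square_corners(7.45)), range(4)) == pytest.approx(
            7.45**2, abs=1e-9
        )

    def test_rectangle_under_rigid_transform(self, rng):
        corners = np.array(
            [[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]], dtype=float
        )
        for _ in range(10):
            R, t = random_rigid(rng)
            area = gate_area(frame_from(corners @ R.T + t), range(4))
            assert area == pytest.approx(2.0, abs=1e-9)

    def test_invariant_under_corner_permutation(self, rng):
        corners = square_corners(7.45) + rng.normal(0, 0.3, size=(4, 3))
        ref = gate_area(frame_from(corners), range(4))
        for perm in ([1, 0, 3, 2], [3, 2, 1, 0], [2, 0, 3, 1]):
            assert gate_area(frame_from(corners[perm]), range(4)) == pytest.approx(
                ref, abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_vector_area_oracle_for_planar_quads(self, seed):
        """Random planar convex quadrilaterals agree with the cross-product
        polygon-area oracle to 1e-9."""
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=4))
        radii = rng.uniform(2, 6, size=4)
        flat = np.stack(
            [radii * np.cos(angles), radii * np.sin(angles), np.zeros(4)], axis=1
        )
        # order by azimuth about the vertex centroid (the polygon definition)
        rel = flat - flat.mean(axis=0)
        flat = flat[np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))]
        R, t = random_rigid(rng)
        corners = flat @ R.T + t
        vec = np.zeros(3)
        c = corners.mean(axis=0)
        for i in range(4):
            vec += np.cross(corners[i] - c, corners[(i + 1) % 4] - c)
        oracle = 0.5 * np.linalg.norm(vec)
        assert gate_area(frame_from(corners), range(4)) == pytest.approx(oracle, abs=1e-9)

    def test_wrong_corner_count_rejected(self):
        top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABC"])
        f = make_trajectory(top, [np.zeros((3, 3))])[0]
        with pytest.raises(SelectionError):
            gate_area(f, range(3))


class TestGateAreaSeries:
    def test_constant_geometry_zero_sd(self):
        top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABCD"])
        traj = make_trajectory(top, [square_corners(7.45)] * 5)
        s = gate_area_series(traj, range(4))
        assert s.sd_A2 == 0.0
        assert s.mean_A2 == pytest.approx(7.45**2, abs=1e-9)

    def test_single_frame_sd_zero(self):
        top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABCD"])
        traj = make_trajectory(top, [square_corners(3.0)])
        s = gate_area_series(traj, range(4))
        assert s.sd_A2 == 0.0

    def test_segment_summaries(self):
        top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABCD"])
        frames = [square_corners(7.0)] * 4 + [square_corners(8.0)] * 4
        traj = make_trajectory(top, frames)
        s = gate_area_series(
            traj, range(4), segments={"closed": (0, 4), "open": (4, 8)}
        )
        seg = dict((lab, m) for lab, m, _ in s.segment_summaries)
        assert seg["closed"] == pytest.approx(49.0, abs=1e-9)
        assert seg["open"] == pytest.approx(64.0, abs=1e-9)

    def test_generator_round_trip_mean_within_2se(self):
        cfg = ChannelSimConfig(n_frames=400, n_waters=0, seed=9)
        top = build_tetramer_topology(cfg)
        traj = simulate_channel_trajectory(top, cfg)
        s = gate_area_series(traj, select(top, residue_number=715, atom_name="CA"))
        target = 7.45**2 + 0.19**2
        se = s.sd_A2 / np.sqrt(cfg.n_frames)
        assert abs(s.mean_A2 - target) < 2 * se + 0.15  # 0.15 Å² noise-inflation slack


class TestPairDistance:
    def test_fixed_separation(self):
        top = make_topology([("CA", "C", 733, "TRP", "A"), ("CA", "C", 594, "ARG", "A")])
        traj = make_trajectory(top, [[[0, 0, 0], [8, 0, 0]]] * 3)
        s = ca_pair_distance_series(traj, 0, 1, label="W733-R594")
        assert s.mean_A == pytest.approx(8.0)
        assert s.sd_A == 0.0

    def test_coincident_atoms(self):
        top = make_topology([("CA", "C", 733, "TRP", "A"), ("CA", "C", 594, "ARG", "A")])
        traj = make_trajectory(top, [[[1, 2, 3], [1, 2, 3]]])
        assert ca_pair_distance_series(traj, 0, 1).mean_A == 0.0

    def test_jittered_pair_mean_within_2se(self, rng):
        n = 2000
        base = np.array([[0, 0, 0], [8, 0, 0]], dtype=float)
        frames = base[None] + rng.normal(0, 0.2, size=(n, 2, 3))
        top = make_topology([("CA", "C", 733, "TRP", "A"), ("CA", "C", 594, "ARG", "A")])
        s = ca_pair_distance_series(make_trajectory(top, frames), 0, 1)
        se = s.sd_A / np.sqrt(n)
        # jitter adds a small positive bias O(sigma^2/d); allow it alongside 2 SE
        assert abs(s.mean_A - 8.0) < 2 * se + 2 * 0.2**2 / 8.0


def crossings_oracle(z, d):
    """Interval-scan oracle: compartment sequence of out-of-slab visits."""
    comp = [(-1 if v < -d else 1) for v in z if abs(v) > d]
    up = down = 0
    for a, b in zip(comp, comp[1:]):
        if a == -1 and b == 1:
            up += 1
        elif a == 1 and b == -1:
            down += 1
    return up, down


class TestWaterCrossings:
    def _run(self, z_paths, d=5.0):
        z = np.asarray(z_paths, dtype=float).T  # (frames, waters)
        top = make_topology(
            [("CA", "C", 715, "ILE", s) for s in "ABCD"]
            + [("CA", "C", 733, "TRP", s) for s in "ABCD"]
            + [("OW", "O", 9001 + i, "HOH", "W") for i in range(z.shape[1])]
        )
        coords = gate_water_coords(z.shape[0], 7.45, z)
        traj = make_trajectory(top, coords)
        waters = select(top, role=Role.WATER)
        gate = select(top, residue_number=715, atom_name="CA")
        return count_water_crossings(traj, waters, gate, plane_offset_A=d)

    @pytest.mark.parametrize(
        "path, up, down",
        [
            (np.linspace(-10, 10, 21), 1, 0),  # monotone ascent
            (list(np.linspace(-10, -1, 10)) * 2, 0, 0),  # never exits upward
            (list(np.linspace(-10, 10, 11)) + list(np.linspace(10, -10, 11)), 1, 1),
            ([-10, -4, 2, 4, -2, -6, -10], 0, 0),  # touch and retreat
            ([-10, 10], 1, 0),  # jump straight across the slab
            ([-10, -6, 4, -6, 4, 6, 10], 1, 0),  # hysteresis suppresses flicker
            ([8, 0, -8, 0, 8, 0, -8], 1, 2),  # starts above
        ],
    )
    def test_hand_enumerated_paths(self, path, up, down):
        log = self._run([path])
        assert (log.n_up, log.n_down) == (up, down)
        oracle = crossings_oracle(path, 5.0)
        assert (log.n_up, log.n_down) == oracle

    def test_event_frames_are_ordered(self):
        log = self._run([np.linspace(-10, 10, 21)])
        (event,) = log.events
        assert event.entry_frame <= event.exit_frame
        assert event.direction == "up"

    def test_invalid_offset_rejected(self):
        with pytest.raises(ConfigurationError):
            self._run([np.linspace(-10, 10, 5)], d=0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_walks_match_interval_scan_oracle(self, seed):
        """Counts on 20-water random-walk fixtures equal the oracle exactly,
        and up − down equals the net compartment change."""
        rng = np.random.default_rng(seed)
        n_frames, n_waters = 200, 20
        z = np.cumsum(rng.normal(0, 2.0, size=(n_waters, n_frames)), axis=1)
        z += rng.uniform(-8, 8, size=(n_waters, 1))
        log = self._run(z)
        ups = downs = net = 0
        for w in range(n_waters):
            u, d = crossings_oracle(z[w], 5.0)
            ups += u
            downs += d
            comp = [(-1 if v < -5 else 1) for v in z[w] if abs(v) > 5]
            if comp:
                net += (comp[-1] - comp[0]) // 2
        assert (log.n_up, log.n_down) == (ups, downs)
        # up − down equals the net first→last compartment change over waters
        assert log.n_up - log.n_down == net

    def test_generator_requested_crossings_recovered(self):
        cfg = ChannelSimConfig(
            n_frames=120, n_waters=10, crossings_up=4, crossings_down=2, seed=21
        )
        top = build_tetramer_topology(cfg)
        traj = simulate_channel_trajectory(top, cfg)
        log = count_water_crossings(
            traj,
            select(top, role=Role.WATER),
            select(top, residue_number=715, atom_name="CA"),
        )
        assert (log.n_up, log.n_down) == (4, 2)


class TestWaterPresence:
    def test_no_waters_all_zero(self):
        top = make_topology([("CA", "C", 715, "ILE", s) for s in "ABCD"])
        traj = make_trajectory(top, [square_corners(7.0)] * 3)
        s = water_presence_series(traj, [], range(4))
        assert np.all(s.counts == 0)

    def test_water_at_centroid_counts_one(self):
        z = np.zeros((4, 1))
        top = make_topology(
            [("CA", "C", 715, "ILE", s) for s in "ABCD"]
            + [("CA", "C", 733, "TRP", s) for s in "ABCD"]
            + [("OW", "O", 9001, "HOH", "W")]
        )
        traj = make_trajectory(top, gate_water_coords(4, 7.0, z))
        s = water_presence_series(traj, [8], range(4))
        assert np.all(s.counts == 1)

    def test_matches_brute_force_recount(self, rng):
        n_frames, n_waters = 30, 8
        z = rng.uniform(-12, 12, size=(n_frames, n_waters))
        top = make_topology(
            [("CA", "C", 715, "ILE", s) for s in "ABCD"]
            + [("CA", "C", 733, "TRP", s) for s in "ABCD"]
            + [("OW", "O", 9001 + i, "HOH", "W") for i in range(n_waters)]
        )
        coords = gate_water_coords(n_frames, 7.0, z)
        traj = make_trajectory(top, coords)
        widx = list(range(8, 8 + n_waters))
        s = water_presence_series(traj, widx, range(4), radius_A=6.0)
        for t in range(n_frames):
            centroid = coords[t, :4].mean(axis=0)
            count = sum(
                np.linalg.norm(coords[t, w] - centroid) <= 6.0 for w in widx
            )
            assert s.counts[t] == count
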