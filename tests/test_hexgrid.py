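"""Lattice geometry, obstacles, periphery and shortest-path queries."""

import collections

import numpy as np
import pytest

import hexcolony as hx
from hexcolony.hexgrid import AXIAL_DIRECTIONS, GeometryError

SQRT3 = np.sqrt(3.0)


def brute_force_axial_count(radius: float, side: float) -> int:
    """Independent loop-based enumeration of hex centres within the disc."""
    pitch = side * SQRT3
    count = 0
    r_max = int(np.ceil(radius / (1.5 * side))) + 2
    q_max = int(np.ceil(radius / pitch)) + r_max + 2
    for r in range(-r_max, r_max + 1):
        for q in range(-q_max, q_max + 1):
            x = pitch * (q + r / 2.0)
            y = 1.5 * side * r
            if x * x + y * y <= radius * radius:
                count += 1
    return count


def bfs_distances(lattice, occupancy, origin):
    """Reference BFS over occupied nodes (independent of the implementation)."""
    occ = occupancy >= 0
    dist = {origin: 0}
    queue = collections.deque([origin])
    while queue:
        u = queue.popleft()
        for v in lattice.neighbor_list(u):
            v = int(v)
            if occ[v] and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


class TestBuildCircularLattice:
    def test_minimal_disc_has_center_plus_ring(self, disc7):
        assert disc7.n_nodes == 7
        assert np.isclose(disc7.pitch, 20.0 * SQRT3)
        # one interior node with 6 neighbours, six rim nodes
        assert sorted(disc7.degree) == [3, 3, 3, 3, 3, 3, 6]
        assert disc7.is_boundary.sum() == 6

    def test_full_domain_count_matches_brute_force(self):
        lattice = hx.build_circular_lattice(5000.0, 20.0)
        assert lattice.n_nodes == brute_force_axial_count(5000.0, 20.0)
        assert lattice.n_nodes > 6e4  # order 7e4 nodes

    def test_invalid_geometry_raises(self):
        with pytest.raises(GeometryError):
            hx.build_circular_lattice(10.0, 20.0)

    def test_all_nodes_within_radius(self, disc3rings):
        assert np.all(disc3rings.radial_distance() <= disc3rings.radius + 1e-9)

    @pytest.mark.parametrize("radius", [34.7, 120.0, 300.0])
    def test_adjacency_symmetric_and_bounded(self, radius):
        lattice = hx.build_circular_lattice(radius, 20.0)
        nb = lattice.neighbors
        for i in range(lattice.n_nodes):
            for j in nb[i][nb[i] >= 0]:
                assert i in nb[j]
        assert nb.shape[1] == 6
        assert np.all(lattice.degree <= 6)
        assert np.all(lattice.is_boundary == (lattice.degree < 6))

    def test_neighbor_distance_is_pitch(self, disc3rings):
        for i in range(disc3rings.n_nodes):
            for j in disc3rings.neighbor_list(i):
                d = np.linalg.norm(disc3rings.positions[i] - disc3rings.positions[j])
                assert np.isclose(d, disc3rings.pitch)

    def test_construction_deterministic(self):
        a = hx.build_circular_lattice(200.0, 20.0)
        b = hx.build_circular_lattice(200.0, 20.0)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.neighbors, b.neighbors)


class TestObstacles:
    def test_mode_none_is_identity(self, disc3rings):
        spec = hx.ObstacleSpec(mode="none")
        assert hx.apply_obstacles(disc3rings, spec) is disc3rings

    def test_regular_layout_matches_direct_enumeration(self):
        lattice = hx.build_circular_lattice(5000.0, 20.0)
        spec = hx.ObstacleSpec(
            mode="regular", diameter_mean=100.0, spacing=500.0, keepout_radius=2000.0
        )
        structured = hx.apply_obstacles(lattice, spec)
        # oracle: enumerate grid centres in the annulus, then flag nodes by
        # direct distance computation
        centers = []
        k = int(np.floor(5000.0 / 500.0)) + 1
        for i in range(-k, k + 1):
            for j in range(-k, k + 1):
                cx, cy = i * 500.0, j * 500.0
                d = np.hypot(cx, cy)
                if 2000.0 + 50.0 <= d <= 5000.0 + 50.0:
                    centers.append((cx, cy))
        assert len(centers) > 0
        expected = np.zeros(lattice.n_nodes, dtype=bool)
        for cx, cy in centers:
            d2 = (lattice.positions[:, 0] - cx) ** 2 + (lattice.positions[:, 1] - cy) ** 2
            expected |= d2 <= 50.0**2
        assert np.array_equal(structured.is_obstacle, expected)

    def test_keepout_disc_remains_obstacle_free(self):
        lattice = hx.build_circular_lattice(1000.0, 20.0)
        spec = hx.ObstacleSpec(
            mode="regular", diameter_mean=100.0, spacing=300.0, keepout_radius=400.0
        )
        structured = hx.apply_obstacles(lattice, spec)
        r = structured.radial_distance()
        assert not np.any(structured.is_obstacle & (r <= 400.0))
        assert structured.is_obstacle.sum() > 0

    def test_obstacles_pruned_from_adjacency(self):
        lattice = hx.build_circular_lattice(1000.0, 20.0)
        spec = hx.ObstacleSpec(
            mode="regular", diameter_mean=100.0, spacing=400.0, keepout_radius=400.0
        )
        structured = hx.apply_obstacles(lattice, spec)
        obstacle_ids = set(np.flatnonzero(structured.is_obstacle))
        for i in range(structured.n_nodes):
            assert not obstacle_ids.intersection(structured.neighbor_list(i))
        assert np.all(structured.neighbors[structured.is_obstacle] == -1)

    def test_zero_variance_stochastic_equals_regular_any_seed(self):
        lattice = hx.build_circular_lattice(1000.0, 20.0)
        regular = hx.apply_obstacles(
            lattice,
            hx.ObstacleSpec(mode="regular", diameter_mean=100.0, spacing=400.0,
                            keepout_radius=400.0),
        )
        for seed in (0, 1, 99):
            stochastic = hx.apply_obstacles(
                lattice,
                hx.ObstacleSpec(mode="stochastic", diameter_mean=100.0,
                                diameter_variance=0.0, spacing=400.0,
                                keepout_radius=400.0, seed=seed),
            )
            assert np.array_equal(stochastic.is_obstacle, regular.is_obstacle)

    def test_stochastic_reproducible_given_seed(self):
        lattice = hx.build_circular_lattice(1000.0, 20.0)
        spec = hx.ObstacleSpec(mode="stochastic", diameter_mean=100.0,
                               diameter_variance=20.0, spacing=400.0,
                               keepout_radius=400.0, seed=7)
        a = hx.apply_obstacles(lattice, spec)
        b = hx.apply_obstacles(lattice, spec)
        assert np.array_equal(a.is_obstacle, b.is_obstacle)

    def test_invalid_spec_rejected(self):
        with pytest.raises(GeometryError):
            hx.ObstacleSpec(mode="regular", diameter_mean=500.0, spacing=400.0).validate()


class TestPeriphery:
    def test_single_occupied_node(self, disc3rings):
        occupancy = np.full(disc3rings.n_nodes, -1)
        occupancy[0] = 0
        assert list(hx.periphery(disc3rings, occupancy)) == [0]

    def test_filled_disc7_excludes_center(self, disc7, disc3rings):
        # the whole lattice occupied: no vacancies anywhere, empty periphery
        occupancy = np.zeros(disc7.n_nodes, dtype=int)
        assert set(hx.periphery(disc7, occupancy)) == set()
        # a 7-node disc inside a larger lattice: the six ring nodes touch
        # vacancies, the centre does not
        r = disc3rings.radial_distance()
        occupancy = np.where(r <= 1.05 * disc3rings.pitch, 0, -1)
        per = set(hx.periphery(disc3rings, occupancy))
        center = int(np.argmin(r))
        assert center not in per
        assert per == set(np.flatnonzero(occupancy >= 0)) - {center}
        assert len(per) == 6

    def test_filled_three_rings_matches_neighbor_scan(self, disc3rings):
        lattice = hx.build_circular_lattice(160.0, 20.0)  # 4 rings
        r = lattice.radial_distance()
        occupancy = np.where(r <= 3.05 * lattice.pitch, 0, -1)
        per = set(hx.periphery(lattice, occupancy))
        # oracle: exhaustive scan
        expected = set()
        occ = occupancy >= 0
        for i in np.flatnonzero(occ):
            if any(not occ[j] for j in lattice.neighbor_list(i)):
                expected.add(int(i))
        assert per == expected
        assert len(per) > 0

    def test_empty_occupancy_gives_empty_set(self, disc3rings):
        occupancy = np.full(disc3rings.n_nodes, -1)
        assert hx.periphery(disc3rings, occupancy).size == 0

    def test_obstacle_nodes_never_peripheral(self):
        lattice = hx.build_circular_lattice(1000.0, 20.0)
        spec = hx.ObstacleSpec(mode="regular", diameter_mean=100.0, spacing=400.0,
                               keepout_radius=400.0)
        structured = hx.apply_obstacles(lattice, spec)
        occupancy = np.where(structured.is_obstacle, -1, 0)
        per = hx.periphery(structured, occupancy)
        assert not np.any(structured.is_obstacle[per])


class TestShortestPathToPeriphery:
    def test_origin_on_periphery_returns_itself(self, disc7):
        occupancy = np.full(disc7.n_nodes, -1)
        occupancy[0] = 0
        assert hx.shortest_path_to_periphery(disc7, occupancy, 0) == [0]

    def test_center_of_filled_disc(self):
        # a 3-ring colony inside a larger domain: the disc rim is the
        # colony periphery (it borders vacancies)
        lattice = hx.build_circular_lattice(190.0, 20.0)
        r = lattice.radial_distance()
        occupancy = np.where(r <= 3.05 * lattice.pitch, 0, -1)
        center = int(np.argmin(r))
        rng = np.random.default_rng(0)
        path = hx.shortest_path_to_periphery(lattice, occupancy, center, rng)
        assert path is not None
        assert path[0] == center
        # centre of a 3-ring disc: graph distance 3 to the rim, 4 nodes
        assert len(path) == 4
        # consecutive nodes adjacent and all occupied
        for a, b in zip(path, path[1:]):
            assert b in lattice.neighbor_list(a)
        assert all(occupancy[n] >= 0 for n in path)

    def test_path_length_matches_bfs_oracle_everywhere(self):
        lattice = hx.build_circular_lattice(190.0, 20.0)  # ~5 rings
        r = lattice.radial_distance()
        occupancy = np.where(r <= 4.05 * lattice.pitch, 0, -1)
        per = set(hx.periphery(lattice, occupancy))
        assert per
        rng = np.random.default_rng(1)
        for origin in np.flatnonzero(occupancy >= 0):
            origin = int(origin)
            dist = bfs_distances(lattice, occupancy, origin)
            expected = min(dist[p] for p in per if p in dist)
            path = hx.shortest_path_to_periphery(lattice, occupancy, origin, rng)
            assert path is not None
            assert len(path) - 1 == expected

    def test_unoccupied_origin_rejected(self, disc7):
        occupancy = np.full(disc7.n_nodes, -1)
        occupancy[1] = 0
        with pytest.raises(ValueError):
            hx.shortest_path_to_periphery(disc7, occupancy, 0)

    def test_enclosed_origin_returns_none(self):
        # centre node walled in by obstacles: no reachable periphery
        coords = [(0, 0)] + list(AXIAL_DIRECTIONS)
        lattice = hx.lattice_from_axial(coords, side=20.0)
        lattice.is_obstacle[1:] = True
        lattice.neighbors[lattice.is_obstacle] = -1
        lattice.neighbors[0] = -1
        occupancy = np.full(lattice.n_nodes, -1)
        occupancy[0] = 0
        assert hx.shortest_path_to_periphery(lattice, occupancy, 0) is None

    def test_max_depth_cutoff(self):
        lattice = hx.build_circular_lattice(190.0, 20.0)
        r = lattice.radial_distance()
        occupancy = np.where(r <= 3.05 * lattice.pitch, 0, -1)
        center = int(np.argmin(r))
        assert (
            hx.shortest_path_to_periphery(lattice, occupancy, center, max_depth=2)
            is None
        )

    def test_tie_break_uses_rng_and_covers_targets(self, disc3rings):
        r = disc3rings.radial_distance()
        occupancy = np.where(r <= 2.05 * disc3rings.pitch, 0, -1)
        center = int(np.argmin(r))
        rng = np.random.default_rng(42)
        ends = {
            hx.shortest_path_to_periphery(disc3rings, occupancy, center, rng)[-1]
            for _ in range(200)
        }
        assert len(ends) > 1  # multiple shortest paths get sampled
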