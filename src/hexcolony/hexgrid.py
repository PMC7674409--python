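"""Hexagonal-lattice domain geometry.

The simulation domain is a disc tiled by regular, pointy-top hexagons.
Each lattice node is the centre of one hexagon and carries up to six
neighbours; nodes on the outer rim (incomplete neighbour rings) are the
nutrient-source boundary.  Solid obstacles are modelled by flagging nodes
and removing them from all adjacency traversals, so neither diffusion nor
cells can cross them.

Coordinate convention
---------------------
Axial coordinates ``(q, r)`` with pointy-top orientation:

    x = pitch * (q + r / 2),   y = 1.5 * side * r

where ``pitch = side * sqrt(3)`` is the centre-to-centre distance between
adjacent hexagons.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HexLattice",
    "ObstacleSpec",
    "build_circular_lattice",
    "lattice_from_axial",
    "apply_obstacles",
    "periphery",
    "shortest_path_to_periphery",
]

SQRT3 = np.sqrt(3.0)

#: axial offsets of the six neighbours of a pointy-top hexagon
AXIAL_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1),
)


class GeometryError(ValueError):
    """Invalid domain geometry or obstacle layout."""


@dataclass(eq=False)
class HexLattice:
    """Immutable circular hexagonal-lattice domain.

    Attributes
    ----------
    positions:
        ``(n, 2)`` node centre coordinates in µm.
    axial:
        ``(n, 2)`` integer axial coordinates ``(q, r)``.
    neighbors:
        ``(n, 6)`` neighbour ids padded with ``-1``.  Obstacle nodes are
        removed from every neighbour list, so traversals never cross them.
    is_boundary:
        Nodes on the outer rim of the disc (incomplete neighbour ring at
        construction time).  These act as the nitrate source.
    is_obstacle:
        Solid, impenetrable nodes.
    side:
        Hexagon side length in µm.
    radius:
        Radius of the circular domain in µm.
    """

    positions: np.ndarray
    axial: np.ndarray
    neighbors: np.ndarray
    is_boundary: np.ndarray
    is_obstacle: np.ndarray
    side: float
    radius: float

    @property
    def pitch(self) -> float:
        """Centre-to-centre distance of adjacent nodes, ``side * sqrt(3)`` µm."""
        return self.side * SQRT3

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    @property
    def degree(self) -> np.ndarray:
        """Number of traversable neighbours per node."""
        return (self.neighbors >= 0).sum(axis=1)

    def hex_area_m2(self) -> float:
        """Area of one hexagon in m² (side is stored in µm)."""
        return 1.5 * SQRT3 * (self.side * 1e-6) ** 2

    def radial_distance(self) -> np.ndarray:
        """Distance of every node centre from the domain origin, µm."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    def neighbor_list(self, node: int) -> np.ndarray:
        row = self.neighbors[node]
        return row[row >= 0]

    def to_table(self) -> pd.DataFrame:
        """Tabular node export: id, x, y, boundary and obstacle flags."""
        return pd.DataFrame(
            {
                "node": self.node_ids,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "is_boundary": self.is_boundary.astype(int),
                "is_obstacle": self.is_obstacle.astype(int),
            }
        )

    def write_node_table(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ObstacleSpec:
    """Layout of solid obstacles inside the domain.

    ``regular`` mode lays obstacle discs of fixed diameter on a square grid
    of the given spacing.  ``stochastic`` mode keeps the regular grid of
    centres but draws each diameter from a normal distribution with mean
    ``diameter_mean``.  The printed spread of that distribution is
    ambiguous between a standard deviation and a variance; by default it
    is interpreted as a standard deviation in µm
    (``variance_is_sigma=True``), with the literal reading
    ``sigma = sqrt(diameter_variance)`` available behind the switch.

    Obstacles whose disc would intrude into the central inoculation region
    (``keepout_radius``) are dropped so the inoculum is always placeable;
    discs may overlap the domain rim and are clipped to it.
    """

    mode: Literal["none", "regular", "stochastic"] = "none"
    diameter_mean: float = 100.0
    diameter_variance: float = 20.0
    spacing: float = 500.0
    seed: int = 0
    keepout_radius: float = 2000.0
    variance_is_sigma: bool = True

    def validate(self) -> None:
        if self.mode == "none":
            return
        if self.mode not in ("regular", "stochastic"):
            raise GeometryError(f"unknown obstacle mode {self.mode!r}")
        if not (self.spacing > self.diameter_mean > 0):
            raise GeometryError(
                "obstacle layout requires spacing > diameter_mean > 0, got "
                f"spacing={self.spacing}, diameter_mean={self.diameter_mean}"
            )
        if self.diameter_variance < 0:
            raise GeometryError("diameter_variance must be >= 0")

    @property
    def sigma(self) -> float:
        if self.variance_is_sigma:
            return float(self.diameter_variance)
        return float(np.sqrt(self.diameter_variance))


def build_circular_lattice(radius: float, side: float) -> HexLattice:
    """Build the circular hexagonal-lattice domain.

    Parameters
    ----------
    radius:
        Radius of the circular domain in µm.  Every node whose centre lies
        within this radius belongs to the domain.
    side:
        Hexagon side length in µm.

    Returns
    -------
    HexLattice
        Lattice with symmetric adjacency; nodes with fewer than six
        neighbours are flagged as the domain boundary (rim).
    """
    if not radius > side > 0:
        raise GeometryError(
            f"invalid geometry: require radius > side > 0, got radius={radius}, side={side}"
        )
    pitch = side * SQRT3
    # enumerate axial coordinates in a bounding window of the disc
    q_max = int(np.ceil(radius / pitch)) + 2
    r_max = int(np.ceil(radius / (1.5 * side))) + 2
    r_vals = np.arange(-r_max, r_max + 1)
    q_vals = np.arange(-2 * q_max, 2 * q_max + 1)
    qq, rr = np.meshgrid(q_vals, r_vals, indexing="ij")
    x = pitch * (qq + rr / 2.0)
    y = 1.5 * side * rr
    inside = x * x + y * y <= radius * radius
    q_in = qq[inside]
    r_in = rr[inside]
    axial = np.stack([q_in, r_in], axis=1).astype(np.int32)
    positions = np.stack([x[inside], y[inside]], axis=1).astype(np.float64)
    return _assemble(axial, positions, side, radius)


def lattice_from_axial(
    coords: Sequence[tuple[int, int]], side: float, radius: float | None = None
) -> HexLattice:
    """Build a lattice from an explicit list of axial coordinates.

    Intended for small hand-built fixtures (lines, pairs, custom shapes)
    where the circular construction is inconvenient.  Boundary flags are
    set on nodes with fewer than six neighbours.
    """
    axial = np.asarray(list(coords), dtype=np.int32).reshape(-1, 2)
    if len(np.unique(axial, axis=0)) != len(axial):
        raise GeometryError("duplicate axial coordinates in fixture")
    pitch = side * SQRT3
    positions = np.stack(
        [pitch * (axial[:, 0] + axial[:, 1] / 2.0), 1.5 * side * axial[:, 1]], axis=1
    ).astype(np.float64)
    if radius is None:
        radius = float(np.hypot(positions[:, 0], positions[:, 1]).max() + side)
    return _assemble(axial, positions, side, float(radius))


def _assemble(axial: np.ndarray, positions: np.ndarray, side: float, radius: float) -> HexLattice:
    n = axial.shape[0]
    index = {(int(q), int(r)): i for i, (q, r) in enumerate(axial)}
    neighbors = np.full((n, 6), -1, dtype=np.int32)
    for i, (q, r) in enumerate(axial):
        for k, (dq, dr) in enumerate(AXIAL_DIRECTIONS):
            j = index.get((int(q) + dq, int(r) + dr))
            if j is not None:
                neighbors[i, k] = j
    degree = (neighbors >= 0).sum(axis=1)
    is_boundary = degree < 6
    return HexLattice(
        positions=positions,
        axial=axial,
        neighbors=neighbors,
        is_boundary=is_boundary,
        is_obstacle=np.zeros(n, dtype=bool),
        side=float(side),
        radius=float(radius),
    )


def _regular_centers(radius: float, spacing: float) -> np.ndarray:
    k = int(np.floor(radius / spacing)) + 1
    vals = np.arange(-k, k + 1) * spacing
    cx, cy = np.meshgrid(vals, vals, indexing="ij")
    return np.stack([cx.ravel(), cy.ravel()], axis=1)


def apply_obstacles(lattice: HexLattice, spec: ObstacleSpec) -> HexLattice:
    """Return a copy of the lattice with obstacle nodes flagged and pruned.

    Obstacle centres sit on a square grid of the configured spacing.  Any
    node whose centre falls inside an obstacle disc is flagged and removed
    from all neighbour lists.  Centres whose disc would overlap the
    central keep-out disc (inoculation region) are skipped; discs
    overlapping the domain rim are clipped to the domain.
    """
    spec.validate()
    if spec.mode == "none":
        return lattice

    centers = _regular_centers(lattice.radius, spec.spacing)
    dist_origin = np.hypot(centers[:, 0], centers[:, 1])
    if spec.mode == "stochastic":
        rng = np.random.default_rng(spec.seed)
        diameters = rng.normal(spec.diameter_mean, spec.sigma, size=len(centers))
        diameters = np.clip(diameters, 0.0, None)
    else:
        diameters = np.full(len(centers), float(spec.diameter_mean))
    keep = (dist_origin - diameters / 2.0 >= spec.keepout_radius) & (
        dist_origin - diameters / 2.0 <= lattice.radius
    )
    centers, diameters = centers[keep], diameters[keep]

    is_obstacle = lattice.is_obstacle.copy()
    if len(centers):
        d2 = (
            (lattice.positions[:, None, 0] - centers[None, :, 0]) ** 2
            + (lattice.positions[:, None, 1] - centers[None, :, 1]) ** 2
        )
        is_obstacle |= (d2 <= (diameters[None, :] / 2.0) ** 2).any(axis=1)

    if np.all(is_obstacle[lattice.is_boundary]):
        raise GeometryError(
            "obstacle layout covers the entire boundary rim; the colony "
            "periphery could never be scored"
        )

    neighbors = lattice.neighbors.copy()
    # drop obstacle nodes from every adjacency list and clear their own rows
    obstructed = np.zeros(lattice.n_nodes + 1, dtype=bool)
    obstructed[:-1] = is_obstacle
    neighbors[obstructed[neighbors]] = -1
    neighbors[is_obstacle] = -1
    return replace(
        lattice,
        neighbors=neighbors,
        is_obstacle=is_obstacle,
        positions=lattice.positions,
        axial=lattice.axial,
        is_boundary=lattice.is_boundary,
    )


def _occupied_mask(lattice: HexLattice, occupancy: np.ndarray) -> np.ndarray:
    occupancy = np.asarray(occupancy)
    if occupancy.shape != (lattice.n_nodes,):
        raise ValueError("occupancy must have one entry per lattice node")
    return occupancy >= 0


def periphery(lattice: HexLattice, occupancy: np.ndarray) -> np.ndarray:
    """Ids of occupied nodes with at least one empty, non-obstacle neighbour.

    ``occupancy`` is an integer array with ``-1`` marking empty nodes and
    any value ``>= 0`` marking an occupant (strain index).
    """
    occ = _occupied_mask(lattice, occupancy)
    nb = lattice.neighbors
    valid = nb >= 0
    occ_padded = np.concatenate([occ, [True]])  # padded slot reads as occupied
    has_empty = (valid & ~occ_padded[np.where(valid, nb, -1)]).any(axis=1)
    return np.flatnonzero(occ & has_empty)


def _has_empty_neighbor(lattice: HexLattice, occ: np.ndarray, node: int) -> bool:
    for j in lattice.neighbor_list(node):
        if not occ[j]:
            return True
    return False


def shortest_path_to_periphery(
    lattice: HexLattice,
    occupancy: np.ndarray,
    origin: int,
    rng: np.random.Generator | None = None,
    max_depth: int | None = None,
) -> list[int] | None:
    """Shortest path through occupied nodes from ``origin`` to the periphery.

    Runs a breadth-first search restricted to occupied, non-obstacle nodes
    and stops at the first depth containing a periphery node (an occupied
    node with an empty traversable neighbour).  Among all shortest paths to
    all nearest periphery nodes one is drawn uniformly at random: the BFS
    counts the number of distinct shortest paths to every node, the target
    is chosen with probability proportional to its path count, and the
    path is reconstructed backwards sampling predecessors with the same
    weights.

    Returns the node list from origin to periphery inclusive, or ``None``
    if no periphery is reachable (optionally within ``max_depth`` edges).
    """
    occ = _occupied_mask(lattice, occupancy)
    if not occ[origin]:
        raise ValueError(f"origin node {origin} is unoccupied")
    if rng is None:
        rng = np.random.default_rng()

    if _has_empty_neighbor(lattice, occ, origin):
        return [origin]

    n = lattice.n_nodes
    dist = np.full(n, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.float64)  # float: counts can grow combinatorially
    dist[origin] = 0
    counts[origin] = 1.0
    frontier = [origin]
    depth = 0
    while frontier:
        if max_depth is not None and depth >= max_depth:
            return None
        depth += 1
        nxt: list[int] = []
        for u in frontier:
            for v in lattice.neighbor_list(u):
                if not occ[v]:
                    continue
                if dist[v] == -1:
                    dist[v] = depth
                    counts[v] = counts[u]
                    nxt.append(int(v))
                elif dist[v] == depth:
                    counts[v] += counts[u]
        targets = [v for v in nxt if _has_empty_neighbor(lattice, occ, v)]
        if targets:
            weights = counts[targets]
            t = int(rng.choice(targets, p=weights / weights.sum()))
            path = [t]
            node = t
            for d in range(depth - 1, -1, -1):
                preds = [
                    int(u)
                    for u in lattice.neighbor_list(node)
                    if occ[u] and dist[u] == d
                ]
                w = counts[preds]
                node = int(rng.choice(preds, p=w / w.sum()))
                path.append(node)
            path.reverse()
            return path
        frontier = nxt
    return None
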