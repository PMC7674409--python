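"""Colony state and expansion mechanics: inoculation, division, shoving.

Each lattice node holds at most one *super-agent* — the biomass of many
real cells of a single strain and ancestral lineage.  On reaching the
critical division mass an agent splits in two; the daughter is placed, in
priority order, on a random empty neighbour node, by shoving a chain of
cells towards the nearby colony periphery, or — when the periphery is out
of shoving range — stacked in a layer above the node (pseudo-3D growth).
Shoved agents carry their strain, lineage and stacked biomass with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from . import hexgrid
from .hexgrid import HexLattice
from .kinetics import Strain, StrainRole

__all__ = [
    "ExpansionParams",
    "SuperAgent",
    "Colony",
    "inoculate",
    "divide",
    "shove",
    "division_sweep",
]


@dataclass(frozen=True)
class ExpansionParams:
    """Division and placement parameters.

    ``division_mass`` is the critical mass (kg dry weight) at which a
    super-agent divides.  The default, 1.5e-10 kg, is 10³ cells of
    1.5e-13 kg at division — a 20 µm hexagon holds on the order of a
    thousand tightly packed cells in a monolayer.  Together with the
    diffusion-layer depth this constant sets the biomass–nutrient
    coupling and hence the depth of the actively growing layer, so it is
    a deliberate configuration knob.

    ``shove_radius_cells`` is the maximum graph distance (edges) to the
    periphery within which a blocked divider shoves; beyond it the
    daughter stacks.  ``inoculum_mass_range`` is the uniform range of
    initial masses as fractions of the division mass.  ``encasement``
    overwrites the outermost inoculated ring with one strain (used to
    probe super-sector nucleation).  ``stacked_grows`` lets the stacked
    layer keep growing and consuming (it never divides laterally).
    """

    division_mass: float = 1.5e-10
    shove_radius_cells: int = 5
    shoving_enabled: bool = True
    inoculation_radius: float = 2000.0
    inoculum_mass_range: tuple[float, float] = (0.1, 1.0)
    encasement: Literal["none", "consumer_ring", "producer_ring"] = "none"
    stacked_grows: bool = True

    def validate(self) -> None:
        if self.division_mass <= 0:
            raise ValueError("division_mass must be positive")
        if self.shove_radius_cells < 0:
            raise ValueError("shove_radius_cells must be >= 0")
        lo, hi = self.inoculum_mass_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("inoculum_mass_range fractions must lie in (0, 1]")
        if self.encasement not in ("none", "consumer_ring", "producer_ring"):
            raise ValueError(f"unknown encasement mode {self.encasement!r}")


@dataclass(frozen=True)
class SuperAgent:
    """Read-only view of one occupied node's biological state.

    ``mu`` is the growth rate evaluated at the most recent step (0 before
    the first step).
    """

    node: int
    strain: Strain
    mass: float
    lineage_id: int
    stacked_mass: float
    mu: float = 0.0


class Colony:
    """Array-backed occupancy of a lattice by super-agents.

    ``strain_idx`` is ``-1`` for empty nodes and otherwise indexes into
    ``strains``; ``lineage`` carries the immutable founder id; ``mass``
    and ``stacked`` are the lattice-layer and stacked-layer biomass (kg).
    """

    def __init__(self, lattice: HexLattice, strains: tuple[Strain, Strain]):
        n = lattice.n_nodes
        self.lattice = lattice
        self.strains = strains
        self.strain_idx = np.full(n, -1, dtype=np.int8)
        self.mass = np.zeros(n)
        self.stacked = np.zeros(n)
        self.lineage = np.full(n, -1, dtype=np.int64)
        self.last_mu = np.zeros(n)  # growth rate at the most recent step, s⁻¹
        self.next_lineage_id = 0

    # -- queries -----------------------------------------------------------

    def occupied(self) -> np.ndarray:
        return self.strain_idx >= 0

    def n_agents(self) -> int:
        return int(self.occupied().sum())

    def periphery(self) -> np.ndarray:
        return hexgrid.periphery(self.lattice, self.strain_idx)

    def agent(self, node: int) -> SuperAgent:
        if self.strain_idx[node] < 0:
            raise ValueError(f"node {node} is unoccupied")
        return SuperAgent(
            node=int(node),
            strain=self.strains[self.strain_idx[node]],
            mass=float(self.mass[node]),
            lineage_id=int(self.lineage[node]),
            stacked_mass=float(self.stacked[node]),
            mu=float(self.last_mu[node]),
        )

    def agents(self) -> Iterator[SuperAgent]:
        for node in np.flatnonzero(self.occupied()):
            yield self.agent(int(node))

    def total_biomass(self) -> float:
        occ = self.occupied()
        return float(self.mass[occ].sum() + self.stacked[occ].sum())

    def biomass_by_lineage(self, n_lineages: int | None = None) -> np.ndarray:
        """Final living biomass (lattice + stacked layers) per lineage id."""
        occ = self.occupied()
        n = self.next_lineage_id if n_lineages is None else n_lineages
        return np.bincount(
            self.lineage[occ],
            weights=self.mass[occ] + self.stacked[occ],
            minlength=n,
        )

    def role_mask(self, role: StrainRole) -> np.ndarray:
        mask = np.zeros(self.lattice.n_nodes, dtype=bool)
        for idx, strain in enumerate(self.strains):
            if strain.role is role:
                mask |= self.strain_idx == idx
        return mask

    def colony_radius(self) -> float:
        occ = self.occupied()
        if not occ.any():
            return 0.0
        return float(self.lattice.radial_distance()[occ].max())

    def to_table(self) -> pd.DataFrame:
        occ = np.flatnonzero(self.occupied())
        return pd.DataFrame(
            {
                "node": occ,
                "strain": [self.strains[i].label for i in self.strain_idx[occ]],
                "lineage_id": self.lineage[occ],
                "mass_kg": self.mass[occ],
                "stacked_mass_kg": self.stacked[occ],
                "mu_per_s": self.last_mu[occ],
            }
        )

    # -- mutation helpers --------------------------------------------------

    def place(self, node: int, strain_idx: int, mass: float, lineage_id: int) -> None:
        if self.strain_idx[node] >= 0:
            raise ValueError(f"node {node} already occupied")
        if self.lattice.is_obstacle[node]:
            raise ValueError(f"node {node} is an obstacle")
        self.strain_idx[node] = strain_idx
        self.mass[node] = mass
        self.stacked[node] = 0.0
        self.lineage[node] = lineage_id
        self.last_mu[node] = 0.0

    def move(self, src: int, dst: int) -> None:
        """Relocate an agent (with its stacked layer) to an empty node."""
        if self.strain_idx[dst] >= 0:
            raise ValueError(f"destination node {dst} occupied")
        self.strain_idx[dst] = self.strain_idx[src]
        self.mass[dst] = self.mass[src]
        self.stacked[dst] = self.stacked[src]
        self.lineage[dst] = self.lineage[src]
        self.last_mu[dst] = self.last_mu[src]
        self.strain_idx[src] = -1
        self.mass[src] = 0.0
        self.stacked[src] = 0.0
        self.lineage[src] = -1
        self.last_mu[src] = 0.0


def _empty_open_neighbors(colony: Colony, node: int) -> np.ndarray:
    nb = colony.lattice.neighbor_list(node)
    return nb[colony.strain_idx[nb] < 0]


def inoculate(
    lattice: HexLattice,
    params: ExpansionParams,
    strains: tuple[Strain, Strain],
    rng: np.random.Generator,
) -> Colony:
    """Seed the central inoculation disc with randomly assigned agents.

    Every non-obstacle node within the inoculation radius receives one
    agent with a uniformly random strain (1:1 mixing ratio), an initial
    mass drawn uniformly from the configured fraction range of the
    division mass, and a unique lineage id.  Encasement modes then
    overwrite the outermost occupied ring with the designated strain
    under fresh lineage ids.
    """
    params.validate()
    r = lattice.radial_distance()
    disc = r <= params.inoculation_radius
    if np.any(disc & lattice.is_obstacle):
        raise ValueError("obstacle nodes inside the inoculation disc")
    nodes = np.flatnonzero(disc)
    if nodes.size == 0:
        raise ValueError("inoculation radius contains no lattice nodes")

    colony = Colony(lattice, strains)
    lo, hi = params.inoculum_mass_range
    colony.strain_idx[nodes] = rng.integers(0, 2, size=nodes.size).astype(np.int8)
    colony.mass[nodes] = rng.uniform(lo, hi, size=nodes.size) * params.division_mass
    colony.lineage[nodes] = np.arange(nodes.size)
    colony.next_lineage_id = int(nodes.size)

    if params.encasement != "none":
        ring_role = (
            StrainRole.CONSUMER
            if params.encasement == "consumer_ring"
            else StrainRole.PRODUCER
        )
        ring_idx = next(
            i for i, s in enumerate(strains) if s.role is ring_role
        )
        ring_nodes = colony.periphery()
        colony.strain_idx[ring_nodes] = ring_idx
        fresh = np.arange(
            colony.next_lineage_id, colony.next_lineage_id + ring_nodes.size
        )
        colony.lineage[ring_nodes] = fresh
        colony.next_lineage_id += int(ring_nodes.size)
    return colony


def shove(
    colony: Colony, path: list[int], rng: np.random.Generator
) -> bool:
    """Shove the chain of agents along ``path`` one node towards the periphery.

    The periphery-end agent moves to a uniformly random empty,
    non-obstacle neighbour of its node; every other agent on the path
    advances one position; the origin node (``path[0]``) is left vacant
    for the daughter.  Returns ``False`` without touching the colony when
    the periphery-end agent has nowhere to go.
    """
    tail = path[-1]
    vacancies = _empty_open_neighbors(colony, tail)
    if vacancies.size == 0:
        return False
    dest = int(rng.choice(vacancies))
    colony.move(tail, dest)
    for i in range(len(path) - 2, -1, -1):
        colony.move(path[i], path[i + 1])
    return True


def divide(
    colony: Colony,
    node: int,
    params: ExpansionParams,
    rng: np.random.Generator,
) -> str:
    """Divide the agent at ``node`` (mass must have reached division mass).

    The parent's mass is halved between parent and daughter (exact
    biomass conservation).  Placement cascade: random empty neighbour →
    shove towards a periphery within ``shove_radius_cells`` edges →
    stack at the node.  Returns the branch taken
    (``"neighbor" | "shove" | "stack"``).
    """
    m = colony.mass[node]
    if m < params.division_mass:
        raise ValueError("agent has not reached the division mass")
    half = m / 2.0
    strain_idx = int(colony.strain_idx[node])
    lineage_id = int(colony.lineage[node])

    vacancies = _empty_open_neighbors(colony, node)
    if vacancies.size:
        dst = int(rng.choice(vacancies))
        colony.mass[node] = half
        colony.place(dst, strain_idx, half, lineage_id)
        return "neighbor"

    if params.shoving_enabled:
        path = hexgrid.shortest_path_to_periphery(
            colony.lattice,
            colony.strain_idx,
            node,
            rng=rng,
            max_depth=params.shove_radius_cells,
        )
        # a path of length 1 cannot occur here: it would mean the divider
        # itself borders a vacancy, which the neighbour branch already took
        if path is not None and len(path) > 1 and len(path) - 1 <= params.shove_radius_cells:
            if shove(colony, path, rng):
                # the parent advanced one node along the path; halve it and
                # put the daughter on the vacated origin node
                colony.mass[int(path[1])] = half
                colony.place(node, strain_idx, half, lineage_id)
                return "shove"

    colony.mass[node] = half
    colony.stacked[node] += half
    return "stack"


def division_sweep(
    colony: Colony, params: ExpansionParams, rng: np.random.Generator
) -> int:
    """Divide every ripe agent once, in uniformly shuffled node order.

    A single division per node per sweep; mass beyond one division is
    carried to the next macro step.  Returns the number of divisions.
    """
    ripe = np.flatnonzero(colony.occupied() & (colony.mass >= params.division_mass))
    if ripe.size == 0:
        return 0
    rng.shuffle(ripe)
    count = 0
    for node in ripe:
        # the occupant may have been shoved away by an earlier division
        if colony.strain_idx[node] >= 0 and colony.mass[node] >= params.division_mass:
            divide(colony, int(node), params, rng)
            count += 1
    return count
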