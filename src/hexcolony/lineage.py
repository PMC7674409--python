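"""Ancestral-lineage bookkeeping and spatial-genetics observables.

A *lineage* is one inoculated founder agent plus all of its progeny,
tracked by an immutable integer id.  During range expansion most
lineages are buried behind the advancing front; the observables here
quantify that genetic bottleneck: unique lineages on the periphery,
strain-sector boundaries along the front, connected consumer branches,
lineage-loss percentages and the "lucky fraction" of founders holding
most of the final biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy import stats

from .expansion import Colony
from .kinetics import StrainRole

__all__ = [
    "LineageLedger",
    "peripheral_lineages",
    "interspecies_boundaries",
    "consumer_branches",
    "lineage_loss",
    "lucky_fraction",
    "compare_runs",
]


@dataclass
class LineageLedger:
    """Founder roster fixed at inoculation.

    ``founder_strain`` / ``founder_node`` are indexed by lineage id
    (``-1`` strain marks ids that were retired at inoculation, e.g. by
    encasement overwrites).  ``in_growth_layer`` flags founders that
    started within ``growth_layer_depth`` µm of the inoculum edge — the
    band with nutrient access that actively contributes to expansion.
    """

    founder_strain: np.ndarray
    founder_node: np.ndarray
    in_growth_layer: np.ndarray
    growth_layer_depth: float

    @classmethod
    def from_colony(
        cls,
        colony: Colony,
        inoculation_radius: float,
        growth_layer_depth: float = 100.0,
    ) -> "LineageLedger":
        n = colony.next_lineage_id
        founder_strain = np.full(n, -1, dtype=np.int8)
        founder_node = np.full(n, -1, dtype=np.int64)
        in_layer = np.zeros(n, dtype=bool)
        occ = np.flatnonzero(colony.occupied())
        r = colony.lattice.radial_distance()
        ids = colony.lineage[occ]
        founder_strain[ids] = colony.strain_idx[occ]
        founder_node[ids] = occ
        in_layer[ids] = r[occ] >= inoculation_radius - growth_layer_depth
        return cls(founder_strain, founder_node, in_layer, growth_layer_depth)

    @property
    def valid(self) -> np.ndarray:
        return self.founder_strain >= 0

    @property
    def n_founders(self) -> int:
        return int(self.valid.sum())

    def to_table(self, colony: Colony) -> pd.DataFrame:
        """Final lineage export: founder info, final biomass, survival flag."""
        ids = np.flatnonzero(self.valid)
        biomass = colony.biomass_by_lineage(len(self.founder_strain))
        surviving = set()
        for strain_ids in peripheral_lineages(colony).values():
            surviving.update(strain_ids)
        return pd.DataFrame(
            {
                "lineage_id": ids,
                "strain": [colony.strains[s].label for s in self.founder_strain[ids]],
                "founder_node": self.founder_node[ids],
                "in_growth_layer": self.in_growth_layer[ids].astype(int),
                "final_biomass_kg": biomass[ids],
                "survived_to_periphery": [int(i in surviving) for i in ids],
            }
        )


def peripheral_lineages(colony: Colony) -> dict[str, set[int]]:
    """Unique lineage ids on the colony periphery, keyed by strain label."""
    per = colony.periphery()
    out: dict[str, set[int]] = {s.label: set() for s in colony.strains}
    for node in per:
        label = colony.strains[colony.strain_idx[node]].label
        out[label].add(int(colony.lineage[node]))
    return out


def interspecies_boundaries(colony: Colony) -> int:
    """Number of strain transitions along the periphery, walked by angle.

    Periphery agents are ordered by angular position around the centroid
    of the occupied region (ties broken by radius) and strain changes are
    counted along the cyclic sequence.  A monoclonal periphery gives 0;
    a two-strain periphery forming a single closed walk gives an even
    count.
    """
    per = colony.periphery()
    if per.size == 0:
        raise ValueError("empty periphery")
    pos = colony.lattice.positions[per]
    occ = colony.occupied()
    centroid = colony.lattice.positions[occ].mean(axis=0)
    rel = pos - centroid
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    radii = np.hypot(rel[:, 0], rel[:, 1])
    order = np.lexsort((radii, angles))
    strains = colony.strain_idx[per][order]
    return int((strains != np.roll(strains, 1)).sum())


def consumer_branches(
    colony: Colony, role: StrainRole = StrainRole.CONSUMER
) -> tuple[int, float | None]:
    """Connected components of consumer-occupied nodes reaching the periphery.

    A *branch* is a 6-neighbour connected component of nodes occupied by
    the given role that intersects the colony periphery — the lattice
    counterpart of a visible consumer sector penetrating the producer
    front.  Returns the branch count and the ratio of unique peripheral
    lineages of that role to branches (``None`` when there is no branch).
    """
    mask = colony.role_mask(role)
    nodes = np.flatnonzero(mask)
    per = colony.periphery()
    per_role = per[mask[per]]
    if nodes.size == 0 or per_role.size == 0:
        return 0, None

    index = np.full(colony.lattice.n_nodes, -1, dtype=np.int64)
    index[nodes] = np.arange(nodes.size)
    nb = colony.lattice.neighbors[nodes]
    valid = (nb >= 0) & mask[np.clip(nb, 0, None)]
    rows = np.repeat(np.arange(nodes.size), valid.sum(axis=1))
    cols = index[nb[valid]]
    graph = sp.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(nodes.size, nodes.size)
    )
    _, labels = csgraph.connected_components(graph, directed=False)
    branch_labels = np.unique(labels[index[per_role]])
    n_branches = int(branch_labels.size)

    label = next(s.label for s in colony.strains if s.role is role)
    n_lineages = len(peripheral_lineages(colony)[label])
    return n_branches, n_lineages / n_branches


def lineage_loss(ledger: LineageLedger, colony: Colony) -> tuple[float, float]:
    """Percentages of founder lineages absent from the final periphery.

    Returns ``(loss among growth-layer founders, loss among all
    founders)``, both in percent.  A founder is *lost* when none of its
    descendants sits on the colony periphery at the end of the run.
    """
    surviving: set[int] = set()
    for ids in peripheral_lineages(colony).values():
        surviving.update(ids)
    valid_ids = np.flatnonzero(ledger.valid)
    alive = np.array([i in surviving for i in valid_ids])
    in_layer = ledger.in_growth_layer[valid_ids]

    def pct_lost(mask: np.ndarray) -> float:
        total = int(mask.sum())
        if total == 0:
            return 0.0
        return 100.0 * float((mask & ~alive).sum()) / total

    return pct_lost(in_layer), pct_lost(np.ones_like(alive, dtype=bool))


def lucky_fraction(biomass_by_lineage: np.ndarray) -> float:
    """Smallest percentage of founders holding more than half the biomass.

    Lineages are ranked by final biomass; the head count whose cumulative
    biomass first exceeds 50% of the total is expressed as a percentage
    of all founders.  Result lies in ``(0, 100]``.
    """
    b = np.asarray(biomass_by_lineage, dtype=float)
    if b.size == 0 or b.sum() <= 0:
        raise ValueError("need at least one lineage with positive biomass")
    ordered = np.sort(b)[::-1]
    cum = np.cumsum(ordered)
    k = int(np.searchsorted(cum, 0.5 * cum[-1], side="right")) + 1
    return 100.0 * k / b.size


def compare_runs(
    samples_a: np.ndarray, samples_b: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test on replicate-level metric values."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
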