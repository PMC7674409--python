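"""Raster rendering of colony and field snapshots.

Produces simple scatter rasters of the hexagonal lattice: strain maps
(two-colour, experiment-style), lineage pseudo-colour maps (each founder
id hashed to a colour) and nutrient heatmaps.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chemistry import ChemicalField
from .expansion import Colony
from .hexgrid import HexLattice

__all__ = ["render_colony", "render_field"]

_STRAIN_COLORS = ("#2c7fb8", "#31a354")  # cyan-ish / green-ish fluorescence


def _marker_size(lattice: HexLattice, ax) -> float:
    # scale the marker to roughly one lattice pitch
    span = 2 * lattice.radius
    fig_px = ax.get_figure().get_size_inches()[0] * ax.get_figure().dpi
    return max((lattice.pitch / span * fig_px) ** 2, 1.0)


def render_colony(
    colony: Colony,
    path: str | Path,
    color_by: str = "strain",
    dpi: int = 150,
) -> None:
    """Write a PNG of the occupied lattice, coloured by strain or lineage."""
    lattice = colony.lattice
    occ = np.flatnonzero(colony.occupied())
    fig, ax = plt.subplots(figsize=(6, 6), dpi=dpi)
    ax.set_aspect("equal")
    ax.set_xlim(-lattice.radius, lattice.radius)
    ax.set_ylim(-lattice.radius, lattice.radius)
    size = _marker_size(lattice, ax)
    obstacles = np.flatnonzero(lattice.is_obstacle)
    if obstacles.size:
        ax.scatter(
            lattice.positions[obstacles, 0],
            lattice.positions[obstacles, 1],
            s=size, c="0.3", marker="h", linewidths=0,
        )
    if color_by == "strain":
        for idx, strain in enumerate(colony.strains):
            nodes = occ[colony.strain_idx[occ] == idx]
            ax.scatter(
                lattice.positions[nodes, 0],
                lattice.positions[nodes, 1],
                s=size, c=_STRAIN_COLORS[idx], marker="h", linewidths=0,
                label=strain.label,
            )
        ax.legend(loc="upper right", fontsize=8)
    elif color_by == "lineage":
        # hash lineage ids into a qualitative colour wheel
        ids = colony.lineage[occ]
        hues = (ids * 0.6180339887498949) % 1.0
        colors = plt.get_cmap("hsv")(hues)
        ax.scatter(
            lattice.positions[occ, 0], lattice.positions[occ, 1],
            s=size, c=colors, marker="h", linewidths=0,
        )
    else:
        raise ValueError("color_by must be 'strain' or 'lineage'")
    ax.set_xlabel("x [µm]")
    ax.set_ylabel("y [µm]")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render_field(
    field: ChemicalField,
    lattice: HexLattice,
    path: str | Path,
    species: str = "no3",
    dpi: int = 150,
) -> None:
    """Write a PNG heatmap of one solute concentration."""
    conc = field.c_no3 if species == "no3" else field.c_no2
    fig, ax = plt.subplots(figsize=(6, 6), dpi=dpi)
    ax.set_aspect("equal")
    ax.set_xlim(-lattice.radius, lattice.radius)
    ax.set_ylim(-lattice.radius, lattice.radius)
    keep = ~lattice.is_obstacle
    sc = ax.scatter(
        lattice.positions[keep, 0],
        lattice.positions[keep, 1],
        s=_marker_size(lattice, ax), c=conc[keep], marker="h",
        cmap="viridis", linewidths=0,
    )
    fig.colorbar(sc, ax=ax, label=f"C_{species.upper()} [mM]")
    ax.set_xlabel("x [µm]")
    ax.set_ylabel("y [µm]")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
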