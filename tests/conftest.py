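"""Shared fixtures: tiny hand-built lattices and reduced-scale run batteries.

The expensive session fixtures (replicate batteries on the 1 mm desk
domain) are built lazily so unit-test-only runs never pay for them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import hexcolony as hx
from hexcolony import simulator


@pytest.fixture(scope="session")
def disc7():
    """Minimal hex disc: one centre node plus its 6-neighbour ring."""
    return hx.build_circular_lattice(34.7, 20.0)


@pytest.fixture(scope="session")
def disc3rings():
    """Disc containing the centre and three full neighbour rings."""
    return hx.build_circular_lattice(120.0, 20.0)


@pytest.fixture(scope="session")
def two_node_lattice():
    """Closed two-compartment fixture for the analytic diffusion oracle."""
    return hx.lattice_from_axial([(0, 0), (1, 0)], side=20.0)


@pytest.fixture(scope="session")
def line4_lattice():
    """Four collinear nodes used to hand-trace the shoving chain."""
    return hx.lattice_from_axial([(0, 0), (1, 0), (2, 0), (3, 0)], side=20.0)


def tiny_config(scenario="competition", seed=0, hours=6.0, radius=300.0, inoc=150.0,
                **expansion_kw):
    """A very small but complete configuration for fast property runs."""
    exp = replace(
        hx.ExpansionParams(inoculation_radius=inoc),
        **expansion_kw,
    )
    return simulator.ScenarioConfig(
        scenario=scenario,
        geometry=simulator.GeometryParams(radius=radius, side=20.0, inoculation_radius=inoc),
        kinetics=hx.KineticParams(toxicity_on=(scenario == "strong_mutualism")),
        expansion=exp,
        total_time=hours * 3600.0,
        macro_dt=60.0,
        seed=seed,
        output=simulator.OutputParams(metrics_every=10),
    )


# ---------------------------------------------------------------------------
# reduced-scale batteries shared by the acceptance tests

DESK_TEST_HOURS = 24.0  # battery duration for the lineage-statistics checks
DESK_REPLICATES = 6


def _desk_config(preset_name: str, hours: float = DESK_TEST_HOURS) -> simulator.ScenarioConfig:
    # replicate counts follow the published protocol: six for homogeneous
    # habitats, ten for obstacle-structured ones (set by the preset)
    cfg = simulator.preset(preset_name, scale="desk")
    return replace(
        cfg,
        total_time=hours * 3600.0,
        output=simulator.OutputParams(metrics_every=60),
    )


@pytest.fixture(scope="session")
def desk_engine():
    cfg = _desk_config("competition")
    lattice = simulator.build_lattice(cfg)
    return lattice, hx.DiffusionEngine(lattice, cfg.diffusion)


@pytest.fixture(scope="session")
def desk_battery(desk_engine):
    """Six 24 h replicates of each trophic scenario on the 1 mm domain."""
    lattice, engine = desk_engine
    out = {}
    for name in ("competition", "weak", "strong"):
        cfg = _desk_config(name)
        results, summary = simulator.run_replicates(
            cfg, DESK_REPLICATES, lattice=lattice, engine=engine
        )
        out[cfg.scenario] = (results, summary)
    return out


@pytest.fixture(scope="session")
def weak_noshove_battery(desk_engine):
    lattice, engine = desk_engine
    cfg = _desk_config("weak_noshove")
    return simulator.run_replicates(cfg, DESK_REPLICATES, lattice=lattice, engine=engine)


@pytest.fixture(scope="session")
def structured_battery():
    """Competition in homogeneous vs obstacle-structured desk habitats (12 h)."""
    out = {}
    for habitat in ("homogeneous", "coarse", "medium", "fine"):
        name = "competition" if habitat == "homogeneous" else f"competition-{habitat}"
        cfg = _desk_config(name, hours=12.0)
        results, summary = simulator.run_replicates(cfg)
        out[habitat] = (results, summary)
    return out


def summary_mean(summary, column):
    """Mean row value of a replicate summary table."""
    row = summary[summary["replicate"] == "mean"]
    return float(row[column].iloc[0])
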