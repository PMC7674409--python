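"""Whole-simulation orchestration: configs, presets, the macro-step loop,
and replicate batches.

Each 60 s macro step executes, in order: nitrate boundary source →
diffusion → growth-rate evaluation on the post-diffusion concentrations →
biomass update with clipped, stoichiometric nutrient exchange → division
and shoving → metric collection.  Runs are fully deterministic given the
configuration and seed; replicate seeds derive from the base seed by a
fixed rule so a batch is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import chemistry, expansion, hexgrid, kinetics, lineage
from .chemistry import ChemicalField, DiffusionEngine, DiffusionParams
from .expansion import Colony, ExpansionParams
from .hexgrid import HexLattice, ObstacleSpec
from .kinetics import KineticParams, Strain, StrainRole
from .lineage import LineageLedger

__all__ = [
    "GeometryParams",
    "OutputParams",
    "ScenarioConfig",
    "RunResult",
    "strains_for",
    "run",
    "run_replicates",
    "replicate_seed",
    "preset",
    "PRESET_NAMES",
]

SCENARIOS = ("competition", "weak_mutualism", "strong_mutualism")


@dataclass(frozen=True)
class GeometryParams:
    """Domain geometry in µm: disc radius, hexagon side, inoculation radius."""

    radius: float = 5000.0
    side: float = 20.0
    inoculation_radius: float = 2000.0

    def validate(self) -> None:
        if not self.radius > self.side > 0:
            raise ValueError("require radius > side > 0")
        if not 0 < self.inoculation_radius < self.radius:
            raise ValueError("inoculation radius must lie inside the domain")


@dataclass(frozen=True)
class OutputParams:
    """Metric/snapshot cadence (in macro steps) and optional output directory.

    ``track_mu_history`` records the full per-node growth-rate field at
    every metrics step into ``RunResult.mu_history`` (for growth-rate
    history plots of individual agents).
    """

    metrics_every: int = 30
    snapshot_every: int = 0
    outdir: Optional[str] = None
    track_mu_history: bool = False

    def validate(self) -> None:
        if self.metrics_every < 1:
            raise ValueError("metrics_every must be >= 1")
        if self.snapshot_every < 0:
            raise ValueError("snapshot_every must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulation experiment."""

    scenario: str = "competition"
    geometry: GeometryParams = field(default_factory=GeometryParams)
    obstacles: ObstacleSpec = field(default_factory=ObstacleSpec)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    expansion: ExpansionParams = field(default_factory=ExpansionParams)
    total_time: float = 259200.0  # 72 h
    macro_dt: float = 60.0
    seed: int = 0
    replicates: int = 6
    growth_layer_depth: float = 100.0
    output: OutputParams = field(default_factory=OutputParams)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        self.geometry.validate()
        self.obstacles.validate()
        self.diffusion.validate()
        self.kinetics.validate()
        self.expansion.validate()
        self.output.validate()
        if self.macro_dt <= 0 or self.total_time <= 0:
            raise ValueError("total_time and macro_dt must be positive")
        n = self.total_time / self.macro_dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_time must be divisible by macro_dt")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.kinetics.toxicity_on != (self.scenario == "strong_mutualism"):
            raise ValueError(
                "kinetics.toxicity_on must match the scenario: nitrite is "
                "toxic only under strong mutualism (pH 6.5)"
            )
        if self.expansion.encasement != "none" and self.scenario == "competition":
            raise ValueError("encasement requires a producer/consumer scenario")
        if self.expansion.inoculation_radius != self.geometry.inoculation_radius:
            raise ValueError("expansion and geometry inoculation radii disagree")
        lo, _ = self.expansion.inoculum_mass_range
        if lo <= 0:
            raise ValueError("zero-biomass inoculum is not allowed")

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.macro_dt))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expansion"]["inoculum_mass_range"] = list(
            d["expansion"]["inoculum_mass_range"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["geometry"] = GeometryParams(**d.get("geometry", {}))
        d["obstacles"] = ObstacleSpec(**d.get("obstacles", {}))
        d["diffusion"] = DiffusionParams(**d.get("diffusion", {}))
        d["kinetics"] = KineticParams(**d.get("kinetics", {}))
        exp = dict(d.get("expansion", {}))
        if "inoculum_mass_range" in exp:
            exp["inoculum_mass_range"] = tuple(exp["inoculum_mass_range"])
        d["expansion"] = ExpansionParams(**exp)
        d["output"] = OutputParams(**d.get("output", {}))
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    """Outcome of one simulation run."""

    config: ScenarioConfig
    lattice: HexLattice
    colony: Colony
    chemical_field: ChemicalField
    metrics: pd.DataFrame
    ledger: LineageLedger
    summary: dict
    provenance: dict
    mu_history: Optional[pd.DataFrame] = None  # time × node growth rates


def strains_for(scenario: str) -> tuple[Strain, Strain]:
    """The two strains of a scenario (1:1 inoculation mix)."""
    if scenario == "competition":
        return (
            Strain(StrainRole.COMPLETE_REDUCER, "reducer_A"),
            Strain(StrainRole.COMPLETE_REDUCER, "reducer_B"),
        )
    return (
        Strain(StrainRole.PRODUCER, "producer"),
        Strain(StrainRole.CONSUMER, "consumer"),
    )


def build_lattice(config: ScenarioConfig) -> HexLattice:
    lattice = hexgrid.build_circular_lattice(config.geometry.radius, config.geometry.side)
    if config.obstacles.mode != "none":
        lattice = hexgrid.apply_obstacles(lattice, config.obstacles)
    return lattice


def _collect_metrics(
    colony: Colony,
    fld: ChemicalField,
    time_s: float,
    mu_means: dict[str, float],
    divisions_total: int,
) -> dict:
    per_lin = lineage.peripheral_lineages(colony)
    row = {
        "time_s": time_s,
        "n_agents": colony.n_agents(),
        "total_biomass_kg": colony.total_biomass(),
        "colony_radius_um": colony.colony_radius(),
        "n_interspecies_boundaries": lineage.interspecies_boundaries(colony),
        "divisions_total": divisions_total,
    }
    for strain in colony.strains:
        row[f"n_peripheral_lineages_{strain.label}"] = len(per_lin[strain.label])
        row[f"mean_mu_{strain.label}"] = mu_means.get(strain.label, 0.0)
    row["n_peripheral_lineages_total"] = sum(len(v) for v in per_lin.values())
    n_branches, ratio = lineage.consumer_branches(colony)
    row["n_consumer_branches"] = n_branches
    row["consumer_lineage_branch_ratio"] = np.nan if ratio is None else ratio
    no3, no2 = chemistry.total_mass(fld, colony.lattice)
    row["total_no3_mol"] = no3
    row["total_no2_mol"] = no2
    return row


def run(
    config: ScenarioConfig,
    *,
    lattice: HexLattice | None = None,
    engine: DiffusionEngine | None = None,
) -> RunResult:
    """Execute one full simulation.

    ``lattice`` and ``engine`` may be passed in to reuse geometry and the
    precomputed diffusion propagator across runs that share them (the
    engine build is the single most expensive setup step); they must
    match the configuration.
    """
    config.validate()
    if lattice is None:
        lattice = build_lattice(config)
    if engine is None:
        engine = DiffusionEngine(lattice, config.diffusion)

    ss = np.random.SeedSequence(config.seed)
    inoc_ss, sweep_ss = ss.spawn(2)
    inoc_rng = np.random.default_rng(inoc_ss)
    sweep_rng = np.random.default_rng(sweep_ss)

    strains = strains_for(config.scenario)
    colony = expansion.inoculate(lattice, config.expansion, strains, inoc_rng)
    ledger = LineageLedger.from_colony(
        colony, config.geometry.inoculation_radius, config.growth_layer_depth
    )
    fld = ChemicalField.uniform(
        lattice,
        no3=config.diffusion.boundary_no3,
        no2=0.0,
        layer_depth=config.diffusion.layer_depth,
    )

    kin = config.kinetics
    dt = config.macro_dt
    initial_biomass = colony.total_biomass()
    gain_total = 0.0
    no3_consumed = 0.0
    no2_consumed = 0.0
    no2_produced = 0.0
    clip_events = 0
    divisions_total = 0
    rows: list[dict] = []
    mu_rows: list[tuple[float, np.ndarray]] = []

    outdir = Path(config.output.outdir) if config.output.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        lattice.write_node_table(outdir / "lattice.tsv")

    for step in range(1, config.n_steps + 1):
        fld = chemistry.apply_boundary_source(fld, lattice, config.diffusion)
        fld = engine.step(fld)

        occ = colony.occupied()
        # role masks change as the colony spreads
        producer_mask = colony.role_mask(StrainRole.PRODUCER)
        consumer_mask = colony.role_mask(StrainRole.CONSUMER)
        consumes_no3 = occ & ~consumer_mask

        c3 = np.clip(fld.c_no3, 0.0, None)
        c2 = np.clip(fld.c_no2, 0.0, None)
        mu = np.zeros(lattice.n_nodes)
        mu[consumes_no3] = kin.mu_max * c3[consumes_no3] / (c3[consumes_no3] + kin.k_no3)
        mu[consumer_mask] = kin.mu_max * c2[consumer_mask] / (c2[consumer_mask] + kin.k_no2)

        grow_mass = colony.mass.copy()
        if config.expansion.stacked_grows:
            grow_mass += colony.stacked
        y = np.asarray(kinetics.yield_coefficient(c2, kin))
        demand = np.where(occ, mu * grow_mass / y, 0.0)  # mol s⁻¹

        fld, realized3, _ = chemistry.apply_reactions(
            fld, lattice, sinks_no3=np.where(consumes_no3, demand, 0.0), dt=dt
        )
        sources2 = np.where(producer_mask, realized3 / dt, 0.0)
        fld, _, realized2 = chemistry.apply_reactions(
            fld,
            lattice,
            sinks_no2=np.where(consumer_mask, demand, 0.0),
            sources_no2=sources2,
            dt=dt,
        )
        realized = realized3 + realized2
        demand_mol = demand * dt
        clip_events += int(np.sum(realized < demand_mol * (1 - 1e-9)))

        gain = y * realized
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(grow_mass > 0, colony.mass / np.where(grow_mass > 0, grow_mass, 1.0), 0.0)
        if config.expansion.stacked_grows:
            colony.mass += gain * frac
            colony.stacked += gain * (1.0 - frac)
        else:
            colony.mass += gain

        gain_total += float(gain.sum())
        no3_consumed += float(realized3.sum())
        no2_consumed += float(realized2.sum())
        no2_produced += float(sources2.sum() * dt)

        colony.last_mu = mu
        divisions_total += expansion.division_sweep(colony, config.expansion, sweep_rng)

        if step % config.output.metrics_every == 0 or step == config.n_steps:
            if config.output.track_mu_history:
                mu_rows.append((step * dt, colony.last_mu.copy()))
            mu_means = {
                s.label: float(mu[colony.strain_idx == i].mean())
                if np.any(colony.strain_idx == i)
                else 0.0
                for i, s in enumerate(strains)
            }
            rows.append(
                _collect_metrics(colony, fld, step * dt, mu_means, divisions_total)
            )
        if (
            outdir is not None
            and config.output.snapshot_every
            and (step % config.output.snapshot_every == 0 or step == config.n_steps)
        ):
            tag = f"t{int(step * dt):08d}"
            colony.to_table().to_csv(outdir / f"occupancy_{tag}.tsv", sep="\t", index=False)
            fld.to_table(lattice).to_csv(outdir / f"field_{tag}.tsv", sep="\t", index=False)

    metrics = pd.DataFrame(rows)
    final_biomass = colony.total_biomass()
    stoich_rel_error = abs((final_biomass - initial_biomass) - gain_total) / max(
        gain_total, 1e-300
    )
    loss_layer, loss_all = lineage.lineage_loss(ledger, colony)
    biomass_by_lin = colony.biomass_by_lineage(len(ledger.founder_strain))
    lucky = lineage.lucky_fraction(biomass_by_lin[ledger.valid])
    n_branches, ratio = lineage.consumer_branches(colony)

    summary = {
        "scenario": config.scenario,
        "seed": config.seed,
        "n_founders": ledger.n_founders,
        "n_agents_final": colony.n_agents(),
        "total_biomass_kg": final_biomass,
        "biomass_gain_kg": final_biomass - initial_biomass,
        "colony_radius_um": colony.colony_radius(),
        "loss_growth_layer_pct": loss_layer,
        "loss_all_pct": loss_all,
        "lucky_fraction_pct": lucky,
        "n_interspecies_boundaries": lineage.interspecies_boundaries(colony),
        "n_peripheral_lineages_total": metrics.iloc[-1]["n_peripheral_lineages_total"],
        "n_consumer_branches": n_branches,
        "consumer_lineage_branch_ratio": np.nan if ratio is None else ratio,
        "divisions_total": divisions_total,
        "stoich_rel_error": stoich_rel_error,
    }
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": _pkg_version,
        "n_steps": config.n_steps,
        "diffusion_substeps": engine.n_substeps,
        "dense_propagator": engine.uses_dense_propagator,
        "no3_consumed_mol": no3_consumed,
        "no2_consumed_mol": no2_consumed,
        "no2_produced_mol": no2_produced,
        "clipped_consumption_events": clip_events,
        "strain_labels": [s.label for s in strains],
    }
    mu_history = None
    if config.output.track_mu_history and mu_rows:
        mu_history = pd.DataFrame(
            [r for _, r in mu_rows], index=pd.Index([t for t, _ in mu_rows], name="time_s")
        )
    if outdir is not None:
        metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        ledger.to_table(colony).to_csv(outdir / "lineages.tsv", sep="\t", index=False)
        colony.to_table().to_csv(outdir / "occupancy_final.tsv", sep="\t", index=False)
    return RunResult(
        config, lattice, colony, fld, metrics, ledger, summary, provenance, mu_history
    )


def replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed derived from the base seed."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def run_replicates(
    config: ScenarioConfig,
    n: int | None = None,
    *,
    lattice: HexLattice | None = None,
    engine: DiffusionEngine | None = None,
) -> tuple[list[RunResult], pd.DataFrame]:
    """Run ``n`` replicates differing only in seed (and, for stochastic
    obstacle fields, in the obstacle draw, which is redrawn per replicate).

    Returns the individual results and a summary table with one row per
    replicate plus aggregate ``mean``/``sd`` rows for the numeric metrics.
    """
    config.validate()
    if n is None:
        n = config.replicates
    if n < 1:
        raise ValueError("need at least one replicate")

    share_geometry = config.obstacles.mode != "stochastic"
    if share_geometry:
        if lattice is None:
            lattice = build_lattice(config)
        if engine is None:
            engine = DiffusionEngine(lattice, config.diffusion)

    results: list[RunResult] = []
    for i in range(n):
        seed_i = replicate_seed(config.seed, i)
        cfg_i = replace(config, seed=seed_i)
        if not share_geometry:
            cfg_i = replace(
                cfg_i, obstacles=replace(config.obstacles, seed=seed_i)
            )
            results.append(run(cfg_i))
        else:
            results.append(run(cfg_i, lattice=lattice, engine=engine))

    per_rep = pd.DataFrame([r.summary for r in results])
    numeric = per_rep.select_dtypes(include=[np.number])
    agg = pd.DataFrame(
        [numeric.mean(), numeric.std(ddof=1)], index=["mean", "sd"]
    ).reset_index(names="replicate")
    per_rep.insert(0, "replicate", np.arange(n))
    summary = pd.concat([per_rep, agg], ignore_index=True)
    return results, summary


# ---------------------------------------------------------------------------
# presets

_HABITATS = {
    "homogeneous": None,
    "coarse": 500.0,
    "medium": 400.0,
    "fine": 300.0,
    "stochastic": 400.0,
}

PRESET_NAMES = tuple(
    f"{scen}-{hab}" if hab != "homogeneous" else scen
    for scen in ("competition", "weak", "strong")
    for hab in _HABITATS
) + ("weak_noshove", "weak_consumer_ring", "weak_producer_ring")

_SCENARIO_ALIASES = {
    "competition": "competition",
    "weak": "weak_mutualism",
    "strong": "strong_mutualism",
}


def preset(name: str, scale: str = "full", seed: int = 0) -> ScenarioConfig:
    """Named experiment configurations for the standard scenarios.

    ``name`` is ``{competition, weak, strong}`` optionally suffixed with a
    habitat (``-coarse``, ``-medium``, ``-fine``, ``-stochastic``;
    obstacle grids of 100 µm discs at 500/400/300 µm spacing), or one of
    the weak-mutualism variants ``weak_noshove``, ``weak_consumer_ring``,
    ``weak_producer_ring``.

    ``scale`` selects ``"full"`` (5 mm domain, 2 mm inoculum — the
    reference setup) or ``"desk"`` (1 mm domain, 0.4 mm inoculum, same
    72 h duration and kinetics), a reduced domain that runs in about a
    minute on one CPU while preserving the inoculum/domain ratio.
    """
    base = name
    habitat = "homogeneous"
    encasement = "none"
    shoving = True
    if name in ("weak_noshove", "weak_consumer_ring", "weak_producer_ring"):
        base = "weak"
        if name == "weak_noshove":
            shoving = False
        elif name == "weak_consumer_ring":
            encasement = "consumer_ring"
        else:
            encasement = "producer_ring"
    elif "-" in name:
        base, habitat = name.split("-", 1)
    if base not in _SCENARIO_ALIASES or habitat not in _HABITATS:
        raise ValueError(f"unknown preset {name!r}; known presets: {PRESET_NAMES}")
    scenario = _SCENARIO_ALIASES[base]

    if scale == "full":
        geometry = GeometryParams(radius=5000.0, side=20.0, inoculation_radius=2000.0)
    elif scale == "desk":
        geometry = GeometryParams(radius=1000.0, side=20.0, inoculation_radius=400.0)
    else:
        raise ValueError("scale must be 'full' or 'desk'")

    if habitat == "homogeneous":
        obstacles = ObstacleSpec(mode="none")
        replicates = 6
    else:
        obstacles = ObstacleSpec(
            mode="stochastic" if habitat == "stochastic" else "regular",
            diameter_mean=100.0,
            diameter_variance=20.0,
            spacing=_HABITATS[habitat],
            seed=seed,
            keepout_radius=geometry.inoculation_radius,
        )
        replicates = 10

    return ScenarioConfig(
        scenario=scenario,
        geometry=geometry,
        obstacles=obstacles,
        diffusion=DiffusionParams(),
        kinetics=KineticParams(toxicity_on=(scenario == "strong_mutualism")),
        expansion=ExpansionParams(
            shoving_enabled=shoving,
            encasement=encasement,
            inoculation_radius=geometry.inoculation_radius,
        ),
        total_time=259200.0,
        macro_dt=60.0,
        seed=seed,
        replicates=replicates,
    )
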