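# Model and methods

`hexcolony` simulates the range expansion of a two-strain denitrifying
bacterial community on an agar-like surface, at the resolution of
super-agents (one lattice node ≈ 10³ cells), coupling nutrient diffusion,
Monod growth, on-grid mechanics and ancestral-lineage bookkeeping.

## Domain

The habitat is a circular disc of radius *R* (default 5 mm; 1 mm in the
reduced "desk" presets) tiled by regular pointy-top hexagons of side
*s* = 20 µm. Axial coordinates `(q, r)` map to positions
`x = p(q + r/2)`, `y = 1.5 s r` with centre-to-centre pitch
`p = s√3 ≈ 34.64 µm`; every interior node has six neighbours at distance
*p*. Nodes with incomplete neighbour rings form the rim and act as the
nitrate source. The pitch convention matters: both the diffusion bond
conductance and the five-cell shoving radius are expressed in lattice
units, so it is fixed and documented here rather than configurable.

Obstacle-structured habitats flag nodes inside solid discs (default
100 µm diameter) laid on a square grid of 500/400/300 µm spacing
(coarse/medium/fine) or with normally distributed diameters
(mean 100 µm). The printed spread of that distribution is ambiguous
between a standard deviation and a variance; the default reads it as
σ = 20 µm, with σ = √20 µm available via
`ObstacleSpec(variance_is_sigma=False)`. Obstacle nodes are removed from
all adjacency lists: no solute flux crosses them and no cell ever
occupies them. Obstacles whose disc would intrude into the central
inoculation region are dropped so the inoculum is always placeable
(so structured habitats never perturb the inoculum itself); discs may
overlap the rim and are clipped to the domain.

## Solute transport

Two solutes are tracked — nitrate (electron acceptor supplied at the
boundary) and nitrite (the cross-fed intermediate, produced only by
metabolism). Concentrations are node-averaged, in mM ≡ mol m⁻³.
Exchange between adjacent nodes is one-dimensional Fickian flux
`D·A·(C_j − C_i)/p` through the shared hexagon edge (`A = s·d`, with *d*
the thickness of the nutrient-bearing layer). Dividing by the node
volume `V = (3√3/2)s²·d` gives the per-bond exchange rate

    k = D / (4.5 s²)  ≈ 0.94 s⁻¹   (D = 1.7e-9 m² s⁻¹, s = 20 µm)

independent of *d*. The resulting graph Laplacian is symmetric with zero
column sums, so pairwise exchange conserves mass to machine precision.

Each 60 s macro step is integrated by explicit forward Euler substeps.
The substep is capped at half the positivity bound `1/(k·deg_max)`
(≈ 0.088 s here, i.e. ~680 substeps per macro step), which guarantees
stability, non-negativity and a discrete maximum principle. Because the
operator is constant in time, the composite map of one macro step —
`(I + Δt·D·L)ⁿ` — is precomputed once per lattice by binary
exponentiation whenever the lattice has ≤ 4096 nodes (`DiffusionEngine`),
reducing a macro step to one dense matrix–vector product. This is
algebraically the same linear map as the substep loop (validated to
1e-13 in the tests); larger lattices fall back to sparse substepping.

Boundary condition: nitrate on all rim nodes is reset to 1 mM *before*
each diffusion step (a constant peripheral source). It is not re-imposed
afterwards, and nitrite is neither reset nor absorbed anywhere — the
domain is closed for nitrite.

## Growth kinetics

Strains are isogenic apart from their trophic role:

* complete reducer (competition scenario, used pairwise): Monod growth
  on nitrate, `µ = µ_max C_NO3/(C_NO3 + K_NO3)`, no nitrite release;
* producer: same nitrate Monod, releasing 1 mol nitrite per mol nitrate
  reduced;
* consumer: Monod growth on nitrite.

Defaults: `µ_max = 5.4e-6 s⁻¹` (anaerobic denitrifying growth; doubling
time ≈ 36 h), `K_NO3 = K_NO2 = 0.04 mM` (equal by construction to avoid
biasing the comparison between substrates), `K_inh = 0.02 mM`,
`Y_max = 0.06`, `Y_min = 0.006 kgDW mol⁻¹`.

Nitrite toxicity (strong mutualism, ambient pH 6.5) acts **only on the
yield**, of both strains:
`Y = (Y_max − Y_min)·K_inh/(K_inh + C_NO2) + Y_min`; under weak
mutualism (pH 7.5) and competition `Y = Y_max`. Growth rate is never
affected by toxicity.

Biomass integrates explicitly, `m ← m(1 + µΔt)`, and consumption follows
the yield, `ϑ = µ·m/Y` (mol s⁻¹). Within a macro step the order is:
boundary source → diffusion → growth-rate evaluation on the
post-diffusion concentrations → reaction application and biomass update
→ division/shoving. Consumption is clipped at the locally available
moles; the realised uptake is what generates biomass, so
`gain = Y · realised moles` holds exactly per node per step and the
run-level stoichiometric audit closes to < 1e-6 relative. Producer
nitrite release is coupled 1:1 to *realised* nitrate uptake and credited
before consumer uptake within the same operator split.

## Colony mechanics

Every node holds at most one super-agent (strain, biomass, lineage id,
stacked-layer biomass). Inoculation fills all nodes within the
inoculation radius (default 2 mm; 0.4 mm desk) with a uniformly random
strain (1:1) and an initial mass uniform in 10–100% of the division
mass; each founder gets a unique lineage id. Optional encasement modes
overwrite the outermost inoculated ring with one strain (fresh ids) to
probe super-sector nucleation.

On reaching the division mass an agent splits in half (exact biomass
conservation). Daughter placement cascade:

1. a uniformly random empty neighbour node;
2. else, if shoving is enabled and the shortest path through occupied
   nodes to the colony periphery is ≤ 5 edges: the periphery-end agent
   steps to a random empty neighbour, every agent on the path advances
   one node (carrying lineage and stacked biomass), and the daughter
   takes the vacated origin;
3. else the daughter mass is stacked in a layer above the node
   (pseudo-3D growth).

Shortest paths are breadth-first through occupied, non-obstacle nodes;
ties are broken **uniformly over all shortest paths** by counting paths
during the BFS and sampling predecessors proportionally — a cheap exact
scheme that avoids directional artifacts. If the periphery-end agent has
no vacancy the shove aborts and the daughter stacks (conservative
fallback for a case the mechanics leave open). Agents divide at most
once per macro step, processed in uniformly shuffled order; surplus mass
carries over. The stacked layer keeps growing and consuming (it is live
biomass) but never divides laterally; `stacked_grows=False` disables
this.

The division mass is the main free constant: it couples biomass to
nutrient demand via `ϑ = µm/Y` and thereby sets the nitrate penetration
depth into the colony. The default, 1.5e-10 kg (≈ 10³ cells of
1.5e-13 kg — a 20 µm hexagon holds on the order of a thousand cells in a
monolayer), together with the default 1 mm diffusion-layer depth gives a
penetration depth of a few hundred µm: the colony interior starves while
a peripheral growth layer keeps expanding, which is the qualitative
regime the simulator is meant to reproduce. Both constants are exposed
in the configuration (`expansion.division_mass`,
`diffusion.layer_depth`) because they rescale each other: only the
ratio matters for the growth-layer depth.

## Lineage observables

* *Peripheral lineages*: unique founder ids among periphery agents
  (occupied nodes with ≥ 1 empty, non-obstacle neighbour), per strain.
* *Interspecies boundaries*: periphery agents ordered by angle around
  the occupied-region centroid (radius breaks ties); strain transitions
  counted along the cyclic sequence. Even by construction for a
  two-strain single closed front.
* *Consumer branches*: 6-neighbour connected components of
  consumer-occupied nodes that touch the periphery (the lattice
  counterpart of a visible consumer sector penetrating the producer
  front), with the ratio of unique peripheral consumer lineages to
  branches; monoclonal super-sectors give a ratio near 1.
* *Lineage loss*: % of founders with no descendant on the final
  periphery, over (a) founders that started within the growth layer
  (default 100 µm — five cells, matching the shoving radius — from the
  inoculum edge; configurable, since the "actively growing layer" is
  defined only graphically) and (b) all founders.
* *Lucky fraction*: smallest head-fraction of biomass-ranked founders
  whose cumulative final biomass (lattice + stacked layers) exceeds 50%
  of the total, as % of the founder count.
* *Replicate comparison*: Welch two-sample t-test on replicate-level
  metrics.

## Randomness and reproducibility

One master seed per run; inoculation and the division/shoving sweep draw
from independent streams spawned from it. Replicate seeds derive from
the base seed by a fixed `SeedSequence([base, index])` rule; stochastic
obstacle fields are redrawn per replicate (regular fields are shared).
Identical configuration + seed reproduces byte-identical metrics files.
Provenance (config hash, seed, substep count, clipped-consumption event
count) is attached to every result.

## Reduced-scale presets and what they show

The full-size domain (5 mm, ≈ 7×10⁴ nodes) exceeds a desk/CI budget, so
`preset(name, scale="desk")` shrinks the domain to 1 mm radius with a
0.4 mm inoculum — preserving the 2:5 inoculum/domain ratio — while
keeping the kinetics, the 60 s step and the 72 h duration. A desk run
takes ~40 s on one CPU. The acceptance script uses six desk replicates
per scenario; the test suite's replicate battery additionally shortens
runs to 24 h to stay within CI budgets.

Lineage statistics must be interpreted with the model clock in mind:
population-genetic observables (lineage loss, sector coarsening, lucky
fractions) are driven by the number of generations at the expanding
front, and with `µ_max = 5.4e-6 s⁻¹` a 72 h run spans only ≈ 2 doubling
times. Expansion is therefore a few cell rings and founder lineage loss
sits close to its geometric floor (the ratio of growth-layer founders to
final periphery slots), while the lucky fraction remains dominated by
the random inoculum masses (tens of %, all scenarios similar). Sharper
bottlenecks and %-level lucky fractions require many more elapsed
generations (longer simulated time or faster kinetics) — a property of
the model itself, not of the domain size: shrinking or enlarging the
lattice does not change the number of generations.

The synthetic scenarios emulate anaerobic colony growth on nitrate agar:
diffusion-limited nutrient fields, trophic coupling through nitrite, and
drift at a quasi-1D front. They do not emulate cell-scale mechanics
(rod shapes, nematic ordering), EPS, water films, pH fields (pH enters
only as the binary toxicity switch), mutation, death or detachment —
conclusions from passing tests transfer to real colonies only at the
level of these coarse-grained mechanisms.

## Numerical choices and degenerate inputs

* Substeps: auto = `ceil(Δt_macro / (0.5 · positivity bound))`;
  user-supplied substep counts below the bound raise a configuration
  error that reports the maximum stable substep.
* Consumption clipping keeps concentrations ≥ 0 exactly; clipped events
  are counted in provenance rather than warned per-node.
* The division sweep re-checks ripeness per node because an earlier
  shove in the same sweep can relocate an agent.
* A shove path of length 1 cannot occur (a divider bordering a vacancy
  takes the vacancy branch); the code guards for it anyway.
* Empty peripheries raise on boundary counting (undefined walk); a zero
  branch count reports the lineage/branch ratio as absent (NaN in
  tables), not 0.
* `lucky_fraction` requires at least one lineage with positive biomass.

## Known limitations

* The explicit scheme spends ~680 substeps per macro step at the default
  lattice pitch; the dense propagator amortises this for ≤ 4096 nodes,
  but full-scale (7×10⁴ node) runs fall back to sparse substepping and
  are slow (hours) — correct but not optimised.
* Angular boundary counting assumes a star-convex-ish front; for
  strongly lobed colonies (dense obstacles) transitions can be
  over-counted relative to a walk along the actual front.
* The stacked layer is a scalar reservoir: vertical structure, shading
  and diffusion into the stack are not modelled.
* Obstacle discs are clipped to the domain; layouts that would cover the
  entire rim are rejected rather than partially honoured.
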