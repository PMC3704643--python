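# Methods

`mpaconnect` models larval connectivity between marine protected areas
(MPAs) as a three-stage computation: Lagrangian transport of virtual larvae
through gridded daily ocean currents, settlement scoring of final positions
against MPA polygons, and network/statistical analysis of the resulting
connectivity matrix. This note documents the model, its parameters, the
synthetic data generator, and the numerical and design choices.

## Transport model

Virtual larvae are passive particles. Each iteration, the current velocity
is tri-linearly interpolated in (lon, lat, depth) to the particle position
from the daily-mean snapshot covering the current time (fields are treated
as piecewise-constant in time within a day — the simplest reading of daily
forcing with purely spatial interpolation). The position is advanced by an
explicit forward-Euler step on the sphere (R = 6371 km), with meters
converted to degrees through the local metric (1 deg lat = 111.195 km, 1
deg lon scaled by cos lat).

Sub-grid turbulence is a random walk added to the horizontal velocity:

    u_r = delta * sqrt(2 K_h / dt),   delta ~ U[-1, 1] per component

with the Lagrangian horizontal diffusivity given by the Monin–Ozmidov
scaling `K_h = eps^(1/3) l^(4/3)`, where `eps = 1e-9 m^2 s^-3` is the
turbulent dissipation rate and `l` the horizontal cell width. With Var
(delta) = 1/3 this yields a 2-D mean squared displacement of
`(4/3) K_h t`, the diffusion law the tests check. For a 1/12-degree
Mediterranean-latitude cell (l ≈ 6.9 km), K_h ≈ 131 m²/s.

The iteration time step must satisfy `dt <= l / max_speed` so a particle
never crosses more than one cell per step; with 6–8 km cells and ~0.5 m/s
peak currents the bound is 12000–16000 s, and the default `dt = 7200 s`
(2 h) is comfortably admissible. Positions are recorded daily (every 12
iterations).

Boundary rules: particles crossing the outer domain edge are *lost* and
excluded from every downstream count; particles surfacing are reflected
back into the water; particles reaching a land cell are reverted to their
last sea position and enter *standstill* — frozen in place, clock still
running, and still scoreable at settlement (they are never revived by later
favourable currents). Depths below the deepest level midpoint are clamped
as a numerical guard; velocities at layer midpoints vanish at the bottom,
so the seafloor is not otherwise reachable.

## Release and settlement

The default spawning schedule follows a late-summer serranid: ten release
events every 3 days from the 1st of the spawning month (August by
default), 1000 larvae per event per MPA (10,000 per MPA-year), released at
0.2 m depth at uniform-random sea points inside each MPA polygon (the
within-polygon placement is otherwise unconstrained). The pelagic larval
duration (PLD) defaults to 30 days and is explored over 20–40 days.
Settlement is scored from final positions only — no competency window —
by point-in-polygon tests; points exactly on a polygon edge count as
inside, with ties between edge-sharing polygons broken toward the lowest
MPA id. Overlapping polygon interiors raise an error (the generator
guarantees disjoint MPAs).

The connectivity matrix C holds `c(i, j)` = fraction of larvae released in
source MPA j ending inside destination MPA i; columns sum to at most 1,
with the remainder at large or lost. Connectance is the fraction of
nonzero entries over n² (diagonal included); local retention is `c(i, i)`;
self-recruitment divides it by the total input `sum_j c(i, j)` and is
reported as undefined (NaN) for MPAs receiving nothing. With 50,000
larvae per source the smallest resolvable probability is 1/50,000 =
0.00002.

## Diel vertical migration

The optional behaviour forces larvae to 0.2 m depth when the clock crosses
20:00 and to 50 m (capped above the local seafloor at the deepest level
midpoint) when it crosses 08:00, as instantaneous depth reassignment — no
swim speed is modelled. Between triggers depth evolves only through
vertical advection. In any surface-intensified flow this halves the
daytime transport, shortening dispersal.

## Graph analysis

The MPA graph has a directed edge j → i for every off-diagonal
`c(i, j) > 0`; self-loops are flagged separately and excluded from
degrees, paths and clustering. Downstream/upstream neighborhood sizes are
out-/in-degrees; isolated nodes, pure sources and pure sinks are
classified. Strong clusters are strongly connected components (mutual
directed reachability); weak clusters forget edge direction. Betweenness
centrality is the sum over ordered pairs (k, l), k ≠ i ≠ l, of the
fraction of hop-count shortest directed paths through i; edges are
unweighted for path-finding even though probabilities exist, endpoints are
excluded (including them would make the metric degenerate), and pairs with
no connecting path contribute nothing. Raw sums are reported alongside a
variant normalized by (n−1)(n−2). Components and betweenness are computed
with networkx; the test suite checks them against hand-written
transitive-closure and BFS path-enumeration oracles on exhaustive small
digraphs and random medium ones.

## Shelf export

The continental shelf is every sea cell with bathymetry strictly below
200 m. Non-lost final positions are binned into grid cells;
the summary reports the fractions of larvae on the shelf, in the open sea
and inside MPAs, and the *unseeded* fraction of shelf area — cells
receiving no larvae at all, weighted by spherical cell area rather than
cell count. Standstill larvae count in their coastal cell. Abundance maps
can weight larval production by MPA surface area (normalized to preserve
the total), and reduce to the uniform map when all areas are equal.

## Sensitivity statistics

Scenario ensembles vary PLD, vertical migration and spawning month, with
replicate r of every scenario sharing seed `base + r` so contrasts are
paired through common random numbers. PLD effects are tested by OLS of
each response on PLD in days (slope per day, two-sided p from t with n−2
df); vertical migration by a two-sample pooled-variance t test; spawning
month by one-way ANOVA. Degenerate zero-variance comparisons return
(0, 1) by convention. No multiple-testing correction is applied.

## Synthetic study domain

The generator emulates eddy-resolving regional-model output (daily means,
1/12-degree, layered, land-masked) and a coastal MPA layer, with four
elementary flows: uniform, solid rotation, a streamfunction-derived gyre
field, and an along-coast boundary jet decaying offshore. The gyre field
is differentiated discretely from the streamfunction, so its centered
divergence vanishes identically in the sea interior. All fields are zero
on land, which the standstill rule relies on.

The packaged study system (`demo_study_domain`) is a 10×4-degree basin
with a northern coast and a 40 km shelf: a westward coastal jet of
0.05 m/s (35 km e-folding, the along-slope mean drift) over two
counter-rotating 0.15 m/s gyres confined offshore of the shelf break and
slowly propagating (90-day phase period) — the meso-scale eddy field. Both
are surface-intensified with a 75 m e-folding depth and weaken 0.3 %/day
through late summer, so July currents are stronger than September ones.
Twelve small (~65 km²) coastal MPAs sit in three groups of four on the
eastern shelf (29 km within groups, ~85 km gaps), leaving a long MPA-free
downstream shelf. These choices place the system in the qualitative regime
of a basin-scale MPA network: median dispersal of order 10² km at PLD 30,
a sparse directed graph organised into a few clusters bridged by marginal
links, and a shelf whose seeded extent is limited by larval reach.

What the generator does *not* emulate: curvilinear/partial-cell grids,
realistic coastline complexity (headland eddies, bays), tides,
wind-driven interannual variability, habitat availability, and larval
mortality or behaviour beyond the single diel-migration scenario. Passing
directional tests on this domain therefore show that the *pipeline*
responds to PLD and behaviour the way the real system does, not that the
synthetic ocean is realistic in detail.

## Problem sizes and determinism

Scenario ensembles default to 400 larvae per event (4,000 per MPA-year,
48,000 per run) and a single synthetic season — enough to saturate
point-in-polygon settlement counts and shelf seeding in the reachable
zone while keeping a full 61-run sensitivity ensemble to a few minutes on
one core. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical
trajectories, matrices and statistics. `scripts/acceptance.py --seed S`
re-runs every stage from scratch under seed S.

## Known limitations

- Forward Euler is first-order; the admissibility bound keeps errors small
  at the default scales (closed-form tests bound uniform-flow error at
  0.5% and orbit closure at 1% per rotation), but very long PLDs with
  strong curvature would accumulate drift.
- The random walk is horizontal only; no vertical diffusion.
- Settlement uses final positions only; species with long competency
  windows are outside the model.
- Lost larvae are censored, which slightly biases dispersal statistics in
  domains with strong outflow.
- Strong-cluster counts on small networks are coarse, step-like statistics;
  their replicate variance is non-Gaussian, so the t test on them is
  approximate (the direction of the mean difference is the robust signal).
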