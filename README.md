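# mpaconnect

Biophysical larval-dispersal and connectivity analysis for networks of
marine protected areas (MPAs).

Sedentary coastal fish depend on a drifting larval phase to connect
populations, so the conservation value of an MPA system hinges on whether
larvae released in one reserve can reach another. `mpaconnect` estimates
that connectivity by tracking virtual larvae through gridded ocean-current
fields and analysing where they end up:

- **Lagrangian tracker** — forward-Euler advection of passive (or
  diel-migrating) larvae with tri-linear velocity interpolation and a
  random-walk horizontal diffusion, `u_r = δ·√(2K_h/Δt)` with
  `K_h = ε^{1/3} l^{4/3}` (Monin–Ozmidov), plus coastal boundary rules
  (loss at the open edge, surface reflection, standstill at the coast).
- **Connectivity matrix** — `c(i,j)`: the fraction of larvae released in
  MPA *j* whose final position lies inside MPA *i*; connectance, local
  retention `lr(i) = c(i,i)`, self-recruitment
  `sr(i) = c(i,i)/Σ_j c(i,j)` and subsidy recruitment `1 − sr`.
- **Graph metrics** — the directed MPA graph: upstream/downstream
  neighborhoods, strongly/weakly connected clusters, and betweenness
  centrality `b(i) = Σ_{k≠l} σ_{kl}(i)/σ_{kl}` over hop-count shortest
  paths, identifying gateway MPAs.
- **Shelf export** — larval abundance maps on the continental shelf
  (< 200 m) and the fraction of shelf area receiving no larvae.
- **Sensitivity statistics** — replicate ensembles over pelagic larval
  duration (OLS regression), diel vertical migration (Student's t) and
  spawning month (ANOVA).

A synthetic-data module generates NEMOMED12-like current fields
(eddying, divergence-free, land-masked, daily means), bathymetry,
coastlines and MPA polygons, so the entire pipeline runs with no
downloads. See `docs/methods.md` for the model description.

## Worked example

Run the packaged study system — a Mediterranean-like basin with a westward
coastal jet over two offshore gyres and 12 coastal MPAs in three groups —
for one August spawning season at PLD 30:

```python
import numpy as np
from mpaconnect import (SimulationConfig, run_simulation, assign_settlement,
                        connectivity_matrix, recruitment_stats,
                        dispersal_distances, build_graph, export_summary)
from mpaconnect.synth import demo_study_domain
from mpaconnect.graphs import strong_clusters, n_clusters

grid, mpas, field, _ = demo_study_domain()
cfg = SimulationConfig(larvae_per_event=400, spawn_start_date="2000-08-01", seed=0)
traj = run_simulation(field, grid, mpas, cfg)

counts = assign_settlement(traj, mpas)
released = np.array([np.sum(traj.source_mpa == m.id) for m in mpas], float)
C = connectivity_matrix(counts, released, [m.id for m in mpas])
print("median dispersal", dispersal_distances(traj)["pooled"]["median_km"])
print("connectance     ", recruitment_stats(C).connectance)
print("strong clusters ", n_clusters(strong_clusters(build_graph(C))))
print("unseeded shelf  ", export_summary(traj, grid, mpas).frac_shelf_unseeded)
```

prints (48,000 larvae released in total)

```
median dispersal 65.5687854642822
connectance      0.4722222222222222
strong clusters  3
unseeded shelf   0.21664085852728499
```

i.e. with a 30-day drift the median larva travels ~66 km, about half of
all ordered MPA pairs exchange at least one larva, the twelve MPAs resolve
into their three geographic groups (each group mutually connected, the
gaps between groups crossed mostly one-way downstream), and ~22% of the
shelf area receives no larvae at all. Longer PLDs raise connectance and
merge clusters; diel vertical migration does the opposite.

There is also a CLI with one subcommand per stage:

```bash
mpaconnect synth --out data/                 # field.nc + mpas.geojson
mpaconnect simulate --field data/field.nc --mpas data/mpas.geojson \
                    --pld 30 --seed 1 --out traj.csv
mpaconnect connect  --traj traj.csv --mpas data/mpas.geojson --out results/
mpaconnect graph    --connectivity results/connectivity.csv --out results/
mpaconnect export   --traj traj.csv --field data/field.nc \
                    --mpas data/mpas.geojson --out results/
mpaconnect run-all  --config config.yaml --out results/
```

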