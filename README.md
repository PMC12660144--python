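# teamscape

Agent-based simulation of networked collective problem solving on
rugged payoff landscapes.

Skill-typed agents hill-climb on a 100×100 payoff grid. Each cell and
each agent carries one of `s` skill types; an agent can evaluate and
move to its adjacent cells plus cells within Euclidean radius `r` that
match its own skill. Agents are linked by an undirected social
network and, on each asynchronous update, either **copy** (add their
neighbors' occupied cells to their candidate set) or **collaborate**
(add cells within `r` matching any neighbor's skill), moving only on a
strict payoff improvement. The package includes the full experiment
harness: collaboration-frequency sweeps, network-density sweeps, and
collaborate-then-copy phase schedules, replicated over independent
runs with mean/SEM summaries.

## Layout

| module | contents |
| --- | --- |
| `teamscape.landscape` | payoff surfaces (Gaussian signal + fractal Perlin noise, or a simple unimodal bump), skill grids, local-optima counting, CSV import/export |
| `teamscape.perception` | individual / collaborative / copy candidate-cell sets |
| `teamscape.networks` | path, complete, edgeless networks; random densification; density |
| `teamscape.engine` | mode schedules, simulation config, asynchronous update dynamics, termination |
| `teamscape.metrics` | group payoff summaries and the Gini coefficient |
| `teamscape.experiments` | batch runner, named protocols, results tables, manifests |

## CLI

```sh
# generate a landscape + skill grid as CSV (with JSON metadata sidecars)
teamscape landscape --kind complex --seed 1 --out scratch/inst

# one simulation run from a YAML/JSON config
teamscape run --config examples/run.yaml --seed 7 --out scratch/traj.csv

# a named experimental protocol (timeseries, p_sweep, density_sweep, phase_sweep)
teamscape protocol p_sweep --runs 1000 --seed 0 --out scratch/results
```

A run config is a flat mapping of `SimulationConfig` fields, e.g.

```yaml
n: 16
s: 100
r: 6
width: 100
height: 100
landscape_kind: complex
network: {kind: path}
schedule: {kind: constant_p, p: 0.5}
```

## Reproducibility

Every run is driven by a single master seed: it spawns one substream
for initialization (landscape, skills, network, agents) and one for
the dynamics, and batch replicates use disjoint child streams, so any
run or results table is bit-reproducible from its config and seed and
independent of which other runs execute.
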