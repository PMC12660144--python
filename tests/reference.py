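"""Naive brute-force reference implementations used as test oracles.

Candidate sets are computed by double loops over every grid cell and
the dynamics by a direct transcription of the update rules. The
reference shares only the documented RNG protocol with the package
(permutation per step; one uniform variate per agent update under a
constant-p schedule; one integer draw into the sorted tied cells when
more than one candidate attains the maximum), so trajectory equality
checks the engine's semantics, not its code.
"""

from __future__ import annotations

import math

import numpy as np

from teamscape import SimulationConfig
from teamscape.engine import _as_seedseq, initialize


def naive_individual_set(agent, instance, r):
    height, width = instance.shape
    row, col = agent.position
    out = set()
    for rr in range(height):
        for cc in range(width):
            if max(abs(rr - row), abs(cc - col)) <= 1:
                out.add((rr, cc))
            elif math.dist((rr, cc), (row, col)) <= r + 1e-9:
                if instance.skills.labels[rr, cc] == agent.skill:
                    out.add((rr, cc))
    return out


def naive_collaborative_set(agent, neighbor_skills, instance, r):
    height, width = instance.shape
    row, col = agent.position
    skills = {agent.skill} | set(neighbor_skills)
    out = set()
    for rr in range(height):
        for cc in range(width):
            if max(abs(rr - row), abs(cc - col)) <= 1:
                out.add((rr, cc))
            elif math.dist((rr, cc), (row, col)) <= r + 1e-9:
                if instance.skills.labels[rr, cc] in skills:
                    out.add((rr, cc))
    return out


def naive_copy_set(agent, neighbor_positions, instance, r):
    return naive_individual_set(agent, instance, r) | {
        (int(p[0]), int(p[1])) for p in neighbor_positions
    }


def naive_gini(values):
    values = list(values)
    n = len(values)
    total = sum(values)
    if total == 0:
        return 0.0
    acc = 0.0
    for a in values:
        for b in values:
            acc += abs(a - b)
    return acc / (2 * n * n * (total / n))


def naive_count_local_optima(grid):
    grid = np.asarray(grid, dtype=float)
    height, width = grid.shape
    count = 0
    for r in range(height):
        for c in range(width):
            is_opt = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < height and 0 <= cc < width:
                        if grid[rr, cc] > grid[r, c]:
                            is_opt = False
            count += is_opt
    return count


def reference_run(config: SimulationConfig) -> np.ndarray:
    """Step-by-step re-enactment of a run; returns the payoff history.

    Initialization is shared with the package (the oracle targets the
    dynamics); everything after that is recomputed naively.
    """
    init_ss, dyn_ss = _as_seedseq(config.seed).spawn(2)
    instance, net, state = initialize(config, np.random.default_rng(init_ss))
    rng = np.random.default_rng(dyn_ss)
    vals = instance.payoffs.values
    schedule = config.schedule
    agents = state.agents

    history = [[vals[a.position] for a in agents]]
    step = 0
    while True:
        step += 1
        moved = False
        for idx in rng.permutation(len(agents)):
            agent = agents[int(idx)]
            if schedule.kind == "phase":
                mode = "collaborate" if step <= schedule.k else "copy"
            else:
                mode = "collaborate" if rng.random() < schedule.p else "copy"
            nbrs = net.neighbors(agent.id)
            if mode == "collaborate":
                cand = naive_collaborative_set(
                    agent, {agents[j].skill for j in nbrs}, instance, config.r
                )
            else:
                cand = naive_copy_set(
                    agent, {agents[j].position for j in nbrs}, instance, config.r
                )
            cur = vals[agent.position]
            best = max(vals[c] for c in cand)
            if best > cur:
                tied = sorted(c for c in cand if vals[c] == best)
                choice = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
                agent.position = choice
                moved = True
        history.append([vals[a.position] for a in agents])
        if schedule.kind == "phase":
            if step >= schedule.total_rounds:
                break
        elif not moved or step >= config.max_steps:
            break
    return np.array(history)
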