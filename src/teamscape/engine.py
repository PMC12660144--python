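"""Asynchronous update dynamics: mode choice, moves, stepping, termination.

Each time step draws a fresh uniform permutation of the agents and
updates them sequentially, so later agents see earlier agents' new
positions within the same step. An updating agent either collaborates
(candidate set = cells within r matching its own or any neighbor's
skill, plus the Moore neighborhood) or copies (own-skill cells within
r, Moore neighborhood, plus neighbors' occupied cells), moving to the
highest-payoff candidate only if it strictly exceeds the current
payoff. Runs with a constant collaboration probability terminate
after the first step in which no agent moves; phase schedules run a
fixed horizon.

RNG protocol (relied on by reproducibility tests): the master seed
spawns two substreams, one consumed by :func:`initialize` (landscape,
skills, network, agent skills then agent positions, in that order)
and one by the dynamics. Per step the dynamics stream draws the
permutation; per agent update, a constant-p schedule draws one
uniform variate for the mode (collaborate iff u < p); a tie among
more than one argmax candidate draws one integer index into the
lexicographically sorted tied cells. No other draws occur.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Any

import numpy as np

from .landscape import (
    NoiseSpec,
    ProblemInstance,
    assign_skills,
    generate_complex_landscape,
    generate_simple_landscape,
)
from .networks import InteractionNetwork, NetworkSpec
from .perception import (
    Agent,
    PerceptionParams,
    Position,
    collaborative_visible_set,
    copy_candidate_set,
)

__all__ = [
    "ModeSchedule",
    "SimulationConfig",
    "PopulationState",
    "Trajectory",
    "initialize",
    "select_mode",
    "update_agent",
    "advance_step",
    "run_simulation",
]

COLLABORATE = "collaborate"
COPY = "copy"


@dataclasses.dataclass(frozen=True)
class ModeSchedule:
    """Either a constant collaboration probability p, or a phase plan
    (collaborate for the first k rounds, copy for the rest of a fixed
    ``total_rounds`` horizon)."""

    kind: str = "constant_p"
    p: float = 0.5
    k: int = 0
    total_rounds: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("constant_p", "phase"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "constant_p" and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.kind == "phase" and not 0 <= self.k <= self.total_rounds:
            raise ValueError(f"k must be in [0, {self.total_rounds}], got {self.k}")

    @classmethod
    def constant(cls, p: float) -> "ModeSchedule":
        return cls(kind="constant_p", p=p)

    @classmethod
    def phased(cls, k: int, total_rounds: int = 10) -> "ModeSchedule":
        return cls(kind="phase", k=k, total_rounds=total_rounds)

    @classmethod
    def from_value(cls, value: "ModeSchedule | dict") -> "ModeSchedule":
        if isinstance(value, ModeSchedule):
            return value
        return cls(**value)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run."""

    n: int = 16
    s: int = 100
    r: float = 6.0
    width: int = 100
    height: int = 100
    landscape_kind: str = "complex"
    network: NetworkSpec = dataclasses.field(default_factory=NetworkSpec)
    schedule: ModeSchedule = dataclasses.field(default_factory=ModeSchedule)
    signal_variance: float = 3.0
    noise_spec: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    max_steps: int = 10_000
    record_positions: bool = False
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size n must be >= 1, got {self.n}")
        if self.s < 1:
            raise ValueError(f"skill count s must be >= 1, got {self.s}")
        if self.r < 0:
            raise ValueError(f"radius r must be >= 0, got {self.r}")
        if self.width < 3 or self.height < 3:
            raise ValueError("grid dimensions must be >= 3")
        if self.landscape_kind not in ("complex", "simple"):
            raise ValueError(f"unknown landscape kind {self.landscape_kind!r}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        object.__setattr__(self, "network", NetworkSpec.from_value(self.network))
        object.__setattr__(self, "schedule", ModeSchedule.from_value(self.schedule))
        if isinstance(self.noise_spec, dict):
            object.__setattr__(self, "noise_spec", NoiseSpec(**self.noise_spec))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        if isinstance(out["seed"], np.random.SeedSequence):
            out["seed"] = out["seed"].entropy
        return out


@dataclasses.dataclass
class PopulationState:
    """Whole-group snapshot: agents, completed-step count, last moved flag."""

    agents: list[Agent]
    step: int = 0
    moved_last_step: bool | None = None

    @property
    def n(self) -> int:
        return len(self.agents)

    def payoffs(self, instance: ProblemInstance) -> np.ndarray:
        vals = instance.payoffs.values
        return np.array([vals[a.position] for a in self.agents])

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.agents], dtype=np.int64)


@dataclasses.dataclass
class Trajectory:
    """Per-step payoff records for one run.

    ``payoffs[t, i]`` is agent i's payoff after t completed steps (row
    0 is the initial state). ``termination_step`` is the number of
    steps executed.
    """

    payoffs: np.ndarray
    termination_step: int
    config: SimulationConfig
    positions: np.ndarray | None = None
    hit_step_cap: bool = False

    @property
    def n_agents(self) -> int:
        return self.payoffs.shape[1]

    @property
    def final_payoffs(self) -> np.ndarray:
        return self.payoffs[-1]

    def padded(self, horizon: int) -> np.ndarray:
        """Payoffs padded with the final row out to ``horizon`` steps
        (shape ``(horizon + 1, n)``), truncated if the run was longer."""
        t = self.payoffs.shape[0]
        if t >= horizon + 1:
            return self.payoffs[: horizon + 1]
        pad = np.repeat(self.payoffs[-1][None, :], horizon + 1 - t, axis=0)
        return np.vstack([self.payoffs, pad])


def _as_seedseq(seed: int | np.random.SeedSequence | None) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def initialize(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[ProblemInstance, InteractionNetwork, PopulationState]:
    """Fresh landscape, skill grid, network, and uniformly random agents."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if config.landscape_kind == "simple":
        payoffs = generate_simple_landscape(config.width, config.height, rng=gen)
    else:
        payoffs = generate_complex_landscape(
            config.width, config.height, config.signal_variance,
            config.noise_spec, rng=gen,
        )
    skills = assign_skills(config.width, config.height, config.s, rng=gen)
    instance = ProblemInstance(payoffs=payoffs, skills=skills)
    net = config.network.build(config.n, rng=gen)
    agent_skills = gen.integers(0, config.s, size=config.n)
    rows = gen.integers(0, config.height, size=config.n)
    cols = gen.integers(0, config.width, size=config.n)
    agents = [
        Agent(id=i, skill=int(agent_skills[i]), position=(int(rows[i]), int(cols[i])))
        for i in range(config.n)
    ]
    return instance, net, PopulationState(agents=agents)


def select_mode(
    schedule: ModeSchedule, step: int, rng: np.random.Generator
) -> str:
    """Mode for one agent update during time step ``step`` (1-based)."""
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if schedule.kind == "phase":
        return COLLABORATE if step <= schedule.k else COPY
    return COLLABORATE if rng.random() < schedule.p else COPY


def update_agent(
    agent: Agent,
    state: PopulationState,
    mode: str,
    instance: ProblemInstance,
    net: InteractionNetwork,
    params: PerceptionParams,
    rng: np.random.Generator,
) -> Position:
    """Best candidate cell if it strictly beats the current payoff, else stay.

    Ties among maxima are broken uniformly at random over the
    lexicographically sorted tied cells.
    """
    neighbor_ids = net.neighbors(agent.id)
    if mode == COLLABORATE:
        nbr_skills = {state.agents[j].skill for j in neighbor_ids}
        candidates = collaborative_visible_set(agent, nbr_skills, instance, params)
    elif mode == COPY:
        nbr_positions = {state.agents[j].position for j in neighbor_ids}
        candidates = copy_candidate_set(agent, nbr_positions, instance, params)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    vals = instance.payoffs.values
    current = vals[agent.position]
    best = current
    best_cells: list[Position] = []
    for cell in candidates:
        v = vals[cell]
        if v > best:
            best = v
            best_cells = [cell]
        elif v == best and v > current:
            best_cells.append(cell)
    if not best_cells:
        return agent.position
    if len(best_cells) == 1:
        return best_cells[0]
    best_cells.sort()
    return best_cells[int(rng.integers(len(best_cells)))]


def advance_step(
    state: PopulationState,
    instance: ProblemInstance,
    net: InteractionNetwork,
    schedule: ModeSchedule,
    params: PerceptionParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, bool]:
    """Run one time step in place: fresh random order, sequential updates."""
    step = state.step + 1
    moved = False
    order = rng.permutation(state.n)
    for idx in order:
        agent = state.agents[int(idx)]
        mode = select_mode(schedule, step, rng)
        new_pos = update_agent(agent, state, mode, instance, net, params, rng)
        if new_pos != agent.position:
            agent.position = new_pos
            moved = True
    state.step = step
    state.moved_last_step = moved
    return state, moved


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one full simulation from a config's master seed.

    Constant-p schedules run until the first step with no movement
    (capped at ``max_steps`` as a safety net, which sets
    ``hit_step_cap``); phase schedules run exactly ``total_rounds``
    steps regardless of movement.
    """
    init_ss, dyn_ss = _as_seedseq(config.seed).spawn(2)
    instance, net, state = initialize(config, np.random.default_rng(init_ss))
    dyn_rng = np.random.default_rng(dyn_ss)
    params = PerceptionParams(r=config.r)
    schedule = config.schedule

    payoff_rows = [state.payoffs(instance)]
    position_rows = [state.positions()] if config.record_positions else None

    hit_cap = False
    if schedule.kind == "phase":
        for _ in range(schedule.total_rounds):
            advance_step(state, instance, net, schedule, params, dyn_rng)
            payoff_rows.append(state.payoffs(instance))
            if position_rows is not None:
                position_rows.append(state.positions())
    else:
        while True:
            _, moved = advance_step(state, instance, net, schedule, params, dyn_rng)
            payoff_rows.append(state.payoffs(instance))
            if position_rows is not None:
                position_rows.append(state.positions())
            if not moved:
                break
            if state.step >= config.max_steps:
                hit_cap = True
                warnings.warn(
                    f"run hit max_steps={config.max_steps} without terminating",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break

    return Trajectory(
        payoffs=np.array(payoff_rows),
        termination_step=state.step,
        config=config,
        positions=np.array(position_rows) if position_rows is not None else None,
        hit_step_cap=hit_cap,
    )
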