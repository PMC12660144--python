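"""Batch runner and named experimental protocols.

Protocols replicate the study designs: per-step payoff time series
under a few communication profiles, collaboration-frequency sweeps on
path vs. complete networks, network-density sweeps at the two extreme
collaboration rates, and collaborate-then-copy phase schedules. Each
condition is replicated over independent runs (fresh landscape,
skills, network, and agents per run) and summarized by the mean and
SEM of the group max/mean/min payoff and Gini coefficient.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import ModeSchedule, SimulationConfig, Trajectory, run_simulation
from .metrics import gini_coefficient
from .networks import NetworkSpec

__all__ = [
    "OutcomeStat",
    "ConditionSummary",
    "Protocol",
    "run_batch",
    "summarize",
    "run_protocol",
    "timeseries_protocol",
    "p_sweep_protocol",
    "density_sweep_protocol",
    "phase_sweep_protocol",
    "make_protocol",
    "write_results",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("max_payoff", "mean_payoff", "min_payoff", "gini")


@dataclasses.dataclass(frozen=True)
class OutcomeStat:
    mean: float
    sem: float


@dataclasses.dataclass(frozen=True)
class ConditionSummary:
    """Mean and SEM of each outcome across runs for one condition."""

    params: dict[str, Any]
    outcomes: dict[str, OutcomeStat]
    n_runs: int


@dataclasses.dataclass(frozen=True)
class Protocol:
    """A named batch design: a base config, a list of condition
    overrides, a replication count, and a master seed."""

    name: str
    base: SimulationConfig
    conditions: list[dict[str, Any]]
    n_runs: int = 1000
    seed: int = 0
    at: str = "final"
    horizon: int | None = None


def run_batch(
    base: SimulationConfig,
    n_runs: int,
    seed: int | np.random.SeedSequence | None = None,
) -> list[Trajectory]:
    """Independent replicated runs from disjoint substreams of one seed."""
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    return [
        run_simulation(dataclasses.replace(base, seed=child)) for child in children
    ]


def _outcome_matrix(payoffs_by_run: np.ndarray) -> dict[str, np.ndarray]:
    """Per-run outcomes from a (runs, n_agents) payoff array."""
    return {
        "max_payoff": payoffs_by_run.max(axis=1),
        "mean_payoff": payoffs_by_run.mean(axis=1),
        "min_payoff": payoffs_by_run.min(axis=1),
        "gini": np.array([gini_coefficient(row) for row in payoffs_by_run]),
    }


def _stats(values: np.ndarray, n_runs: int) -> OutcomeStat:
    sem = float(values.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
    return OutcomeStat(mean=float(values.mean()), sem=sem)


def summarize(
    trajectories: Sequence[Trajectory],
    at: str = "final",
    horizon: int | None = None,
) -> list[ConditionSummary]:
    """Mean and SEM of each outcome across runs.

    ``at="final"`` returns a single summary of final payoffs;
    ``at="per-step"`` returns one summary per step with trajectories
    padded by their final values out to ``horizon`` (default: the
    longest run).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n_runs = len(trajectories)
    if n_runs < 2:
        raise ValueError("SEM requires at least 2 trajectories")
    if at == "final":
        payoffs = np.array([t.final_payoffs for t in trajectories])
        outcomes = {k: _stats(v, n_runs) for k, v in _outcome_matrix(payoffs).items()}
        return [ConditionSummary(params={}, outcomes=outcomes, n_runs=n_runs)]
    if at != "per-step":
        raise ValueError(f"unknown summary mode {at!r}")
    if horizon is None:
        horizon = max(t.payoffs.shape[0] - 1 for t in trajectories)
    padded = np.array([t.padded(horizon) for t in trajectories])  # (runs, h+1, n)
    out = []
    for step in range(horizon + 1):
        outcomes = {
            k: _stats(v, n_runs)
            for k, v in _outcome_matrix(padded[:, step, :]).items()
        }
        out.append(ConditionSummary(params={"step": step}, outcomes=outcomes, n_runs=n_runs))
    return out


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def apply_condition(base: SimulationConfig, condition: dict[str, Any]) -> SimulationConfig:
    """Overlay condition parameters onto a base config.

    Shorthand keys: ``p`` (constant-p schedule), ``k`` (phase
    schedule; optional ``total_rounds``), ``network`` (a kind name, a
    NetworkSpec, or a dict), ``density`` (densified path network).
    Remaining keys must be SimulationConfig fields.
    """
    overrides: dict[str, Any] = {}
    cond = dict(condition)
    if "p" in cond and "k" in cond:
        raise ValueError("condition cannot set both p and k")
    if "p" in cond:
        overrides["schedule"] = ModeSchedule.constant(cond.pop("p"))
    if "k" in cond:
        total = cond.pop("total_rounds", 10)
        overrides["schedule"] = ModeSchedule.phased(cond.pop("k"), total_rounds=total)
    if "density" in cond and "network" not in cond:
        overrides["network"] = NetworkSpec(kind="density", density=cond.pop("density"))
    elif "network" in cond:
        cond.pop("density", None)
        overrides["network"] = NetworkSpec.from_value(cond.pop("network"))
    unknown = set(cond) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown condition keys: {sorted(unknown)}")
    overrides.update(cond)
    return dataclasses.replace(base, **overrides)


def _condition_columns(condition: dict[str, Any]) -> dict[str, Any]:
    cols: dict[str, Any] = {}
    for key, value in condition.items():
        if key == "network":
            spec = NetworkSpec.from_value(value)
            cols["network"] = spec.kind
            if spec.density is not None:
                cols["density"] = spec.density
        else:
            cols[key] = value
    return cols


def run_protocol(protocol: Protocol, progress: bool = False) -> pd.DataFrame:
    """Run every condition of a protocol and return a tidy results table.

    One row per condition (x step for per-step protocols) x outcome,
    with columns for the condition parameters plus ``outcome``,
    ``mean``, ``sem``, and ``n_runs``. Bit-reproducible from
    (protocol, seed): condition seeds are disjoint substreams of the
    protocol seed, so each condition's rows do not depend on which
    other conditions run.
    """
    condition_seeds = np.random.SeedSequence(protocol.seed).spawn(len(protocol.conditions))
    rows: list[dict[str, Any]] = []
    for i, condition in enumerate(protocol.conditions):
        config = apply_condition(protocol.base, condition)
        logger.info("protocol %s: condition %d/%d %s",
                    protocol.name, i + 1, len(protocol.conditions), condition)
        trajectories = run_batch(config, protocol.n_runs, seed=condition_seeds[i])
        summaries = summarize(trajectories, at=protocol.at, horizon=protocol.horizon)
        cols = _condition_columns(condition)
        for summary in summaries:
            for outcome, stat in summary.outcomes.items():
                rows.append({
                    **cols, **summary.params,
                    "outcome": outcome, "mean": stat.mean, "sem": stat.sem,
                    "n_runs": summary.n_runs,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named protocol factories


def _base_config(**overrides: Any) -> SimulationConfig:
    return SimulationConfig(**overrides)


def timeseries_protocol(
    landscape_kind: str = "complex",
    p_values: Iterable[float] = (0.0, 0.1, 0.9, 1.0),
    include_baseline: bool = True,
    horizon: int = 30,
    n_runs: int = 1000,
    seed: int = 0,
) -> Protocol:
    """Per-step payoffs on a complete network across communication
    profiles, plus an individuals-only baseline."""
    conditions: list[dict[str, Any]] = [
        {"p": p, "network": "complete"} for p in p_values
    ]
    if include_baseline:
        conditions.append({"p": 0.5, "network": "edgeless"})
    base = _base_config(landscape_kind=landscape_kind)
    return Protocol(
        name="timeseries", base=base, conditions=conditions,
        n_runs=n_runs, seed=seed, at="per-step", horizon=horizon,
    )


def p_sweep_protocol(
    p_values: Iterable[float] = tuple(np.round(np.linspace(0, 1, 11), 2)),
    networks: Iterable[str] = ("path", "complete"),
    n_runs: int = 1000,
    seed: int = 0,
) -> Protocol:
    """Final outcomes vs. collaboration probability on each network."""
    conditions = [
        {"p": float(p), "network": net} for net in networks for p in p_values
    ]
    return Protocol(
        name="p_sweep", base=_base_config(), conditions=conditions,
        n_runs=n_runs, seed=seed, at="final",
    )


def density_sweep_protocol(
    densities: Iterable[float] = (0.125, 0.25, 0.5, 0.75, 1.0),
    p_values: Iterable[float] = (0.0, 1.0),
    n_runs: int = 1000,
    seed: int = 0,
) -> Protocol:
    """Final outcomes vs. network density (path densified at random)
    when agents only copy or only collaborate."""
    conditions = [
        {"p": float(p), "density": float(d)} for p in p_values for d in densities
    ]
    return Protocol(
        name="density_sweep", base=_base_config(), conditions=conditions,
        n_runs=n_runs, seed=seed, at="final",
    )


def phase_sweep_protocol(
    k_values: Iterable[int] = tuple(range(11)),
    networks: Iterable[str] = ("path", "complete"),
    total_rounds: int = 10,
    n_runs: int = 1000,
    seed: int = 0,
) -> Protocol:
    """Final outcomes when groups collaborate for k rounds then copy
    for the remaining rounds of a fixed horizon."""
    conditions = [
        {"k": int(k), "total_rounds": total_rounds, "network": net}
        for net in networks for k in k_values
    ]
    return Protocol(
        name="phase_sweep", base=_base_config(), conditions=conditions,
        n_runs=n_runs, seed=seed, at="final",
    )


_PROTOCOL_FACTORIES = {
    "timeseries": timeseries_protocol,
    "p_sweep": p_sweep_protocol,
    "density_sweep": density_sweep_protocol,
    "phase_sweep": phase_sweep_protocol,
}


def make_protocol(name: str, **kwargs: Any) -> Protocol:
    if name not in _PROTOCOL_FACTORIES:
        raise ValueError(
            f"unknown protocol {name!r}; one of {sorted(_PROTOCOL_FACTORIES)}"
        )
    return _PROTOCOL_FACTORIES[name](**kwargs)


def write_results(
    df: pd.DataFrame, protocol: Protocol, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the results CSV and a JSON manifest; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{protocol.name}.csv"
    df.to_csv(csv_path, index=False)
    from . import __version__

    manifest = {
        "protocol": protocol.name,
        "n_runs": protocol.n_runs,
        "seed": protocol.seed,
        "at": protocol.at,
        "horizon": protocol.horizon,
        "conditions": protocol.conditions,
        "base_config": protocol.base.to_dict(),
        "version": __version__,
    }
    manifest_path = out_dir / f"{protocol.name}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return csv_path, manifest_path
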