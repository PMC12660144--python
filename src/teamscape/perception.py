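"""Candidate cell sets visible to an agent under each update mode.

Every set contains the agent's current cell and its clipped Moore
neighborhood (Chebyshev distance 1). Skill-matched cells are visible
within Euclidean distance ``r`` between integer cell centers,
inclusive. Collaboration extends the skill match to the neighbors'
labels; copying instead adds the neighbors' occupied cells.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Iterable

import numpy as np

from .landscape import ProblemInstance

__all__ = [
    "Position",
    "Agent",
    "PerceptionParams",
    "individual_visible_set",
    "collaborative_visible_set",
    "copy_candidate_set",
]

Position = tuple[int, int]


@dataclasses.dataclass
class Agent:
    """One searcher: index, skill label, current lattice cell."""

    id: int
    skill: int
    position: Position


@dataclasses.dataclass(frozen=True)
class PerceptionParams:
    """Perception radius ``r`` in cell units (Euclidean, center to center)."""

    r: float = 6.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"radius must be >= 0, got {self.r}")


@lru_cache(maxsize=32)
def _disk_offsets(r: float) -> np.ndarray:
    """All (drow, dcol) offsets with drow^2 + dcol^2 <= r^2, excluding (0, 0)."""
    m = int(np.floor(r))
    if m < 1:
        return np.empty((0, 2), dtype=np.int64)
    d = np.arange(-m, m + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    mask = (dr**2 + dc**2 <= r**2 + 1e-9) & ~((dr == 0) & (dc == 0))
    return np.stack([dr[mask], dc[mask]], axis=1)


def _moore_cells(pos: Position, height: int, width: int) -> set[Position]:
    row, col = pos
    out: set[Position] = set()
    for dr in (-1, 0, 1):
        rr = row + dr
        if not 0 <= rr < height:
            continue
        for dc in (-1, 0, 1):
            cc = col + dc
            if 0 <= cc < width:
                out.add((rr, cc))
    return out


def _skill_matched_cells(
    pos: Position,
    skill_labels: Iterable[int],
    instance: ProblemInstance,
    r: float,
) -> set[Position]:
    offsets = _disk_offsets(r)
    if offsets.shape[0] == 0:
        return set()
    height, width = instance.shape
    rows = offsets[:, 0] + pos[0]
    cols = offsets[:, 1] + pos[1]
    inb = (rows >= 0) & (rows < height) & (cols >= 0) & (cols < width)
    rows = rows[inb]
    cols = cols[inb]
    cell_skills = instance.skills.labels[rows, cols]
    match = np.isin(cell_skills, np.fromiter(skill_labels, dtype=np.int64))
    return set(zip(rows[match].tolist(), cols[match].tolist()))


def _check_in_bounds(pos: Position, instance: ProblemInstance) -> None:
    height, width = instance.shape
    if not (0 <= pos[0] < height and 0 <= pos[1] < width):
        raise ValueError(f"position {pos} out of bounds for grid {instance.shape}")


def individual_visible_set(
    agent: Agent, instance: ProblemInstance, params: PerceptionParams
) -> set[Position]:
    """Current cell, clipped Moore neighborhood, and own-skill cells within r."""
    _check_in_bounds(agent.position, instance)
    height, width = instance.shape
    cells = _moore_cells(agent.position, height, width)
    cells |= _skill_matched_cells(agent.position, (agent.skill,), instance, params.r)
    return cells


def collaborative_visible_set(
    agent: Agent,
    neighbor_skills: Iterable[int],
    instance: ProblemInstance,
    params: PerceptionParams,
) -> set[Position]:
    """Individual set plus cells within r matching any neighbor's skill."""
    _check_in_bounds(agent.position, instance)
    height, width = instance.shape
    skills = {agent.skill} | set(neighbor_skills)
    cells = _moore_cells(agent.position, height, width)
    cells |= _skill_matched_cells(agent.position, skills, instance, params.r)
    return cells


def copy_candidate_set(
    agent: Agent,
    neighbor_positions: Iterable[Position],
    instance: ProblemInstance,
    params: PerceptionParams,
) -> set[Position]:
    """Individual set plus the cells the agent's neighbors occupy."""
    cells = individual_visible_set(agent, instance, params)
    for pos in neighbor_positions:
        _check_in_bounds(pos, instance)
        cells.add((int(pos[0]), int(pos[1])))
    return cells
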