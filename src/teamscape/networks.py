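"""Interaction networks: construction, densification, and density.

Networks are undirected simple graphs on agent indices 0..n-1. The
two reference topologies are the path (linear) network and the
complete network; ``densify`` interpolates between them by adding
uniformly random absent edges to a base network. The edgeless network
models agents working as individuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "InteractionNetwork",
    "path_network",
    "complete_network",
    "edgeless_network",
    "densify",
    "density",
    "NetworkSpec",
    "write_edgelist",
    "read_edgelist",
]


class InteractionNetwork:
    """Undirected simple graph on ``n`` nodes with precomputed adjacency."""

    __slots__ = ("n", "edges", "_adj")

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] = ()):
        if n < 1:
            raise ValueError(f"node count must be >= 1, got {n}")
        norm: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) outside node range [0, {n - 1}]")
            norm.add((min(u, v), max(u, v)))
        self.n = n
        self.edges: frozenset[tuple[int, int]] = frozenset(norm)
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in sorted(norm):
            adj[u].append(v)
            adj[v].append(u)
        self._adj = tuple(tuple(a) for a in adj)

    def neighbors(self, node: int) -> tuple[int, ...]:
        return self._adj[node]

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.n == other.n and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"InteractionNetwork(n={self.n}, edges={self.n_edges})"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionNetwork":
        nodes = sorted(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        return cls(len(nodes), [(index[u], index[v]) for u, v in g.edges])


def path_network(n: int) -> InteractionNetwork:
    """Linear network: node i linked to i+1 only."""
    if n < 2:
        raise ValueError(f"path network needs n >= 2, got {n}")
    return InteractionNetwork(n, [(i, i + 1) for i in range(n - 1)])


def complete_network(n: int) -> InteractionNetwork:
    """Fully connected network: all n(n-1)/2 edges."""
    if n < 2:
        raise ValueError(f"complete network needs n >= 2, got {n}")
    return InteractionNetwork(n, itertools.combinations(range(n), 2))


def edgeless_network(n: int) -> InteractionNetwork:
    """No edges: agents work as individuals, sharing no information."""
    return InteractionNetwork(n, ())


def density(net: InteractionNetwork) -> float:
    """Edge count over the complete graph's edge count on the same nodes."""
    if net.n < 2:
        raise ValueError("density requires n >= 2")
    return net.n_edges / (net.n * (net.n - 1) / 2)


def densify(
    base: InteractionNetwork,
    target_density: float,
    rng: np.random.Generator | int | None = None,
) -> InteractionNetwork:
    """Add uniformly random absent edges until the target density is reached.

    The edge count is ``round(target_density * n(n-1)/2)``; the result
    is a superset of the base's edges.
    """
    if not 0 < target_density <= 1:
        raise ValueError(f"target_density must be in (0, 1], got {target_density}")
    max_edges = base.n * (base.n - 1) // 2
    target_edges = int(round(target_density * max_edges))
    if target_edges < base.n_edges:
        raise ValueError(
            f"target density {target_density} below current density {density(base)}"
        )
    n_add = target_edges - base.n_edges
    if n_add == 0:
        return base
    non_edges = sorted(
        set(itertools.combinations(range(base.n), 2)) - set(base.edges)
    )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    chosen = gen.choice(len(non_edges), size=n_add, replace=False)
    new_edges = set(base.edges) | {non_edges[i] for i in chosen}
    return InteractionNetwork(base.n, new_edges)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network choice used inside a simulation config.

    kind: one of "path", "complete", "edgeless", "density"; the
    "density" kind densifies a path network to ``density`` using the
    run's RNG stream (redrawn per run).
    """

    kind: str = "complete"
    density: float | None = None

    _KINDS = ("path", "complete", "edgeless", "density")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}; one of {self._KINDS}")
        if self.kind == "density":
            if self.density is None or not 0 < self.density <= 1:
                raise ValueError("density kind requires density in (0, 1]")

    def build(
        self, n: int, rng: np.random.Generator | int | None = None
    ) -> InteractionNetwork:
        if self.kind == "path":
            return path_network(n)
        if self.kind == "complete":
            return complete_network(n)
        if self.kind == "edgeless":
            return edgeless_network(n)
        return densify(path_network(n), self.density, rng)

    @classmethod
    def from_value(cls, value: "NetworkSpec | str | dict") -> "NetworkSpec":
        if isinstance(value, NetworkSpec):
            return value
        if isinstance(value, str):
            return cls(kind=value)
        return cls(**value)


def write_edgelist(net: InteractionNetwork, path: str | Path) -> None:
    """One "i j" pair per line; a leading "# n=<n>" comment keeps isolates."""
    lines = [f"# n={net.n}"]
    lines += [f"{u} {v}" for u, v in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path, n: int | None = None) -> InteractionNetwork:
    edges: list[tuple[int, int]] = []
    max_node = -1
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if n is None and "n=" in line:
                n = int(line.split("n=")[1])
            continue
        u, v = map(int, line.split())
        edges.append((u, v))
        max_node = max(max_node, u, v)
    if n is None:
        n = max_node + 1
    return InteractionNetwork(n, edges)
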