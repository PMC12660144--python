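"""Payoff landscapes and skill grids defining a problem instance.

A problem instance pairs a payoff surface over a ``height x width``
cell lattice with a skill label per cell. Complex landscapes are a
narrow bivariate Gaussian signal summed with fractal Perlin noise;
simple landscapes are a single broad Gaussian bump. All payoffs are
min-max normalized to [0, 1].

Coordinates are 0-based ``(row, col)``; cell centers sit at integer
lattice points and boundaries are hard (no wraparound).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._perlin import fractal_noise

__all__ = [
    "NoiseSpec",
    "PayoffGrid",
    "SkillGrid",
    "ProblemInstance",
    "generate_complex_landscape",
    "generate_simple_landscape",
    "assign_skills",
    "count_local_optima",
    "write_payoff_csv",
    "read_payoff_csv",
    "write_skill_csv",
    "read_skill_csv",
]


class DegenerateLandscapeError(ValueError):
    """Raised when a generated surface is constant before normalization."""


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Fractal Perlin noise parameters.

    ``amplitude`` scales the noise relative to the unit-peak Gaussian
    signal; ``base_period`` is the largest feature size in cells.
    """

    octaves: int = 5
    persistence: float = 0.6
    lacunarity: float = 2.0
    base_period: float = 40.0
    amplitude: float = 3.0

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.base_period <= 0 or self.persistence <= 0 or self.lacunarity <= 0:
            raise ValueError("base_period, persistence and lacunarity must be positive")


@dataclasses.dataclass(frozen=True)
class PayoffGrid:
    """Normalized payoff surface on a cell lattice.

    ``values[row, col]`` is the payoff of that cell, in [0, 1] for
    generated grids. ``kind`` tags the construction ("complex",
    "simple", or "custom" for imported data).
    """

    values: np.ndarray
    kind: str = "custom"
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"payoff grid must be a 2-D array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("payoff grid contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class SkillGrid:
    """Integer skill label in [0, s-1] per cell."""

    labels: np.ndarray
    s: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"skill grid must be a 2-D array, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int64)
        if self.s < 1:
            raise ValueError(f"skill count s must be >= 1, got {self.s}")
        if arr.size and (arr.min() < 0 or arr.max() >= self.s):
            raise ValueError(f"skill labels must lie in [0, {self.s - 1}]")
        object.__setattr__(self, "labels", arr)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]


@dataclasses.dataclass(frozen=True)
class ProblemInstance:
    """Paired payoff and skill grids sharing one lattice."""

    payoffs: PayoffGrid
    skills: SkillGrid
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.payoffs.shape != self.skills.labels.shape:
            raise ValueError(
                f"payoff grid {self.payoffs.shape} and skill grid "
                f"{self.skills.labels.shape} dimensions differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.payoffs.shape


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo = raw.min()
    hi = raw.max()
    if hi - lo <= 0:
        raise DegenerateLandscapeError("surface is constant before normalization")
    return (raw - lo) / (hi - lo)


def _gaussian_bump(
    width: int, height: int, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-peak isotropic Gaussian centered on a uniformly random cell."""
    mu_r = int(rng.integers(0, height))
    mu_c = int(rng.integers(0, width))
    rows = np.arange(height, dtype=float)[:, None]
    cols = np.arange(width, dtype=float)[None, :]
    d2 = (rows - mu_r) ** 2 + (cols - mu_c) ** 2
    return np.exp(-d2 / (2.0 * variance))


def generate_complex_landscape(
    width: int = 100,
    height: int = 100,
    signal_variance: float = 3.0,
    noise_spec: NoiseSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> PayoffGrid:
    """Rugged landscape: Gaussian signal plus fractal Perlin noise.

    The signal is a unit-peak bivariate Gaussian with a uniformly
    random mean cell and the given variance; fractal noise scaled by
    ``noise_spec.amplitude`` is added and the sum min-max normalized
    to [0, 1]. With nonzero noise amplitude the surface typically has
    many local optima.
    """
    if width < 3 or height < 3:
        raise ValueError("grid dimensions must be >= 3")
    if signal_variance <= 0:
        raise ValueError("signal_variance must be positive")
    spec = noise_spec if noise_spec is not None else NoiseSpec()
    seed = rng if isinstance(rng, int) else None
    gen = _as_rng(rng)

    signal = _gaussian_bump(width, height, signal_variance, gen)
    raw = signal
    if spec.amplitude > 0:
        raw = raw + spec.amplitude * fractal_noise(
            width, height, spec.base_period, spec.octaves,
            spec.persistence, spec.lacunarity, gen,
        )
    return PayoffGrid(values=_normalize(raw), kind="complex", seed=seed)


def generate_simple_landscape(
    width: int = 100,
    height: int = 100,
    rng: np.random.Generator | int | None = None,
    variance: float | None = None,
) -> PayoffGrid:
    """Unimodal landscape: one broad Gaussian bump, no noise.

    The default variance scales with the grid ((w^2 + h^2) / 16) so
    payoffs never underflow to a flat plateau; the surface is then
    strictly decreasing in Euclidean distance from the peak cell and
    has exactly one local optimum.
    """
    if width < 3 or height < 3:
        raise ValueError("grid dimensions must be >= 3")
    if variance is None:
        variance = (width**2 + height**2) / 16.0
    if variance <= 0:
        raise ValueError("variance must be positive")
    seed = rng if isinstance(rng, int) else None
    gen = _as_rng(rng)
    raw = _gaussian_bump(width, height, variance, gen)
    return PayoffGrid(values=_normalize(raw), kind="simple", seed=seed)


def assign_skills(
    width: int,
    height: int,
    s: int,
    rng: np.random.Generator | int | None = None,
) -> SkillGrid:
    """I.i.d. uniform skill labels in [0, s-1], one per cell."""
    if s < 1:
        raise ValueError(f"skill count s must be >= 1, got {s}")
    gen = _as_rng(rng)
    labels = gen.integers(0, s, size=(height, width))
    return SkillGrid(labels=labels, s=s)


def count_local_optima(grid: PayoffGrid | np.ndarray) -> int:
    """Number of cells with no strictly greater 8-neighbor.

    Weak definition: a cell ties with itself, so a constant grid has
    ``width * height`` optima. Boundary neighborhoods are clipped.
    """
    arr = grid.values if isinstance(grid, PayoffGrid) else np.asarray(grid, dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(
        arr, footprint=footprint, mode="constant", cval=-np.inf
    )
    return int(np.count_nonzero(arr >= neighbor_max))


# ---------------------------------------------------------------------------
# delimited-matrix import/export with JSON metadata sidecar


def write_payoff_csv(grid: PayoffGrid, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, grid.values, delimiter=",", fmt="%.17g")
    meta = {"kind": grid.kind, "seed": grid.seed,
            "width": grid.width, "height": grid.height}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_payoff_csv(path: str | Path) -> PayoffGrid:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    kind, seed = "custom", None
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kind = meta.get("kind", "custom")
        seed = meta.get("seed")
    return PayoffGrid(values=values, kind=kind, seed=seed)


def write_skill_csv(grid: SkillGrid, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, grid.labels, delimiter=",", fmt="%d")
    meta = {"s": grid.s, "width": grid.width, "height": grid.height}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_skill_csv(path: str | Path, s: int | None = None) -> SkillGrid:
    path = Path(path)
    labels = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    if s is None:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            s = json.loads(meta_path.read_text())["s"]
        else:
            s = int(labels.max()) + 1 if labels.size else 1
    return SkillGrid(labels=labels, s=s)
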