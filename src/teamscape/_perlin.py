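"""Vectorized 2-D gradient (Perlin) noise.

Classic lattice-gradient noise: random unit gradients on an integer
lattice, dot products with corner offset vectors, quintic-smoothstep
interpolation. Fractal variant sums octaves with geometrically
decreasing amplitude and increasing frequency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["perlin2d", "fractal_noise"]


def _fade(t: np.ndarray) -> np.ndarray:
    # 6t^5 - 15t^4 + 10t^3: zero first and second derivative at 0 and 1
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin2d(width: int, height: int, period: float, rng: np.random.Generator) -> np.ndarray:
    """Single-octave Perlin noise on a ``height x width`` grid.

    ``period`` is the lattice spacing in cells; features span roughly
    that many cells. Output is in [-1, 1] (not rescaled).
    """
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    ny = int(np.ceil((height - 1) / period)) + 2
    nx = int(np.ceil((width - 1) / period)) + 2
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(ny, nx))
    gy_lat = np.sin(theta)
    gx_lat = np.cos(theta)

    y = np.arange(height, dtype=float)[:, None] / period
    x = np.arange(width, dtype=float)[None, :] / period
    y0 = np.floor(y).astype(int)
    x0 = np.floor(x).astype(int)
    ty = y - y0
    tx = x - x0

    def corner(dy: int, dx: int) -> np.ndarray:
        gy = gy_lat[y0 + dy, x0 + dx]
        gx = gx_lat[y0 + dy, x0 + dx]
        return gx * (tx - dx) + gy * (ty - dy)

    n00 = corner(0, 0)
    n01 = corner(0, 1)
    n10 = corner(1, 0)
    n11 = corner(1, 1)

    u = _fade(tx)
    v = _fade(ty)
    top = n00 * (1.0 - u) + n01 * u
    bot = n10 * (1.0 - u) + n11 * u
    out = top * (1.0 - v) + bot * v
    # dot-product range is [-sqrt(2)/2, sqrt(2)/2]; rescale to ~[-1, 1]
    return out * np.sqrt(2.0)


def fractal_noise(
    width: int,
    height: int,
    base_period: float,
    octaves: int,
    persistence: float,
    lacunarity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of ``octaves`` Perlin octaves, amplitude-normalized to ~[-1, 1]."""
    if octaves < 1:
        raise ValueError(f"octaves must be >= 1, got {octaves}")
    total = np.zeros((height, width))
    amp = 1.0
    period = float(base_period)
    amp_sum = 0.0
    for _ in range(octaves):
        total += amp * perlin2d(width, height, period, rng)
        amp_sum += amp
        amp *= persistence
        period /= lacunarity
    return total / amp_sum
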