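"""Shared test helpers: tiny grids and independent brute-force references."""

from __future__ import annotations

import numpy as np

from fftdock.voxelizer import GridSpec, ScoreGrid


def make_gridspec(edge: int = 2, pitch: float = 1.0) -> GridSpec:
    return GridSpec(pitch=pitch, edge=edge, origin=np.zeros(3))


def random_score_grid(
    g: GridSpec, rng: np.random.Generator, role: str = "receptor", complex_vals: bool = True
) -> ScoreGrid:
    """A random grid supported on the leading edge³ sub-block."""
    n, e = g.fft_size, g.edge
    block = rng.normal(size=(e, e, e))
    if complex_vals:
        block = block + 1j * rng.normal(size=(e, e, e))
    values = np.zeros((n, n, n), dtype=np.complex64)
    values[:e, :e, :e] = block
    return ScoreGrid(spec=g, values=values, role=role)


def in_bounds_translations(edge: int):
    """All signed translations with components in ±(edge − 1)."""
    r = range(-(edge - 1), edge)
    return [(tx, ty, tz) for tx in r for ty in r for tz in r]


def loop_score(rv: np.ndarray, lv: np.ndarray, t: tuple[int, int, int]) -> float:
    """Pure-python triple-loop Re Σ_v conj(R(v))·L(v+t); independent of the package."""
    n = rv.shape[0]
    total = 0.0 + 0.0j
    for x in range(n):
        for y in range(n):
            for z in range(n):
                xx, yy, zz = x + t[0], y + t[1], z + t[2]
                if 0 <= xx < n and 0 <= yy < n and 0 <= zz < n:
                    total += np.conj(complex(rv[x, y, z])) * complex(lv[xx, yy, zz])
    return total.real


def wrapped_index(t: tuple[int, int, int], n: int) -> tuple[int, int, int]:
    """DFT index of a signed translation."""
    return tuple(c % n for c in t)
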