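"""The docking search: FFT cross-correlation, brute-force oracle, ranking.

The docking score of a relative pose (rotation, integer translation t in
voxels) is the conjugated cross-correlation of the packed score grids,

    S(t) = Re Σ_{v ∈ V} conj(R(v)) · L(v + t),

evaluated for all t at once as ``Re IFFT[conj(FFT[R]) ⊙ FFT[L]]``.  Direct
evaluation of the sum costs O(N³) per translation — O(N⁶) for the full
field — while the FFT route costs O(N³ log N); :func:`direct_score` keeps
the direct sum as the testing oracle.

The search itself (:func:`dock`) follows the canonical stage decomposition
of FFT docking codes: initialization (P1), receptor voxelization (P2),
receptor forward FFT (P3), then a loop over all ligand rotations doing
ligand rotation+voxelization (P4), ligand forward FFT (P5), convolution
(P6), inverse FFT (P7) and best-solution identification (P8), and finally
post-processing (P9).  The receptor spectrum is computed once and reused
across every rotation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import fft as _fft

from .rotations import RotationSet, apply_rotation
from .structures import Structure
from .voxelizer import GridSpec, ScoreGrid, determine_grid, voxelize_ligand, voxelize_receptor

__all__ = [
    "DecoyScore",
    "DockingResult",
    "STAGES",
    "forward_fft",
    "inverse_fft",
    "correlate",
    "direct_score",
    "best_per_rotation",
    "top_k_decoys",
    "dock",
]

logger = logging.getLogger(__name__)

#: Stage labels of the canonical FFT-docking process decomposition.
STAGES: tuple[str, ...] = (
    "P1. Initialization",
    "P2. Receptor voxelization",
    "P3. Forward FFT of receptor",
    "P4. Ligand rotation & voxelization",
    "P5. Forward FFT of ligand",
    "P6. Convolution",
    "P7. Inverse FFT",
    "P8. Identifying best solutions",
    "P9. Post processes",
)


@dataclass(frozen=True)
class DecoyScore:
    """One candidate pose: rotation index, voxel translation t, and score S."""

    rotation_index: int
    translation: tuple[int, int, int]
    score: float

    def sort_key(self) -> tuple:
        """Deterministic ranking key: score desc, then rotation, then t lex (z,y,x)."""
        tx, ty, tz = self.translation
        return (-self.score, self.rotation_index, tz, ty, tx)


@dataclass
class DockingResult:
    """Full outcome of a docking run."""

    per_rotation_best: list[DecoyScore]
    top_k: list[DecoyScore]
    grid: GridSpec
    rotations: RotationSet
    pose_count: int
    config_echo: dict[str, Any]
    timings: dict[str, float] | None = None


def _as_cube(values: np.ndarray | ScoreGrid) -> np.ndarray:
    arr = values.values if isinstance(values, ScoreGrid) else np.asarray(values)
    if arr.ndim != 3 or len(set(arr.shape)) != 1:
        raise ValueError(f"expected a cubic 3D array, got shape {arr.shape}")
    return arr


def forward_fft(g: np.ndarray | ScoreGrid) -> np.ndarray:
    """Unnormalized forward DFT of the padded N³ grid (double precision)."""
    return _fft.fftn(_as_cube(g).astype(np.complex128))


def inverse_fft(spectrum: np.ndarray) -> np.ndarray:
    """Inverse DFT; ``inverse_fft(forward_fft(g)) == g`` to fp precision."""
    return _fft.ifftn(_as_cube(spectrum).astype(np.complex128))


def correlate(r: ScoreGrid, l: ScoreGrid) -> np.ndarray:
    """Score field over all translations: ``Re IFFT[conj(FFT[R]) ⊙ FFT[L]]``.

    The returned real N³ array is indexed by the translation t with the
    standard DFT wrap convention (indices above N/2 are negative t).
    Agrees with :func:`direct_score` at every in-bounds translation.
    """
    if r.spec != l.spec:
        raise ValueError("receptor and ligand grids have different GridSpecs")
    return np.real(inverse_fft(np.conj(forward_fft(r)) * forward_fft(l)))


def direct_score(r: ScoreGrid, l: ScoreGrid, t: tuple[int, int, int]) -> float:
    """Brute-force score at one translation: ``Re Σ_v conj(R(v))·L(v+t)``.

    Out-of-grid ligand samples count as zero.  This is the O(N³)-per-
    translation testing oracle; scanning all t with it costs O(N⁶).
    """
    if r.spec != l.spec:
        raise ValueError("receptor and ligand grids have different GridSpecs")
    edge = r.spec.edge
    t = tuple(int(c) for c in t)
    if any(abs(c) > edge - 1 for c in t):
        raise ValueError(f"translation {t} outside bounds ±{edge - 1}")
    n = r.spec.fft_size
    rv = r.values
    lv = l.values
    total = 0.0 + 0.0j
    # overlap of v in [0, n) with v + t in [0, n)
    sl_r, sl_l = [], []
    for c in t:
        lo = max(0, -c)
        hi = min(n, n - c)
        sl_r.append(slice(lo, hi))
        sl_l.append(slice(lo + c, hi + c))
    block_r = rv[tuple(sl_r)].astype(np.complex128)
    block_l = lv[tuple(sl_l)].astype(np.complex128)
    total = np.sum(np.conj(block_r) * block_l)
    return float(total.real)


def _signed_coords(n: int) -> np.ndarray:
    """Signed translation value of each DFT index (wrap convention)."""
    s = np.arange(n)
    return np.where(s <= n // 2, s, s - n)


def best_per_rotation(field: np.ndarray, rotation_index: int = 0) -> DecoyScore:
    """Pick the best-scoring in-bounds translation from an N³ score field.

    Only translations with every component in ±(edge−1) are eligible (the
    wrap-free region guaranteed by the N = 2·edge padding).  Ties are broken
    by the lexicographically smallest signed (tz, ty, tx).
    """
    field = _as_cube(field)
    n = field.shape[0]
    edge = n // 2
    s = _signed_coords(n)
    valid_1d = np.abs(s) <= edge - 1
    valid = valid_1d[:, None, None] & valid_1d[None, :, None] & valid_1d[None, None, :]
    masked = np.where(valid, field, -np.inf)
    best = masked.max()
    idx = np.argwhere(masked == best)
    signed = s[idx]  # (m, 3) signed (tx, ty, tz)
    order = np.lexsort((signed[:, 0], signed[:, 1], signed[:, 2]))
    tx, ty, tz = (int(c) for c in signed[order[0]])
    return DecoyScore(rotation_index=rotation_index, translation=(tx, ty, tz), score=float(best))


def top_k_decoys(decoys: list[DecoyScore], k: int) -> list[DecoyScore]:
    """The k highest-scoring decoys, deterministically ordered."""
    return sorted(decoys, key=DecoyScore.sort_key)[:k]


def pose_structure(
    ligand: Structure, rotations: RotationSet, grid: GridSpec, decoy: DecoyScore
) -> Structure:
    """Realize a decoy as a transformed ligand structure in receptor space.

    The ligand is rotated about its centroid, re-centered at the center of V
    (the placement the ligand grid was built with), then shifted by
    ``−t · pitch``: the score at translation t pairs receptor voxel v with
    ligand voxel v + t, so the ligand content moves the opposite way.
    """
    rotated = apply_rotation(ligand, rotations.matrices[decoy.rotation_index])
    shift = (
        grid.center
        - ligand.centroid
        - np.asarray(decoy.translation, dtype=np.float64) * grid.pitch
    )
    return rotated.with_positions(rotated.positions + shift)


def dock(receptor: Structure, ligand: Structure, config) -> DockingResult:
    """Run the full exhaustive rigid-body docking search.

    ``config`` is a :class:`fftdock.config.RunConfig` (or anything with the
    same attributes).  The receptor grid and its spectrum are built once;
    each of the n_θ rotations then voxelizes the rotated ligand, transforms
    it, convolves against the conjugated receptor spectrum, inverse
    transforms, and records the best translation.  A total of n_θ × N³
    candidate poses are evaluated.  Deterministic for a fixed config.
    """
    timings = {stage: 0.0 for stage in STAGES} if config.profile else None

    def _tick() -> float:
        return time.perf_counter()

    # P1: grid geometry + rotation set
    t0 = _tick()
    params = config.score_params
    grid = determine_grid(receptor, ligand, pitch=config.pitch, margin=config.margin)
    rotations = config.rotation_set()
    center = ligand.centroid
    if timings is not None:
        timings[STAGES[0]] += _tick() - t0

    logger.info(
        "grid: edge %d, FFT size %d, pitch %.3g Å; n_theta %d; pose count %d",
        grid.edge,
        grid.fft_size,
        grid.pitch,
        rotations.n_theta,
        rotations.n_theta * grid.fft_size**3,
    )

    # P2: receptor voxelization
    t0 = _tick()
    r_grid = voxelize_receptor(receptor, grid, params)
    if timings is not None:
        timings[STAGES[1]] += _tick() - t0

    # P3: receptor forward FFT (conjugated once, reused for every rotation)
    t0 = _tick()
    r_spectrum_conj = np.conj(forward_fft(r_grid))
    if timings is not None:
        timings[STAGES[2]] += _tick() - t0

    per_rotation_best: list[DecoyScore] = []
    for ri, rot in enumerate(rotations.matrices):
        # P4: ligand rotation & voxelization
        t0 = _tick()
        rotated = apply_rotation(ligand, rot, center=center)
        try:
            l_grid = voxelize_ligand(rotated, grid, params)
        except Exception as exc:
            raise RuntimeError(f"rotation {ri} (stage P4): {exc}") from exc
        if timings is not None:
            timings[STAGES[3]] += _tick() - t0

        # P5: ligand forward FFT
        t0 = _tick()
        l_spectrum = forward_fft(l_grid)
        if timings is not None:
            timings[STAGES[4]] += _tick() - t0

        # P6: convolution with the conjugated receptor spectrum
        t0 = _tick()
        product = r_spectrum_conj * l_spectrum
        if timings is not None:
            timings[STAGES[5]] += _tick() - t0

        # P7: inverse FFT
        t0 = _tick()
        score_field = np.real(inverse_fft(product))
        if timings is not None:
            timings[STAGES[6]] += _tick() - t0

        # P8: identifying the best solution for this rotation
        t0 = _tick()
        per_rotation_best.append(best_per_rotation(score_field, rotation_index=ri))
        if timings is not None:
            timings[STAGES[7]] += _tick() - t0

    # P9: post processes (ranking, echo)
    t0 = _tick()
    result = DockingResult(
        per_rotation_best=per_rotation_best,
        top_k=top_k_decoys(per_rotation_best, config.top_k),
        grid=grid,
        rotations=rotations,
        pose_count=rotations.n_theta * grid.fft_size**3,
        config_echo=config.to_dict(),
        timings=timings,
    )
    if timings is not None:
        timings[STAGES[8]] += _tick() - t0
    return result
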