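"""Grid geometry and complex-valued score grids (receptor/ligand voxelization).

The scored grid space V is a cube of ``edge³`` voxels; the FFT array is
``N³`` with N = 2·edge, and both score grids are zero outside the leading
``edge³`` sub-block.  That doubling guarantees the circular cross-correlation
computed by the FFT is free of wraparound for all translations with
components in ±(edge−1).

Three score channels are built per body and packed into one complex grid so
the whole score evaluates in a single complex FFT:

* shape — receptor: soft-core/surface-shell scoring (surface voxels get a
  small reward, core voxels a large penalty); ligand: binary occupancy;
* electrostatics — receptor: clamped distance-weighted potential (sign
  flipped so opposite-charge attraction scores positively); ligand:
  cumulative per-voxel charge within each atom's vdW radius;
* desolvation — receptor: per-voxel atom-overlap (burial) count capped at a
  maximum; ligand: shares the binary occupancy channel.

The receptor packs as ``(w_shape·shape + w_desolv·desolv) + i·(w_elec·elec)``
and the ligand as ``occupancy + i·elec``, which makes the real part of the
conjugated correlation equal to the weighted sum of the three single-term
correlations.  The shape term follows the real-valued pairwise
shape-complementarity idea; the electrostatic and desolvation channels are
simplified configurable stand-ins for grid-electrostatics and
receptor-desolvation scoring, not reproductions of any published
parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .structures import Structure

__all__ = [
    "GridSpec",
    "ScoreGrid",
    "ScoreParams",
    "GridOverflowError",
    "determine_grid",
    "voxelize_ligand",
    "voxelize_receptor",
    "electrostatic_field",
    "pack_complex",
]


class GridOverflowError(ValueError):
    """A structure does not fit inside the scored grid space V."""


@dataclass(frozen=True, eq=False)
class GridSpec:
    """Geometry of the scored grid V and its padded FFT array.

    Voxel ``(i, j, k)`` spans the half-open box
    ``[origin + i·pitch, origin + (i+1)·pitch)`` per axis; membership tests
    use the voxel center ``origin + (i + 0.5)·pitch``.
    """

    pitch: float  # Å per voxel
    edge: int  # voxels per side of V (= N/2)
    origin: np.ndarray  # world position of voxel (0,0,0) corner, Å

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.pitch == other.pitch
            and self.edge == other.edge
            and bool(np.all(self.origin == other.origin))
        )

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.edge < 1:
            raise ValueError(f"edge must be >= 1, got {self.edge}")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))

    @property
    def fft_size(self) -> int:
        """FFT array side N = 2 × edge."""
        return 2 * self.edge

    @property
    def center(self) -> np.ndarray:
        """World position of the center of V (Å)."""
        return self.origin + 0.5 * self.edge * self.pitch

    def voxel_centers_1d(self) -> np.ndarray:
        """Voxel-center offsets from origin along one axis, shape (edge,)."""
        return (np.arange(self.edge) + 0.5) * self.pitch


@dataclass(frozen=True, eq=False)
class ScoreGrid:
    """A packed complex score grid over the padded N³ array.

    ``values`` is complex64 (single precision, the reference storage
    precision for grids), nonzero only in the leading ``edge³`` sub-block.
    Ligand grids additionally carry their binary occupancy over V.
    """

    spec: GridSpec
    values: np.ndarray  # (N, N, N) complex64
    role: Literal["receptor", "ligand"]
    occupancy: np.ndarray | None = None  # (edge,)*3 bool, ligand only

    def __post_init__(self) -> None:
        n = self.spec.fft_size
        vals = np.ascontiguousarray(self.values, dtype=np.complex64)
        if vals.shape != (n, n, n):
            raise ValueError(f"values must be shape {(n, n, n)}, got {vals.shape}")
        if not np.all(np.isfinite(vals.view(np.float32))):
            raise ValueError("grid contains non-finite values")
        e = self.spec.edge
        pad = vals.copy()
        pad[:e, :e, :e] = 0
        if np.any(pad != 0):
            raise ValueError("grid has nonzero values outside the V sub-block")
        object.__setattr__(self, "values", vals)
        if self.occupancy is not None:
            occ = np.asarray(self.occupancy)
            if occ.shape != (e, e, e):
                raise ValueError(f"occupancy must be shape {(e, e, e)}, got {occ.shape}")
            object.__setattr__(self, "occupancy", occ.astype(bool))


@dataclass(frozen=True)
class ScoreParams:
    """Score-model constants and term weights.

    All constants are configurable stand-ins; see module docstring.
    """

    surface_value: float = 1.0  # receptor shape reward on the surface shell
    core_value: float = -45.0  # receptor shape penalty inside atoms
    surface_thickness: int = 2  # shell thickness, voxels (Chebyshev dilation)
    elec_clamp: float = 10.0  # per-voxel potential clamp, ±
    desolv_cap: int = 4  # burial-count cap
    w_shape: float = 1.0
    w_elec: float = 1.0
    w_desolv: float = 1.0

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_shape, self.w_elec, self.w_desolv)


def determine_grid(
    receptor: Structure, ligand: Structure, pitch: float, margin: int = 1
) -> GridSpec:
    """Size the scored grid V from the receptor and fix the FFT size N = 2·edge.

    ``edge`` is the smallest integer at least
    ``(largest axis-aligned receptor extent + 2·max radius)/pitch + 2·margin``
    and the origin centers the receptor in V.  Sizing from the receptor alone
    plus the doubling rule is sufficient to keep all reported translations
    wraparound-free.
    """
    if not pitch > 0:
        raise ValueError(f"pitch must be > 0, got {pitch}")
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if len(receptor) == 0 or len(ligand) == 0:  # Structure forbids this, belt & braces
        raise ValueError("empty structure")
    pos = receptor.positions
    extent = float(np.max(pos.max(axis=0) - pos.min(axis=0)))
    max_radius = float(receptor.radii.max())
    edge = max(1, math.ceil((extent + 2.0 * max_radius) / pitch - 1e-9) + 2 * margin)
    center = 0.5 * (pos.max(axis=0) + pos.min(axis=0))
    origin = center - 0.5 * edge * pitch
    return GridSpec(pitch=pitch, edge=edge, origin=origin)


def _local_positions(structure: Structure, g: GridSpec, recenter: bool) -> np.ndarray:
    """Positions relative to the grid origin, optionally centroid-centered in V."""
    pos = structure.positions - g.origin
    if recenter:
        pos = pos + (0.5 * g.edge * g.pitch - (structure.centroid - g.origin))
    return pos


def _check_fit(pos: np.ndarray, radii: np.ndarray, g: GridSpec, label: str) -> None:
    lo = (pos - radii[:, None]).min(axis=0)
    hi = (pos + radii[:, None]).max(axis=0)
    side = g.edge * g.pitch
    if np.any(lo < -1e-9) or np.any(hi > side + 1e-9):
        raise GridOverflowError(
            f"{label} does not fit inside V (edge {g.edge}, pitch {g.pitch} Å): "
            f"atom bounds [{lo.min():.2f}, {hi.max():.2f}] Å vs [0, {side:.2f}] Å; "
            "increase the grid margin or pitch"
        )


def _sphere_accumulate(
    pos: np.ndarray, radii: np.ndarray, weights: np.ndarray | None, g: GridSpec
) -> np.ndarray:
    """Per-voxel sum over atoms whose vdW sphere contains the voxel center.

    With ``weights=None`` counts atoms (burial count); otherwise sums the
    per-atom weights (e.g. charges).  Only the local bounding box of each
    sphere is visited.
    """
    e = g.edge
    out = np.zeros((e, e, e), dtype=np.float64)
    centers = g.voxel_centers_1d()
    for a in range(len(pos)):
        r = radii[a]
        lo = np.maximum(np.floor((pos[a] - r) / g.pitch - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((pos[a] + r) / g.pitch - 0.5).astype(int) + 1, e)
        if np.any(lo >= hi):
            continue
        cx = centers[lo[0] : hi[0]] - pos[a, 0]
        cy = centers[lo[1] : hi[1]] - pos[a, 1]
        cz = centers[lo[2] : hi[2]] - pos[a, 2]
        d2 = cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
        inside = d2 <= r * r + 1e-12
        w = 1.0 if weights is None else weights[a]
        out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += w * inside
    return out


def _occupancy(pos: np.ndarray, radii: np.ndarray, g: GridSpec) -> np.ndarray:
    return _sphere_accumulate(pos, radii, None, g) > 0


def electrostatic_field(structure: Structure, g: GridSpec, clamp: float = 10.0) -> np.ndarray:
    """Cumulative clamped distance-weighted potential over V (real, edge³).

    ``field(v) = Σ_i q_i / max(d(v, atom_i)/pitch, 1)`` with the per-voxel
    total clipped to ``[−clamp, +clamp]``.  Additive over atoms, so the
    accumulation order is irrelevant.  Positions are taken relative to the
    grid origin (no recentring).
    """
    pos = _local_positions(structure, g, recenter=False)
    charges = structure.charges
    centers = g.voxel_centers_1d()
    field = np.zeros((g.edge,) * 3, dtype=np.float64)
    for a in range(len(pos)):
        q = charges[a]
        if q == 0.0:
            continue
        dx = centers - pos[a, 0]
        dy = centers - pos[a, 1]
        dz = centers - pos[a, 2]
        d = np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        field += q / np.maximum(d / g.pitch, 1.0)
    return np.clip(field, -clamp, clamp)


def pack_complex(
    shape: np.ndarray,
    elec: np.ndarray,
    desolv: np.ndarray,
    weights: tuple[float, float, float],
    g: GridSpec,
    role: Literal["receptor", "ligand"] = "receptor",
    occupancy: np.ndarray | None = None,
) -> ScoreGrid:
    """Pack three real edge³ score channels into one padded complex N³ grid.

    Receptor: ``R = (w_shape·shape + w_desolv·desolv) + i·(w_elec·elec)``.
    Ligand:   ``L = shape + i·elec`` (the weights live on the receptor side
    so each product term carries its weight exactly once; the ligand
    desolvation channel is its occupancy, i.e. the shape channel itself).

    With the conjugated correlation ``Re Σ_v conj(R(v))·L(v+t)`` this packing
    yields ``w_shape·S_shape + w_desolv·S_desolv + w_elec·S_elec``.
    """
    e = g.edge
    for name, arr in (("shape", shape), ("elec", elec), ("desolv", desolv)):
        if np.asarray(arr).shape != (e, e, e):
            raise ValueError(f"{name} grid has shape {np.asarray(arr).shape}, expected {(e, e, e)}")
    w_shape, w_elec, w_desolv = weights
    if role == "receptor":
        real = w_shape * np.asarray(shape, dtype=np.float64) + w_desolv * np.asarray(
            desolv, dtype=np.float64
        )
        imag = w_elec * np.asarray(elec, dtype=np.float64)
    else:
        real = np.asarray(shape, dtype=np.float64)
        imag = np.asarray(elec, dtype=np.float64)
    n = g.fft_size
    values = np.zeros((n, n, n), dtype=np.complex64)
    values[:e, :e, :e] = real + 1j * imag
    return ScoreGrid(spec=g, values=values, role=role, occupancy=occupancy)


def voxelize_ligand(structure: Structure, g: GridSpec, params: ScoreParams) -> ScoreGrid:
    """Build the ligand score grid L (process P4).

    The ligand is recentered so its centroid sits at the center of V (it must
    then fit entirely inside V, else :class:`GridOverflowError`).  The shape
    channel is the binary occupancy — 1 iff the voxel center lies within the
    vdW radius of at least one atom; the electrostatic channel accumulates
    atom charges over the same spheres; the desolvation channel is the
    occupancy itself.
    """
    pos = _local_positions(structure, g, recenter=True)
    radii = structure.radii
    _check_fit(pos, radii, g, f"ligand {structure.id!r}")
    occ = _occupancy(pos, radii, g)
    elec = _sphere_accumulate(pos, radii, structure.charges, g)
    shape = occ.astype(np.float64)
    return pack_complex(shape, elec, shape, params.weights, g, role="ligand", occupancy=occ)


def voxelize_receptor(structure: Structure, g: GridSpec, params: ScoreParams) -> ScoreGrid:
    """Build the receptor score grid R (process P2).

    Shape channel: ``core_value`` inside any atom's vdW sphere,
    ``surface_value`` on the unoccupied shell within ``surface_thickness``
    voxels (Chebyshev) of an occupied voxel, 0 elsewhere.  Electrostatic
    channel: negated clamped potential (attraction scores positively).
    Desolvation channel: atom-overlap count capped at ``desolv_cap``.
    """
    pos = _local_positions(structure, g, recenter=False)
    radii = structure.radii
    _check_fit(pos, radii, g, f"receptor {structure.id!r}")
    counts = _sphere_accumulate(pos, radii, None, g)
    occ = counts > 0
    if params.surface_thickness > 0:
        dilated = ndimage.binary_dilation(
            occ, structure=np.ones((3, 3, 3), dtype=bool), iterations=params.surface_thickness
        )
        shell = dilated & ~occ
    else:
        shell = np.zeros_like(occ)
    shape = params.core_value * occ + params.surface_value * shell
    elec = -electrostatic_field(structure, g, clamp=params.elec_clamp)
    desolv = np.minimum(counts, params.desolv_cap)
    return pack_complex(shape, elec, desolv, params.weights, g, role="receptor")
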