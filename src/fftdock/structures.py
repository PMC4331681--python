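"""Rigid protein structures: PDB I/O, parameterization, and synthetic fixtures.

A :class:`Structure` is an ordered list of :class:`Atom` records carrying the
three per-atom quantities the docking grids need: a position (Å), a van der
Waals radius (Å), and a point charge (elementary charge units).  Structures
are treated as rigid bodies throughout — no protonation, repair, or any other
preparation happens here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "StructureError",
    "EmptyStructureError",
    "PDBParseError",
    "ParameterizationError",
    "DEFAULT_VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_pdb",
    "write_pdb",
    "assign_parameters",
    "make_synthetic_structure",
    "make_complementary_pair",
]

#: Per-element van der Waals radii (Å).  Standard Bondi-style values; the
#: choice is configurable via :func:`assign_parameters`.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "H": 1.2,
    "P": 1.8,
}

#: Fallback radius (Å) for elements not in the table (carbon-like).
DEFAULT_VDW_RADIUS: float = 1.7


class StructureError(ValueError):
    """Base class for structure-related errors."""


class EmptyStructureError(StructureError):
    """Raised when a structure contains no usable atoms."""


class PDBParseError(StructureError):
    """Raised when a PDB file cannot be parsed into atoms."""


class ParameterizationError(StructureError):
    """Raised when atoms cannot be resolved in a parameter table."""


@dataclass(frozen=True, eq=False)
class Atom:
    """One pseudo-atom of a rigid body.

    Parameters
    ----------
    name
        Atom label (e.g. ``"CA"``).
    residue_id
        Residue label, e.g. ``"GLY1"``.
    position
        Cartesian coordinates in Å, shape ``(3,)``.
    vdw_radius
        van der Waals radius in Å; must be positive.
    charge
        Point charge in elementary charge units.
    element
        Element symbol, used for default radius lookup and PDB output.
    """

    name: str
    residue_id: str
    position: np.ndarray
    vdw_radius: float
    charge: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=np.float64)
        if pos.shape != (3,):
            raise StructureError(f"atom position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name!r} has non-finite position {pos}")
        if not (math.isfinite(self.vdw_radius) and self.vdw_radius > 0):
            raise StructureError(f"atom {self.name!r} has invalid vdW radius {self.vdw_radius}")
        if not math.isfinite(self.charge):
            raise StructureError(f"atom {self.name!r} has non-finite charge")
        object.__setattr__(self, "position", pos)


@dataclass(eq=False)
class Structure:
    """An ordered rigid collection of atoms."""

    id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        self.atoms = list(self.atoms)
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} contains no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """Atom coordinates as an ``(n, 3)`` float64 array (Å)."""
        return np.array([a.position for a in self.atoms], dtype=np.float64)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=np.float64)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=np.float64)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of atom positions (Å)."""
        return self.positions.mean(axis=0)

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Return a copy with atom positions replaced (same order, same count)."""
        positions = np.asarray(positions, dtype=np.float64)
        if positions.shape != (len(self.atoms), 3):
            raise StructureError(
                f"expected positions of shape ({len(self.atoms)}, 3), got {positions.shape}"
            )
        atoms = [replace(a, position=p) for a, p in zip(self.atoms, positions)]
        return Structure(id=self.id, atoms=atoms)


def read_pdb(
    path: str | Path,
    *,
    heavy_only: bool = True,
    include_hetero: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL of a multi-model file is used (rigid-body docking
    takes one conformer) and alternate locations are resolved to the first
    conformer (lowest altloc identifier).  Default per-element vdW radii are
    assigned; charges are initialised to 0 (use :func:`assign_parameters`).

    Parameters
    ----------
    heavy_only
        Skip hydrogen/deuterium atoms (default).  The voxelizer only needs
        heavy-atom shape at typical grid pitches.
    include_hetero
        Include HETATM residues (waters, ligands).  Off by default.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    sid = structure_id if structure_id is not None else path.stem
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        models = list(parser.get_structure(sid, str(path)).get_models())
    except PDBConstructionException as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if not models:
        raise EmptyStructureError(f"{path}: no models found")
    model = models[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if not include_hetero and residue.id[0].strip():
                continue
            res_label = f"{residue.get_resname().strip()}{residue.id[1]}"
            for bio_atom in residue:
                if bio_atom.is_disordered():
                    # first conformer = lowest altloc id
                    first = sorted(bio_atom.child_dict)[0]
                    bio_atom = bio_atom.child_dict[first]
                element = (bio_atom.element or "").strip().upper()
                if heavy_only and element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        residue_id=res_label,
                        position=np.asarray(bio_atom.coord, dtype=np.float64),
                        vdw_radius=DEFAULT_VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                        charge=0.0,
                        element=element,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records usable as atoms")
    return Structure(id=sid, atoms=atoms)


_RESID_RE = re.compile(r"^([A-Za-z]*)(\d*)$")


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as fixed-column PDB ATOM records.

    Coordinates are written at PDB precision (1e-3 Å), which bounds the
    read/write roundtrip error.
    """
    path = Path(path)
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        m = _RESID_RE.match(atom.residue_id)
        resname = (m.group(1) if m and m.group(1) else "UNK")[:3].upper()
        resseq = int(m.group(2)) if m and m.group(2) else i
        element = (atom.element or atom.name[:1]).upper()[:2]
        name = atom.name[:4]
        # short names start in column 14 by convention
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = atom.position
        lines.append(
            f"ATOM  {i:5d} {name_field:<4s} {resname:<3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def assign_parameters(
    structure: Structure,
    table: Mapping[str, tuple[float, float]],
    *,
    use_defaults: bool = True,
) -> Structure:
    """Populate vdW radii and charges from a lookup table.

    Each table key is tried in order: the atom name (``"CA"``), then
    ``"residue:atom"`` (``"GLY1:CA"``), then the element symbol.  With
    ``use_defaults`` the per-element radius table (charge 0) backs unresolved
    atoms; without it unresolved atoms raise :class:`ParameterizationError`
    listing every offender.  Positions are never touched, and the operation
    is idempotent for a fixed table.
    """
    new_atoms: list[Atom] = []
    offenders: list[str] = []
    for atom in structure.atoms:
        entry = None
        for key in (atom.name, f"{atom.residue_id}:{atom.name}", atom.element):
            if key and key in table:
                entry = table[key]
                break
        if entry is not None:
            radius, charge = float(entry[0]), float(entry[1])
        elif use_defaults:
            radius = DEFAULT_VDW_RADII.get(atom.element.upper(), DEFAULT_VDW_RADIUS)
            charge = 0.0
        else:
            offenders.append(atom.name)
            continue
        new_atoms.append(replace(atom, vdw_radius=radius, charge=charge))
    if offenders:
        raise ParameterizationError(
            "no parameters for atoms (and defaults disabled): " + ", ".join(offenders)
        )
    return Structure(id=structure.id, atoms=new_atoms)


def make_synthetic_structure(n_atoms: int, extent: float, seed: int) -> Structure:
    """Generate a deterministic random rigid body for tests and demos.

    Atoms are placed uniformly in the cube ``[0, extent]³`` with radii drawn
    uniformly from [1.0, 2.0] Å and charges from [−1, 1] e.  Output is
    bit-identical for a fixed ``(n_atoms, extent, seed)``.
    """
    if n_atoms < 1:
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    if not extent > 0:
        raise ValueError(f"extent must be > 0, got {extent}")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, extent, size=(n_atoms, 3))
    radii = rng.uniform(1.0, 2.0, size=n_atoms)
    charges = rng.uniform(-1.0, 1.0, size=n_atoms)
    atoms = [
        Atom(
            name=f"X{i + 1}",
            residue_id=f"SYN{i + 1}",
            position=positions[i],
            vdw_radius=float(radii[i]),
            charge=float(charges[i]),
            element="C",
        )
        for i in range(n_atoms)
    ]
    return Structure(id=f"synthetic-{n_atoms}-{seed}", atoms=atoms)


def _body(sid: str, coords: Sequence[tuple[float, float, float]], radius: float) -> Structure:
    atoms = [
        Atom(
            name=f"X{i + 1}",
            residue_id=f"SYN{i + 1}",
            position=np.array(c, dtype=np.float64),
            vdw_radius=radius,
            charge=0.0,
            element="C",
        )
        for i, c in enumerate(coords)
    ]
    return Structure(id=sid, atoms=atoms)


def make_complementary_pair() -> tuple[Structure, Structure]:
    """Build a small shape-complementary receptor/ligand pair.

    The receptor is a flat 3×3 plate of atoms with an L-shaped notch left
    open on one face (the pocket); the ligand is the matching 3-atom
    L-shaped plug.  Both bodies use 1.0 Å radii and zero charges, and the
    receptor fits an FFT grid of edge ≤ 8 at 1.0 Å pitch, so exhaustive
    brute-force pose enumeration stays cheap.  With shape-only score
    weights the globally best pose seats the plug in the notch.
    """
    # base plate at z=0, 3x3 at 2 Å spacing; second layer at z=2 with an
    # L-shaped hole at (0,0), (2,0), (0,2)
    plate = [(x, y, 0.0) for x in (0.0, 2.0, 4.0) for y in (0.0, 2.0, 4.0)]
    layer = [
        (x, y, 2.0)
        for x in (0.0, 2.0, 4.0)
        for y in (0.0, 2.0, 4.0)
        if (x, y) not in ((0.0, 0.0), (2.0, 0.0), (0.0, 2.0))
    ]
    receptor = _body("pocket-receptor", plate + layer, radius=1.0)
    # the plug is self-symmetric under the in-plane arm swap, so the two
    # seated rotations produce bit-identical grids and the deterministic
    # rotation-index tie-break resolves them the same way in the FFT path
    # and in brute-force enumeration; the seated score is well separated
    # from every geometrically distinct pose
    ligand = _body("plug-ligand", [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0), (0.0, 2.0, 0.0)], radius=1.0)
    return receptor, ligand
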