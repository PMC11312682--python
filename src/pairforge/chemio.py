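"""Molecular data model, XYZ/Tinker-XYZ I/O, vdW volumes, bundled fixtures.

The in-memory model is deliberately small: a :class:`Molecule` is an ordered
list of :class:`AtomRecord` plus a 0-based bond list. Tinker-XYZ files use
1-based indices; the conversion happens at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from ._elements import (
    COVALENT_RADIUS,
    MASS,
    VABC_AROMATIC_RING_TERM,
    VABC_BOND_TERM,
    VABC_CONTRIB,
    VABC_NONAROMATIC_RING_TERM,
    VDW_RADIUS,
)

__all__ = [
    "AtomRecord",
    "Molecule",
    "TrajectoryFrame",
    "XYZParseError",
    "read_xyz",
    "read_tinker_xyz",
    "write_xyz",
    "write_tinker_xyz",
    "infer_bonds",
    "vabc_volume",
    "molecule_center",
    "fixture",
    "FIXTURE_NAMES",
]


class XYZParseError(ValueError):
    """Raised when an XYZ or Tinker-XYZ file violates its format contract."""


@dataclass
class AtomRecord:
    """One atom: element, position (Å) and optional force-field attributes.

    ``charge`` is a partial charge in elementary-charge units, ``vdw_radius``
    a Bondi-type radius in Å, ``mass`` in amu. ``sigma``/``epsilon`` (or
    ``r_min``/``epsilon``) hold per-atom vdW parameters once assigned.
    """

    element: str
    coords: np.ndarray
    atom_type: str | None = None
    charge: float | None = None
    vdw_radius: float | None = None
    mass: float | None = None
    sigma: float | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"coords must be a finite 3-vector, got {self.coords!r}")
        if self.element not in MASS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive when set")
        if self.mass is None:
            self.mass = MASS[self.element]
        if self.vdw_radius is None:
            self.vdw_radius = VDW_RADIUS.get(self.element)


@dataclass
class Molecule:
    """An ordered collection of atoms with an optional bond graph.

    Bonds are 0-based unordered index pairs. ``metadata`` carries provenance
    (source file, SMILES for fixtures, parameter backend used).
    """

    name: str
    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    vdw_volume: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("a Molecule needs at least one atom")
        n = len(self.atoms)
        norm: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) out of range for {n} atoms")
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                norm.append(key)
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.coords for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        if any(a.charge is None for a in self.atoms):
            raise ValueError(f"molecule {self.name!r} has unassigned charges")
        return np.array([a.charge for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of the molecule with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Molecule(self.name, atoms, list(self.bonds), self.vdw_volume,
                        dict(self.metadata))


@dataclass
class TrajectoryFrame:
    """One recorded MD frame: wrapped positions plus molecule ownership."""

    step: int
    box_edge: float
    positions: np.ndarray
    molecule_index: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if len(self.positions) != len(self.molecule_index):
            raise ValueError("positions and molecule_index length mismatch")


# ---------------------------------------------------------------------------
# XYZ dialects


def _normalize_element(token: str) -> str:
    sym = token.strip()
    # tolerate Tinker-style type suffixes ("O2", "HO") by taking the symbol part
    head = sym[:2].capitalize()
    if head in MASS and len(sym) >= 2 and sym[1].isalpha():
        return head
    head = sym[0].upper()
    if head in MASS:
        return head
    raise XYZParseError(f"unknown element symbol {token!r}")


def read_xyz(path: str | Path) -> Molecule:
    """Read a plain XYZ file (count line, comment, ``element x y z`` rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZParseError(f"{path}:1: malformed atom count line") from exc
    if len(lines) < n + 2:
        raise XYZParseError(
            f"{path}: count line says {n} atoms but only {max(len(lines) - 2, 0)} rows follow")
    atoms = []
    for k in range(n):
        row = lines[2 + k].split()
        if len(row) < 4:
            raise XYZParseError(f"{path}:{3 + k}: expected 'element x y z'")
        elem = _normalize_element(row[0])
        try:
            xyz = [float(v) for v in row[1:4]]
        except ValueError as exc:
            raise XYZParseError(f"{path}:{3 + k}: bad coordinate") from exc
        atoms.append(AtomRecord(elem, np.array(xyz)))
    name = lines[1].strip() or path.stem
    return Molecule(name=name, atoms=atoms, metadata={"source": str(path)})


def read_tinker_xyz(path: str | Path) -> Molecule:
    """Read a Tinker-XYZ (.txyz) file with atom types and connectivity.

    Rows are ``index element x y z type bonded-indices...`` with 1-based
    indices. Non-reciprocal bond listings are symmetrized with a warning.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except ValueError as exc:
        raise XYZParseError(f"{path}:1: malformed atom count line") from exc
    if len(lines) < n + 1:
        raise XYZParseError(f"{path}: count line says {n} atoms but "
                            f"{len(lines) - 1} rows follow")
    atoms: list[AtomRecord] = []
    adjacency: list[set[int]] = []
    for k in range(n):
        row = lines[1 + k].split()
        if len(row) < 6:
            raise XYZParseError(f"{path}:{2 + k}: expected "
                                "'index element x y z type [bonds...]'")
        elem = _normalize_element(row[1])
        xyz = [float(v) for v in row[2:5]]
        atoms.append(AtomRecord(elem, np.array(xyz), atom_type=row[5]))
        nbrs = set()
        for tok in row[6:]:
            j = int(tok)
            if not (1 <= j <= n):
                raise XYZParseError(
                    f"{path}:{2 + k}: bond to atom {j} out of range 1..{n}")
            nbrs.add(j - 1)
        adjacency.append(nbrs)
    bonds: set[tuple[int, int]] = set()
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            if i not in adjacency[j]:
                warnings.warn(
                    f"{path}: bond {i + 1}-{j + 1} listed only once; symmetrized",
                    stacklevel=2)
            bonds.add((min(i, j), max(i, j)))
    name = " ".join(head[1:]) or path.stem
    return Molecule(name=name, atoms=atoms, bonds=sorted(bonds),
                    metadata={"source": str(path)})


def write_xyz(mol_or_frames: Molecule | Sequence[tuple[np.ndarray, Sequence[str]]],
              path: str | Path, comment: str = "") -> None:
    """Write plain XYZ; multi-frame input produces one block per frame.

    Frames are ``(coords, elements)`` tuples with coordinates in Å.
    """
    path = Path(path)
    if isinstance(mol_or_frames, Molecule):
        frames: Iterable[tuple[np.ndarray, Sequence[str]]] = [
            (mol_or_frames.coords, mol_or_frames.elements)]
        comment = comment or mol_or_frames.name
    else:
        frames = mol_or_frames
    out = []
    for coords, elements in frames:
        coords = np.asarray(coords, dtype=float)
        out.append(f"{len(elements)}")
        out.append(comment)
        for el, c in zip(elements, coords):
            out.append(f"{el:<3s} {c[0]:15.8f} {c[1]:15.8f} {c[2]:15.8f}")
    path.write_text("\n".join(out) + "\n")


def write_tinker_xyz(mol: Molecule, path: str | Path) -> None:
    """Write a Tinker-XYZ file (1-based indices, type column, bond lists)."""
    path = Path(path)
    adjacency: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for a, b in mol.bonds:
        adjacency[a].append(b)
        adjacency[b].append(a)
    lines = [f"{mol.n_atoms:>6d}  {mol.name}"]
    for i, atom in enumerate(mol.atoms):
        t = atom.atom_type or atom.element
        c = atom.coords
        nbrs = " ".join(f"{j + 1:>5d}" for j in sorted(adjacency[i]))
        lines.append(f"{i + 1:>6d}  {atom.element:<3s}"
                     f"{c[0]:14.8f}{c[1]:14.8f}{c[2]:14.8f}  {t:<6s} {nbrs}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry helpers


def infer_bonds(mol: Molecule, scale: float = 1.3) -> list[tuple[int, int]]:
    """Distance-rule bond inference: r < scale * (covalent radius sum)."""
    coords = mol.coords
    radii = np.array([COVALENT_RADIUS[e] for e in mol.elements])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = scale * (radii[:, None] + radii[None, :])
    bonds = []
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cut[i, j]:
                bonds.append((i, j))
    return bonds


def molecule_center(mol: Molecule,
                    mode: Literal["geometric", "mass"] = "geometric") -> np.ndarray:
    """Center of the molecule, Å.

    ``geometric`` (default) is the unweighted mean of atom positions — the
    convention under which the reference acetic-acid dimer separation of
    4.91 Å is reproduced. ``mass`` gives the center of mass.
    """
    coords = mol.coords
    if mode == "geometric":
        return coords.mean(axis=0)
    if mode == "mass":
        m = mol.masses
        return m @ coords / m.sum()
    raise ValueError(f"unknown center mode {mode!r}")


def _count_rings(n_atoms: int, bonds: Sequence[tuple[int, int]]) -> int:
    """Cycle-space dimension of the bond graph: bonds − atoms + components."""
    parent = list(range(n_atoms))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in bonds:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    components = len({find(i) for i in range(n_atoms)})
    return len(bonds) - n_atoms + components


def vabc_volume(mol: Molecule, n_aromatic_rings: int = 0) -> float:
    """Additive van der Waals volume (Å³).

    Sums published per-element contributions and subtracts 5.92 Å³ per bond,
    14.7 Å³ per aromatic ring and 3.8 Å³ per non-aromatic ring. Ring count
    comes from the bond graph; bonds are inferred by the covalent-distance
    rule if the molecule carries none. Bundled fixtures have no aromatic
    rings, so ``n_aromatic_rings`` defaults to 0.
    """
    missing = sorted({e for e in mol.elements if e not in VABC_CONTRIB})
    if missing:
        raise ValueError(
            f"no vdW volume contribution for element(s): {', '.join(missing)}")
    bonds = mol.bonds if mol.bonds or mol.n_atoms == 1 else infer_bonds(mol)
    rings = _count_rings(mol.n_atoms, bonds)
    n_nonaromatic = max(rings - n_aromatic_rings, 0)
    return (sum(VABC_CONTRIB[e] for e in mol.elements)
            - VABC_BOND_TERM * len(bonds)
            - VABC_AROMATIC_RING_TERM * n_aromatic_rings
            - VABC_NONAROMATIC_RING_TERM * n_nonaromatic)


# ---------------------------------------------------------------------------
# Bundled fixtures

#: name -> (SMILES, .txyz resource). SMILES carries bond orders for the
#: MMFF94 backend; geometries in the .txyz files are MMFF94-optimized.
_FIXTURES: dict[str, tuple[str, str]] = {
    "H2O": ("O", "h2o.txyz"),
    "Me": ("C", "me.txyz"),
    "Et": ("CC", "et.txyz"),
    "MeOH": ("CO", "meoh.txyz"),
    "EtOH": ("CCO", "etoh.txyz"),
    "Me2O": ("COC", "me2o.txyz"),
    "HAc": ("CC(=O)O", "hac.txyz"),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture(name: str) -> Molecule:
    """Return a bundled monomer with geometry, bonds, types and SMILES.

    Available: H2O, Me (methane), Et (ethane), MeOH, EtOH, Me2O
    (dimethyl ether), HAc (acetic acid).
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")
    smiles, resource_name = _FIXTURES[name]
    ref = resources.files("pairforge").joinpath("data", "fixtures", resource_name)
    with resources.as_file(ref) as p:
        mol = read_tinker_xyz(p)
    mol.name = name
    mol.metadata["smiles"] = smiles
    mol.metadata["fixture"] = name
    return mol
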