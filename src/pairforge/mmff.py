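"""MMFF94 backend: typing, charges, pair parameters, all-atom minimization.

This module satisfies two backend contracts with a single provider (RDKit's
MMFF94 implementation): parameter assignment (per-atom charges and vdW
parameters for a molecule) and unconstrained all-atom local optimization of a
dimer with the full force field.

The intermolecular MMFF94 energy decomposes exactly into buffered 14-7 vdW
terms with pair-specific (R*_ij, ε_ij) — including the donor/acceptor
scaling MMFF94 applies to some pairs — plus buffered Coulomb terms
332.0716·q_iq_j/(r + 0.05). :func:`mmff_pair_potential` extracts those pair
parameters so that rigid-body sampling can evaluate millions of
configurations vectorized while remaining numerically identical to the
force field's own interfragment energy.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDetermineBonds
from rdkit.Geometry import Point3D

from .chemio import Molecule
from .constants import MMFF_COULOMB_BUFFER, MMFF_COULOMB_CONSTANT
from .energy import PairPotential

__all__ = [
    "to_rdkit",
    "assign_mmff_parameters",
    "mmff_pair_potential",
    "optimize_monomer",
    "optimize_dimer",
    "monomer_energy",
]

_SIXTH_ROOT_OF_TWO = 2.0 ** (1.0 / 6.0)


def to_rdkit(mol: Molecule, charge: int | None = None) -> Chem.Mol:
    """Build a sanitized RDKit molecule with the same atom order.

    Bond orders are perceived from the 3D geometry; the net formal charge
    defaults to ``mol.metadata['formal_charge']`` or 0.
    """
    if charge is None:
        charge = int(mol.metadata.get("formal_charge", 0))
    rw = Chem.RWMol()
    conf = Chem.Conformer(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        rw.AddAtom(Chem.Atom(atom.element))
        conf.SetAtomPosition(i, Point3D(*atom.coords))
    rd = rw.GetMol()
    rd.AddConformer(conf)
    try:
        rdDetermineBonds.DetermineBonds(rd, charge=charge)
    except ValueError as exc:
        raise ValueError(
            f"could not perceive bonds for {mol.name!r}: {exc}") from exc
    Chem.SanitizeMol(rd)
    return rd


def _properties(rd: Chem.Mol, variant: str):
    props = AllChem.MMFFGetMoleculeProperties(rd, mmffVariant=variant)
    if props is None:
        raise ValueError("MMFF94 could not type the molecule")
    return props


def assign_mmff_parameters(mol: Molecule, variant: str = "MMFF94") -> Molecule:
    """Copy of ``mol`` with MMFF94 charges, types and homonuclear vdW minima.

    ``sigma`` is stored as R*_ii/2^(1/6) so the generic LJ model can also
    consume MMFF-derived parameters.
    """
    rd = to_rdkit(mol)
    props = _properties(rd, variant)
    atoms = []
    for i, a in enumerate(mol.atoms):
        rstar, eps = props.GetMMFFVdWParams(i, i)[2:4]
        atoms.append(replace(
            a,
            charge=props.GetMMFFPartialCharge(i),
            atom_type=str(props.GetMMFFAtomType(i)),
            sigma=rstar / _SIXTH_ROOT_OF_TWO,
            epsilon=eps,
        ))
    out = Molecule(mol.name, atoms, list(mol.bonds) or
                   [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rd.GetBonds()],
                   mol.vdw_volume, dict(mol.metadata))
    out.metadata["parameter_backend"] = f"rdkit-{variant}"
    return out


def mmff_pair_potential(mol_i: Molecule, mol_j: Molecule,
                        variant: str = "MMFF94") -> PairPotential:
    """Exact MMFF94 intermolecular pair parameters for one monomer pair."""
    rd_i, rd_j = to_rdkit(mol_i), to_rdkit(mol_j)
    combined = Chem.CombineMols(rd_i, rd_j)
    Chem.SanitizeMol(combined)
    props = _properties(combined, variant)
    ni, nj = mol_i.n_atoms, mol_j.n_atoms
    rstar = np.empty((ni, nj))
    eps = np.empty((ni, nj))
    for a in range(ni):
        for b in range(nj):
            rstar[a, b], eps[a, b] = props.GetMMFFVdWParams(a, ni + b)[2:4]
    q_i = np.array([props.GetMMFFPartialCharge(a) for a in range(ni)])
    q_j = np.array([props.GetMMFFPartialCharge(ni + b) for b in range(nj)])
    qq = MMFF_COULOMB_CONSTANT * np.outer(q_i, q_j)
    return PairPotential("buffered-14-7", rstar, eps, qq,
                         coulomb_buffer=MMFF_COULOMB_BUFFER,
                         provenance=f"rdkit-{variant}")


def _forcefield(rd: Chem.Mol, variant: str, inter: bool = False):
    props = _properties(rd, variant)
    return AllChem.MMFFGetMoleculeForceField(
        rd, props, ignoreInterfragInteractions=not inter)


def monomer_energy(mol: Molecule, variant: str = "MMFF94") -> float:
    """Total MMFF94 energy of the monomer at its current geometry, kcal/mol."""
    rd = to_rdkit(mol)  # must outlive the force field, which borrows it
    ff = _forcefield(rd, variant)
    energy = ff.CalcEnergy()
    del ff
    return energy


def optimize_monomer(mol: Molecule, variant: str = "MMFF94",
                     max_iterations: int = 20000) -> tuple[Molecule, float]:
    """Local all-atom minimization; returns (optimized molecule, energy)."""
    rd = to_rdkit(mol)
    ff = _forcefield(rd, variant)
    ff.Minimize(maxIts=max_iterations, energyTol=1e-10, forceTol=1e-6)
    coords = rd.GetConformer().GetPositions()
    return mol.with_coords(coords), ff.CalcEnergy()


def optimize_dimer(mol_i: Molecule, mol_j: Molecule,
                   coords_i: np.ndarray, coords_j: np.ndarray,
                   variant: str = "MMFF94", max_iterations: int = 50000,
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Unconstrained all-atom minimization of a placed dimer.

    Returns optimized coordinates of both monomers and the interaction
    energy: dimer total minus the separately optimized monomer totals
    (monomers are free to relax away from their isolated minima inside the
    dimer, so this can drop below any rigid-sampling energy).
    """
    rd_i, rd_j = to_rdkit(mol_i), to_rdkit(mol_j)
    combined = Chem.CombineMols(rd_i, rd_j)
    Chem.SanitizeMol(combined)
    conf = combined.GetConformer()
    ni = mol_i.n_atoms
    for a in range(ni):
        conf.SetAtomPosition(a, Point3D(*coords_i[a]))
    for b in range(mol_j.n_atoms):
        conf.SetAtomPosition(ni + b, Point3D(*coords_j[b]))
    ff = _forcefield(combined, variant, inter=True)
    ff.Minimize(maxIts=max_iterations, energyTol=1e-12, forceTol=1e-8)
    dimer_energy = ff.CalcEnergy()
    _, e_i = optimize_monomer(mol_i, variant)
    _, e_j = optimize_monomer(mol_j, variant)
    pos = combined.GetConformer().GetPositions()
    return pos[:ni].copy(), pos[ni:].copy(), dimer_energy - e_i - e_j
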