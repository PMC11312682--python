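"""Non-bonded intermolecular energy models for rigid monomer pairs.

The interaction energy of two rigid monomers is the sum over all
*intermolecular* atom pairs of a van der Waals term (12-6 Lennard-Jones or
the MMFF94 buffered 14-7) and a Coulomb term (plain or MMFF94-buffered).
For rigid monomers this equals the dimer-minus-monomers energy difference,
since intramolecular terms cancel.

:class:`PairPotential` is the workhorse: it freezes all per-atom-pair
parameters of one (i, j) monomer pair into arrays so that energies can be
evaluated for arbitrary batches of rigid-body placements in one vectorized
call. Parameters come either from the bundled generic table
(``assign_parameters(..., backend="table")``) or from an MMFF94 provider
(:mod:`pairforge.mmff`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal

import numpy as np

from .chemio import Molecule
from .constants import COULOMB_CONSTANT, MMFF_COULOMB_BUFFER

__all__ = [
    "EnergyModelSpec",
    "PairEnergyBreakdown",
    "PairPotential",
    "lj_pair_term",
    "buffered_14_7_term",
    "coulomb_term",
    "assign_parameters",
    "pair_interaction_energy",
    "load_parameter_table",
]


@dataclass(frozen=True)
class EnergyModelSpec:
    """Choice of functional forms for the non-bonded energy."""

    vdw_form: Literal["lj-12-6", "buffered-14-7"] = "lj-12-6"
    electrostatics: Literal["coulomb", "buffered-coulomb"] = "coulomb"
    combination_rule: Literal["lorentz-berthelot", "geometric"] = "lorentz-berthelot"
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if self.vdw_form not in ("lj-12-6", "buffered-14-7"):
            raise ValueError(f"unknown vdw_form {self.vdw_form!r}")
        if self.electrostatics not in ("coulomb", "buffered-coulomb"):
            raise ValueError(f"unknown electrostatics {self.electrostatics!r}")
        if self.combination_rule not in ("lorentz-berthelot", "geometric"):
            raise ValueError(f"unknown combination_rule {self.combination_rule!r}")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass(frozen=True)
class PairEnergyBreakdown:
    """vdW / electrostatic decomposition of one pair interaction, kcal/mol."""

    vdw: float
    electrostatic: float

    @property
    def total(self) -> float:
        return self.vdw + self.electrostatic


def lj_pair_term(r: float, sigma_ij: float, epsilon_ij: float) -> float:
    """12-6 Lennard-Jones energy: 4ε[(σ/r)¹² − (σ/r)⁶]."""
    if r <= 0:
        raise ValueError("r must be positive")
    s6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (s6 * s6 - s6)


def buffered_14_7_term(r: float, r_min_ij: float, epsilon_ij: float) -> float:
    """MMFF94 buffered 14-7 vdW energy with buffering constants 0.07, 0.12.

    Has its minimum of −ε at r = r_min and decays to zero at large r.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    rho = r / r_min_ij
    return (epsilon_ij
            * (1.07 / (rho + 0.07)) ** 7
            * (1.12 / (rho ** 7 + 0.12) - 2.0))


def coulomb_term(r: float, q_i: float, q_j: float, dielectric: float = 1.0,
                 buffered: bool = False,
                 constant: float = COULOMB_CONSTANT) -> float:
    """Coulomb energy C·q_iq_j/(D·r); the buffered variant uses r + 0.05 Å."""
    if buffered:
        return constant * q_i * q_j / (dielectric * (r + MMFF_COULOMB_BUFFER))
    if r <= 0:
        raise ValueError("r must be positive for the unbuffered Coulomb term")
    return constant * q_i * q_j / (dielectric * r)


# ---------------------------------------------------------------------------
# Parameter assignment


def load_parameter_table() -> dict[str, dict[str, float]]:
    """Bundled generic parameter table: atom type -> sigma/epsilon/charge."""
    ref = resources.files("pairforge").joinpath("data", "generic_params.csv")
    table: dict[str, dict[str, float]] = {}
    with ref.open() as fh:
        for row in csv.DictReader(fh):
            table[row["type"]] = {
                "element": row["element"],
                "sigma": float(row["sigma"]),
                "epsilon": float(row["epsilon"]),
                "charge": float(row["charge"]),
            }
    return table


def assign_parameters(mol: Molecule,
                      backend: Literal["table", "mmff"] = "table") -> Molecule:
    """Return a copy of ``mol`` with per-atom charges and vdW parameters set.

    ``table`` looks atom types up in the bundled generic table (LJ σ/ε plus
    fixed partial charges). ``mmff`` delegates to the MMFF94 provider, which
    types the molecule and assigns MMFF94 charges and homonuclear vdW minima.
    """
    if backend == "table":
        table = load_parameter_table()
        atoms = []
        for i, a in enumerate(mol.atoms):
            if a.atom_type is None or a.atom_type not in table:
                raise KeyError(
                    f"atom {i} ({a.element}) of {mol.name!r}: type "
                    f"{a.atom_type!r} not in the bundled parameter table")
            p = table[a.atom_type]
            atoms.append(replace(a, charge=p["charge"], sigma=p["sigma"],
                                 epsilon=p["epsilon"]))
        out = Molecule(mol.name, atoms, list(mol.bonds), mol.vdw_volume,
                       dict(mol.metadata))
        out.metadata["parameter_backend"] = "bundled-table"
        return out
    if backend == "mmff":
        from . import mmff
        return mmff.assign_mmff_parameters(mol)
    raise ValueError(f"unknown parameter backend {backend!r}")


# ---------------------------------------------------------------------------
# Pair potential over a fixed (i, j) monomer pair


class PairPotential:
    """All per-atom-pair parameters of one monomer pair, batch-evaluatable.

    Arrays are shaped (n_i, n_j): ``qq`` holds C·q_iq_j/D, ``vdw_a``/``vdw_b``
    the two vdW parameters per pair (σ, ε for LJ; R*, ε for buffered 14-7).
    """

    def __init__(self, vdw_form: str, vdw_a: np.ndarray, vdw_b: np.ndarray,
                 qq: np.ndarray, coulomb_buffer: float = 0.0,
                 provenance: str = "generic"):
        self.vdw_form = vdw_form
        self.vdw_a = np.asarray(vdw_a, dtype=float)
        self.vdw_b = np.asarray(vdw_b, dtype=float)
        self.qq = np.asarray(qq, dtype=float)
        self.coulomb_buffer = float(coulomb_buffer)
        self.provenance = provenance
        if not (self.vdw_a.shape == self.vdw_b.shape == self.qq.shape):
            raise ValueError("parameter matrices must share one (n_i, n_j) shape")

    @classmethod
    def from_generic(cls, mol_i: Molecule, mol_j: Molecule,
                     model_spec: EnergyModelSpec | None = None) -> "PairPotential":
        """Build from per-atom σ/ε/q using the model's combination rule."""
        spec = model_spec or EnergyModelSpec()
        for m in (mol_i, mol_j):
            for k, a in enumerate(m.atoms):
                if a.charge is None or a.sigma is None or a.epsilon is None:
                    raise ValueError(
                        f"atom {k} ({a.element}) of {m.name!r} lacks parameters; "
                        "run assign_parameters first")
        si = np.array([a.sigma for a in mol_i.atoms])
        sj = np.array([a.sigma for a in mol_j.atoms])
        ei = np.array([a.epsilon for a in mol_i.atoms])
        ej = np.array([a.epsilon for a in mol_j.atoms])
        if spec.combination_rule == "lorentz-berthelot":
            sig = 0.5 * (si[:, None] + sj[None, :])
        else:
            sig = np.sqrt(si[:, None] * sj[None, :])
        eps = np.sqrt(ei[:, None] * ej[None, :])
        if spec.vdw_form == "buffered-14-7":
            vdw_a = sig * 2.0 ** (1.0 / 6.0)  # treat σ as LJ σ; R* at minimum
        else:
            vdw_a = sig
        qq = (spec.coulomb_constant / spec.dielectric
              * np.outer(mol_i.charges, mol_j.charges))
        buffer = MMFF_COULOMB_BUFFER if spec.electrostatics == "buffered-coulomb" else 0.0
        return cls(spec.vdw_form, vdw_a, eps, qq, buffer, provenance="generic")

    @classmethod
    def from_mmff(cls, mol_i: Molecule, mol_j: Molecule,
                  variant: str = "MMFF94") -> "PairPotential":
        """Exact MMFF94 intermolecular parameters via the MMFF94 provider."""
        from . import mmff
        return mmff.mmff_pair_potential(mol_i, mol_j, variant=variant)

    @property
    def shape(self) -> tuple[int, int]:
        return self.qq.shape

    def _terms(self, coords_i: np.ndarray, coords_j: np.ndarray):
        ci = np.asarray(coords_i, dtype=float)
        cj = np.asarray(coords_j, dtype=float)
        diff = ci[..., :, None, :] - cj[..., None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        r = np.clip(r, 1e-12, None)  # overlapping configs -> huge repulsion
        if self.vdw_form == "lj-12-6":
            s6 = (self.vdw_a / r) ** 6
            vdw = 4.0 * self.vdw_b * (s6 * s6 - s6)
        else:
            rho = r / self.vdw_a
            vdw = (self.vdw_b * (1.07 / (rho + 0.07)) ** 7
                   * (1.12 / (rho ** 7 + 0.12) - 2.0))
        ele = self.qq / (r + self.coulomb_buffer)
        return vdw, ele

    def energies(self, coords_i: np.ndarray, coords_j: np.ndarray) -> np.ndarray:
        """Total interaction energy for broadcast batches of placements.

        ``coords_i``: (..., n_i, 3), ``coords_j``: (..., n_j, 3); leading
        dimensions broadcast. Returns the summed energy per configuration.
        """
        vdw, ele = self._terms(coords_i, coords_j)
        return np.sum(vdw + ele, axis=(-2, -1))

    def breakdown(self, coords_i: np.ndarray,
                  coords_j: np.ndarray) -> PairEnergyBreakdown:
        vdw, ele = self._terms(coords_i, coords_j)
        return PairEnergyBreakdown(float(np.sum(vdw)), float(np.sum(ele)))


def pair_interaction_energy(mol_i: Molecule, mol_j: Molecule,
                            model_spec: EnergyModelSpec | None = None,
                            coords_i: np.ndarray | None = None,
                            coords_j: np.ndarray | None = None,
                            ) -> PairEnergyBreakdown:
    """Intermolecular energy of one placed monomer pair.

    Coordinates default to the molecules' own; pass ``coords_i``/``coords_j``
    to evaluate a specific placement without copying molecules.
    """
    pot = PairPotential.from_generic(mol_i, mol_j, model_spec)
    ci = mol_i.coords if coords_i is None else coords_i
    cj = mol_j.coords if coords_j is None else coords_j
    return pot.breakdown(ci, cj)
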