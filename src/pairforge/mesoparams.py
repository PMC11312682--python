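"""Differential pair energies, Flory–Huggins χ, and DPD repulsion sets.

The differential pair interaction energy ΔE_ij = E_ij − (E_ii + E_jj)/2
measures the excess of the mixed interaction over the mean of the
self-interactions; with per-pair coordination numbers Z it generalizes to
ΔE_ij^Z = ½(Z_ij·E_ij + Z_ji·E_ji) − ½(Z_ii·E_ii + Z_jj·E_jj). Dividing by
k_BT gives the Flory–Huggins parameter χ_ij, which maps onto the maximum
isotropic repulsion of Dissipative Particle Dynamics particles as
a_ij(T) = 75·k_BT/ρ_DPD + 3.4965·k_BT·χ_ij, with thermal energy expressed
in units where k_B·T_ref = 1 (T_ref = 300 K reproduces the conventional
diagonal a_ii = 24.83 at 298 K). Off-diagonal values of a finished particle
set are linearly rescaled about the diagonal so the strongest attraction
sits a fixed distance (20 by default) below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KB_KCAL

__all__ = [
    "InteractionMatrix",
    "CoordinationMatrix",
    "ParticleSet",
    "differential_energy",
    "differential_energy_z",
    "flory_huggins",
    "conversion_coefficient",
    "dpd_repulsion",
    "scale_particle_set",
    "dpd_conservative_force",
    "export_particle_set",
    "load_particle_set",
]

#: χ → a_ij coefficient: the published inverse value is 0.286, i.e. 1/0.286
CHI_COEFFICIENT = 1.0 / 0.286


def conversion_coefficient(decimals: int = 4) -> float:
    """The χ coefficient of the repulsion mapping, 1/0.286 ≈ 3.4965."""
    return round(CHI_COEFFICIENT, decimals)


@dataclass
class InteractionMatrix:
    """Symmetric E_ij^min and ⟨E_ij⟩^min matrices over labeled molecules."""

    names: list[str]
    e_min: np.ndarray
    e_mean_min: np.ndarray
    temperature: float = 298.0

    def __post_init__(self) -> None:
        n = len(self.names)
        self.e_min = np.asarray(self.e_min, dtype=float)
        self.e_mean_min = np.asarray(self.e_mean_min, dtype=float)
        for m in (self.e_min, self.e_mean_min):
            if m.shape != (n, n):
                raise ValueError("matrix shape must match the name list")
            if not np.allclose(m, m.T, atol=1e-9):
                raise ValueError("interaction matrices must be symmetric")

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class CoordinationMatrix:
    """Z_ij matrix; generally asymmetric (Z_ij need not equal Z_ji)."""

    names: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape must match the name list")
        if np.any(self.z <= 0):
            raise ValueError("coordination numbers must be positive")


def differential_energy(e_ii: float, e_jj: float, e_ij: float) -> float:
    """ΔE_ij = E_ij − ½(E_ii + E_jj); applies to minima or averages alike."""
    return e_ij - 0.5 * (e_ii + e_jj)


def differential_energy_z(e: np.ndarray, z: np.ndarray, i: int, j: int) -> float:
    """Coordination-weighted excess:
    ½(Z_ij·E_ij + Z_ji·E_ji) − ½(Z_ii·E_ii + Z_jj·E_jj)."""
    e = np.asarray(e, dtype=float)
    z = np.asarray(z, dtype=float)
    return float(0.5 * (z[i, j] * e[i, j] + z[j, i] * e[j, i])
                 - 0.5 * (z[i, i] * e[i, i] + z[j, j] * e[j, j]))


def flory_huggins(delta_e_z: float, temperature: float) -> float:
    """χ_ij = ΔE^Z / (k_B·T), dimensionless."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return delta_e_z / (KB_KCAL * temperature)


def dpd_repulsion(chi: float, rho_dpd: float = 3.0, temperature: float = 298.0,
                  reference_temperature: float = 300.0) -> float:
    """a_ij(T) = 75·k_BT/ρ_DPD + 3.4965·k_BT·χ_ij, in k_B·T_ref units.

    With k_BT expressed so that k_B·T_ref = 1, the thermal factor is
    T/T_ref, so χ = 0 at T = T_ref gives exactly 75/ρ.
    """
    if rho_dpd <= 0:
        raise ValueError("rho_dpd must be positive")
    kbt = temperature / reference_temperature
    return kbt * (75.0 / rho_dpd + CHI_COEFFICIENT * chi)


@dataclass
class ParticleSet:
    """Named DPD particles with their symmetric repulsion matrix (k_BT)."""

    names: list[str]
    a: np.ndarray
    diagonal_value: float
    scaling: dict = field(default_factory=dict)
    rho_dpd: float = 3.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.names)
        if self.a.shape != (n, n):
            raise ValueError("repulsion matrix shape must match names")
        if not np.allclose(self.a, self.a.T, atol=1e-9):
            raise ValueError("repulsion matrix must be symmetric")
        if not np.allclose(np.diag(self.a), self.diagonal_value, atol=1e-9):
            raise ValueError("diagonal entries must equal diagonal_value")


def scale_particle_set(raw_a: np.ndarray, names: list[str],
                       diagonal_value: float = 24.83,
                       max_deviation: float = 20.0,
                       rho_dpd: float = 3.0,
                       temperature: float = 298.0) -> ParticleSet:
    """Linear off-diagonal rescaling about the diagonal value.

    a'_ij = a_ii + s·(a_ij − a_ii) with s chosen so the smallest off-diagonal
    lands exactly at a_ii − max_deviation. Rank order of the off-diagonals is
    preserved; the pair attaining the minimum is recorded as the base pair.
    """
    raw = np.asarray(raw_a, dtype=float)
    n = len(names)
    if raw.shape != (n, n) or not np.allclose(raw, raw.T, atol=1e-9):
        raise ValueError("raw repulsion matrix must be symmetric and match names")
    if n < 2:
        raise ValueError("need at least one off-diagonal pair")
    off = ~np.eye(n, dtype=bool)
    deviation = np.abs(raw[off].min() - diagonal_value)
    if deviation < 1e-12:
        raise ValueError("all off-diagonal values equal the diagonal; "
                         "scaling factor is undefined")
    s = max_deviation / deviation
    scaled = diagonal_value + s * (raw - diagonal_value)
    np.fill_diagonal(scaled, diagonal_value)
    flat = np.where(off, raw, np.inf)
    i, j = np.unravel_index(int(np.argmin(flat)), flat.shape)
    return ParticleSet(
        names=list(names), a=scaled, diagonal_value=diagonal_value,
        scaling={"factor": float(s), "max_deviation": float(max_deviation),
                 "base_pair": [names[i], names[j]]},
        rho_dpd=rho_dpd, temperature=temperature)


def dpd_conservative_force(r_vector: np.ndarray, a_ij: float) -> np.ndarray:
    """Soft conservative DPD force a_ij(1 − r)·r̂ for r < 1, zero beyond.

    Distances are in cutoff units; the force on particle i from j points
    along r_ij = r_i − r_j.
    """
    if a_ij < 0:
        raise ValueError("a_ij must be non-negative")
    r_vector = np.asarray(r_vector, dtype=float)
    r = float(np.linalg.norm(r_vector))
    if r == 0.0:
        raise ValueError("zero separation: unit vector undefined")
    if r >= 1.0:
        return np.zeros(3)
    return a_ij * (1.0 - r) * (r_vector / r)


def export_particle_set(ps: ParticleSet, path_prefix: str | Path,
                        extra_metadata: dict | None = None) -> tuple[Path, Path]:
    """Write the repulsion matrix as CSV and the metadata as JSON.

    Returns (csv_path, json_path); re-importing reproduces the matrix.
    """
    from . import __version__
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    frame = pd.DataFrame(ps.a, index=ps.names, columns=ps.names)
    frame.to_csv(csv_path, float_format="%.12g")
    meta = {
        "names": ps.names,
        "diagonal_value": ps.diagonal_value,
        "scaling": ps.scaling,
        "rho_dpd": ps.rho_dpd,
        "temperature": ps.temperature,
        "software_version": __version__,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def load_particle_set(path_prefix: str | Path) -> ParticleSet:
    """Re-import a particle set written by :func:`export_particle_set`."""
    prefix = Path(path_prefix)
    frame = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ParticleSet(
        names=list(frame.index), a=frame.to_numpy(dtype=float),
        diagonal_value=meta["diagonal_value"], scaling=meta["scaling"],
        rho_dpd=meta["rho_dpd"], temperature=meta["temperature"])
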