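"""Exhaustive rigid-body dimer configuration sampling and Boltzmann curves.

For one monomer pair at a fixed center separation r_fix, a unit sphere around
each monomer's center carries N_sphere near-uniform Fibonacci-lattice points.
Each (point_i, point_j) combination is realized by rotating each monomer about
its own center so that its lattice point lies on the center–center axis; the
second monomer is additionally spun about that axis in N_rot equal steps.
That enumerates exactly N_sphere² · N_rot rigid configurations per distance.

Per distance, the minimum sampled energy E^C* and the Boltzmann-weighted mean
⟨E⟩ are recorded; a coarse 3–16 Å scan (0.5 Å steps) is refined around the
incumbent minimum at 0.1 Å and then 0.01 Å resolution. The refined minimum
configuration C* seeds a final unconstrained optimization, either rigid-body
(6 relative degrees of freedom under the sampling potential) or all-atom via
an external force-field backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .chemio import Molecule, molecule_center
from .constants import KB_KCAL
from .energy import PairPotential

__all__ = [
    "SphereLattice",
    "DimerConfiguration",
    "DistanceScanResult",
    "OptimizedDimer",
    "fibonacci_sphere",
    "orient_to_axis",
    "DimerSampler",
    "enumerate_configurations",
    "scan_distance_grid",
    "refine_minimum",
    "boltzmann_average",
    "optimize_dimer",
    "extract_curves",
]

_GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
_AXIS = np.array([1.0, 0.0, 0.0])  # center-to-center axis convention: +x


@dataclass(frozen=True)
class SphereLattice:
    """N near-uniform unit vectors from the golden-angle spiral."""

    n_points: int
    points: np.ndarray


def fibonacci_sphere(n: int) -> SphereLattice:
    """Golden-angle spiral lattice: z uniform in (−1, 1), azimuth k·2π(1−1/φ)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    azimuth = 2.0 * np.pi * (1.0 - 1.0 / _GOLDEN_RATIO) * k
    s = np.sqrt(1.0 - z * z)
    pts = np.column_stack([s * np.cos(azimuth), s * np.sin(azimuth), z])
    return SphereLattice(n, pts)


def _minimal_rotation(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector t.

    Rotates about the axis perpendicular to both; the antiparallel case uses
    a fixed fallback axis so results are deterministic.
    """
    c = float(np.dot(u, t))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    v = np.cross(u, t)
    k = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def orient_to_axis(mol: Molecule, center: np.ndarray, lattice_point: np.ndarray,
                   axis_sign: int = 1) -> np.ndarray:
    """Rotation (3×3) about ``center`` mapping ``lattice_point`` to ±x̂."""
    target = _AXIS * (1 if axis_sign >= 0 else -1)
    return _minimal_rotation(np.asarray(lattice_point, float), target)


@dataclass
class DimerConfiguration:
    """One sampled rigid placement: lattice indices, spin index, distance."""

    distance: float
    point_i: int
    point_j: int
    spin_k: int
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class DistanceScanResult:
    """Minimum and Boltzmann-averaged sampled energy at one distance."""

    distance: float
    e_cstar: float
    e_mean: float
    best_config: DimerConfiguration


@dataclass
class OptimizedDimer:
    """Final dimer after unconstrained optimization from C*."""

    coords_i: np.ndarray
    coords_j: np.ndarray
    e_min: float
    r_min: float
    backend: str


def boltzmann_average(energies: np.ndarray, temperature: float,
                      reference_energy: float | None = None) -> float:
    """Boltzmann-weighted mean Σ E·w / Σ w with w = exp(−(E − ref)/k_BT).

    The result is independent of the reference (the shift cancels); for
    numerical stability the batch minimum is always subtracted internally.
    """
    e = np.asarray(energies, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("energies must be non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    shift = e.min() if reference_energy is None else min(reference_energy, e.min())
    w = np.exp(-(e - shift) / (KB_KCAL * temperature))
    return float(np.sum(e * w) / np.sum(w))


class DimerSampler:
    """Precomputed rotated monomer frames for fast per-distance enumeration.

    Monomers are treated as rigid in their input conformations. Molecule i
    sits with its center at the origin, lattice point rotated onto +x̂;
    molecule j's lattice point is rotated onto −x̂, spun about x̂ in
    2π/N_rot steps, and translated to (r_fix, 0, 0). Only molecule j is
    spun — spinning both would enumerate each relative orientation N_rot
    times.
    """

    def __init__(self, mol_i: Molecule, mol_j: Molecule, potential: PairPotential,
                 n_sphere: int = 144, n_rot: int = 16,
                 center: Literal["geometric", "mass"] = "geometric"):
        if potential.shape != (mol_i.n_atoms, mol_j.n_atoms):
            raise ValueError("potential shape does not match the monomer pair")
        self.mol_i, self.mol_j = mol_i, mol_j
        self.potential = potential
        self.n_sphere, self.n_rot = int(n_sphere), int(n_rot)
        self.center_mode = center
        self.lattice = fibonacci_sphere(self.n_sphere)

        xi = mol_i.coords - molecule_center(mol_i, center)
        xj = mol_j.coords - molecule_center(mol_j, center)
        rot_i = np.stack([_minimal_rotation(p, _AXIS) for p in self.lattice.points])
        rot_j = np.stack([_minimal_rotation(p, -_AXIS) for p in self.lattice.points])
        self._frames_i = np.einsum("kab,nb->kna", rot_i, xi)   # (ns, n_i, 3)
        base_j = np.einsum("kab,nb->kna", rot_j, xj)           # (ns, n_j, 3)
        angles = 2.0 * np.pi * np.arange(self.n_rot) / self.n_rot
        spin = Rotation.from_rotvec(np.outer(angles, _AXIS)).as_matrix()
        self._spin = spin
        # (ns, nrot, n_j, 3)
        self._frames_j = np.einsum("sab,knb->ksna", spin, base_j)

    @property
    def n_configurations(self) -> int:
        return self.n_sphere * self.n_sphere * self.n_rot

    def energies(self, r_fix: float, chunk: int = 8) -> np.ndarray:
        """(n_sphere, n_sphere, n_rot) energy array at one distance."""
        if r_fix <= 0:
            raise ValueError("r_fix must be positive")
        offset = np.array([r_fix, 0.0, 0.0])
        frames_j = (self._frames_j + offset).reshape(-1, self.mol_j.n_atoms, 3)
        out = np.empty((self.n_sphere, frames_j.shape[0]))
        for start in range(0, self.n_sphere, chunk):
            block = self._frames_i[start:start + chunk]
            out[start:start + chunk] = self.potential.energies(
                block[:, None, :, :], frames_j[None, :, :, :])
        return out.reshape(self.n_sphere, self.n_sphere, self.n_rot)

    def config_coords(self, config: DimerConfiguration) -> tuple[np.ndarray, np.ndarray]:
        """Absolute coordinates (Å) of both monomers for one configuration."""
        ci = self._frames_i[config.point_i]
        cj = (self._frames_j[config.point_j, config.spin_k]
              + np.array([config.distance, 0.0, 0.0]))
        return ci.copy(), cj.copy()

    def sample_distance(self, r_fix: float, temperature: float = 298.0,
                        ) -> tuple[DistanceScanResult, np.ndarray]:
        """Scan one distance: returns the summary and the raw energy array."""
        e = self.energies(r_fix)
        flat_index = int(np.argmin(e))  # first minimum in C order = lexicographic
        pi, pj, sk = np.unravel_index(flat_index, e.shape)
        e_cstar = float(e[pi, pj, sk])
        config = DimerConfiguration(r_fix, int(pi), int(pj), int(sk), e_cstar)
        return DistanceScanResult(r_fix, e_cstar,
                                  boltzmann_average(e, temperature), config), e


def enumerate_configurations(mol_i: Molecule, mol_j: Molecule, r_fix: float,
                             potential: PairPotential, n_sphere: int = 144,
                             n_rot: int = 16,
                             center: Literal["geometric", "mass"] = "geometric",
                             ) -> Iterator[DimerConfiguration]:
    """Yield all N_sphere²·N_rot configurations at r_fix with energies.

    Order is lexicographic in (point_i, point_j, spin_k).
    """
    sampler = DimerSampler(mol_i, mol_j, potential, n_sphere, n_rot, center)
    e = sampler.energies(r_fix)
    for pi in range(n_sphere):
        for pj in range(n_sphere):
            for sk in range(n_rot):
                yield DimerConfiguration(r_fix, pi, pj, sk, float(e[pi, pj, sk]))


def _distance_grid(r_start: float, r_end: float, step: float) -> np.ndarray:
    if r_start > r_end:
        raise ValueError("r_start must not exceed r_end")
    n = int(round((r_end - r_start) / step)) + 1 if r_end > r_start else 1
    grid = np.round(r_start + step * np.arange(n), 9)
    grid = grid[grid <= r_end + 1e-9]
    if grid.size == 0:
        raise ValueError("empty distance grid")
    return grid


def scan_distance_grid(sampler: DimerSampler, r_start: float = 3.0,
                       r_end: float = 16.0, step: float = 0.5,
                       temperature: float = 298.0) -> list[DistanceScanResult]:
    """One DistanceScanResult per grid distance, endpoints inclusive."""
    return [sampler.sample_distance(float(r), temperature)[0]
            for r in _distance_grid(r_start, r_end, step)]


def refine_minimum(scan: Sequence[DistanceScanResult], sampler: DimerSampler,
                   temperature: float = 298.0,
                   ) -> tuple[DistanceScanResult, list[list[DistanceScanResult]]]:
    """Two-stage distance refinement around the coarse scan minimum.

    Re-scans a ±0.5 Å window at 0.1 Å resolution around the incumbent, then
    ±0.1 Å at 0.01 Å around the new incumbent; ties resolve to the first
    (smallest-distance) grid point. Returns the finest-resolution best result
    and the two refinement scans.
    """
    if not scan:
        raise ValueError("scan must be non-empty")
    history: list[list[DistanceScanResult]] = []
    best = min(scan, key=lambda s: s.e_cstar)
    for window, step in ((0.5, 0.1), (0.1, 0.01)):
        lo = max(best.distance - window, step)
        results = scan_distance_grid(sampler, lo, best.distance + window,
                                     step, temperature)
        history.append(results)
        best = min(results, key=lambda s: s.e_cstar)
    return best, history


def extract_curves(results: Sequence[DistanceScanResult]) -> pd.DataFrame:
    """Curve table (r, E^C*, ⟨E⟩) for plotting or CSV export."""
    return pd.DataFrame({
        "r": [s.distance for s in results],
        "e_cstar": [s.e_cstar for s in results],
        "e_mean": [s.e_mean for s in results],
    })


def optimize_dimer(sampler: DimerSampler, config: DimerConfiguration,
                   backend: Literal["rigid", "mmff"] = "rigid",
                   ) -> OptimizedDimer:
    """Unconstrained optimization of the dimer starting from configuration C*.

    ``rigid`` relaxes the 6 relative rigid-body degrees of freedom (rotation
    and translation of molecule j; molecule i stays fixed, which removes the
    global-motion redundancy) under the sampling potential. ``mmff`` hands
    the full dimer to the all-atom MMFF94 backend, so the monomers may relax
    out of their input conformations; its energy is the dimer total minus
    the separately optimized monomer totals.
    """
    ci, cj = sampler.config_coords(config)
    if backend == "mmff":
        from . import mmff
        oi, oj, e_min = mmff.optimize_dimer(sampler.mol_i, sampler.mol_j, ci, cj)
    elif backend == "rigid":
        center_j = cj.mean(axis=0) if sampler.center_mode == "geometric" else (
            sampler.mol_j.masses @ cj / sampler.mol_j.masses.sum())
        local_j = cj - center_j
        pot = sampler.potential

        def placed(x: np.ndarray) -> np.ndarray:
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            return local_j @ rot.T + center_j + x[3:]

        def objective(x: np.ndarray) -> float:
            return float(pot.energies(ci, placed(x)))

        res = _scipy_minimize(objective, np.zeros(6), method="BFGS",
                              options={"gtol": 1e-8, "maxiter": 2000})
        best_x = res.x if res.fun <= objective(np.zeros(6)) else np.zeros(6)
        oi, oj = ci, placed(best_x)
        e_min = float(pot.energies(oi, oj))
    else:
        raise ValueError(f"unknown optimizer backend {backend!r}")

    if sampler.center_mode == "geometric":
        centers = oi.mean(axis=0), oj.mean(axis=0)
    else:
        mi, mj = sampler.mol_i.masses, sampler.mol_j.masses
        centers = mi @ oi / mi.sum(), mj @ oj / mj.sum()
    return OptimizedDimer(oi, oj, e_min,
                          float(np.linalg.norm(centers[0] - centers[1])),
                          backend)
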