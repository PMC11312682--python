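"""Periodic-box construction, minimal MD engine, coordination numbers.

The coordination number Z_ij (how many molecules j simultaneously neighbor a
single molecule i) is estimated from an NVT trajectory of one solute in a
cubic solvent box whose edge follows from van der Waals volumes: a water
molecule occupies 30.00 Å³ of liquid at 298 K against a vdW volume of
17.35 Å³, and that packing ratio is transferred to any molecule X, giving
a = (N · 30.00/17.35 · V_vdW^X)^(1/3).

The MD engine is intentionally small: velocity-Verlet, minimum-image cubic
periodicity, a radial cutoff on the non-bonded (LJ + Coulomb) interactions,
an Andersen thermostat, and stiff harmonic bond/angle restraints that hold
each molecule near its input geometry (a pragmatic stand-in for full bonded
force-field terms). Two neighbor-counting routes — brute force over all atom
pairs and a periodic cell-index search — must agree exactly; two molecules
are neighbors when any interatomic distance is ≤ the sum of the atoms' vdW
radii plus a catch radius (1 Å by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._elements import VDW_RADIUS
from .chemio import Molecule, TrajectoryFrame, molecule_center
from .constants import (ACCEL_CONVERSION, KB_MD, WATER_BOX_VOLUME,
                        WATER_VDW_VOLUME)

__all__ = [
    "MDSettings",
    "NeighborCriterion",
    "SimulationBox",
    "CoordinationEstimate",
    "box_edge_length",
    "per_molecule_volume",
    "build_solvent_box",
    "insert_solute",
    "minimize_box",
    "run_md",
    "count_neighbors_bruteforce",
    "count_neighbors_cellindex",
    "estimate_coordination_number",
]

logger = logging.getLogger(__name__)

BOND_FORCE_CONSTANT = 300.0   # kcal/mol/Å², restraint toward input bond length
ANGLE_FORCE_CONSTANT = 100.0  # kcal/mol/rad², restraint toward input angle


def per_molecule_volume(molar_mass: float, density: float) -> float:
    """Liquid volume per molecule, Å³, from molar mass (g/mol) and density
    (g/cm³): V = M / (ρ·N_A). Water at 298 K (0.99705 g/cm³) gives 30.00 Å³."""
    if molar_mass <= 0 or density <= 0:
        raise ValueError("molar_mass and density must be positive")
    avogadro_per_cm3_to_a3 = 0.6022140763  # N_A · 10⁻²⁴
    return molar_mass / (density * avogadro_per_cm3_to_a3)


def box_edge_length(n_molecules: int, vdw_volume_x: float,
                    water_box_volume: float = WATER_BOX_VOLUME,
                    water_vdw_volume: float = WATER_VDW_VOLUME) -> float:
    """Cubic edge a = (N · (V_box^H2O/V_vdW^H2O) · V_vdW^X)^(1/3), Å."""
    if n_molecules <= 0 or vdw_volume_x <= 0:
        raise ValueError("n_molecules and vdw_volume_x must be positive")
    return float(np.cbrt(n_molecules * water_box_volume / water_vdw_volume
                         * vdw_volume_x))


@dataclass
class MDSettings:
    """Integrator and thermostat settings (fs, K, steps)."""

    timestep: float = 1.0
    temperature: float = 298.0
    equilibration_steps: int = 10_000
    production_steps: int = 400_000
    record_interval: int = 100
    thermostat_rate: float = 25.0   # collisions per atom per ps; 0 disables
    cutoff: float | None = 9.0      # Å; None disables the cutoff

    def __post_init__(self) -> None:
        for name in ("timestep", "temperature", "record_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.equilibration_steps < 0 or self.thermostat_rate < 0:
            raise ValueError("equilibration_steps and thermostat_rate must be "
                             "non-negative")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive or None")
        if self.production_steps < 0:
            raise ValueError("production_steps must be non-negative")
        if self.production_steps and self.record_interval > self.production_steps:
            raise ValueError("record_interval exceeds production_steps")


@dataclass
class NeighborCriterion:
    """Neighborship rule: d ≤ r_vdW(a) + r_vdW(b) + catch_radius."""

    catch_radius: float = 1.0
    radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADIUS))

    def __post_init__(self) -> None:
        if self.catch_radius < 0:
            raise ValueError("catch_radius must be non-negative")

    def radius_of(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError as exc:
            raise KeyError(f"no vdW radius for element {element!r}") from exc


@dataclass
class SimulationBox:
    """Flattened periodic system state plus per-atom parameters."""

    edge: float
    positions: np.ndarray            # (N, 3), wrapped into [0, edge)
    velocities: np.ndarray           # (N, 3), Å/fs
    molecule_index: np.ndarray       # (N,), owning molecule id
    elements: list[str]
    masses: np.ndarray
    charges: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    bonds: np.ndarray                # (nb, 2) global indices
    bond_lengths: np.ndarray         # (nb,) reference lengths
    angles: np.ndarray               # (na, 3) global indices, center second
    angle_values: np.ndarray         # (na,) reference angles, rad
    solute_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("edge must be positive")
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        self.positions = np.mod(self.positions, self.edge)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_atoms else 0


def _molecule_angles(mol: Molecule) -> list[tuple[int, int, int]]:
    adjacency: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for a, b in mol.bonds:
        adjacency[a].append(b)
        adjacency[b].append(a)
    angles = []
    for center, nbrs in enumerate(adjacency):
        nbrs = sorted(nbrs)
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                angles.append((nbrs[x], center, nbrs[y]))
    return angles


def _require_parameters(mol: Molecule) -> None:
    for k, a in enumerate(mol.atoms):
        if a.charge is None or a.sigma is None or a.epsilon is None:
            raise ValueError(f"atom {k} of {mol.name!r} lacks non-bonded "
                             "parameters; run assign_parameters first")


def _assemble(edge: float, placed: list[tuple[Molecule, np.ndarray]],
              solute_index: int | None = None) -> SimulationBox:
    positions, mol_index, elements = [], [], []
    masses, charges, sigma, epsilon = [], [], [], []
    bonds, bond_lengths, angles, angle_values = [], [], [], []
    offset = 0
    for mol_id, (mol, coords) in enumerate(placed):
        n = mol.n_atoms
        positions.append(coords)
        mol_index.extend([mol_id] * n)
        elements.extend(mol.elements)
        masses.extend(mol.masses)
        charges.extend(a.charge for a in mol.atoms)
        sigma.extend(a.sigma for a in mol.atoms)
        epsilon.extend(a.epsilon for a in mol.atoms)
        ref = mol.coords
        for a, b in mol.bonds:
            bonds.append((offset + a, offset + b))
            bond_lengths.append(float(np.linalg.norm(ref[a] - ref[b])))
        for a, c, b in _molecule_angles(mol):
            u, v = ref[a] - ref[c], ref[b] - ref[c]
            cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angles.append((offset + a, offset + c, offset + b))
            angle_values.append(float(np.arccos(np.clip(cosv, -1.0, 1.0))))
        offset += n
    pos = np.concatenate(positions) if positions else np.zeros((0, 3))
    return SimulationBox(
        edge=edge, positions=pos, velocities=np.zeros_like(pos),
        molecule_index=np.array(mol_index, dtype=int), elements=elements,
        masses=np.array(masses), charges=np.array(charges),
        sigma=np.array(sigma), epsilon=np.array(epsilon),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_lengths=np.array(bond_lengths),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_values=np.array(angle_values),
        solute_index=solute_index)


def _min_image(diff: np.ndarray, edge: float) -> np.ndarray:
    return diff - edge * np.round(diff / edge)


def build_solvent_box(mol_j: Molecule, n: int, edge: float,
                      seed: int | np.random.Generator = 0,
                      min_spacing: float = 1.5,
                      max_retries: int = 200) -> SimulationBox:
    """Place n copies of a parameterized solvent on a jittered cubic lattice.

    Each copy gets a random orientation; placement retries until no two atoms
    of different molecules are closer than ``min_spacing`` (minimum image).
    """
    _require_parameters(mol_j)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = math.ceil(n ** (1.0 / 3.0))
    if m**3 < n:
        m += 1
    spacing = edge / m
    sites = np.array([((i + 0.5) * spacing, (j + 0.5) * spacing, (k + 0.5) * spacing)
                      for i in range(m) for j in range(m) for k in range(m)][:n])
    local = mol_j.coords - molecule_center(mol_j)
    jitter_scale = max(spacing * 0.05, 0.01)

    def place_one(site: np.ndarray) -> np.ndarray:
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()
        jitter = rng.uniform(-jitter_scale, jitter_scale, 3)
        return local @ rot.T + site + jitter

    coords = [place_one(s) for s in sites]

    def violations() -> set[int]:
        pos = np.concatenate(coords)
        ids = np.repeat(np.arange(n), mol_j.n_atoms)
        diff = _min_image(pos[:, None, :] - pos[None, :, :], edge)
        d = np.linalg.norm(diff, axis=-1)
        bad = (d < min_spacing) & (ids[:, None] != ids[None, :])
        return set(ids[np.unique(np.nonzero(bad)[0])].tolist())

    for _ in range(max_retries):
        bad = violations()
        if not bad:
            break
        for mol_id in bad:
            coords[mol_id] = place_one(sites[mol_id])
    else:
        raise RuntimeError(
            f"could not satisfy {min_spacing} Å spacing for {n} molecules "
            f"in an edge-{edge:.2f} Å box after {max_retries} retries")

    box = _assemble(edge, [(mol_j, c) for c in coords])
    box.metadata.update(solvent=mol_j.name, n_solvent=n)
    return box


def insert_solute(box: SimulationBox, mol_i: Molecule,
                  overlap_factor: float = 0.8) -> SimulationBox:
    """Place one solute at the box center, removing overlapping solvent.

    A solvent molecule is removed when any of its atoms lies within
    ``overlap_factor`` × (vdW radius sum) of any solute atom (minimum image),
    which emulates density-preserving insertion.
    """
    _require_parameters(mol_i)
    center = np.full(3, box.edge / 2.0)
    solute_coords = mol_i.coords - molecule_center(mol_i) + center
    radii_solute = np.array([a.vdw_radius for a in mol_i.atoms])
    radii_box = np.array([VDW_RADIUS.get(e, 1.5) for e in box.elements])
    diff = _min_image(solute_coords[:, None, :] - box.positions[None, :, :],
                      box.edge)
    d = np.linalg.norm(diff, axis=-1)
    threshold = overlap_factor * (radii_solute[:, None] + radii_box[None, :])
    clashing_atoms = np.nonzero((d < threshold).any(axis=0))[0]
    removed_ids = sorted(set(box.molecule_index[clashing_atoms].tolist()))
    keep = ~np.isin(box.molecule_index, removed_ids)

    # rebuild with surviving solvent then the solute as the last molecule
    placed: list[tuple[Molecule, np.ndarray]] = []
    kept_ids = [mid for mid in range(box.n_molecules) if mid not in removed_ids]
    for mid in kept_ids:
        mask = box.molecule_index == mid
        sub = _submolecule(box, mask)
        placed.append((sub, box.positions[mask]))
    placed.append((mol_i, solute_coords))
    out = _assemble(box.edge, placed, solute_index=len(placed) - 1)
    out.metadata.update(box.metadata)
    out.metadata["removed_on_insertion"] = len(removed_ids)
    out.metadata["solute"] = mol_i.name
    return out


def _submolecule(box: SimulationBox, mask: np.ndarray) -> Molecule:
    """Rebuild a Molecule (with parameters) for one molecule id in the box."""
    from .chemio import AtomRecord
    idx = np.nonzero(mask)[0]
    remap = {int(g): k for k, g in enumerate(idx)}
    atoms = [AtomRecord(box.elements[g], box.positions[g].copy(),
                        charge=float(box.charges[g]), sigma=float(box.sigma[g]),
                        epsilon=float(box.epsilon[g]), mass=float(box.masses[g]))
             for g in idx]
    bonds = [(remap[int(a)], remap[int(b)]) for a, b in box.bonds
             if int(a) in remap and int(b) in remap]
    return Molecule("fragment", atoms, bonds)


# ---------------------------------------------------------------------------
# Energy and forces


def _nonbonded(box: SimulationBox, positions: np.ndarray, cutoff: float | None,
               ) -> tuple[float, np.ndarray]:
    n = len(positions)
    forces = np.zeros_like(positions)
    if n < 2:
        return 0.0, forces
    iu, ju = np.triu_indices(n, k=1)
    same = box.molecule_index[iu] == box.molecule_index[ju]
    iu, ju = iu[~same], ju[~same]
    diff = _min_image(positions[iu] - positions[ju], box.edge)
    r = np.linalg.norm(diff, axis=-1)
    if cutoff is not None:
        within = r < cutoff
        iu, ju, diff, r = iu[within], ju[within], diff[within], r[within]
    r = np.clip(r, 1e-9, None)
    sig = 0.5 * (box.sigma[iu] + box.sigma[ju])
    eps = np.sqrt(box.epsilon[iu] * box.epsilon[ju])
    s6 = (sig / r) ** 6
    from .constants import COULOMB_CONSTANT
    qq = COULOMB_CONSTANT * box.charges[iu] * box.charges[ju]
    energy = float(np.sum(4.0 * eps * (s6 * s6 - s6)) + np.sum(qq / r))
    # dE/dr
    dedr = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r - qq / r**2
    fpair = (-dedr / r)[:, None] * diff
    np.add.at(forces, iu, fpair)
    np.add.at(forces, ju, -fpair)
    return energy, forces


def _restraints(box: SimulationBox, positions: np.ndarray,
                ) -> tuple[float, np.ndarray]:
    forces = np.zeros_like(positions)
    energy = 0.0
    if len(box.bonds):
        a, b = box.bonds[:, 0], box.bonds[:, 1]
        diff = _min_image(positions[a] - positions[b], box.edge)
        r = np.linalg.norm(diff, axis=-1).clip(1e-9)
        dr = r - box.bond_lengths
        energy += float(np.sum(BOND_FORCE_CONSTANT * dr**2))
        f = (-2.0 * BOND_FORCE_CONSTANT * dr / r)[:, None] * diff
        np.add.at(forces, a, f)
        np.add.at(forces, b, -f)
    if len(box.angles):
        i, c, k = box.angles[:, 0], box.angles[:, 1], box.angles[:, 2]
        u = _min_image(positions[i] - positions[c], box.edge)
        v = _min_image(positions[k] - positions[c], box.edge)
        nu = np.linalg.norm(u, axis=-1).clip(1e-9)
        nv = np.linalg.norm(v, axis=-1).clip(1e-9)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cosv = np.clip(np.sum(uh * vh, axis=-1), -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cosv)
        sinv = np.sqrt(1.0 - cosv**2)
        dtheta = theta - box.angle_values
        energy += float(np.sum(ANGLE_FORCE_CONSTANT * dtheta**2))
        dedt = 2.0 * ANGLE_FORCE_CONSTANT * dtheta
        grad_i = (cosv[:, None] * uh - vh) / (nu * sinv)[:, None]
        grad_k = (cosv[:, None] * vh - uh) / (nv * sinv)[:, None]
        f_i = -dedt[:, None] * grad_i
        f_k = -dedt[:, None] * grad_k
        np.add.at(forces, i, f_i)
        np.add.at(forces, k, f_k)
        np.add.at(forces, c, -(f_i + f_k))
    return energy, forces


def system_energy_forces(box: SimulationBox, positions: np.ndarray | None = None,
                         cutoff: float | None = 9.0,
                         ) -> tuple[float, np.ndarray]:
    """Total potential energy (kcal/mol) and forces (kcal/mol/Å)."""
    pos = box.positions if positions is None else positions
    e_nb, f_nb = _nonbonded(box, pos, cutoff)
    e_r, f_r = _restraints(box, pos)
    return e_nb + e_r, f_nb + f_r


def minimize_box(box: SimulationBox, cutoff: float | None = 9.0,
                 max_iterations: int = 500,
                 force_tol: float = 1.0) -> SimulationBox:
    """Local energy minimization (L-BFGS); never returns a worse state."""
    from scipy.optimize import minimize as scipy_minimize
    x0 = box.positions.ravel().copy()
    e0, _ = system_energy_forces(box, cutoff=cutoff)

    def fun(x: np.ndarray):
        e, f = system_energy_forces(box, x.reshape(-1, 3), cutoff)
        return e, -f.ravel()

    res = scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                         options={"maxiter": max_iterations, "gtol": force_tol})
    best = res.x if res.fun <= e0 else x0
    out = SimulationBox(**{**box.__dict__, "positions": best.reshape(-1, 3).copy()})
    out.metadata = dict(box.metadata)
    out.metadata["minimized_energy"] = float(min(res.fun, e0))
    return out


def run_md(box: SimulationBox, settings: MDSettings,
           seed: int | np.random.Generator = 0,
           divergence_threshold: float = 1e8,
           observer=None) -> list[TrajectoryFrame]:
    """Velocity-Verlet NVT trajectory; frames recorded after equilibration.

    The Andersen thermostat re-draws each atom's velocity from the
    Maxwell–Boltzmann distribution with probability rate·dt per step
    (``thermostat_rate = 0`` gives plain NVE). Identical seeds give
    identical trajectories. ``observer(step, positions, velocities,
    potential_energy)`` is called after every step when provided.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = box.positions.copy()
    masses = box.masses[:, None]
    kt = KB_MD * settings.temperature
    vel = (box.velocities.copy() if np.any(box.velocities)
           else rng.normal(0.0, np.sqrt(kt / masses), pos.shape))
    dt = settings.timestep
    collision_prob = settings.thermostat_rate * dt / 1000.0  # rate is per ps
    energy, forces = system_energy_forces(box, pos, settings.cutoff)
    if not np.isfinite(energy) or abs(energy) > divergence_threshold:
        raise RuntimeError(
            f"initial energy {energy:.3g} kcal/mol exceeds the divergence "
            "threshold; minimize the box before running dynamics")
    accel = forces * ACCEL_CONVERSION / masses
    frames: list[TrajectoryFrame] = []
    total_steps = settings.equilibration_steps + settings.production_steps
    for step in range(1, total_steps + 1):
        vel += 0.5 * dt * accel
        pos = np.mod(pos + dt * vel, box.edge)
        energy, forces = system_energy_forces(box, pos, settings.cutoff)
        if not np.isfinite(energy) or abs(energy) > divergence_threshold:
            raise RuntimeError(
                f"energy diverged at step {step} (E={energy:.3g} kcal/mol); "
                "minimize the box before running dynamics")
        accel = forces * ACCEL_CONVERSION / masses
        vel += 0.5 * dt * accel
        if collision_prob > 0:
            hit = rng.random(len(pos)) < collision_prob
            if np.any(hit):
                vel[hit] = rng.normal(0.0, np.sqrt(kt / masses[hit]),
                                      (int(hit.sum()), 3))
        if observer is not None:
            observer(step, pos, vel, energy)
        production = step - settings.equilibration_steps
        if production > 0 and production % settings.record_interval == 0:
            frames.append(TrajectoryFrame(step, box.edge, pos.copy(),
                                          box.molecule_index.copy()))
    box.positions = pos
    box.velocities = vel
    return frames


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature, K."""
    ke = 0.5 * np.sum(masses[:, None] * velocities**2)
    return float(2.0 * ke / (3.0 * len(masses) * KB_MD))


# ---------------------------------------------------------------------------
# Neighbor counting


def _neighbor_thresholds(criterion: NeighborCriterion, elements_a: Sequence[str],
                         elements_b: Sequence[str]) -> np.ndarray:
    ra = np.array([criterion.radius_of(e) for e in elements_a])
    rb = np.array([criterion.radius_of(e) for e in elements_b])
    return ra[:, None] + rb[None, :] + criterion.catch_radius


def count_neighbors_bruteforce(frame: TrajectoryFrame, solute_index: int,
                               criterion: NeighborCriterion,
                               elements: Sequence[str]) -> int:
    """All-pairs neighbor count of solvent molecules around the solute."""
    solute_mask = frame.molecule_index == solute_index
    if not solute_mask.any():
        raise ValueError(f"no atoms belong to solute molecule {solute_index}")
    spos = frame.positions[solute_mask]
    opos = frame.positions[~solute_mask]
    if len(opos) == 0:
        return 0
    sel = np.asarray(elements)
    thresholds = _neighbor_thresholds(criterion, sel[solute_mask],
                                      sel[~solute_mask])
    diff = _min_image(spos[:, None, :] - opos[None, :, :], frame.box_edge)
    d = np.linalg.norm(diff, axis=-1)
    hit = (d <= thresholds).any(axis=0)
    return int(len(np.unique(frame.molecule_index[~solute_mask][hit])))


def count_neighbors_cellindex(frame: TrajectoryFrame, solute_index: int,
                              criterion: NeighborCriterion,
                              elements: Sequence[str]) -> int:
    """Cell-index neighbor count; exactly equals the brute-force count.

    Cells are at least as large as the largest neighbor threshold, so every
    qualifying pair lies in adjacent (periodically wrapped) cells. Boxes
    shorter than three cells fall back to brute force.
    """
    sel = np.asarray(elements)
    solute_mask = frame.molecule_index == solute_index
    if not solute_mask.any():
        raise ValueError(f"no atoms belong to solute molecule {solute_index}")
    if not (~solute_mask).any():
        return 0
    max_threshold = float(np.max(_neighbor_thresholds(
        criterion, sorted(set(sel)), sorted(set(sel)))))
    n_cells = int(frame.box_edge // max_threshold)
    if n_cells < 3:
        logger.info("box edge %.2f Å supports only %d cells of %.2f Å; "
                    "falling back to brute force", frame.box_edge, n_cells,
                    max_threshold)
        return count_neighbors_bruteforce(frame, solute_index, criterion, elements)
    cell_len = frame.box_edge / n_cells
    opos = frame.positions[~solute_mask]
    omol = frame.molecule_index[~solute_mask]
    oel = sel[~solute_mask]
    ocell = np.floor(opos / cell_len).astype(int) % n_cells
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for idx, c in enumerate(map(tuple, ocell)):
        buckets.setdefault(c, []).append(idx)
    neighbors: set[int] = set()
    spos = frame.positions[solute_mask]
    selements = sel[solute_mask]
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    for apos, ael in zip(spos, selements):
        cx, cy, cz = (np.floor(apos / cell_len).astype(int) % n_cells)
        cand: list[int] = []
        for dx, dy, dz in offsets:
            cand.extend(buckets.get(((cx + dx) % n_cells, (cy + dy) % n_cells,
                                     (cz + dz) % n_cells), ()))
        if not cand:
            continue
        cand = np.array(cand)
        d = np.linalg.norm(_min_image(opos[cand] - apos, frame.box_edge), axis=-1)
        ra = criterion.radius_of(ael)
        rb = np.array([criterion.radius_of(e) for e in oel[cand]])
        hit = d <= (ra + rb + criterion.catch_radius)
        neighbors.update(omol[cand[hit]].tolist())
    return len(neighbors)


@dataclass
class CoordinationEstimate:
    """Per-frame neighbor counts and their mean Z_ij."""

    per_frame_counts: np.ndarray
    n_frames: int

    @property
    def running_mean(self) -> float:
        return float(np.mean(self.per_frame_counts))

    @property
    def convergence(self) -> np.ndarray:
        """Cumulative mean after each recorded frame (Fig.-3-style series)."""
        counts = np.asarray(self.per_frame_counts, dtype=float)
        return np.cumsum(counts) / np.arange(1, len(counts) + 1)


def estimate_coordination_number(frames: Sequence[TrajectoryFrame],
                                 solute_index: int,
                                 criterion: NeighborCriterion,
                                 elements: Sequence[str],
                                 method: Literal["bruteforce", "cellindex"] = "cellindex",
                                 ) -> CoordinationEstimate:
    """Average neighbor count over all recorded frames."""
    if not frames:
        raise ValueError("trajectory has no recorded frames")
    counter = (count_neighbors_bruteforce if method == "bruteforce"
               else count_neighbors_cellindex)
    counts = np.array([counter(f, solute_index, criterion, elements)
                       for f in frames], dtype=int)
    return CoordinationEstimate(counts, len(frames))
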