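"""End-to-end orchestration: monomer set in, particle set out.

For every unordered molecule pair the pipeline runs the distance scan with
refinement, Boltzmann curves and the final dimer optimization; for every
ordered pair it runs the coordination-number MD protocol. The resulting
E^min / ⟨E⟩^min and Z matrices feed the Flory–Huggins and DPD repulsion
mapping. All stages are logged, all outputs carry the fully-resolved
configuration and package version, and reruns with the same seed are
bit-identical for the deterministic (sampling) stages.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, chemio, mdcoord, mesoparams, mmff, sampling
from .energy import EnergyModelSpec, PairPotential, assign_parameters

__all__ = ["PipelineConfig", "run_pipeline", "self_test"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline settings; defaults mirror the standard protocol."""

    molecules: list[str] = field(default_factory=lambda: ["H2O"])
    model: str = "mmff"               # "mmff" or "table" (generic LJ/Coulomb)
    n_sphere: int = 144
    n_rot: int = 16
    r_start: float = 3.0
    r_end: float = 16.0
    r_step: float = 0.5
    temperature: float = 298.0
    n_solvent: int = 400
    equilibration_steps: int = 10_000
    production_steps: int = 400_000
    record_interval: int = 100
    catch_radius: float = 1.0
    neighbor_method: str = "cellindex"
    run_md: bool = True
    diagonal_value: float = 24.83
    max_deviation: float = 20.0
    rho_dpd: float = 3.0
    zij_one: bool = False             # fixed Z_ij = 1 variant of the mapping
    seed: int = 1
    workers: int = 1
    out_dir: str = "pairforge_run"

    def __post_init__(self) -> None:
        if not self.molecules:
            raise ValueError("molecule list is empty")
        if self.model not in ("mmff", "table"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("n_sphere", "n_rot", "temperature", "n_solvent",
                     "record_interval", "catch_radius", "r_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_start >= self.r_end:
            raise ValueError("r_start must be below r_end")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must fit in a signed 32-bit integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _load_molecule(name: str) -> chemio.Molecule:
    if name in chemio.FIXTURE_NAMES:
        return chemio.fixture(name)
    path = Path(name)
    if path.suffix == ".txyz":
        return chemio.read_tinker_xyz(path)
    return chemio.read_xyz(path)


def _pair_potential(mol_i, mol_j, config: PipelineConfig) -> PairPotential:
    if config.model == "mmff":
        return PairPotential.from_mmff(mol_i, mol_j)
    return PairPotential.from_generic(mol_i, mol_j, EnergyModelSpec())


def _scan_pair(mol_i, mol_j, config: PipelineConfig, out_dir: Path) -> dict:
    """Scan, refine and optimize one unordered pair; write curve/geometry files."""
    potential = _pair_potential(mol_i, mol_j, config)
    sampler = sampling.DimerSampler(mol_i, mol_j, potential,
                                    config.n_sphere, config.n_rot)
    scan = sampling.scan_distance_grid(sampler, config.r_start, config.r_end,
                                       config.r_step, config.temperature)
    best, history = sampling.refine_minimum(scan, sampler, config.temperature)
    backend = "mmff" if config.model == "mmff" else "rigid"
    optimized = sampling.optimize_dimer(sampler, best.best_config, backend)
    e_mean_min = min(s.e_mean for s in itertools.chain(scan, *history))

    tag = f"{mol_i.name}-{mol_j.name}"
    curves = sampling.extract_curves(scan)
    curves.to_csv(out_dir / f"curves_{tag}.csv", index=False)
    ci, cj = sampler.config_coords(best.best_config)
    elements = mol_i.elements + mol_j.elements
    chemio.write_xyz([(np.vstack([ci, cj]), elements)],
                     out_dir / f"cstar_{tag}.xyz", comment=f"C* {tag}")
    chemio.write_xyz([(np.vstack([optimized.coords_i, optimized.coords_j]),
                       elements)],
                     out_dir / f"optimized_{tag}.xyz",
                     comment=f"optimized dimer {tag}")
    summary = {
        "pair": [mol_i.name, mol_j.name],
        "r_cstar": best.distance,
        "e_cstar": best.e_cstar,
        "e_mean_at_cstar": best.e_mean,
        "e_mean_min": e_mean_min,
        "e_min": optimized.e_min,
        "r_min": optimized.r_min,
        "optimizer_backend": optimized.backend,
        "center_convention": sampler.center_mode,
        "n_configurations_per_distance": sampler.n_configurations,
    }
    _write_json(out_dir / f"dimer_{tag}.json", summary, config)
    return summary


def _coordination_pair(mol_i, mol_j, config: PipelineConfig, out_dir: Path,
                       seed: int) -> dict:
    """Coordination MD for the ordered pair (solute i in solvent j)."""
    vol = chemio.vabc_volume(mol_j)
    edge = mdcoord.box_edge_length(config.n_solvent, vol)
    rng = np.random.default_rng(seed)
    box = mdcoord.build_solvent_box(mol_j, config.n_solvent, edge, rng)
    box = mdcoord.insert_solute(box, mol_i)
    settings = mdcoord.MDSettings(
        temperature=config.temperature,
        equilibration_steps=config.equilibration_steps,
        production_steps=config.production_steps,
        record_interval=config.record_interval,
        cutoff=min(9.0, edge / 2.0 * 0.99))
    box = mdcoord.minimize_box(box, cutoff=settings.cutoff)
    frames = mdcoord.run_md(box, settings, rng)
    criterion = mdcoord.NeighborCriterion(catch_radius=config.catch_radius)
    estimate = mdcoord.estimate_coordination_number(
        frames, box.solute_index, criterion, box.elements,
        method=config.neighbor_method)
    tag = f"{mol_i.name}-in-{mol_j.name}"
    np.savetxt(out_dir / f"counts_{tag}.csv",
               np.column_stack([np.arange(1, estimate.n_frames + 1),
                                estimate.per_frame_counts,
                                estimate.convergence]),
               delimiter=",", header="frame,count,cumulative_mean", comments="")
    result = {
        "solute": mol_i.name, "solvent": mol_j.name, "z": estimate.running_mean,
        "n_frames": estimate.n_frames, "box_edge": edge,
        "removed_on_insertion": box.metadata.get("removed_on_insertion", 0),
    }
    _write_json(out_dir / f"coordination_{tag}.json", result, config)
    return result


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    doc = dict(payload)
    doc["config"] = asdict(config)
    doc["version"] = __version__
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run scans, MD and the repulsion mapping for a whole molecule set.

    Returns the result bundle (also written to ``config.out_dir`` with a
    manifest). Failures are recorded per pair and the remaining pairs still
    run; the bundle's ``failed`` list is non-empty in that case.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    molecules = []
    backend = "mmff" if config.model == "mmff" else "table"
    for name in config.molecules:
        mol = _load_molecule(name)
        molecules.append(assign_parameters(mol, backend=backend))
    names = [m.name for m in molecules]
    n = len(molecules)
    e_min = np.zeros((n, n))
    e_mean_min = np.zeros((n, n))
    z = np.ones((n, n))
    failed: list[dict] = []
    timings: dict[str, float] = {}

    for i, j in itertools.combinations_with_replacement(range(n), 2):
        tag = f"scan:{names[i]}-{names[j]}"
        t0 = time.time()
        try:
            summary = _scan_pair(molecules[i], molecules[j], config, out_dir)
            e_min[i, j] = e_min[j, i] = summary["e_min"]
            e_mean_min[i, j] = e_mean_min[j, i] = summary["e_mean_min"]
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage %s failed", tag)
            failed.append({"stage": tag, "error": str(exc)})
        timings[tag] = time.time() - t0
        logger.info("%s done in %.1f s", tag, timings[tag])

    if config.run_md and not config.zij_one:
        for i, j in itertools.product(range(n), repeat=2):
            tag = f"md:{names[i]}-in-{names[j]}"
            t0 = time.time()
            try:
                result = _coordination_pair(molecules[i], molecules[j], config,
                                            out_dir, seed=config.seed + i * n + j)
                z[i, j] = result["z"]
            except Exception as exc:  # noqa: BLE001
                logger.exception("stage %s failed", tag)
                failed.append({"stage": tag, "error": str(exc)})
            timings[tag] = time.time() - t0
            logger.info("%s done in %.1f s", tag, timings[tag])

    raw_a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            delta = mesoparams.differential_energy_z(e_mean_min, z, i, j)
            chi = mesoparams.flory_huggins(delta, config.temperature)
            raw_a[i, j] = mesoparams.dpd_repulsion(
                chi, config.rho_dpd, config.temperature)
    particle_set = None
    if n >= 2:
        try:
            particle_set = mesoparams.scale_particle_set(
                raw_a, names, config.diagonal_value, config.max_deviation,
                config.rho_dpd, config.temperature)
            mesoparams.export_particle_set(
                particle_set, out_dir / "particle_set",
                extra_metadata={"e_mean_min": e_mean_min.tolist(),
                                "z": z.tolist(), "config": asdict(config),
                                "zij_one": config.zij_one})
        except ValueError as exc:
            failed.append({"stage": "particle-set", "error": str(exc)})

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "timings": timings,
        "failed": failed,
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(out_dir.iterdir()) if p.name != "manifest.json"},
        "wall_time": time.time() - t_start,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "names": names, "e_min": e_min, "e_mean_min": e_mean_min, "z": z,
        "raw_a": raw_a, "particle_set": particle_set, "failed": failed,
        "manifest": manifest,
    }


def self_test(verbose: bool = False) -> dict:
    """Reduced installation check: small water–water scan plus a short MD.

    Verifies the configuration-count invariant, the ⟨E⟩ ≥ E^C* inequality on
    every scanned distance, agreement of the two neighbor counters, and the
    repulsion-mapping fixed points. Returns a report dict with a ``passed``
    flag and the names of any failed checks.
    """
    checks: dict[str, bool] = {}
    water = assign_parameters(chemio.fixture("H2O"), backend="table")
    potential = PairPotential.from_generic(water, water)
    sampler = sampling.DimerSampler(water, water, potential, n_sphere=16, n_rot=4)
    scan = sampling.scan_distance_grid(sampler, 2.0, 8.0, 0.5)
    checks["configuration_count"] = sampler.n_configurations == 16 * 16 * 4
    checks["scan_grid_length"] = len(scan) == 13
    checks["mean_above_minimum"] = all(s.e_mean >= s.e_cstar - 1e-9 for s in scan)
    checks["scan_has_attractive_minimum"] = min(s.e_cstar for s in scan) < 0

    edge = mdcoord.box_edge_length(8, chemio.vabc_volume(water))
    box = mdcoord.build_solvent_box(water, 8, edge, seed=7)
    box = mdcoord.insert_solute(box, water)
    box = mdcoord.minimize_box(box, cutoff=edge / 2 * 0.99)
    settings = mdcoord.MDSettings(equilibration_steps=100, production_steps=400,
                                  record_interval=50, cutoff=edge / 2 * 0.99)
    frames = mdcoord.run_md(box, settings, seed=7)
    checks["md_recorded_frames"] = len(frames) == 8
    criterion = mdcoord.NeighborCriterion()
    agree = all(
        mdcoord.count_neighbors_bruteforce(f, box.solute_index, criterion, box.elements)
        == mdcoord.count_neighbors_cellindex(f, box.solute_index, criterion, box.elements)
        for f in frames)
    checks["cellindex_equals_bruteforce"] = agree
    checks["dpd_diagonal"] = abs(mesoparams.dpd_repulsion(0.0, 3.0, 300.0, 300.0)
                                 - 25.0) < 1e-12

    failed = sorted(name for name, ok in checks.items() if not ok)
    report = {"passed": not failed, "checks": checks, "failed": failed}
    if verbose:
        for name, ok in checks.items():
            print(f"{'PASS' if ok else 'FAIL'}  {name}")
    return report
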