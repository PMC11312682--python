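"""Box construction, the MD engine, and coordination-number counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairforge.chemio import AtomRecord, Molecule, TrajectoryFrame, fixture
from pairforge.constants import KB_MD
from pairforge.energy import assign_parameters
from pairforge.mdcoord import (CoordinationEstimate, MDSettings,
                               NeighborCriterion, box_edge_length,
                               build_solvent_box, count_neighbors_bruteforce,
                               count_neighbors_cellindex,
                               estimate_coordination_number, insert_solute,
                               kinetic_temperature, minimize_box,
                               per_molecule_volume, run_md,
                               system_energy_forces, _min_image)

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


def _lj_molecule(sigma=3.0, epsilon=0.2, element="Ne", charge=0.0):
    return Molecule("lj", [AtomRecord(element, np.zeros(3), charge=charge,
                                      sigma=sigma, epsilon=epsilon)])


@pytest.fixture(scope="module")
def water():
    return assign_parameters(fixture("H2O"), backend="table")


# --- box construction --------------------------------------------------------


def test_water_per_molecule_volume_from_density():
    # molar mass 18.015 g/mol, density 0.99705 g/cm3 at 298 K
    assert per_molecule_volume(18.015, 0.99705) == pytest.approx(30.00, abs=0.01)


def test_box_edge_single_water():
    assert box_edge_length(1, 17.35) == pytest.approx(np.cbrt(30.00), abs=1e-9)


def test_box_edge_400_waters_and_density():
    edge = box_edge_length(400, 17.35)
    assert edge == pytest.approx(np.cbrt(12000.0), abs=1e-9)
    assert 400 / edge**3 == pytest.approx(1.0 / 30.00, abs=1e-9)


def test_box_edge_cube_root_scaling():
    assert box_edge_length(8 * 50, 20.0) == pytest.approx(
        2.0 * box_edge_length(50, 20.0), rel=1e-12)


def test_box_edge_rejects_nonpositive():
    with pytest.raises(ValueError):
        box_edge_length(0, 17.35)


def test_build_box_spacing_and_determinism(water):
    edge = 12.0
    box1 = build_solvent_box(water, 8, edge, seed=4)
    box2 = build_solvent_box(water, 8, edge, seed=4)
    assert box1.n_molecules == 8
    np.testing.assert_array_equal(box1.positions, box2.positions)
    d = np.linalg.norm(_min_image(
        box1.positions[:, None] - box1.positions[None, :], edge), axis=-1)
    inter = box1.molecule_index[:, None] != box1.molecule_index[None, :]
    assert d[inter].min() >= 1.5
    assert (box1.positions >= 0).all() and (box1.positions < edge).all()


def test_insert_solute_removal_matches_bruteforce_recount(water):
    edge = box_edge_length(27, 17.35)
    box = build_solvent_box(water, 27, edge, seed=9)
    hac = assign_parameters(fixture("HAc"), backend="table")
    out = insert_solute(box, hac)
    # independent recount of overlaps against the pre-insertion box
    from pairforge._elements import VDW_RADIUS
    from pairforge.chemio import molecule_center
    solute_coords = hac.coords - molecule_center(hac) + edge / 2.0
    r_sol = np.array([VDW_RADIUS[e] for e in hac.elements])
    removed = set()
    for mid in range(box.n_molecules):
        mask = box.molecule_index == mid
        pos = box.positions[mask]
        r_solv = np.array([VDW_RADIUS[e]
                           for e, m in zip(box.elements, mask) if m])
        d = np.linalg.norm(_min_image(
            solute_coords[:, None] - pos[None, :], edge), axis=-1)
        if (d < 0.8 * (r_sol[:, None] + r_solv[None, :])).any():
            removed.add(mid)
    assert out.metadata["removed_on_insertion"] == len(removed)
    assert out.solute_index == out.n_molecules - 1


def test_insert_solute_into_empty_box(water):
    box = build_solvent_box(water, 1, 30.0, seed=1)
    # push the lone solvent far from the center so nothing is removed
    box.positions += 10.0
    box.positions %= box.edge
    out = insert_solute(box, water)
    assert out.metadata["removed_on_insertion"] in (0, 1)


# --- forces and integration --------------------------------------------------


def test_forces_match_numerical_gradient(water):
    box = build_solvent_box(water, 2, 8.0, seed=3)
    e0, forces = system_energy_forces(box, cutoff=3.9)
    h = 1e-6
    numeric = np.zeros_like(forces)
    for a in range(box.n_atoms):
        for k in range(3):
            plus = box.positions.copy()
            minus = box.positions.copy()
            plus[a, k] += h
            minus[a, k] -= h
            ep, _ = system_energy_forces(box, plus, cutoff=3.9)
            em, _ = system_energy_forces(box, minus, cutoff=3.9)
            numeric[a, k] = -(ep - em) / (2 * h)
    np.testing.assert_allclose(forces, numeric, atol=5e-4)


def test_minimize_overlapping_lj_atoms_separate():
    a, b = _lj_molecule(), _lj_molecule()
    edge = 20.0
    from pairforge.mdcoord import _assemble
    box = _assemble(edge, [(a, np.array([[8.0, 8.0, 8.0]])),
                           (b, np.array([[10.0, 8.0, 8.0]]))])
    e_before, _ = system_energy_forces(box, cutoff=None)
    out = minimize_box(box, cutoff=None, max_iterations=300, force_tol=1e-8)
    e_after, _ = system_energy_forces(out, cutoff=None)
    assert e_after <= e_before
    d = np.linalg.norm(_min_image(out.positions[0] - out.positions[1], edge))
    assert d == pytest.approx(3.0 * SIXTH_ROOT_2, abs=1e-2)


def test_minimize_is_fixed_point(water):
    box = build_solvent_box(water, 4, 12.0, seed=6)
    once = minimize_box(box, cutoff=5.9)
    twice = minimize_box(once, cutoff=5.9)
    e1, _ = system_energy_forces(once, cutoff=5.9)
    e2, _ = system_energy_forces(twice, cutoff=5.9)
    assert e2 <= e1 + 1e-9


def _lj_gas_box(n=10, edge=16.0, seed=0):
    from pairforge.mdcoord import _assemble
    rng = np.random.default_rng(seed)
    m = _lj_molecule()
    sites = []
    grid = np.linspace(1.5, edge - 1.5, 3)
    for x in grid:
        for y in grid:
            for z in grid:
                sites.append((x, y, z))
    placed = [(m, np.array([sites[k]]) + rng.normal(0, 0.1, 3))
              for k in range(n)]
    return _assemble(edge, placed)


def test_thermostat_holds_target_temperature():
    box = _lj_gas_box(n=10)
    settings = MDSettings(equilibration_steps=0, production_steps=5000,
                          record_interval=5000, thermostat_rate=25.0,
                          cutoff=None, temperature=298.0)
    temps = []
    run_md(box, settings, seed=12,
           observer=lambda s, p, v, e: temps.append(
               kinetic_temperature(v, box.masses)))
    mean_t = np.mean(temps[1000:])
    assert abs(mean_t - 298.0) / 298.0 < 0.15


def test_nve_energy_drift_below_one_percent():
    box = _lj_gas_box(n=8)
    rng = np.random.default_rng(21)
    box.velocities = rng.normal(0, np.sqrt(KB_MD * 50.0 / box.masses[:, None]),
                                box.positions.shape)
    settings = MDSettings(equilibration_steps=0, production_steps=10_000,
                          record_interval=10_000, thermostat_rate=0.0,
                          cutoff=None, temperature=50.0)
    totals = []

    def observer(step, pos, vel, pe):
        ke = 0.5 * np.sum(box.masses[:, None] * vel**2) / 4.184e-4
        totals.append(pe + ke)

    run_md(box, settings, seed=3, observer=observer)
    totals = np.asarray(totals)
    scale = max(abs(totals[0]), 0.1)
    assert np.max(np.abs(totals - totals[0])) / scale < 0.01


def test_md_zero_production_steps_gives_empty_trajectory(water):
    box = build_solvent_box(water, 2, 10.0, seed=5)
    settings = MDSettings(equilibration_steps=10, production_steps=0,
                          record_interval=1, cutoff=4.9)
    assert run_md(box, settings, seed=1) == []


def test_md_same_seed_identical_trajectory(water):
    settings = MDSettings(equilibration_steps=20, production_steps=60,
                          record_interval=20, cutoff=4.9)
    frames = []
    for _ in range(2):
        box = build_solvent_box(water, 3, 10.0, seed=8)
        frames.append(run_md(box, settings, seed=13))
    assert len(frames[0]) == 3
    for f1, f2 in zip(*frames):
        np.testing.assert_array_equal(f1.positions, f2.positions)


def test_md_positions_stay_wrapped(water):
    box = build_solvent_box(water, 3, 10.0, seed=8)
    settings = MDSettings(equilibration_steps=0, production_steps=100,
                          record_interval=10, cutoff=4.9)
    for frame in run_md(box, settings, seed=2):
        assert (frame.positions >= 0).all()
        assert (frame.positions < box.edge).all()


def test_md_divergence_raises():
    a, b = _lj_molecule(), _lj_molecule()
    from pairforge.mdcoord import _assemble
    box = _assemble(10.0, [(a, np.array([[5.0, 5.0, 5.0]])),
                           (b, np.array([[5.05, 5.0, 5.0]]))])  # deep overlap
    settings = MDSettings(equilibration_steps=0, production_steps=100,
                          record_interval=10, cutoff=None)
    with pytest.raises(RuntimeError, match="diverge|minimize"):
        run_md(box, settings, seed=1, divergence_threshold=1e4)


@settings(deadline=None)
@given(st.floats(1.0, 100.0),
       st.lists(st.floats(-500, 500), min_size=3, max_size=3))
def test_minimum_image_bound(edge, vec):
    d = np.linalg.norm(_min_image(np.array(vec), edge))
    assert d <= edge * np.sqrt(3.0) / 2.0 + 1e-9


# --- neighbor counting -------------------------------------------------------


def _random_frame(rng, edge=15.0, n_solvent=30, atoms_per_molecule=2):
    n_solute_atoms = 3
    n_total = n_solute_atoms + n_solvent * atoms_per_molecule
    positions = rng.uniform(0, edge, (n_total, 3))
    mol_index = np.concatenate([
        np.zeros(n_solute_atoms, dtype=int),
        1 + np.repeat(np.arange(n_solvent), atoms_per_molecule)])
    elements = rng.choice(["O", "H", "C"], size=n_total).tolist()
    return TrajectoryFrame(0, edge, positions, mol_index), elements


def test_lone_solute_has_zero_neighbors():
    frame = TrajectoryFrame(0, 10.0, np.array([[5.0, 5.0, 5.0]]),
                            np.array([0]))
    assert count_neighbors_bruteforce(frame, 0, NeighborCriterion(), ["O"]) == 0
    assert count_neighbors_cellindex(frame, 0, NeighborCriterion(), ["O"]) == 0


def test_threshold_is_inclusive():
    # O-O threshold: 1.52 + 1.52 + 1.0 = 4.04 Å, counted at exactly 4.04
    crit = NeighborCriterion(catch_radius=1.0)
    for offset, expected in [(0.0, 1), (-0.1, 1), (+1e-6, 0)]:
        frame = TrajectoryFrame(
            0, 30.0, np.array([[5.0, 5.0, 5.0], [5.0 + 4.04 + offset, 5.0, 5.0]]),
            np.array([0, 1]))
        assert count_neighbors_bruteforce(frame, 0, crit, ["O", "O"]) == expected


def test_neighbor_across_periodic_boundary():
    crit = NeighborCriterion(catch_radius=1.0)
    edge = 20.0
    frame = TrajectoryFrame(
        0, edge, np.array([[0.5, 0.5, 0.5], [edge - 0.5, 0.5, 0.5]]),
        np.array([0, 1]))
    assert count_neighbors_bruteforce(frame, 0, crit, ["O", "O"]) == 1
    assert count_neighbors_cellindex(frame, 0, crit, ["O", "O"]) == 1


def test_neighbor_relation_is_symmetric():
    rng = np.random.default_rng(17)
    crit = NeighborCriterion()
    for _ in range(30):
        pos = rng.uniform(0, 15.0, (4, 3))
        frame = TrajectoryFrame(0, 15.0, pos, np.array([0, 0, 1, 1]))
        elements = ["O", "H", "C", "H"]
        a = count_neighbors_bruteforce(frame, 0, crit, elements)
        b = count_neighbors_bruteforce(frame, 1, crit, elements)
        assert a == b


def test_cellindex_equals_bruteforce_on_many_random_frames():
    rng = np.random.default_rng(99)
    crit = NeighborCriterion(catch_radius=1.0)
    for _ in range(200):
        frame, elements = _random_frame(rng)
        assert (count_neighbors_cellindex(frame, 0, crit, elements)
                == count_neighbors_bruteforce(frame, 0, crit, elements))


def test_cellindex_small_box_fallback():
    rng = np.random.default_rng(5)
    crit = NeighborCriterion(catch_radius=1.0)
    frame, elements = _random_frame(rng, edge=8.0, n_solvent=10)
    assert (count_neighbors_cellindex(frame, 0, crit, elements)
            == count_neighbors_bruteforce(frame, 0, crit, elements))


def test_estimate_coordination_number_means():
    frames = [TrajectoryFrame(i, 30.0,
                              np.array([[5.0, 5.0, 5.0],
                                        [5.0 + 2.0 + i, 5.0, 5.0]]),
                              np.array([0, 1]))
              for i in range(3)]
    est = estimate_coordination_number(frames, 0, NeighborCriterion(),
                                       ["O", "O"], method="bruteforce")
    assert est.n_frames == 3
    assert est.running_mean == pytest.approx(np.mean(est.per_frame_counts))
    np.testing.assert_allclose(
        est.convergence,
        np.cumsum(est.per_frame_counts) / np.arange(1, 4))


def test_estimate_requires_frames():
    with pytest.raises(ValueError):
        estimate_coordination_number([], 0, NeighborCriterion(), [])


def test_coordination_estimate_simple_means():
    est = CoordinationEstimate(np.array([1, 2, 3]), 3)
    assert est.running_mean == pytest.approx(2.0)
    est5 = CoordinationEstimate(np.array([5] * 10), 10)
    assert est5.running_mean == pytest.approx(5.0)
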