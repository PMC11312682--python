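"""Fibonacci lattices, configuration enumeration, Boltzmann averaging,
distance refinement and dimer optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairforge.chemio import molecule_center
from pairforge.constants import KB_KCAL
from pairforge.energy import PairPotential
from pairforge.sampling import (DimerConfiguration, DimerSampler,
                                boltzmann_average, enumerate_configurations,
                                extract_curves, fibonacci_sphere,
                                optimize_dimer, orient_to_axis, refine_minimum,
                                scan_distance_grid)

SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


def _lj_pair_sampler(make_lj_atom, sigma=3.0, epsilon=1.0, n_sphere=1, n_rot=1):
    a, b = make_lj_atom(sigma, epsilon), make_lj_atom(sigma, epsilon)
    pot = PairPotential.from_generic(a, b)
    return DimerSampler(a, b, pot, n_sphere=n_sphere, n_rot=n_rot)


# --- Fibonacci lattice -------------------------------------------------------


def test_fibonacci_single_point_is_unit():
    lat = fibonacci_sphere(1)
    assert lat.points.shape == (1, 3)
    assert np.linalg.norm(lat.points[0]) == pytest.approx(1.0, abs=1e-12)


def test_fibonacci_rejects_nonpositive():
    with pytest.raises(ValueError):
        fibonacci_sphere(0)


def test_fibonacci_144_uniformity():
    lat = fibonacci_sphere(144)
    norms = np.linalg.norm(lat.points, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-12)
    # brute-force pairwise angular separation scan
    dots = np.clip(lat.points @ lat.points.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    min_angle = np.arccos(dots.max())
    ideal = np.sqrt(4.0 * np.pi / 144)
    assert 0.5 * ideal <= min_angle <= 1.5 * ideal
    # near-uniform coverage: centroid close to the origin
    assert np.linalg.norm(lat.points.mean(axis=0)) < 0.05


def test_fibonacci_points_distinct():
    lat = fibonacci_sphere(200)
    d = np.linalg.norm(lat.points[:, None] - lat.points[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() > 1e-6


# --- orientation -------------------------------------------------------------


def test_orient_identity_when_already_on_axis(water_table):
    rot = orient_to_axis(water_table, np.zeros(3), np.array([1.0, 0, 0]), +1)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)


def test_orient_antiparallel_uses_fallback(water_table):
    rot = orient_to_axis(water_table, np.zeros(3), np.array([-1.0, 0, 0]), +1)
    mapped = rot @ np.array([-1.0, 0, 0])
    np.testing.assert_allclose(mapped, [1.0, 0, 0], atol=1e-10)
    np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)


def test_orient_random_points_postcondition(water_table):
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.normal(size=3)
        p /= np.linalg.norm(p)
        for sign in (+1, -1):
            rot = orient_to_axis(water_table, np.zeros(3), p, sign)
            mapped = rot @ p
            assert abs(mapped @ np.array([1.0, 0, 0])) == pytest.approx(1.0, abs=1e-10)
            assert np.sign(mapped[0]) == sign


# --- enumeration -------------------------------------------------------------


def test_enumeration_count_and_default_plan(water_table):
    pot = PairPotential.from_generic(water_table, water_table)
    sampler = DimerSampler(water_table, water_table, pot, n_sphere=144, n_rot=16)
    assert sampler.n_configurations == 331_776
    small = DimerSampler(water_table, water_table, pot, n_sphere=3, n_rot=2)
    configs = list(enumerate_configurations(water_table, water_table, 4.0, pot,
                                            n_sphere=3, n_rot=2))
    assert len(configs) == small.n_configurations == 3 * 3 * 2
    assert all(c.energy is not None for c in configs)


def test_single_configuration_case(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom, n_sphere=1, n_rot=1)
    e = sampler.energies(3.0)
    assert e.shape == (1, 1, 1)


def test_spherical_symmetry_all_energies_equal(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom, n_sphere=2, n_rot=2)
    e = sampler.energies(4.0)
    assert e.size == 8
    np.testing.assert_allclose(e, e.flat[0], atol=1e-12)


def test_center_separation_equals_r_fix(hac):
    from pairforge.energy import assign_parameters
    mol = assign_parameters(hac, backend="table")
    pot = PairPotential.from_generic(mol, mol)
    sampler = DimerSampler(mol, mol, pot, n_sphere=5, n_rot=3)
    rng = np.random.default_rng(2)
    for _ in range(10):
        cfg = DimerConfiguration(4.75, int(rng.integers(5)),
                                 int(rng.integers(5)), int(rng.integers(3)))
        ci, cj = sampler.config_coords(cfg)
        assert np.linalg.norm(ci.mean(0) - cj.mean(0)) == pytest.approx(
            4.75, abs=1e-9)


def test_rejects_nonpositive_distance(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom)
    with pytest.raises(ValueError):
        sampler.energies(0.0)


# --- Boltzmann averaging -----------------------------------------------------


def test_boltzmann_equal_energies():
    assert boltzmann_average([2.5, 2.5, 2.5], 298.0) == pytest.approx(2.5)


def test_boltzmann_ln2_closed_form():
    # energies {0, kT ln 2} -> weights {1, 1/2} -> mean E/3
    t = 298.0
    e = KB_KCAL * t * np.log(2.0)
    assert boltzmann_average([0.0, e], t) == pytest.approx(e / 3.0, rel=1e-12)


def test_boltzmann_high_temperature_is_arithmetic_mean():
    assert boltzmann_average([0.0, 1.0, 2.0], 1e9) == pytest.approx(1.0, abs=1e-5)


def test_boltzmann_low_temperature_is_minimum():
    assert boltzmann_average([0.0, 1.0, 2.0], 1e-3) == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=30),
       st.floats(-100, 100), st.floats(10, 2000))
def test_boltzmann_shift_invariance(energies, shift, temperature):
    base = boltzmann_average(energies, temperature)
    shifted = boltzmann_average([e + shift for e in energies], temperature)
    assert shifted - shift == pytest.approx(base, abs=1e-10)


def test_boltzmann_empty_input():
    with pytest.raises(ValueError):
        boltzmann_average([], 298.0)


# --- scanning and refinement -------------------------------------------------


def test_default_grid_has_27_distances(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom)
    scan = scan_distance_grid(sampler, 3.0, 16.0, 0.5)
    assert len(scan) == 27
    assert scan[0].distance == 3.0 and scan[-1].distance == 16.0


def test_single_point_grid(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom)
    scan = scan_distance_grid(sampler, 5.0, 5.0, 0.5)
    assert len(scan) == 1 and scan[0].distance == 5.0


def test_mean_above_minimum_chain(water_table):
    pot = PairPotential.from_generic(water_table, water_table)
    sampler = DimerSampler(water_table, water_table, pot, n_sphere=8, n_rot=4)
    scan = scan_distance_grid(sampler, 2.5, 8.0, 0.5)
    for s in scan:
        assert s.e_mean >= s.e_cstar - 1e-9
    e_at_end = scan[-1].e_cstar
    assert e_at_end >= min(s.e_cstar for s in scan)


def test_refinement_recovers_lj_minimum(make_lj_atom):
    sigma = 3.0
    sampler = _lj_pair_sampler(make_lj_atom, sigma=sigma)
    scan = scan_distance_grid(sampler, 3.0, 16.0, 0.5)
    best, history = refine_minimum(scan, sampler)
    analytic = sigma * SIXTH_ROOT_2
    assert best.distance == pytest.approx(analytic, abs=0.01)
    assert best.e_cstar <= min(s.e_cstar for s in scan) + 1e-12
    assert len(history) == 2


def test_refinement_flat_curve_takes_first_point(make_lj_atom):
    # far apart the LJ curve is numerically flat at double precision
    sampler = _lj_pair_sampler(make_lj_atom, epsilon=1e-30)
    scan = scan_distance_grid(sampler, 100.0, 102.0, 0.5)
    best, _ = refine_minimum(scan, sampler)
    # ties resolve to the first grid point at each stage, so the result is
    # the lower edge of the finest refinement window: 100 - 0.5 - 0.1
    assert best.distance == pytest.approx(99.4, abs=1e-9)


def test_extract_curves_table(make_lj_atom):
    sampler = _lj_pair_sampler(make_lj_atom)
    scan = scan_distance_grid(sampler, 3.0, 16.0, 0.5)
    table = extract_curves(scan)
    assert list(table.columns) == ["r", "e_cstar", "e_mean"]
    assert len(table) == 27
    assert (table.e_mean >= table.e_cstar - 1e-9).all()
    # LJ tail approaches zero from below, monotonically
    tail = table[table.r >= 5.0].e_cstar.to_numpy()
    assert np.all(np.diff(tail) > 0) and np.all(tail < 0)


# --- optimization ------------------------------------------------------------


def test_rigid_optimization_reaches_lj_minimum(make_lj_atom):
    sigma = 3.0
    sampler = _lj_pair_sampler(make_lj_atom, sigma=sigma)
    start = DimerConfiguration(1.5 * sigma, 0, 0, 0)
    opt = optimize_dimer(sampler, start, backend="rigid")
    assert opt.r_min == pytest.approx(sigma * SIXTH_ROOT_2, abs=1e-3)
    assert opt.e_min == pytest.approx(-1.0, abs=1e-6)


def test_rigid_optimization_is_fixed_point_at_minimum(make_lj_atom):
    sigma = 3.0
    sampler = _lj_pair_sampler(make_lj_atom, sigma=sigma)
    start = DimerConfiguration(sigma * SIXTH_ROOT_2, 0, 0, 0)
    opt = optimize_dimer(sampler, start, backend="rigid")
    assert opt.r_min == pytest.approx(sigma * SIXTH_ROOT_2, abs=1e-6)


def test_acetic_acid_mmff_curve_has_single_minimum(hac):
    """Full-lattice MMFF94 scan of the acetic acid dimer: the Boltzmann
    curve over 3-16 Å must show exactly one minimum, near 4.9 Å."""
    pot = PairPotential.from_mmff(hac, hac)
    sampler = DimerSampler(hac, hac, pot)   # default 144 x 144 x 16 lattice
    scan = scan_distance_grid(sampler, 3.0, 16.0, 0.5)
    e_mean = np.array([s.e_mean for s in scan])
    r = np.array([s.distance for s in scan])
    slope_sign_changes = int(np.sum(np.diff(np.sign(np.diff(e_mean))) != 0))
    assert slope_sign_changes == 1
    assert 4.5 <= r[np.argmin(e_mean)] <= 5.5
    assert all(s.e_mean >= s.e_cstar - 1e-9 for s in scan)


def test_optimization_never_exceeds_start(water_table):
    pot = PairPotential.from_generic(water_table, water_table)
    sampler = DimerSampler(water_table, water_table, pot, n_sphere=6, n_rot=4)
    result, _ = sampler.sample_distance(3.5)
    opt = optimize_dimer(sampler, result.best_config, backend="rigid")
    assert opt.e_min <= result.e_cstar + 1e-9
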