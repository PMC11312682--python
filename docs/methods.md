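# Methods

## Interaction energy of rigid monomer pairs

The intermolecular energy of two monomers in a fixed relative placement is
the sum over all intermolecular atom pairs of a van der Waals term and a
Coulomb term. For rigid monomers this equals the dimer-minus-monomers total
energy difference, because all intramolecular terms cancel; computing the
intermolecular pair sum directly avoids implementing bonded terms in the
sampling hot loop.

Two models are provided:

- **Generic**: 12-6 Lennard-Jones with Lorentz–Berthelot (or geometric)
  combination and plain Coulomb electrostatics (C = 332.0637 kcal·Å/(mol·e²),
  unit dielectric). Parameters come from a bundled per-atom-type table whose
  charges are MMFF94 partial charges and whose LJ minima match the MMFF94
  homonuclear van der Waals minima of the fixture molecules.
- **MMFF94**: the buffered 14-7 form with the published buffering constants
  (0.07, 0.12) and buffered Coulomb 332.0716·q_iq_j/(r + 0.05 Å). Typing,
  charges and *pairwise* (R*_ij, ε_ij) — including MMFF94's donor/acceptor
  pair scaling — are taken from RDKit's MMFF94 implementation, which also
  serves as the all-atom optimizer backend. The vectorized pair evaluator is
  tested to agree with the force field's own interfragment energy to 1e-8
  kcal/mol, so batch sampling and the optimizer share one energy surface.

Interaction energies are defined as vdW + electrostatics throughout; the
model choice is recorded in output metadata. No distance cutoff is applied
in dimer sampling (the systems are finite and exactness is cheap); the MD
engine uses a cutoff (below).

## Configuration sampling

Unit spheres around the two monomer centers carry N_sphere points from the
golden-angle Fibonacci spiral (z uniform in (−1, 1), azimuth k·2π(1 − 1/φ)),
the standard offset variant without polar nodes. Each (point_i, point_j)
combination is realized by the minimal rotation taking the lattice point
onto the center–center axis (a fixed fallback axis handles the antiparallel
case deterministically); molecule j is additionally spun about the axis in
N_rot equal steps. Only molecule j is spun — spinning both monomers would
enumerate each relative orientation N_rot times. This yields exactly
N_sphere²·N_rot configurations per distance (331,776 at the 144/16
defaults).

**Centers.** The "center" of a molecule is the unweighted geometric mean of
its atom positions by default, with a center-of-mass switch. The geometric
convention is load-bearing: the reference acetic acid dimer has a
geometric-center separation of 4.91 Å but a center-of-mass separation of
only 3.89 Å, and sampling at the wrong convention misses the doubly
hydrogen-bonded minimum entirely.

**Distance protocol.** Coarse grid 3–16 Å in 0.5 Å steps (endpoints
inclusive), then re-scans of ±0.5 Å at 0.1 Å and ±0.1 Å at 0.01 Å around the
incumbent minimum. Window widths are one coarse step around the incumbent.
Ties in minimum energy resolve to the lowest (point_i, point_j, spin_k)
lexicographic index and, across distances, to the smallest distance, so
reruns are bit-identical.

**Boltzmann averages.** ⟨E⟩(r) = Σ E·w / Σ w with w = exp(−(E − ref)/k_BT),
k_B = 1.987204259e-3 kcal/(mol·K). The reference energy cancels between
numerator and denominator; the per-distance minimum is subtracted internally
for numerical stability, which is mathematically equivalent to any other
reference.

**Final optimization.** The refined C* seeds either a rigid-body
optimization over the 6 relative degrees of freedom (molecule i fixed, BFGS
on the sampling potential — the result can never exceed the C* energy), or
an unconstrained all-atom MMFF94 minimization in which the monomers relax
out of their input conformations. The all-atom interaction energy is the
dimer total minus the separately optimized monomer totals.

The initial monomer orientation (as read from the input file) weakly
influences which lattice configuration wins; the sampled minimum can shift
by the order of the lattice spacing. Fixture geometries are frozen so this
is reproducible.

## Box construction and MD

Box edges follow from van der Waals volumes via the water packing ratio:
one water occupies V_box = 30.00 Å³ of liquid at 298 K (molar mass over
density·N_A) against an additive vdW volume of 17.35 Å³, and
a = (N·(30.00/17.35)·V_vdW^X)^(1/3) for N molecules of X. vdW volumes use
the additive atomic-contribution scheme (e.g. H 7.24, C 20.58, O 14.71 Å³)
minus 5.92 Å³ per bond and ring corrections from the bond-graph cycle count;
the bundled fixtures contain no aromatic rings.

Solvent molecules are placed on a jittered cubic sublattice with random
orientations (seeded; no two atoms of different molecules closer than
1.5 Å), the solute is inserted at the box center, and solvent molecules with
any atom within 0.8 × (vdW radius sum) of a solute atom are removed — a
stated approximation to density-preserving insertion; the removal count is
recorded. The box is then energy-minimized (L-BFGS on the analytic
gradient) before dynamics.

The MD engine integrates velocity-Verlet at 1 fs with minimum-image cubic
periodicity and a 9 Å non-bonded cutoff (halved-edge-capped for small
boxes; no long-range correction). Intramolecular geometry is held near the
input structure by stiff harmonic bond (k = 300 kcal/mol/Å², auto-generated
from the bond graph) and angle (k = 100 kcal/mol/rad²) restraints, with
intramolecular non-bonded terms excluded — a deliberate simplification of
full bonded force-field terms that keeps molecules intact without constraint
algorithms. Temperature is controlled by an Andersen thermostat that
re-draws single-atom velocities from the Maxwell–Boltzmann distribution at a
collision rate of 25 ps⁻¹ per atom (rate 0 gives NVE; the integrator drifts
< 1% over 10⁴ steps on a small LJ system). One seeded RNG drives packing,
insertion and thermostat in fixed order, so trajectories are reproducible.
Defaults: 10,000 equilibration and 400,000 production steps, one frame per
100 steps.

## Coordination numbers

Two molecules are neighbors when any interatomic distance is ≤ the sum of
their Bondi vdW radii plus a catch radius (default 1 Å, inclusive
comparison). Per frame, the number of solvent molecules neighboring the
solute is counted either brute-force over all atom pairs or with a periodic
cell-index search whose cells are at least as large as the largest neighbor
threshold; the two counts are exactly equal by construction and this
equality is property-tested over a thousand random frames. Z_ij is the mean
over recorded frames, with the cumulative-mean series exported for
convergence inspection. The full 400-molecule, 400,000-step protocol is a
multi-hour validation run; the test suite exercises the protocol end-to-end
at reduced size and asserts the counter equivalence instead.

## Flory–Huggins and DPD mapping

χ_ij = ΔE_ij^Z / k_BT uses the coordination-weighted excess of the
Boltzmann-averaged minima by default; a Z_ij = 1 switch reproduces the
variant based solely on ⟨E_ij⟩^min. Repulsions follow
a_ij(T) = 75·k_BT/ρ_DPD + 3.4965·k_BT·χ_ij with the χ coefficient stored at
full precision as 1/0.286. Thermal energy is expressed in units where
k_B·300 K = 1; this reference temperature is a configuration knob, chosen
because it reproduces the conventional diagonal a_ii = 25·(298/300) = 24.83
at 298 K, and the convention is written into output metadata. ρ_DPD defaults
to 3, the standard DPD density. Off-diagonals of a finished set are
linearly rescaled about the diagonal so the smallest value sits exactly
max_deviation (default 20) below a_ii; the mapping is affine and monotone,
so repulsion rankings are preserved, and the base pair attaining the
minimum is recorded. The conservative DPD force kernel
a_ij(1 − r)·r̂ for r < 1 (zero beyond, continuous at the cutoff) is provided
as a standalone utility; dissipative/random forces and DPD integration are
out of scope.

## Fixtures and the synthetic parameter table

Bundled monomers (water, methane, ethane, methanol, ethanol, dimethyl
ether, acetic acid) are MMFF94-optimized geometries frozen as Tinker-XYZ
text with bonds and atom-type labels; acetic acid is the lowest of a
multi-conformer embedding. The generic parameter table is synthetic in the
sense that it is derived (MMFF94 charges, LJ parameters from MMFF94
homonuclear minima) rather than taken from a named biomolecular force
field; it exists so the generic model and the MD engine are fully
self-contained. Quantitative liquid-state properties from this table should
not be over-interpreted — it reproduces sensible dimer minima and hydrogen
bonding, not calibrated densities or heats of vaporization.

## Numerical notes and limitations

- Energies kcal/mol, distances Å, time fs, charges e, masses amu;
  k_B = 1.987204259e-3 kcal/(mol·K).
- Batch energies clip interatomic distances at 1e-12 Å so overlapping
  sampled configurations register as enormous repulsion rather than NaN;
  scalar terms raise on r = 0.
- Plain-XYZ input has no bonds; they are inferred by the covalent-radius
  distance rule (1.3 × radius sum) for volume estimation only. Tinker-XYZ
  bonds are authoritative, symmetrized with a warning if one-sided.
- The all-atom optimized dimer energy depends on the MMFF94 implementation.
  RDKit's MMFF94 gives −17.10 kcal/mol for the acetic acid dimer where other
  MMFF94 implementations report values up to ~0.5 kcal/mol lower; hydrogen
  bond geometry (1.63 Å H···O, 2.62 Å O···O) is implementation-stable.
- The restrained-geometry MD is an approximation to fully flexible
  force-field dynamics; its effect on absolute Z_ij values is unquantified,
  which is why coordination validation at full scale is reported rather than
  asserted.
- No Ewald/PME electrostatics, NPT, constraint algorithms, polarizable
  force fields, or torsional conformer searches of monomers.
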