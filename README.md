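# pairforge

Force-field pair interaction energies for small-molecule dimers, and their
mapping onto mesoscopic simulation parameters.

Mixing behavior of liquids is governed by *differential pair interaction
energies*: how much more (or less) favorably two molecules i and j interact
with each other than with their own kind,

```
ΔE_ij = E_ij − ½ (E_ii + E_jj)
```

and, with per-pair coordination numbers Z_ij (how many j molecules
simultaneously surround one i),

```
ΔE_ij^Z = ½ (Z_ij E_ij + Z_ji E_ji) − ½ (Z_ii E_ii + Z_jj E_jj).
```

`pairforge` computes every ingredient of that expression from classical
force fields and turns the result into Flory–Huggins parameters
χ_ij = ΔE_ij^Z / k_BT and Dissipative Particle Dynamics (DPD) repulsions
a_ij(T) = 75·k_BT/ρ_DPD + 3.4965·k_BT·χ_ij, i.e. complete, consistently
scaled particle sets for mesoscopic simulation engines. It is aimed at
molecular modelers who need robust pairwise interaction estimates for dozens
of molecule pairs without hand-curating each dimer.

What it does:

- **Exhaustive rigid-body dimer sampling.** For each center separation r, a
  Fibonacci sphere lattice of N_sphere points is placed around each monomer;
  rotating each monomer so its lattice point lies on the center–center axis,
  and spinning the second monomer through N_rot angles, enumerates
  N_sphere²·N_rot configurations (331,776 with the default 144/16). The
  distance grid (3–16 Å in 0.5 Å steps) is refined around the minimum to
  0.1 Å and then 0.01 Å, yielding the minimum sampled configuration C* and
  Boltzmann-averaged curves ⟨E⟩(r) at a chosen temperature.
- **Final optimization.** C* seeds an unconstrained optimization — either
  rigid-body (6 relative degrees of freedom) or all-atom under MMFF94 — to
  approximate the global minimum energy dimer E_ij^min.
- **Coordination numbers from MD.** A cubic box of N solvent molecules with
  an edge derived from van der Waals volumes (water occupies 30.00 Å³ of
  liquid against a 17.35 Å³ vdW volume; that packing ratio transfers to any
  molecule) hosts one solute; a velocity-Verlet/Andersen NVT trajectory is
  analyzed frame by frame, counting solvent molecules with any atom within
  the vdW-radius sum plus a 1 Å catch radius of any solute atom, by brute
  force or an exactly equivalent periodic cell-index search.
- **Particle sets.** χ and a_ij matrices with the standard linear
  off-diagonal rescaling (smallest a_ij pinned at a_ii − 20, with
  a_ii = 24.83 at 298 K), exported as CSV + JSON.

Energy models: a generic 12-6 Lennard-Jones + Coulomb model with a bundled
parameter table, and a genuine MMFF94 backend (typing, partial charges,
buffered 14-7 pair parameters and all-atom minimization via RDKit). The
vectorized MMFF94 pair evaluator is numerically identical to the force
field's own interfragment energy, which keeps full-lattice sampling at
hundreds of thousands of configurations per distance in the seconds range.

## Worked example: the acetic acid dimer

The acetic acid dimer is the classic stress test — a planar, doubly
hydrogen-bonded minimum:

```python
import numpy as np
from pairforge import fixture, DimerSampler, optimize_dimer
from pairforge.energy import PairPotential

hac = fixture("HAc")                          # MMFF94-optimized acetic acid monomer
potential = PairPotential.from_mmff(hac, hac) # exact MMFF94 intermolecular terms

sampler = DimerSampler(hac, hac, potential, n_sphere=144, n_rot=16)
result, _ = sampler.sample_distance(4.91, temperature=298.0)
print(f"E_C*(4.91 A)  = {result.e_cstar:7.2f} kcal/mol")
print(f"<E>(4.91 A)   = {result.e_mean:7.2f} kcal/mol")

optimized = optimize_dimer(sampler, result.best_config, backend="mmff")
print(f"E_min         = {optimized.e_min:7.2f} kcal/mol")
print(f"r_min         = {optimized.r_min:7.2f} A")
```

prints

```
E_C*(4.91 A)  =  -15.97 kcal/mol
<E>(4.91 A)   =  -15.59 kcal/mol
E_min         =  -17.10 kcal/mol
r_min         =    4.91 A
```

At a geometric-center separation of 4.91 Å the best of the 331,776 sampled
rigid configurations binds by 16.0 kcal/mol and the 298 K Boltzmann average
over all configurations by 15.6 kcal/mol; releasing all atomic degrees of
freedom gains a further ~1.1 kcal/mol while keeping the center separation,
and the optimized dimer shows the expected pair of ~1.63 Å hydrogen bonds
(~2.62 Å between donor and acceptor oxygens).

## Command line

```
pairforge dimer-scan   --mol-i HAc --mol-j HAc --model mmff --out-prefix out/hac
pairforge coordination --solute HAc --solvent H2O --n 400 --seed 1 --model table
pairforge particle-set --energies e_mean_min.csv --z z.csv --out-prefix my_set
pairforge run-all      --config pipeline.yaml
pairforge self-test
```

`run-all` executes every stage for all pairs of a molecule list and writes
curve tables, geometries, coordination series, the scaled particle set and a
manifest with content hashes under one run directory. Bundled fixture
monomers: `H2O`, `Me`, `Et`, `MeOH`, `EtOH`, `Me2O`, `HAc`.

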