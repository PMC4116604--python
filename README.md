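# mmffkit

A standalone, validated implementation of the **MMFF94 / MMFF94s**
molecular-mechanics force fields for all-atom small molecules: MMFF atom
typing and aromaticity perception, the bond-charge-increment charge model,
the seven-term energy expression with analytic Cartesian gradients, staged
("step-down") parameter lookup over the published tables, flat-bottomed
restraints, and constrained geometry optimization — plus a validation
harness and a command-line tool.

It is written for cheminformatics and drug-discovery work: computing and
decomposing conformational energies, relaxing ligand geometries (optionally
under restraints that keep a pose close to its original coordinates), and
scanning torsional profiles — all from plain SDF/MOL (V2000) input with
explicit hydrogens and formal charges.

## The model

The MMFF energy of a conformation is

```
E = Σ E_B(ij) + Σ E_A(ijk) + Σ E_BA(ijk) + Σ E_OOP(ijk;l) + Σ E_T(ijkl)
  + Σ E_vdW(ij) + Σ E_Q(ij)
```

with the canonical MMFF functional forms: a quartic-corrected harmonic bond
stretch (cubic-stretch constant −2 Å⁻¹), a cubic-corrected harmonic angle
bend (−0.4 rad⁻¹) with a cosine form for linear centers, a linear
stretch–bend coupling, a harmonic Wilson-angle out-of-plane term, the
three-cosine torsion ½[V₁(1+cos φ) + V₂(1−cos 2φ) + V₃(1+cos 3φ)], the
buffered 14-7 van der Waals potential with the published combination rules
and donor–acceptor scaling, and a buffered Coulomb term
332.0716·qᵢqⱼ/(D(R+0.05)ⁿ) with constant (n = 1) or distance-dependent
(n = 2) dielectric and 0.75 scaling of 1-4 electrostatics. Partial charges
come from the MMFF charge model: resonance-shared fractional formal charges
plus tabulated bond charge increments. MMFF94 and MMFF94s differ only in
their torsion and out-of-plane parameter tables. See `docs/methods.md` for
the full account.

Flat-bottomed restraints on distances, angles, torsions and atomic (or
center-of-mass) positions are zero inside a user window and grow as ½k·d²
outside it, and can be added to any system for constrained minimization or
torsional scans.

## Worked example

```python
from mmffkit import (FixtureSpec, generate_fixture, load_tables,
                     atom_assignment, enumerate_interactions, calc_energy,
                     minimize)

tables = load_tables()                      # or load_tables(variant="MMFF94s")
mol = generate_fixture(FixtureSpec("acetamide", seed=3))   # or read_sdf(...)
assignment = atom_assignment(mol, tables)   # aromaticity, types, charges
system = enumerate_interactions(mol, assignment, tables)
print(calc_energy(system, mol.coordinates))
result = minimize(system, mol.coordinates, max_iterations=300,
                  grad_tolerance=1e-5)
print(round(result.energy, 4), result.iterations)
```

prints the per-atom assignment (via `assignment.summary_rows()`), e.g. the
amide carbonyl carbon as symbolic type `C=ON` (numeric 3) with partial
charge +0.5690 and the amide nitrogen as `NC=O` (numeric 10) with −0.8000,
and then the energy breakdown of the jittered idealized start geometry:

```
  bond                   9.7682
  angle                 48.0265
  stretch_bend          -5.5624
  oop                    2.8058
  torsion               10.0209
  vdw                    0.0758
  electrostatic        -40.5169
  restraints             0.0000
  total                 24.6179
-28.8922 166
```

All values are kcal/mol; the seven components always sum to the total. The
final line is the minimized energy after 166 quasi-Newton iterations (RMS
gradient below 10⁻⁵ kcal·mol⁻¹·Å⁻¹).

The same operations are available from the shell:

```
mmffkit type     --sdf in.sdf                       # per-atom types/charges (TSV)
mmffkit energy   --sdf in.sdf --variant mmff94s     # seven-term breakdown
mmffkit minimize --sdf in.sdf --out min.sdf --restraints r.txt
mmffkit scan     --sdf in.sdf --dihedral 3,1,2,6 --start 0 --step 10 --n 36 --out profile.tsv
mmffkit validate --sdf suite.sdf --ref refs.json --report report.json
mmffkit selftest                                    # no-download property suite
```

## Validation

The test suite checks the machinery from several independent directions:
round-trip and exhaustive-enumeration oracles for the molecule model,
brute-force scan oracles for the binary-search and step-down parameter
lookups, central finite differences for every analytic gradient, 100-fold
atom-order shuffles and exhaustive kekulé-form enumeration for perception
robustness, and (where RDKit is available) per-term energy, type and charge
agreement with the independent MMFF implementation validated against the
official OPTIMOL references. `run_suite` / `mmffkit validate` can replay
the full official MMFF94 (761 molecules) and MMFF94s (235 molecules)
validation suites against reference records when the user supplies those
files; they are not redistributed here.

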