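# Methods

## The model

mmffkit implements the MMFF94 force field and its "static" MMFF94s variant
for all-atom small molecules. The potential energy of a conformation is the
sum of seven terms — bond stretching, angle bending, stretch–bend coupling,
out-of-plane bending at trigonal centers, torsions, van der Waals, and
electrostatics — each evaluated with the canonical MMFF functional forms:

| term | form | constants |
|---|---|---|
| bond | quartic-corrected harmonic `143.9325/2·kb·Δr²(1 + cs·Δr + 7/12·cs²Δr²)` | cs = −2 Å⁻¹ |
| angle | cubic-corrected harmonic `143.9325(π/180)²/2·ka·Δθ²(1 + cb·Δθ)` | cb = −0.4 rad⁻¹ (−0.006981317 deg⁻¹); linear types use `143.9325·ka·(1+cos θ)` |
| stretch–bend | `143.9325(π/180)·(kba_ijk·Δr_ij + kba_kji·Δr_kj)·Δθ` | |
| out-of-plane | harmonic in the Wilson angle χ, same prefactor as the angle term | |
| torsion | `½[V1(1+cos φ) + V2(1−cos 2φ) + V3(1+cos 3φ)]` | |
| van der Waals | buffered 14-7, `ε·(1.07R*/(R+0.07R*))⁷·(1.12R*⁷/(R⁷+0.12R*⁷) − 2)` | combination rules with B = 0.2, β = 12, donor–acceptor scaling 0.8/0.5 |
| electrostatic | buffered Coulomb `332.0716·qᵢqⱼ/(D(R+0.05)ⁿ)` | n = 1 (constant dielectric) or 2 (distance-dependent); 1-4 pairs scaled by 0.75; 1-4 vdW unscaled |

The rounded constants often quoted (0.043844 for the angle prefactor,
−0.007 deg⁻¹ for the cubic bend, 2.51210 for the stretch–bend prefactor)
are the printed forms of the exact unit conversions used here; the exact
values are required to reproduce reference energies below 10⁻³ kcal/mol.
All constants live in one section of `energy_core.py`.

Nonbonded interactions use a plain O(N²) pair list excluding 1-2 and 1-3
pairs, with no cutoffs — the implementation targets validation-exact
energies on drug-sized molecules, not condensed-phase simulation.

The two variants share every table except torsion and out-of-plane
parameters, which are selected at load time; typing and charges are
identical between variants by construction.

## Perception

Atom typing starts from a kekulized structure. MMFF aromaticity is
re-perceived over 5- and 6-membered rings with a Hückel 4n+2 count: an atom
in a ring double bond contributes one π electron, a divalent O/S or
trivalent N lone-pair donor contributes two, a tricoordinate carbocation
contributes zero, and an exocyclic double bond out of the π system
disqualifies the ring. The count iterates to a fixpoint so fused systems
are recognized regardless of which degenerate kekulé form the input uses.
Atoms of aromatic 5-rings take 5-ring types even when fused into aromatic
6-rings (indole-type fusion atoms are α/β 5-ring carbons, not generic
aromatic carbons); α/β positions are measured from the ring's unique
lone-pair donor, and cationic imidazolium-like rings use the dedicated
delocalized types.

Heavy atoms are typed first by a deterministic per-element decision
procedure over (element, degree, bond orders, formal charge, ring sizes,
aromatic flags, neighbor environments); hydrogens afterwards, as a pure
function of the bonded heavy atom's type. The implemented domain covers
H, C, N, O, F, Si, P, S, Cl, Br, I and the common monoatomic ions, in the
environments of the published type system; an atom outside the rule set
raises a typing error naming the atom and its environment rather than
guessing.

Charges follow the MMFF bond-charge-increment model in three stages:

1. *Fractional formal charges.* Integer formal charges are redistributed
   over resonant groups: equivalent terminal O/S on one center share the
   pool of their formal charges plus any positive charge written on the
   center (so dative and hypervalent notations of nitro-like groups
   normalize to the same fractions: carboxylate −½ per O, nitrate anion
   −⅔ per O, sulfonate −⅓, phosphate −¾); amidinium, guanidinium and
   imidazolium nitrogens take +½, +⅓ and +½; aromatic azolate nitrogens
   share the ring charge; azide and isonitrile dipoles are neutralized.
   The recognized groups are enumerated in `data/resonant_groups.tsv`.
2. *Formal-charge adjustment.* An atom with adjustment factor v (from the
   charge-parameter table; 0 when absent) keeps `(1 − crd·v)` of its
   fractional charge and donates `v` of it to each bonded neighbor
   (e.g. alkoxide oxygen shares half of its −1 with the carbon).
3. *Bond charge increments.* Each bond moves a tabulated charge between its
   atoms; increments are antisymmetric under direction reversal, and a
   missing increment is estimated as the difference of the two partial
   increments. Total charge is conserved to machine precision.

## Parameters

All tables ship as whitespace-delimited text under `mmffkit/data/` (column
schemas in each file header): bond, angle, stretch–bend, default
stretch–bend, out-of-plane and torsion per variant, vdW, bond charge
increments, partial increments with adjustment factors, the atom-property
table, the step-down equivalence table, the symbolic→numeric type map and
the resonant-group list. Values are the published MMFF94/MMFF94s parameter
sets. The symbolic map carries 209 of the 216 published symbolic synonyms
(all 95 numeric types are covered; the handful of missing entries are
alternative names for already-covered numeric types and do not affect any
computation).

Lookups use canonically ordered keys over sorted arrays with binary search.
When an angle, stretch–bend or torsion key has no exact row, a staged
step-down substitutes increasingly generic surrogate types for the terminal
atoms (equivalence stages 2–5, stage 5 being the wildcard); out-of-plane
ligand types step down the same way. Each query reports its provenance
(exact, step-down + stage, empirical-fallback, missing). The exact stage
ordering for half-generalized torsion keys is not uniquely fixed by the
published procedure; this package generalizes both ends simultaneously
(stages (1,1) → (2,2) → … → wildcard), which resolves every key in the
shipped tables identically to a full linear scan under the same stage
order (tested against that brute-force oracle). Missing bond/angle/torsion
parameters raise a structured error listing every failing interaction; the
empirical re-estimation rules for absent bond/angle rows are not
implemented. A tricoordinate center whose out-of-plane key is absent at
every stage simply has no out-of-plane term (recorded in the provenance
log), matching the published tables' treatment of pyramidal centers.

## Restraints and optimization

Flat-bottomed restraints on distances, angles, torsions and positions are
zero inside a [min, max] window and quadratic (½k·d²) outside, C¹ at both
edges. Units are a documented package convention, not a published fact:
distances in Å with k in kcal·mol⁻¹·Å⁻², angles and torsions quadratic in
degrees with k in kcal·mol⁻¹·deg⁻². Torsion windows live on the circle
(−180°, 180°]; deviations are minimal signed circular differences, so
windows crossing ±180° behave continuously. Positional restraints may
tether a dummy point defined as the mass-weighted center of an atom set,
with the gradient distributed over the constituent atoms by mass weight.
Bounds may be given relative to the current geometry and are resolved to
absolute bounds (idempotently) before minimization.

Minimization is limited-memory quasi-Newton (L-BFGS with a strong-Wolfe
line search) over Cartesian coordinates, terminating when the RMS Cartesian
gradient falls below the tolerance (default 10⁻⁴ kcal·mol⁻¹·Å⁻¹, max 200
iterations, both configurable). Runs are deterministic for fixed inputs.
Torsional scans rotate the dihedral to each target, pin it with a narrow
flat-bottomed window (default k = 1000 kcal·mol⁻¹·deg⁻², half-width 0.5°)
and relax everything else; scan energies are reported without the pinning
term.

## Numerical choices and degenerate inputs

* Angles are degrees at every interface; radians only inside the
  trigonometric kernels.
* Near-collinear angle triples clamp the cosine to |cos θ| ≤ 1 − 10⁻¹²;
  torsions whose flanking angle is collinear contribute zero with a
  one-time warning; an out-of-plane term with collinear in-plane ligands
  contributes zero.
* Nonbonded pairs closer than 10⁻⁸ Å raise a guard error instead of
  returning overflowed energies.
* Analytic gradients of every term (including the Wilson-angle chain rule
  and restraints) are validated against central finite differences
  (h = 10⁻⁵ Å) to relative 10⁻⁶ in the test suite.
* Kekulization is a deterministic backtracking perfect matching over the
  π subgraph with lowest-atom-index tie-breaking; the validation layer can
  enumerate all degenerate kekulé forms to prove downstream invariance.

## Synthetic fixtures

The fixture generator builds small all-atom molecules — alkanes, 3-/4-/6-
membered saturated rings, an alkene, benzene, naphthalene, five hetero-
aromatics, carbonyl/amide compounds, alcohols/amines/water, and charged
species (acetate, methylammonium, a zwitterion gallery) — with idealized
bond lengths and angles plus a seeded uniform jitter of ≤ 0.05 Å, so the
same spec and seed give bit-identical coordinates. These are strained,
idealized geometries, not equilibrium conformers: they exercise typing,
parameter assignment, energies, gradients and optimization across the C/H/
N/O chemistry of the type system, but they do not probe conformational
diversity, crystal-quality geometries, S/P hypervalent chemistry, or the
full breadth of the official 761/235-molecule validation suites. Passing
the fixture-based suite therefore demonstrates correctness of the machinery
on representative chemistry; full-suite agreement additionally requires the
official structures and reference logs, which `run_suite` and the
`validate` command consume when the user supplies them (converted to SDF
with formal charges, plus a JSON reference file).

## Known limitations

* Typing covers the common organic/published environments listed above;
  exotic environments (e.g. free carbanions, iodide anion) raise errors.
* The empirical rules for estimating missing bond/angle parameters from
  covalent radii and electronegativities are not implemented; after the
  step-down a missing parameter is an error.
* No periodic boundary conditions, cutoffs, Ewald, Hessians or dynamics.
* The symbolic type map is complete over numeric types but lists 209 of
  216 published synonym spellings.
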