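"""Validation harness: synthetic fixtures, suite runs, robustness tests.

The fixture generator builds small all-atom molecules with deterministic,
chemically sensible 3D coordinates (idealized bond lengths and angles plus a
seeded jitter of at most 0.05 A).  The harness operations reproduce the
robustness protocol used to validate the force-field implementation:
reference-suite comparison, atom-order shuffling, and re-typing across
degenerate kekule forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .chem_model import (
    Atom,
    Bond,
    Molecule,
    enumerate_kekule_forms,
    kekulize,
)

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "standard_fixture_names",
    "ReferenceRecord",
    "ValidationReport",
    "run_suite",
    "make_reference_records",
    "write_reference_file",
    "read_reference_file",
    "shuffle_robustness",
    "rebuild_invariance",
]


# ----------------------------------------------------------------------
# deterministic 3D embedding
# ----------------------------------------------------------------------

_IDEAL_LENGTH = {
    (1, 6): 1.09, (1, 7): 1.01, (1, 8): 0.96, (1, 16): 1.34,
    (6, 6): 1.52, (6, 7): 1.45, (6, 8): 1.42, (6, 9): 1.36,
    (6, 16): 1.81, (6, 17): 1.78, (7, 7): 1.40, (7, 8): 1.40,
    (8, 8): 1.45, (8, 16): 1.50, (8, 15): 1.55, (6, 15): 1.85,
}
_DOUBLE_SHRINK = 0.12
_AROMATIC_SHRINK = 0.065
_TRIPLE_SHRINK = 0.21

_TET = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47


def _ideal_length(el_i: int, el_j: int, order: int, aromatic: bool) -> float:
    key = (min(el_i, el_j), max(el_i, el_j))
    base = _IDEAL_LENGTH.get(key, 0.77 + 0.77)
    if aromatic:
        return base - _AROMATIC_SHRINK
    if order == 2:
        return base - _DOUBLE_SHRINK
    if order == 3:
        return base - _TRIPLE_SHRINK
    return base


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _perp(d: np.ndarray) -> np.ndarray:
    e = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(d, e)) > 0.9:
        e = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(d, e))


def _rotate(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    axis = _unit(axis)
    th = np.radians(deg)
    return (v * np.cos(th) + np.cross(axis, v) * np.sin(th)
            + axis * np.dot(axis, v) * (1.0 - np.cos(th)))


def _new_directions(existing: list[np.ndarray], n_new: int, sp2: bool,
                    normal: np.ndarray | None) -> list[np.ndarray]:
    """Unit vectors for new substituents given already-placed bond directions."""
    if not existing:
        if sp2:
            base = [np.array([1.0, 0.0, 0.0])]
            return [_rotate(base[0], np.array([0.0, 0.0, 1.0]), 120.0 * k)
                    for k in range(n_new)]
        t = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
        ]) / np.sqrt(3.0)
        return [t[k] for k in range(n_new)]
    if sp2:
        nrm = normal if normal is not None else (
            _unit(np.cross(existing[0], existing[1])) if len(existing) >= 2
            else np.array([0.0, 0.0, 1.0]))
        if len(existing) == 1:
            out = [_rotate(-existing[0], nrm, 60.0), _rotate(-existing[0], nrm, -60.0)]
            return out[:n_new]
        return [_unit(-sum(existing[:2]))][:n_new]
    if len(existing) == 1:
        d = existing[0]
        u = _perp(d)
        w = _unit(np.cross(d, u))
        out = []
        for k in range(n_new):
            phi = np.radians(120.0 * k)
            out.append(_unit(d * np.cos(np.radians(_TET))
                             + (u * np.cos(phi) + w * np.sin(phi))
                             * np.sin(np.radians(_TET))))
        return out
    if len(existing) == 2:
        b = _unit(-(existing[0] + existing[1]))
        p = _unit(np.cross(existing[0], existing[1]))
        half = np.radians(_TET / 2.0)
        return [_unit(b * np.cos(half) + p * np.sin(half)),
                _unit(b * np.cos(half) - p * np.sin(half))][:n_new]
    return [_unit(-sum(existing))][:n_new]


def _is_sp2(mol: Molecule, idx: int) -> bool:
    if any(b.order in (2, 4) or b.is_aromatic_mmff
           for b in mol.bonds if idx in (b.begin, b.end)):
        return True
    # ring atoms of aromatic-intent rings handled by bond orders already
    return mol.degree(idx) == 3 and mol.atoms[idx].element == 6 and \
        mol.bond_order_sum(idx) > mol.degree(idx)


def _embed(mol: Molecule, seed: int, pucker: float = 0.25,
           jitter: float = 0.03) -> np.ndarray:
    """Deterministic 3D embedding: ring polygon seed + BFS ideal geometry."""
    n = mol.n_atoms
    coords = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)

    rings = mol.ring_info.rings
    if rings:
        ring = max(rings, key=len)
        m = len(ring)
        aromatic_ring = all(_is_sp2(mol, a) for a in ring)
        side = float(np.mean([
            _ideal_length(mol.atoms[a].element, mol.atoms[b].element,
                          (mol.get_bond(a, b).order if mol.get_bond(a, b) else 1),
                          aromatic_ring)
            for a, b in zip(ring, ring[1:] + ring[:1])]))
        radius = side / (2.0 * np.sin(np.pi / m))
        for k, a in enumerate(ring):
            th = 2.0 * np.pi * k / m
            z = 0.0 if (aromatic_ring or m < 5) else pucker * (-1.0) ** k
            coords[a] = (radius * np.cos(th), radius * np.sin(th), z)
            placed[a] = True
    else:
        coords[0] = 0.0
        placed[0] = True

    # BFS out from placed atoms
    queue = [i for i in range(n) if placed[i]]
    while queue:
        a = queue.pop(0)
        nbrs = mol.neighbors(a)
        todo = [x for x in nbrs if not placed[x]]
        if not todo:
            continue
        existing = [_unit(coords[x] - coords[a]) for x in nbrs if placed[x]]
        sp2 = _is_sp2(mol, a)
        normal = np.array([0.0, 0.0, 1.0]) if sp2 else None
        dirs = _new_directions(existing, len(todo), sp2, normal)
        for x, d in zip(todo, dirs):
            b = mol.get_bond(a, x)
            length = _ideal_length(mol.atoms[a].element, mol.atoms[x].element,
                                   b.order, b.is_aromatic_mmff or b.order == 4)
            coords[x] = coords[a] + d * length
            placed[x] = True
            queue.append(x)

    rng = np.random.default_rng(seed)
    coords = coords + rng.uniform(-jitter, jitter, size=coords.shape)
    return coords


# ----------------------------------------------------------------------
# fixture definitions
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic test molecule."""
    name: str
    seed: int = 0
    size: int = 0  # meaning depends on generator (e.g. chain length)

    def build(self) -> Molecule:
        return generate_fixture(self)


def _mol_from_table(title, atoms, bonds, seed, net_charge=0, **embed_kw) -> Molecule:
    m = Molecule(
        atoms=[Atom(i, el, q) for i, (el, q) in enumerate(atoms)],
        bonds=[Bond(i, j, o) for i, j, o in bonds],
        title=title,
    )
    m = kekulize(m)
    m.coordinates = _embed(m, seed, **embed_kw)
    assert m.net_charge() == net_charge
    return m


def _alkane(n: int, seed: int) -> Molecule:
    atoms = [(6, 0)] * n + [(1, 0)] * (2 * n + 2)
    bonds = [(i, i + 1, 1) for i in range(n - 1)]
    h = n
    for c in range(n):
        nh = 3 if c in (0, n - 1) else 2
        if n == 1:
            nh = 4
        for _ in range(nh):
            bonds.append((c, h, 1))
            h += 1
    return _mol_from_table(f"alkane_{n}", atoms, bonds, seed)


def _cycloalkane(n: int, seed: int) -> Molecule:
    atoms = [(6, 0)] * n + [(1, 0)] * (2 * n)
    bonds = [(i, (i + 1) % n, 1) for i in range(n)]
    h = n
    for c in range(n):
        bonds += [(c, h, 1), (c, h + 1, 1)]
        h += 2
    return _mol_from_table(f"cycloalkane_{n}", atoms, bonds, seed)


def _benzene(seed: int) -> Molecule:
    atoms = [(6, 0)] * 6 + [(1, 0)] * 6
    bonds = [(i, (i + 1) % 6, 2 if i % 2 == 0 else 1) for i in range(6)]
    bonds += [(i, 6 + i, 1) for i in range(6)]
    return _mol_from_table("benzene", atoms, bonds, seed)


def _naphthalene(seed: int) -> Molecule:
    # atoms 0-9 carbons; rings (0..5) and (4,5,6,7,8,9) share bond 4-5
    atoms = [(6, 0)] * 10 + [(1, 0)] * 8
    ring_bonds = [
        (0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),
        (4, 9, 1), (9, 8, 2), (8, 7, 1), (7, 6, 2), (6, 5, 1),
    ]
    h_on = [0, 1, 2, 3, 6, 7, 8, 9]
    bonds = ring_bonds + [(c, 10 + k, 1) for k, c in enumerate(h_on)]
    return _mol_from_table("naphthalene", atoms, bonds, seed)


def _pyridine(seed: int) -> Molecule:
    atoms = [(7, 0)] + [(6, 0)] * 5 + [(1, 0)] * 5
    bonds = [(0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1)]
    bonds += [(i, 5 + i, 1) for i in range(1, 6)]
    return _mol_from_table("pyridine", atoms, bonds, seed)


def _pyrrole(seed: int) -> Molecule:
    atoms = [(7, 0)] + [(6, 0)] * 4 + [(1, 0)] * 5
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 0, 1)]
    bonds += [(0, 5, 1)] + [(i, 5 + i, 1) for i in range(1, 5)]
    return _mol_from_table("pyrrole", atoms, bonds, seed)


def _furan(seed: int) -> Molecule:
    atoms = [(8, 0)] + [(6, 0)] * 4 + [(1, 0)] * 4
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 0, 1)]
    bonds += [(i, 4 + i, 1) for i in range(1, 5)]
    return _mol_from_table("furan", atoms, bonds, seed)


def _imidazole(seed: int) -> Molecule:
    # N1(H)-C2=N3-C4=C5, ring closure C5-N1
    atoms = [(7, 0), (6, 0), (7, 0), (6, 0), (6, 0)] + [(1, 0)] * 4
    bonds = [(0, 1, 1), (1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 0, 1)]
    bonds += [(0, 5, 1), (1, 6, 1), (3, 7, 1), (4, 8, 1)]
    return _mol_from_table("imidazole", atoms, bonds, seed)


def _ethene(seed: int) -> Molecule:
    atoms = [(6, 0), (6, 0)] + [(1, 0)] * 4
    bonds = [(0, 1, 2), (0, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1)]
    return _mol_from_table("ethene", atoms, bonds, seed)


def _acetone(seed: int) -> Molecule:
    atoms = [(6, 0), (6, 0), (6, 0), (8, 0)] + [(1, 0)] * 6
    bonds = [(0, 1, 1), (1, 2, 1), (1, 3, 2)]
    bonds += [(0, 4, 1), (0, 5, 1), (0, 6, 1), (2, 7, 1), (2, 8, 1), (2, 9, 1)]
    return _mol_from_table("acetone", atoms, bonds, seed)


def _acetamide(seed: int) -> Molecule:
    atoms = [(6, 0), (6, 0), (8, 0), (7, 0)] + [(1, 0)] * 5
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, 1)]
    bonds += [(0, 4, 1), (0, 5, 1), (0, 6, 1), (3, 7, 1), (3, 8, 1)]
    return _mol_from_table("acetamide", atoms, bonds, seed)


def _methanol(seed: int) -> Molecule:
    atoms = [(6, 0), (8, 0)] + [(1, 0)] * 4
    bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1), (1, 5, 1)]
    return _mol_from_table("methanol", atoms, bonds, seed)


def _methylamine(seed: int) -> Molecule:
    atoms = [(6, 0), (7, 0)] + [(1, 0)] * 5
    bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1), (1, 5, 1), (1, 6, 1)]
    return _mol_from_table("methylamine", atoms, bonds, seed)


def _water(seed: int) -> Molecule:
    atoms = [(8, 0), (1, 0), (1, 0)]
    bonds = [(0, 1, 1), (0, 2, 1)]
    return _mol_from_table("water", atoms, bonds, seed)


def _acetate(seed: int) -> Molecule:
    atoms = [(6, 0), (6, 0), (8, 0), (8, -1)] + [(1, 0)] * 3
    bonds = [(0, 1, 1), (1, 2, 2), (1, 3, 1), (0, 4, 1), (0, 5, 1), (0, 6, 1)]
    return _mol_from_table("acetate", atoms, bonds, seed, net_charge=-1)


def _methylammonium(seed: int) -> Molecule:
    atoms = [(6, 0), (7, 1)] + [(1, 0)] * 6
    bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1),
             (1, 5, 1), (1, 6, 1), (1, 7, 1)]
    return _mol_from_table("methylammonium", atoms, bonds, seed, net_charge=1)


def _glycine_zwitterion(seed: int) -> Molecule:
    # +H3N-CH2-COO-  : a two-charged-group gallery with declared net charge 0
    atoms = [(7, 1), (6, 0), (6, 0), (8, 0), (8, -1)] + [(1, 0)] * 5
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 2), (2, 4, 1),
             (0, 5, 1), (0, 6, 1), (0, 7, 1), (1, 8, 1), (1, 9, 1)]
    return _mol_from_table("glycine_zwitterion", atoms, bonds, seed, net_charge=0)


_GENERATORS = {
    "alkane": lambda s: _alkane(max(s.size, 2), s.seed),
    "methane": lambda s: _alkane(1, s.seed),
    "cyclopropane": lambda s: _cycloalkane(3, s.seed),
    "cyclobutane": lambda s: _cycloalkane(4, s.seed),
    "cyclohexane": lambda s: _cycloalkane(6, s.seed),
    "ethene": lambda s: _ethene(s.seed),
    "benzene": lambda s: _benzene(s.seed),
    "naphthalene": lambda s: _naphthalene(s.seed),
    "pyridine": lambda s: _pyridine(s.seed),
    "pyrrole": lambda s: _pyrrole(s.seed),
    "furan": lambda s: _furan(s.seed),
    "imidazole": lambda s: _imidazole(s.seed),
    "acetone": lambda s: _acetone(s.seed),
    "acetamide": lambda s: _acetamide(s.seed),
    "methanol": lambda s: _methanol(s.seed),
    "methylamine": lambda s: _methylamine(s.seed),
    "water": lambda s: _water(s.seed),
    "acetate": lambda s: _acetate(s.seed),
    "methylammonium": lambda s: _methylammonium(s.seed),
    "glycine_zwitterion": lambda s: _glycine_zwitterion(s.seed),
}


def standard_fixture_names() -> list[str]:
    return sorted(_GENERATORS)


def generate_fixture(spec: FixtureSpec) -> Molecule:
    """Build the deterministic all-atom molecule described by ``spec``.

    Same spec (name, size, seed) -> bit-identical coordinates.
    """
    try:
        gen = _GENERATORS[spec.name]
    except KeyError:
        raise ValueError(
            f"unknown fixture generator {spec.name!r}; known: "
            f"{', '.join(standard_fixture_names())}") from None
    return gen(spec)


# ----------------------------------------------------------------------
# reference records and suite runs
# ----------------------------------------------------------------------

from .energy_core import (   # noqa: E402  (harness layer imports)
    EnergyOptions,
    TERM_NAMES,
    calc_energy,
    enumerate_interactions,
)
from .param_store import ParameterTables, load_tables  # noqa: E402
from .perception import atom_assignment  # noqa: E402


@dataclass
class ReferenceRecord:
    """Per-molecule expected types, charges and seven-term energies."""
    title: str
    symbolic_types: list
    numeric_types: list
    partial_charges: list
    energies: dict        # term name -> kcal/mol (seven terms)
    total: float

    def to_json(self) -> dict:
        return {
            "title": self.title,
            "symbolic_types": self.symbolic_types,
            "numeric_types": self.numeric_types,
            "partial_charges": self.partial_charges,
            "energies": self.energies,
            "total": self.total,
        }

    @classmethod
    def from_json(cls, d: dict) -> "ReferenceRecord":
        return cls(title=d["title"], symbolic_types=d["symbolic_types"],
                   numeric_types=d["numeric_types"],
                   partial_charges=d["partial_charges"],
                   energies=d["energies"], total=d["total"])


@dataclass
class MoleculeValidation:
    title: str
    types_pass: bool
    charges_pass: bool
    term_pass: dict
    total_pass: bool
    max_charge_dev: float
    max_term_dev: float
    details: list

    @property
    def passed(self) -> bool:
        return (self.types_pass and self.charges_pass and self.total_pass
                and all(self.term_pass.values()))


@dataclass
class ValidationReport:
    results: list
    charge_tolerance: float
    energy_tolerance: float

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.results if r.passed)

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    @property
    def max_deviations(self) -> dict:
        return {
            "charge": max((r.max_charge_dev for r in self.results), default=0.0),
            "energy": max((r.max_term_dev for r in self.results), default=0.0),
        }

    def to_json(self) -> dict:
        return {
            "n_molecules": len(self.results),
            "n_pass": self.n_pass,
            "passed": self.passed,
            "charge_tolerance": self.charge_tolerance,
            "energy_tolerance": self.energy_tolerance,
            "max_deviations": self.max_deviations,
            "failures": [
                {"title": r.title, "details": r.details}
                for r in self.results if not r.passed],
        }


def compute_record(mol: Molecule, tables, options=None) -> ReferenceRecord:
    """Type, charge and evaluate one molecule into a reference record."""
    work = kekulize(mol.copy())
    assignment = atom_assignment(work, tables)
    system = enumerate_interactions(work, assignment, tables,
                                    options or EnergyOptions())
    bd = calc_energy(system, work.coordinates)
    energies = {t: getattr(bd, "e_" + t) for t in TERM_NAMES}
    return ReferenceRecord(
        title=mol.title,
        symbolic_types=list(assignment.symbolic_types),
        numeric_types=list(assignment.numeric_types),
        partial_charges=[float(q) for q in assignment.partial_charges],
        energies=energies, total=bd.total)


def make_reference_records(mols, tables, options=None):
    return [compute_record(m, tables, options) for m in mols]


def write_reference_file(records, path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_json() for r in records], fh, indent=1)


def read_reference_file(path):
    with open(path) as fh:
        return [ReferenceRecord.from_json(d) for d in json.load(fh)]


def run_suite(structures, references, tables=None, options=None,
              charge_tolerance: float = 1e-3,
              energy_tolerance: float = 1e-3) -> ValidationReport:
    """Validate every molecule against its reference record.

    ``structures`` is an SDF path or a list of Molecules; ``references`` a
    reference-file path or list of ReferenceRecords.  Records are paired by
    title when all titles are unique, else by order.  Types must match
    exactly; charges and per-term/total energies within the tolerances
    (kcal/mol).
    """
    from .chem_model import read_sdf
    if isinstance(structures, (str, bytes)) or hasattr(structures, "exists"):
        structures = read_sdf(structures)
    if isinstance(references, (str, bytes)) or hasattr(references, "exists"):
        references = read_reference_file(references)
    tables = tables or load_tables()

    mols = list(structures)
    refs = list(references)
    titles_m = [m.title for m in mols]
    titles_r = [r.title for r in refs]
    if (len(set(titles_m)) == len(titles_m)
            and len(set(titles_r)) == len(titles_r)
            and set(titles_m) or False):
        by_title = {r.title: r for r in refs}
        orphans_m = [t for t in titles_m if t not in by_title]
        orphans_r = [t for t in titles_r if t not in set(titles_m)]
        if orphans_m or orphans_r:
            raise ValueError(
                "unpairable records -- structures without reference: "
                f"{orphans_m}; references without structure: {orphans_r}")
        pairs = [(m, by_title[m.title]) for m in mols]
    else:
        if len(mols) != len(refs):
            raise ValueError(
                f"cannot pair by order: {len(mols)} structures vs "
                f"{len(refs)} references")
        pairs = list(zip(mols, refs))

    results = []
    for mol, ref in pairs:
        details = []
        rec = compute_record(mol, tables, options)
        types_pass = (rec.numeric_types == list(ref.numeric_types)
                      and rec.symbolic_types == list(ref.symbolic_types))
        if not types_pass:
            bad = [i for i, (a, b) in enumerate(
                zip(rec.numeric_types, ref.numeric_types)) if a != b]
            bad += [i for i, (a, b) in enumerate(
                zip(rec.symbolic_types, ref.symbolic_types)) if a != b]
            details.append(f"type mismatch at atoms {sorted(set(bad))}")
        cdev = max((abs(a - b) for a, b in
                    zip(rec.partial_charges, ref.partial_charges)),
                   default=0.0)
        charges_pass = bool(cdev <= charge_tolerance)
        if not charges_pass:
            details.append(f"max charge deviation {cdev:.2e} e")
        term_pass = {}
        tdev = 0.0
        for t in TERM_NAMES:
            d = abs(rec.energies[t] - ref.energies.get(t, 0.0))
            tdev = max(tdev, d)
            term_pass[t] = bool(d <= energy_tolerance)
            if not term_pass[t]:
                details.append(f"{t} energy off by {d:.2e} kcal/mol")
        dtot = abs(rec.total - ref.total)
        total_pass = bool(dtot <= energy_tolerance)
        if not total_pass:
            details.append(f"total energy off by {dtot:.2e} kcal/mol")
        results.append(MoleculeValidation(
            title=mol.title, types_pass=types_pass,
            charges_pass=charges_pass, term_pass=term_pass,
            total_pass=total_pass, max_charge_dev=cdev,
            max_term_dev=max(tdev, dtot), details=details))
    return ValidationReport(results=results,
                            charge_tolerance=charge_tolerance,
                            energy_tolerance=energy_tolerance)


# ----------------------------------------------------------------------
# robustness protocols
# ----------------------------------------------------------------------

def shuffle_robustness(mol: Molecule, tables=None, n_shuffles: int = 100,
                       seed: int = 0, assigner=None) -> int:
    """Count shuffle trials whose perception is permutation-consistent.

    Each trial permutes the atom order (remapping bonds and coordinates),
    re-runs aromaticity perception, typing and charging from scratch, and
    pulls the assignment back through the permutation; a trial passes when
    symbolic/numeric types and partial charges all agree with the reference
    assignment of the unshuffled molecule.  Returns the number of passing
    trials (out of ``n_shuffles``).
    """
    tables = tables or load_tables()
    if assigner is None:
        def assigner(m):
            a = atom_assignment(m, tables)
            return a.symbolic_types, a.numeric_types, a.partial_charges

    ref = assigner(kekulize(mol.copy()))
    rng = np.random.default_rng(seed)
    n_pass = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(mol.n_atoms).tolist()
        shuffled = kekulize(mol.permuted(perm))
        sym, num, chg = assigner(shuffled)
        ok = all(
            sym[perm[i]] == ref[0][i]
            and num[perm[i]] == ref[1][i]
            and abs(chg[perm[i]] - ref[2][i]) <= 1e-8
            for i in range(mol.n_atoms))
        n_pass += ok
    return n_pass


def rebuild_invariance(mol: Molecule, tables=None, limit: int = 32) -> bool:
    """Re-type the molecule across all degenerate kekule forms.

    Returns True when every enumerated kekule form of the aromatic system
    yields identical types and charges (trivially true for non-aromatic
    molecules).
    """
    tables = tables or load_tables()
    base = kekulize(mol.copy())
    ref = atom_assignment(base, tables)
    for form in enumerate_kekule_forms(base, limit=limit):
        a = atom_assignment(form, tables)
        if a.symbolic_types != ref.symbolic_types:
            return False
        if a.numeric_types != ref.numeric_types:
            return False
        if any(abs(x - y) > 1e-8 for x, y in
               zip(a.partial_charges, ref.partial_charges)):
            return False
    return True
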