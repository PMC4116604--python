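"""Load, index and serve the MMFF parameter tables.

All tables are plain whitespace-delimited text files with ``#`` comments,
bundled under ``mmffkit/data`` (see that directory for the column schemas).
Rows are held in canonically sorted arrays and served by binary search, with
the staged "step-down" fallback that substitutes increasingly generic
surrogate atom types (from the equivalence table) when a specific row is
absent.

Key canonicalization
--------------------
bond     (bt, i, j)           i <= j
angle    (at, i, j, k)        i <= k   (j is the central atom)
sb       (sbt, i, j, k)       stored orientation; reversed query swaps the
                              two coupling constants and mirrors sbt
torsion  (tt, i, j, k, l)     j < k, or j == k and i <= l
oop      (j; i, k, l)         the three ligand types sorted ascending
bci      (bt, i, j)           i <= j; reversed query flips the sign
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "AtomTypeProperties",
    "ParameterTables",
    "ParameterQueryResult",
    "MissingParameterError",
    "TableFormatError",
    "default_data_dir",
    "load_tables",
    "canonical_key",
    "lookup",
    "bond_type_index",
    "angle_type_index",
    "stretch_bend_type_index",
    "torsion_type_index",
    "vdw_pair_parameters",
    "bci_for_bond",
]

# buffered 14-7 combination-rule constants (published with the vdW table)
VDW_POWER = 0.25
VDW_B = 0.2
VDW_BETA = 12.0
VDW_DARAD = 0.8
VDW_DAEPS = 0.5

#: provenance labels every lookup reports
PROV_EXACT = "exact"
PROV_STEP_DOWN = "step-down"
PROV_EMPIRICAL = "empirical-fallback"
PROV_MISSING = "missing"

# sbt mirror pairs when the i,k ends of an angle are swapped
_SBT_SWAP = {0: 0, 1: 2, 2: 1, 3: 3, 4: 4, 5: 5, 6: 7, 7: 6, 8: 8, 9: 10, 10: 9, 11: 11}

# periodic-table row used by the default stretch-bend table (H counts as row 0)
_PT_ROW = {1: 0}
_PT_ROW.update({el: 1 for el in range(3, 11)})
_PT_ROW.update({el: 2 for el in range(11, 19)})
_PT_ROW.update({el: 3 for el in range(19, 37)})
_PT_ROW.update({el: 4 for el in range(37, 55)})


class TableFormatError(ValueError):
    """Malformed parameter file (reports file and line)."""


class MissingParameterError(KeyError):
    """No parameter found after the step-down; carries the failing keys."""

    def __init__(self, message: str, failures: list | None = None):
        super().__init__(message)
        self.failures = failures or []

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0]


@dataclass(frozen=True)
class AtomTypeProperties:
    numeric_type: int
    species: int          # atomic number
    crd: int              # coordination number
    val: int              # total valence
    pilp: bool            # has a pi lone pair
    mltb: int             # multiple-bond capacity code
    arom: bool            # aromatic-capable type
    lin: bool             # linear geometry
    sbmb: bool            # can form single bonds to multiple-bond types


@dataclass(frozen=True)
class ParameterQueryResult:
    params: tuple | None
    provenance: str       # exact | step-down | empirical-fallback | missing
    stage: int = 1        # equivalence stage at which the match was found

    @property
    def found(self) -> bool:
        return self.params is not None


class _SortedTable:
    """Immutable sorted (key, value) store with binary-search retrieval."""

    def __init__(self, pairs: dict[tuple, tuple]):
        items = sorted(pairs.items())
        self.keys = [k for k, _ in items]
        self.values = [v for _, v in items]

    def get(self, key: tuple) -> tuple | None:
        i = bisect.bisect_left(self.keys, key)
        if i < len(self.keys) and self.keys[i] == key:
            return self.values[i]
        return None

    def __len__(self) -> int:
        return len(self.keys)

    def items(self):
        return zip(self.keys, self.values)


@dataclass
class ParameterTables:
    variant: str
    bond: _SortedTable
    angle: _SortedTable
    stretch_bend: _SortedTable
    default_stretch_bend: _SortedTable
    oop: _SortedTable
    torsion: _SortedTable
    vdw: dict[int, tuple]               # type -> (alpha, N, A, G, DA)
    bci: _SortedTable
    pbci: dict[int, float]
    fcadj: dict[int, float]
    equivalence: dict[int, tuple]       # type -> (self, l2, l3, l4, l5)
    properties: dict[int, AtomTypeProperties]
    symbolic_map: dict[str, int]
    resonant_groups: list[tuple]

    def equivalent_type(self, numeric_type: int, stage: int) -> int:
        """Surrogate type at equivalence stage 1..5 (stage 1 = the type itself)."""
        return self.equivalence[numeric_type][stage - 1]


def default_data_dir() -> Path:
    return Path(resources.files("mmffkit") / "data")


def _read_rows(path: Path, n_cols: int) -> list[list[str]]:
    rows = []
    for ln_no, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.split("#", 1)[0].strip()
        if not s:
            continue
        f = s.split()
        if len(f) < n_cols:
            raise TableFormatError(
                f"{path.name}:{ln_no}: expected {n_cols} columns, got {len(f)}")
        rows.append(f)
    return rows


def load_tables(directory=None, variant: str = "MMFF94") -> ParameterTables:
    """Parse all MMFF tables from ``directory`` (default: bundled data).

    ``variant`` ("MMFF94" or "MMFF94s") selects which torsion and
    out-of-plane files serve lookups; all other tables are shared.
    """
    if variant not in ("MMFF94", "MMFF94s"):
        raise ValueError(f"unknown MMFF variant {variant!r}")
    directory = Path(directory) if directory is not None else default_data_dir()
    suffix = "mmff94s" if variant == "MMFF94s" else "mmff94"

    required = ["bond.tsv", "angle.tsv", "stretch_bend.tsv",
                "default_stretch_bend.tsv", f"oop_{suffix}.tsv",
                f"torsion_{suffix}.tsv", "vdw.tsv", "bci.tsv", "pbci.tsv",
                "equivalence.tsv", "atom_properties.tsv", "symbolic_types.tsv",
                "resonant_groups.tsv"]
    for name in required:
        if not (directory / name).exists():
            raise FileNotFoundError(
                f"parameter directory {directory} is missing {name}")

    bond = _SortedTable({
        (int(r[0]), int(r[1]), int(r[2])): (float(r[3]), float(r[4]))
        for r in _read_rows(directory / "bond.tsv", 5)})
    angle = _SortedTable({
        (int(r[0]), int(r[1]), int(r[2]), int(r[3])): (float(r[4]), float(r[5]))
        for r in _read_rows(directory / "angle.tsv", 6)})
    stretch_bend = _SortedTable({
        (int(r[0]), int(r[1]), int(r[2]), int(r[3])): (float(r[4]), float(r[5]))
        for r in _read_rows(directory / "stretch_bend.tsv", 6)})
    dfsb = _SortedTable({
        (int(r[0]), int(r[1]), int(r[2])): (float(r[3]), float(r[4]))
        for r in _read_rows(directory / "default_stretch_bend.tsv", 5)})
    oop = _SortedTable({
        (int(r[1]),) + tuple(sorted((int(r[0]), int(r[2]), int(r[3])))): (float(r[4]),)
        for r in _read_rows(directory / f"oop_{suffix}.tsv", 5)})
    torsion = _SortedTable({
        tuple(int(x) for x in r[:5]): tuple(float(x) for x in r[5:8])
        for r in _read_rows(directory / f"torsion_{suffix}.tsv", 8)})
    vdw = {int(r[0]): (float(r[1]), float(r[2]), float(r[3]), float(r[4]), r[5])
           for r in _read_rows(directory / "vdw.tsv", 6)}
    bci = _SortedTable({
        (int(r[0]), int(r[1]), int(r[2])): (float(r[3]),)
        for r in _read_rows(directory / "bci.tsv", 4)})
    pbci_rows = _read_rows(directory / "pbci.tsv", 3)
    pbci = {int(r[0]): float(r[1]) for r in pbci_rows}
    fcadj = {int(r[0]): float(r[2]) for r in pbci_rows}
    equivalence = {
        int(r[0]): (int(r[0]), int(r[1]), int(r[2]), int(r[3]), int(r[4]))
        for r in _read_rows(directory / "equivalence.tsv", 5)}
    properties = {
        int(r[0]): AtomTypeProperties(
            numeric_type=int(r[0]), species=int(r[1]), crd=int(r[2]),
            val=int(r[3]), pilp=bool(int(r[4])), mltb=int(r[5]),
            arom=bool(int(r[6])), lin=bool(int(r[7])), sbmb=bool(int(r[8])))
        for r in _read_rows(directory / "atom_properties.tsv", 9)}
    symbolic_map = {r[0]: int(r[1])
                    for r in _read_rows(directory / "symbolic_types.tsv", 2)}
    resonant = []
    for r in _read_rows(directory / "resonant_groups.tsv", 4):
        value = None if r[3] == "-" else float(r[3])
        resonant.append((r[0], r[1], int(r[2]), value))

    tables = ParameterTables(
        variant=variant, bond=bond, angle=angle, stretch_bend=stretch_bend,
        default_stretch_bend=dfsb, oop=oop, torsion=torsion, vdw=vdw,
        bci=bci, pbci=pbci, fcadj=fcadj, equivalence=equivalence,
        properties=properties, symbolic_map=symbolic_map,
        resonant_groups=resonant)
    _cross_check(tables)
    return tables


def _cross_check(t: ParameterTables) -> None:
    """Every numeric type referenced anywhere must have property,
    equivalence and vdW rows."""
    emitted = set(t.symbolic_map.values())
    for numeric in sorted(emitted):
        for name, table in (("atom_properties", t.properties),
                            ("equivalence", t.equivalence),
                            ("vdw", t.vdw)):
            if numeric not in table:
                raise TableFormatError(
                    f"numeric type {numeric} has no row in {name}")


# ----------------------------------------------------------------------
# canonical keys
# ----------------------------------------------------------------------

_ARITY = {"bond": 2, "angle": 3, "sb": 3, "torsion": 4, "oop": 4}


def canonical_key(kind: str, types: tuple, type_index: int = 0) -> tuple:
    """Deterministic canonical ordering of a parameter key.  Idempotent."""
    if kind not in _ARITY:
        raise ValueError(f"unknown parameter kind {kind!r}")
    if len(types) != _ARITY[kind]:
        raise ValueError(
            f"{kind} key needs {_ARITY[kind]} types, got {len(types)}")
    t = tuple(int(x) for x in types)
    if kind == "bond":
        i, j = t
        return (type_index, min(i, j), max(i, j))
    if kind == "angle":
        i, j, k = t
        if i > k:
            i, k = k, i
        return (type_index, i, j, k)
    if kind == "sb":
        i, j, k = t
        if i > k:
            i, k = k, i
            type_index = _SBT_SWAP[type_index]
        return (type_index, i, j, k)
    if kind == "torsion":
        i, j, k, l = t
        if j > k or (j == k and i > l):
            i, j, k, l = l, k, j, i
        return (type_index, i, j, k, l)
    # oop: first type is the center, remaining three ligands sorted
    j, *ligands = t
    return (j,) + tuple(sorted(ligands))


# ----------------------------------------------------------------------
# lookups with step-down
# ----------------------------------------------------------------------

def _angle_like_stages(tables: ParameterTables, i: int, k: int):
    """Equivalence stages for terminal atoms of angle/sb/torsion lookups."""
    for stage in (1, 2, 3, 4, 5):
        yield stage, tables.equivalent_type(i, stage), tables.equivalent_type(k, stage)


def lookup(tables: ParameterTables, kind: str, key: tuple) -> ParameterQueryResult:
    """Retrieve parameters for a canonical ``key``.

    Exact binary-search hit when present; otherwise the staged step-down
    substitutes surrogate types for the terminal atoms (angle, stretch-bend,
    torsion) or the ligands (out-of-plane).  Bond-charge increments fall back
    to the difference of partial increments.  An exhausted search yields a
    ``missing`` result, never an exception -- the energy layer decides.
    """
    if kind == "bond":
        v = tables.bond.get(key)
        return ParameterQueryResult(v, PROV_EXACT) if v else \
            ParameterQueryResult(None, PROV_MISSING)

    if kind == "angle":
        at, i, j, k = key
        for stage, ei, ek in _angle_like_stages(tables, i, k):
            v = tables.angle.get(canonical_key("angle", (ei, j, ek), at))
            if v:
                prov = PROV_EXACT if stage == 1 else PROV_STEP_DOWN
                return ParameterQueryResult(v, prov, stage)
        return ParameterQueryResult(None, PROV_MISSING)

    if kind == "sb":
        sbt, i, j, k = key
        v = tables.stretch_bend.get((sbt, i, j, k))
        if v:
            return ParameterQueryResult(v, PROV_EXACT)
        v = tables.stretch_bend.get((_SBT_SWAP[sbt], k, j, i))
        if v:
            return ParameterQueryResult((v[1], v[0]), PROV_EXACT)
        # default table keyed by periodic rows
        pr = tuple(_PT_ROW.get(tables.properties[x].species, 1) for x in (i, j, k))
        v = tables.default_stretch_bend.get(pr)
        if v:
            return ParameterQueryResult(v, PROV_EMPIRICAL)
        v = tables.default_stretch_bend.get((pr[2], pr[1], pr[0]))
        if v:
            return ParameterQueryResult((v[1], v[0]), PROV_EMPIRICAL)
        return ParameterQueryResult(None, PROV_MISSING)

    if kind == "torsion":
        tt, i, j, k, l = key
        for stage, ei, el in _angle_like_stages(tables, i, l):
            v = tables.torsion.get(canonical_key("torsion", (ei, j, k, el), tt))
            if v:
                prov = PROV_EXACT if stage == 1 else PROV_STEP_DOWN
                return ParameterQueryResult(v, prov, stage)
        return ParameterQueryResult(None, PROV_MISSING)

    if kind == "oop":
        j, a, b, c = key
        for stage in (1, 2, 3, 4, 5):
            lig = sorted(tables.equivalent_type(x, stage) for x in (a, b, c))
            v = tables.oop.get((j,) + tuple(lig))
            if v:
                prov = PROV_EXACT if stage == 1 else PROV_STEP_DOWN
                return ParameterQueryResult(v, prov, stage)
        return ParameterQueryResult(None, PROV_MISSING)

    if kind == "bci":
        bt, i, j = key
        v = tables.bci.get((bt, min(i, j), max(i, j)))
        if v:
            b = v[0] if i <= j else -v[0]
            return ParameterQueryResult((b,), PROV_EXACT)
        if i in tables.pbci and j in tables.pbci:
            return ParameterQueryResult(
                (tables.pbci[j] - tables.pbci[i],), PROV_EMPIRICAL)
        return ParameterQueryResult(None, PROV_MISSING)

    if kind == "vdw":
        (t,) = key
        v = tables.vdw.get(t)
        return ParameterQueryResult(v, PROV_EXACT) if v else \
            ParameterQueryResult(None, PROV_MISSING)

    raise ValueError(f"unknown parameter kind {kind!r}")


# ----------------------------------------------------------------------
# interaction type indices (bond graph -> table key components)
# ----------------------------------------------------------------------

def bond_type_index(mol, assignment, bond) -> int:
    """MMFF bond-type index: 1 for a formally single bond between
    sp2/aromatic-capable types that is not itself aromatic, else 0."""
    if bond.order != 1 or bond.is_aromatic_mmff:
        return 0
    ti = assignment.numeric_types[bond.begin]
    tj = assignment.numeric_types[bond.end]
    pi, pj = assignment.properties[ti], assignment.properties[tj]
    if (pi.arom and pj.arom) or (pi.sbmb and pj.sbmb):
        return 1
    return 0


def _in_common_ring(mol, atoms: tuple, size: int) -> bool:
    for ring in mol.ring_info.rings_of_size(size):
        if set(atoms) <= set(ring):
            return True
    return False


def angle_type_index(mol, assignment, i: int, j: int, k: int) -> int:
    """MMFF angle-type index combining constituent bond-type indices with
    3-/4-membered-ring membership."""
    bt1 = bond_type_index(mol, assignment, mol.get_bond(i, j))
    bt2 = bond_type_index(mol, assignment, mol.get_bond(j, k))
    s = bt1 + bt2
    in3 = _in_common_ring(mol, (i, j, k), 3)
    in4 = (not in3) and _in_common_ring(mol, (i, j, k), 4)
    if in3:
        return {0: 3, 1: 5, 2: 6}[s]
    if in4:
        return {0: 4, 1: 7, 2: 8}[s]
    return {0: 0, 1: 1, 2: 2}[s]


_SB_FROM_ANGLE = {
    (0, 0, 0): 0,
    (1, 1, 0): 1, (1, 0, 1): 2,
    (2, 1, 1): 3,
    (4, 0, 0): 4,
    (3, 0, 0): 5,
    (5, 1, 0): 6, (5, 0, 1): 7,
    (6, 1, 1): 8,
    (7, 1, 0): 9, (7, 0, 1): 10,
    (8, 1, 1): 11,
}


def stretch_bend_type_index(mol, assignment, i: int, j: int, k: int) -> int:
    at = angle_type_index(mol, assignment, i, j, k)
    bt1 = bond_type_index(mol, assignment, mol.get_bond(i, j))
    bt2 = bond_type_index(mol, assignment, mol.get_bond(j, k))
    return _SB_FROM_ANGLE[(at, bt1, bt2)]


def torsion_type_index(mol, assignment, i: int, j: int, k: int, l: int) -> int:
    btjk = bond_type_index(mol, assignment, mol.get_bond(j, k))
    btij = bond_type_index(mol, assignment, mol.get_bond(i, j))
    btkl = bond_type_index(mol, assignment, mol.get_bond(k, l))
    tt = 0
    if btjk == 1:
        tt = 1
    elif btij == 1 or btkl == 1:
        tt = 2
    if _in_common_ring(mol, (i, j, k, l), 4):
        tt = 4
    elif _in_common_ring(mol, (i, j, k, l), 5):
        types = [assignment.numeric_types[x] for x in (i, j, k, l)]
        if 1 in types:
            tt = 5
    return tt


# ----------------------------------------------------------------------
# vdW pair parameters and bond charge increments
# ----------------------------------------------------------------------

def vdw_pair_parameters(tables: ParameterTables, ti: int, tj: int):
    """Buffered 14-7 pair parameters (R*_ij in A, eps_ij in kcal/mol).

    Published combination rules: R*_ii = A_i alpha_i^0.25; the cross minimum
    distance uses the arithmetic mean expanded by B(1 - exp(-beta gamma^2))
    unless either atom is a donor; eps from the Slater-Kirkwood expression;
    donor-acceptor pairs scale R* by 0.8 and eps by 0.5.
    """
    ai, ni, aa_i, gi, dai = tables.vdw[ti]
    aj, nj, aa_j, gj, daj = tables.vdw[tj]
    rs_i = aa_i * ai ** VDW_POWER
    rs_j = aa_j * aj ** VDW_POWER
    gamma = (rs_i - rs_j) / (rs_i + rs_j)
    rs = 0.5 * (rs_i + rs_j)
    if dai != "D" and daj != "D":
        rs *= 1.0 + VDW_B * (1.0 - math.exp(-VDW_BETA * gamma * gamma))
    eps = (181.16 * gi * gj * ai * aj
           / (((ai / ni) ** 0.5 + (aj / nj) ** 0.5) * rs ** 6))
    if (dai == "D" and daj == "A") or (dai == "A" and daj == "D"):
        rs *= VDW_DARAD
        eps *= VDW_DAEPS
    return rs, eps


def bci_for_bond(tables: ParameterTables, bt: int, ti: int, tj: int):
    """Signed charge increment received by the atom of type ``tj`` from the
    atom of type ``ti`` across a bond of bond-type index ``bt``."""
    if ti == tj:
        return ParameterQueryResult((0.0,), PROV_EXACT)
    return lookup(tables, "bci", (bt, ti, tj))
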