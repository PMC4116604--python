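"""Molecular graph, conformer and SDF/MOL (V2000) input/output.

MMFF is an all-atom force field: molecules must carry explicit hydrogens,
3D coordinates and correct formal charges.  This module provides the small
data model every other layer consumes -- atoms, kekulized bonds, one
conformer, ring information -- plus a V2000 connection-table reader/writer
and a deterministic kekulization routine.

Conventions
-----------
* Atom indices are 0-based everywhere in memory; 1-based only inside SDF
  records.
* Bond orders are integers in {1, 2, 3} after kekulization.  The SDF
  "aromatic" order 4 is accepted on input and resolved by :func:`kekulize`.
* Coordinates are in Angstrom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "RingInfo",
    "SDFParseError",
    "KekulizationError",
    "read_sdf",
    "read_sdf_string",
    "write_sdf",
    "write_sdf_string",
    "kekulize",
    "enumerate_kekule_forms",
    "ring_perception",
]

# default valences used by the kekulization valence check; element -> neutral valence
_NEUTRAL_VALENCE = {1: 1, 5: 3, 6: 4, 7: 3, 8: 2, 9: 1, 14: 4, 15: 3, 16: 2,
                    17: 1, 35: 1, 53: 1}

_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F",
    11: "Na", 12: "Mg", 14: "Si", 15: "P", 16: "S", 17: "Cl", 19: "K",
    20: "Ca", 26: "Fe", 29: "Cu", 30: "Zn", 35: "Br", 53: "I",
}
_NUMBERS = {v: k for k, v in _SYMBOLS.items()}


class SDFParseError(ValueError):
    """Raised for malformed V2000 connection tables (names the record)."""


class KekulizationError(ValueError):
    """Raised when no alternating bond-order assignment exists."""


@dataclass
class Atom:
    index: int
    element: int
    formal_charge: int = 0
    is_aromatic_mmff: bool = False

    @property
    def symbol(self) -> str:
        return _SYMBOLS.get(self.element, f"El{self.element}")


@dataclass
class Bond:
    begin: int
    end: int
    order: int
    is_aromatic_mmff: bool = False

    def other(self, idx: int) -> int:
        if idx == self.begin:
            return self.end
        if idx == self.end:
            return self.begin
        raise ValueError(f"atom {idx} not in bond {self.begin}-{self.end}")

    def key(self) -> tuple[int, int]:
        return (self.begin, self.end) if self.begin < self.end else (self.end, self.begin)


class RingInfo:
    """All simple rings of size <= 7, with per-atom/per-bond membership."""

    def __init__(self, rings: Sequence[tuple[int, ...]]):
        self.rings = [tuple(r) for r in rings]
        self._atom_sizes: dict[int, set[int]] = {}
        self._bond_sizes: dict[tuple[int, int], set[int]] = {}
        for ring in self.rings:
            n = len(ring)
            for a in ring:
                self._atom_sizes.setdefault(a, set()).add(n)
            for a, b in zip(ring, ring[1:] + ring[:1]):
                k = (a, b) if a < b else (b, a)
                self._bond_sizes.setdefault(k, set()).add(n)

    def atom_ring_sizes(self, idx: int) -> set[int]:
        return self._atom_sizes.get(idx, set())

    def bond_ring_sizes(self, i: int, j: int) -> set[int]:
        k = (i, j) if i < j else (j, i)
        return self._bond_sizes.get(k, set())

    def atom_in_ring_of_size(self, idx: int, size: int) -> bool:
        return size in self.atom_ring_sizes(idx)

    def bond_in_ring_of_size(self, i: int, j: int, size: int) -> bool:
        return size in self.bond_ring_sizes(i, j)

    def rings_of_size(self, size: int) -> list[tuple[int, ...]]:
        return [r for r in self.rings if len(r) == size]


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    coordinates: np.ndarray | None = None  # (n_atoms, 3), Angstrom
    title: str = ""
    _ring_info: RingInfo | None = field(default=None, repr=False)
    _neighbors: list[list[int]] | None = field(default=None, repr=False)

    # -- graph queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, idx: int) -> list[int]:
        if self._neighbors is None:
            nbrs: list[list[int]] = [[] for _ in self.atoms]
            for b in self.bonds:
                nbrs[b.begin].append(b.end)
                nbrs[b.end].append(b.begin)
            self._neighbors = [sorted(x) for x in nbrs]
        return self._neighbors[idx]

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def get_bond(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.begin, b.end} == {i, j}:
                return b
        return None

    def bond_order_sum(self, idx: int) -> int:
        return sum(b.order for b in self.bonds if idx in (b.begin, b.end))

    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def ring_info(self) -> RingInfo:
        if self._ring_info is None:
            self._ring_info = ring_perception(self)
        return self._ring_info

    def invalidate_caches(self) -> None:
        self._ring_info = None
        self._neighbors = None

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.begin, b.end) for b in self.bonds)
        return g

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[Atom(a.index, a.element, a.formal_charge, a.is_aromatic_mmff)
                   for a in self.atoms],
            bonds=[Bond(b.begin, b.end, b.order, b.is_aromatic_mmff)
                   for b in self.bonds],
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
            title=self.title,
        )

    def permuted(self, perm: Sequence[int]) -> "Molecule":
        """Return a copy with atoms reordered: new index ``perm[i]`` holds old atom i."""
        perm = list(perm)
        if sorted(perm) != list(range(self.n_atoms)):
            raise ValueError("not a permutation of atom indices")
        atoms = [None] * self.n_atoms
        for old, new in enumerate(perm):
            a = self.atoms[old]
            atoms[new] = Atom(new, a.element, a.formal_charge, a.is_aromatic_mmff)
        bonds = [Bond(min(perm[b.begin], perm[b.end]), max(perm[b.begin], perm[b.end]),
                      b.order, b.is_aromatic_mmff) for b in self.bonds]
        coords = None
        if self.coordinates is not None:
            coords = np.empty_like(self.coordinates)
            for old, new in enumerate(perm):
                coords[new] = self.coordinates[old]
        return Molecule(atoms=atoms, bonds=bonds, coordinates=coords, title=self.title)


# ----------------------------------------------------------------------
# ring perception
# ----------------------------------------------------------------------

def ring_perception(mol: Molecule, max_size: int = 7) -> RingInfo:
    """Enumerate every simple cycle of size <= ``max_size``.

    MMFF only ever asks about membership in 3-, 4-, 5- and 6-membered rings,
    so exhaustive enumeration of small cycles (rather than an SSSR selection)
    is both sufficient and unambiguous.
    """
    g = mol.to_graph()
    rings = []
    for cyc in nx.simple_cycles(g, length_bound=max_size):
        if len(cyc) >= 3:
            # canonical rotation/direction: start at min atom, go toward smaller neighbor
            m = cyc.index(min(cyc))
            cyc = cyc[m:] + cyc[:m]
            if cyc[1] > cyc[-1]:
                cyc = [cyc[0]] + list(reversed(cyc[1:]))
            rings.append(tuple(cyc))
    rings = sorted(set(rings), key=lambda r: (len(r), r))
    return RingInfo(rings)


# ----------------------------------------------------------------------
# kekulization
# ----------------------------------------------------------------------

def _pi_donor(atom: Atom, degree: int) -> bool:
    """Can this atom sit in an aromatic ring without a double bond?

    Divalent O/S (furan-like), trivalent neutral N (pyrrole-like), anionic
    carbon/nitrogen: these contribute a lone pair instead of a pi bond.
    """
    el, q = atom.element, atom.formal_charge
    if el in (8, 16) and q == 0 and degree == 2:
        return True
    if el == 7 and ((q == 0 and degree == 3) or (q == -1 and degree == 2)):
        return True
    if el == 6 and q == -1 and degree == 3:
        return True
    if el == 7 and q == 1 and degree == 4:
        return True
    return False


def kekulize(mol: Molecule, prefer: Sequence[tuple[int, int]] = ()) -> Molecule:
    """Resolve aromatic (order 4) bonds into alternating single/double bonds.

    A perfect matching is sought on the subgraph of atoms that require one
    double bond each; atoms able to donate a lone pair may stay unmatched.
    The search is a deterministic backtracking over atoms in increasing index
    order, so the same input always yields the same kekule form.  ``prefer``
    biases the tie-break toward containing the given bonds, which lets the
    validation layer enumerate degenerate kekule forms.

    Already-kekulized input (no order-4 bonds) is returned unchanged
    (idempotence).
    """
    aromatic_bonds = [b for b in mol.bonds if b.order == 4]
    if not aromatic_bonds:
        _check_valences(mol)
        return mol

    out = mol.copy()
    arom_atoms = sorted({i for b in aromatic_bonds for i in (b.begin, b.end)})
    adj: dict[int, list[int]] = {a: [] for a in arom_atoms}
    for b in aromatic_bonds:
        adj[b.begin].append(b.end)
        adj[b.end].append(b.begin)
    for a in adj:
        adj[a].sort()

    # atoms that must receive exactly one double bond within the pi system:
    # anything that is not a lone-pair donor and has no double bond already
    # outside the aromatic subgraph
    needs = {}
    for a in arom_atoms:
        atom = out.atoms[a]
        deg = out.degree(a)
        has_exo_double = any(
            b.order in (2, 3) for b in out.bonds
            if a in (b.begin, b.end) and b.order != 4
        )
        needs[a] = not (_pi_donor(atom, deg) or has_exo_double)

    prefer_set = {tuple(sorted(p)) for p in prefer}
    matched: dict[int, int] = {}

    order = sorted(arom_atoms, key=lambda a: (not needs[a], a))
    # put atoms that *must* be matched first so failures surface early

    def backtrack(pos: int) -> bool:
        while pos < len(order) and (order[pos] in matched or not needs[order[pos]]):
            pos += 1
        if pos == len(order):
            return True
        a = order[pos]
        cands = [n for n in adj[a] if n not in matched and needs[n]]
        cands.sort(key=lambda n: ((tuple(sorted((a, n))) not in prefer_set), n))
        for n in cands:
            matched[a] = n
            matched[n] = a
            if backtrack(pos + 1):
                return True
            del matched[a]
            del matched[n]
        return False

    if not backtrack(0):
        raise KekulizationError(
            "no valid kekule assignment for aromatic atoms "
            f"{[a for a in arom_atoms if needs[a]]}"
        )

    for b in out.bonds:
        if b.order == 4:
            b.order = 2 if matched.get(b.begin) == b.end else 1
    out.invalidate_caches()
    _check_valences(out)
    return out


def _check_valences(mol: Molecule) -> None:
    """Cheap consistency check: bond-order sums within element norms."""
    for a in mol.atoms:
        ref = _NEUTRAL_VALENCE.get(a.element)
        if ref is None:
            continue
        bos = mol.bond_order_sum(a.index)
        # allowed valence shifts: charge and hypervalent S/P/N oxides
        allowed = {ref, ref + abs(a.formal_charge)}
        if a.element == 7:
            allowed |= {3 + a.formal_charge} if a.formal_charge > 0 else {3, 2}
        if a.element in (15, 16):
            allowed |= {3, 4, 5, 6}
        if a.element == 8 and a.formal_charge == -1:
            allowed |= {1}
        if a.element == 8 and a.formal_charge == 1:
            allowed |= {3}
        if a.element == 6 and a.formal_charge != 0:
            allowed |= {3}
        if a.element == 7 and a.formal_charge == -1:
            allowed |= {2}
        if bos not in allowed and bos != 0:
            raise KekulizationError(
                f"atom {a.index} ({a.symbol}, charge {a.formal_charge:+d}) has "
                f"bond-order sum {bos}, inconsistent with its valence"
            )


def enumerate_kekule_forms(mol: Molecule, limit: int = 64) -> list[Molecule]:
    """Enumerate distinct kekule forms of a molecule's aromatic system.

    Works on a copy whose current double bonds inside MMFF-aromatic rings are
    reset to order 4, then exhaustively re-matched.  Used by the validation
    layer to prove typing invariance across degenerate forms.
    """
    # collect the aromatic core from mmff flags if set, else from rings of
    # alternating single/double bonds
    arom_bonds = [b for b in mol.bonds if b.is_aromatic_mmff]
    if not arom_bonds:
        return [mol.copy()]
    proto = mol.copy()
    for b in proto.bonds:
        if b.is_aromatic_mmff:
            b.order = 4
    proto.invalidate_caches()

    forms: list[Molecule] = []
    seen: set[frozenset[tuple[int, int]]] = set()
    double_sets = _all_matchings(proto)
    for ds in double_sets[:limit]:
        if ds in seen:
            continue
        seen.add(ds)
        m = proto.copy()
        for b in m.bonds:
            if b.order == 4:
                b.order = 2 if b.key() in ds else 1
        m.invalidate_caches()
        forms.append(m)
    return forms


def _all_matchings(proto: Molecule) -> list[frozenset[tuple[int, int]]]:
    aromatic_bonds = [b for b in proto.bonds if b.order == 4]
    arom_atoms = sorted({i for b in aromatic_bonds for i in (b.begin, b.end)})
    adj: dict[int, list[int]] = {a: [] for a in arom_atoms}
    for b in aromatic_bonds:
        adj[b.begin].append(b.end)
        adj[b.end].append(b.begin)
    needs = {}
    for a in arom_atoms:
        deg = proto.degree(a)
        has_exo_double = any(
            b.order in (2, 3) for b in proto.bonds
            if a in (b.begin, b.end) and b.order != 4
        )
        needs[a] = not (_pi_donor(proto.atoms[a], deg) or has_exo_double)
    must = [a for a in arom_atoms if needs[a]]

    results: list[frozenset[tuple[int, int]]] = []
    matched: dict[int, int] = {}

    def backtrack(i: int) -> None:
        while i < len(must) and must[i] in matched:
            i += 1
        if i == len(must):
            results.append(frozenset(
                tuple(sorted((a, b))) for a, b in matched.items() if a < b))
            return
        a = must[i]
        for n in sorted(adj[a]):
            if n in matched or not needs[n]:
                continue
            matched[a] = n
            matched[n] = a
            backtrack(i + 1)
            del matched[a]
            del matched[n]

    backtrack(0)
    return sorted(set(results), key=sorted)


# ----------------------------------------------------------------------
# SDF / MOL V2000
# ----------------------------------------------------------------------

_OLD_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


def _parse_record(lines: list[str], record_index: int) -> Molecule:
    if len(lines) < 4:
        raise SDFParseError(f"record {record_index}: truncated header block")
    title = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise SDFParseError(
            f"record {record_index}: malformed counts line {counts!r}") from exc
    if "V3000" in counts:
        raise SDFParseError(
            f"record {record_index}: V3000 connection tables are not supported")

    atoms: list[Atom] = []
    coords = np.empty((n_atoms, 3), dtype=float)
    old_charges: dict[int, int] = {}
    base = 4
    if len(lines) < base + n_atoms + n_bonds:
        raise SDFParseError(f"record {record_index}: truncated connection table")
    for i in range(n_atoms):
        ln = lines[base + i]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            sym = ln[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise SDFParseError(
                f"record {record_index}: malformed atom line {i + 1}: {ln!r}") from exc
        if sym not in _NUMBERS:
            raise SDFParseError(
                f"record {record_index}: unknown element symbol {sym!r} on atom "
                f"line {i + 1}")
        coords[i] = (x, y, z)
        atoms.append(Atom(index=i, element=_NUMBERS[sym]))
        cc = ln[36:39].strip()
        if cc:
            code = int(cc)
            if code in _OLD_CHARGE_CODES:
                old_charges[i] = _OLD_CHARGE_CODES[code]

    bonds: list[Bond] = []
    seen_bonds: set[tuple[int, int]] = set()
    for i in range(n_bonds):
        ln = lines[base + n_atoms + i]
        try:
            a = int(ln[0:3]) - 1
            b = int(ln[3:6]) - 1
            order = int(ln[6:9])
        except (ValueError, IndexError) as exc:
            raise SDFParseError(
                f"record {record_index}: malformed bond line {i + 1}: {ln!r}") from exc
        if a == b or not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise SDFParseError(
                f"record {record_index}: bond line {i + 1} references invalid atoms")
        k = (min(a, b), max(a, b))
        if k in seen_bonds:
            raise SDFParseError(
                f"record {record_index}: duplicate bond {a + 1}-{b + 1}")
        seen_bonds.add(k)
        if order not in (1, 2, 3, 4):
            raise SDFParseError(
                f"record {record_index}: unsupported bond order {order}")
        bonds.append(Bond(begin=a, end=b, order=order))

    m_chg: dict[int, int] = {}
    for ln in lines[base + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n = int(fields[2])
            for j in range(n):
                idx = int(fields[3 + 2 * j]) - 1
                m_chg[idx] = int(fields[4 + 2 * j])
        elif ln.startswith("M  END"):
            break

    charges = m_chg if m_chg else old_charges
    for idx, q in charges.items():
        atoms[idx].formal_charge = q

    if not np.all(np.isfinite(coords)):
        raise SDFParseError(f"record {record_index}: non-finite coordinates")
    if n_atoms and np.allclose(coords[:, 2], 0.0) and n_atoms > 3:
        dims = lines[3][20:22].strip() if len(lines[3]) >= 22 else ""
        if dims == "2D":
            raise SDFParseError(
                f"record {record_index}: 2D coordinates; MMFF requires 3D input")

    return Molecule(atoms=atoms, bonds=bonds, coordinates=coords, title=title)


def read_sdf_string(text: str) -> list[Molecule]:
    mols: list[Molecule] = []
    record: list[str] = []
    idx = 0
    for raw in text.splitlines():
        if raw.strip() == "$$$$":
            if any(s.strip() for s in record):
                mols.append(_parse_record(record, idx))
                idx += 1
            record = []
        else:
            record.append(raw)
    if any(s.strip() for s in record):
        mols.append(_parse_record(record, idx))
    return mols


def read_sdf(path) -> list[Molecule]:
    """Read all records of an SDF/MOL file (V2000) into Molecules.

    ``M  CHG`` blocks populate formal charges (they override the legacy
    atom-block charge column, as the format prescribes).  Records are
    returned in file order and atom indices follow file order.
    """
    with open(path, "r") as fh:
        return read_sdf_string(fh.read())


def _format_record(mol: Molecule) -> str:
    if mol.coordinates is None:
        raise ValueError(f"molecule {mol.title!r} has no conformer")
    if mol.n_atoms > 999:
        raise ValueError("V2000 connection tables are limited to 999 atoms")
    lines = [mol.title, "  mmffkit", ""]
    lines.append(f"{mol.n_atoms:3d}{mol.n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        x, y, z = mol.coordinates[a.index]
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.symbol:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        lines.append(f"{b.begin + 1:3d}{b.end + 1:3d}{b.order:3d}  0")
    charged = [a for a in mol.atoms if a.formal_charge != 0]
    for i in range(0, len(charged), 8):
        chunk = charged[i:i + 8]
        s = f"M  CHG{len(chunk):3d}"
        for a in chunk:
            s += f"{a.index + 1:4d}{a.formal_charge:4d}"
        lines.append(s)
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_sdf_string(mols: Iterable[Molecule]) -> str:
    return "".join(_format_record(m) for m in mols)


def write_sdf(mols: Iterable[Molecule], path) -> None:
    """Write molecules as V2000 SDF records (coordinates at 4 decimals)."""
    with open(path, "w") as fh:
        fh.write(write_sdf_string(mols))
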