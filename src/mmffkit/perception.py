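"""MMFF-specific perception: aromaticity, atom typing, and the charge model.

The MMFF aromaticity model differs from the usual toolkit conventions: it is
re-perceived from a kekulized structure over 5- and 6-membered rings using a
Hueckel 4n+2 count in which lone-pair heteroatoms contribute two electrons
and tricoordinate carbocations contribute none.  Atom types are then assigned
to heavy atoms first and to hydrogens afterwards (a hydrogen's type is a pure
function of its heavy neighbor's type).  Finally the MMFF charge model turns
integer formal charges into fractional "resonant" formal charges shared over
equivalent heteroatoms, and partial charges are accumulated from bond charge
increments.

Only the published MMFF chemical domain is typable; an atom outside the rule
set raises :class:`TypingError` naming the atom and its environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_model import Atom, Bond, Molecule
from .param_store import (
    ParameterTables,
    bond_type_index,
    bci_for_bond,
    PROV_MISSING,
)

__all__ = [
    "MMFFAtomAssignment",
    "TypingError",
    "perceive_aromaticity_mmff",
    "assign_atom_types",
    "assign_fractional_formal_charges",
    "compute_partial_charges",
    "atom_assignment",
]


class TypingError(ValueError):
    """Atom's element/environment is outside the implemented MMFF domain."""


@dataclass
class MMFFAtomAssignment:
    """Per-atom MMFF typing and charge state."""

    symbolic_types: list[str]
    numeric_types: list[int]
    fractional_formal_charges: list[float] = field(default_factory=list)
    partial_charges: list[float] = field(default_factory=list)
    properties: dict = field(default_factory=dict)   # numeric type -> row

    def summary_rows(self):
        for i, (s, n) in enumerate(zip(self.symbolic_types, self.numeric_types)):
            q = self.partial_charges[i] if self.partial_charges else float("nan")
            yield i, s, n, q


# ----------------------------------------------------------------------
# aromaticity
# ----------------------------------------------------------------------

def _lone_pair_donor(mol: Molecule, idx: int, ring: tuple) -> bool:
    """Atom can contribute two pi electrons to this ring."""
    a = mol.atoms[idx]
    deg = mol.degree(idx)
    has_double = any(b.order >= 2 for b in mol.bonds if idx in (b.begin, b.end))
    if has_double:
        return False
    if a.element in (8, 16) and deg == 2 and a.formal_charge == 0:
        return True
    if a.element == 7:
        if a.formal_charge == 0 and deg == 3:
            return True
        if a.formal_charge == -1 and deg == 2:
            return True
    if a.element == 6 and a.formal_charge == -1 and deg == 3:
        return True
    return False


def _pi_contribution(mol: Molecule, idx: int, ring: tuple,
                     aromatic_atoms: set) -> int | None:
    """Electrons atom ``idx`` contributes to ``ring``; None disqualifies."""
    a = mol.atoms[idx]
    ring_set = set(ring)
    for b in mol.bonds:
        if idx not in (b.begin, b.end) or b.order < 2:
            continue
        other = b.other(idx)
        if other in ring_set:
            return 1                      # double bond inside the ring
        if other in aromatic_atoms:
            return 1                      # exocyclic into an aromatic ring
        # exocyclic double bond out of the pi system (e.g. C=O) removes the
        # atom's electron from this ring
        return None
    if _lone_pair_donor(mol, idx, ring):
        return 2
    if a.element == 6 and a.formal_charge == 1 and mol.degree(idx) == 3:
        return 0                          # tropylium-like cationic center
    if a.element == 7 and a.formal_charge == 1 and mol.degree(idx) == 4:
        return None
    return None


def perceive_aromaticity_mmff(mol: Molecule) -> Molecule:
    """Set MMFF aromatic flags on atoms/bonds of qualifying 5-/6-rings.

    Iterates to a fixpoint so that fused systems whose kekule form places a
    shared double bond in the neighboring ring are still recognized.  Flags
    are independent of input atom order and of the kekule form chosen.
    """
    for a in mol.atoms:
        a.is_aromatic_mmff = False
    for b in mol.bonds:
        b.is_aromatic_mmff = False

    candidates = [r for r in mol.ring_info.rings if len(r) in (5, 6)]
    aromatic_atoms: set[int] = set()
    aromatic_rings: list[tuple] = []
    pending = list(candidates)
    changed = True
    while changed:
        changed = False
        still = []
        for ring in pending:
            contribs = [_pi_contribution(mol, i, ring, aromatic_atoms)
                        for i in ring]
            if any(c is None for c in contribs):
                still.append(ring)
                continue
            if sum(contribs) == 6:
                aromatic_rings.append(ring)
                aromatic_atoms.update(ring)
                changed = True
            else:
                still.append(ring)
        pending = still

    for ring in aromatic_rings:
        rs = set(ring)
        for i in ring:
            mol.atoms[i].is_aromatic_mmff = True
        for a, b in zip(ring, ring[1:] + ring[:1]):
            bd = mol.get_bond(a, b)
            if bd is not None:
                bd.is_aromatic_mmff = True
    mol._aromatic_rings = aromatic_rings  # cached for typing
    return mol


def _aromatic_rings(mol: Molecule) -> list[tuple]:
    rings = getattr(mol, "_aromatic_rings", None)
    if rings is None:
        perceive_aromaticity_mmff(mol)
        rings = mol._aromatic_rings
    return rings


# ----------------------------------------------------------------------
# heavy-atom typing
# ----------------------------------------------------------------------

def _env(mol: Molecule, idx: int) -> dict:
    a = mol.atoms[idx]
    bonds = [b for b in mol.bonds if idx in (b.begin, b.end)]
    nbrs = mol.neighbors(idx)
    doubles = [b.other(idx) for b in bonds if b.order == 2]
    triples = [b.other(idx) for b in bonds if b.order == 3]
    return {
        "atom": a, "el": a.element, "q": a.formal_charge,
        "deg": len(nbrs), "nbrs": nbrs, "bonds": bonds,
        "doubles": doubles, "triples": triples,
        "bosum": sum(b.order for b in bonds),
        "nbr_el": [mol.atoms[n].element for n in nbrs],
    }


def _terminal_oxygens(mol: Molecule, center: int, element: int = 8) -> list[int]:
    return [n for n in mol.neighbors(center)
            if mol.atoms[n].element == element and mol.degree(n) == 1]


def _ring56_position(mol: Molecule, idx: int):
    """(ring, n_donors, distance-from-pivot) for an atom in an aromatic 5-ring.

    distance 1 = alpha, 2 = beta; None when the ring has no unique pivot.
    """
    for ring in _aromatic_rings(mol):
        if len(ring) != 5 or idx not in ring:
            continue
        donors = [i for i in ring if _lone_pair_donor(mol, i, ring)]
        if len(donors) != 1:
            return ring, len(donors), None
        pivot = donors[0]
        pos = ring.index(idx)
        piv = ring.index(pivot)
        d = min((pos - piv) % 5, (piv - pos) % 5)
        return ring, 1, d
    return None, 0, None


def _in_aromatic_ring_of_size(mol: Molecule, idx: int, size: int) -> bool:
    return any(len(r) == size and idx in r for r in _aromatic_rings(mol))


def _type_carbon(mol: Molecule, idx: int) -> str:
    e = _env(mol, idx)
    if mol.atoms[idx].is_aromatic_mmff:
        ring, n_donors, d = _ring56_position(mol, idx)
        if ring is not None:
            # 5-ring types take precedence for atoms fused into 6-rings
            ring_n = [i for i in ring if mol.atoms[i].element == 7]
            ring_charge = sum(mol.atoms[i].formal_charge for i in ring)
            if ring_charge > 0 and len(ring_n) >= 2:
                # imidazolium-like: charge delocalized over N-C-N
                if sum(1 for n in e["nbrs"] if n in ring_n) == 2:
                    return "CIM+"
                return "C5"
            if d == 1:
                return "C5A"
            if d == 2:
                return "C5B"
            return "C5"
        if _in_aromatic_ring_of_size(mol, idx, 6):
            return "CB"
    if e["triples"]:
        other = e["triples"][0]
        if mol.atoms[other].element == 7 and e["deg"] == 1:
            return "C%"
        return "CSP"
    if len(e["doubles"]) == 2:
        return "=C="
    if len(e["doubles"]) == 1:
        other = e["doubles"][0]
        oel = mol.atoms[other].element
        term_o = _terminal_oxygens(mol, idx)
        term_s = _terminal_oxygens(mol, idx, 16)
        if len(term_o) >= 2 and sum(mol.atoms[o].formal_charge for o in term_o) < 0:
            return "CO2M"
        if len(term_s) >= 2 and sum(mol.atoms[s].formal_charge for s in term_s) < 0:
            return "CS2M"
        n_nbrs = [n for n in e["nbrs"] if mol.atoms[n].element == 7]
        if oel == 7:
            group_charge = mol.atoms[other].formal_charge + sum(
                mol.atoms[n].formal_charge for n in n_nbrs)
            if group_charge > 0 and len(n_nbrs) >= 2:
                return "CGD+" if len(n_nbrs) == 3 else "CNN+"
            if len(n_nbrs) == 3:
                return "CGD"
            return "C=N"
        if oel == 8:
            if any(mol.atoms[n].element == 7 for n in e["nbrs"]):
                return "C=ON"
            if any(mol.atoms[n].element == 8 and n != other for n in e["nbrs"]):
                return "COO"
            return "C=OR"
        if oel == 16:
            return "C=S"
        if oel == 15:
            return "C=P"
        if oel == 6:
            if mol.ring_info.atom_in_ring_of_size(idx, 4) and \
                    any(mol.ring_info.bond_in_ring_of_size(idx, other, 4)
                        for _ in (0,)):
                return "CE4R"
            return "C=C"
        return "C=C"
    if e["q"] == 0:
        sizes = mol.ring_info.atom_ring_sizes(idx)
        if 3 in sizes:
            return "CR3R"
        if 4 in sizes:
            return "CR4R"
        return "CR"
    raise TypingError(
        f"atom {idx}: carbon with charge {e['q']:+d}, degree {e['deg']} is "
        "outside the implemented MMFF typing domain")


def _type_nitrogen(mol: Molecule, idx: int) -> str:
    e = _env(mol, idx)
    term_o = _terminal_oxygens(mol, idx)
    if mol.atoms[idx].is_aromatic_mmff:
        ring, n_donors, d = _ring56_position(mol, idx)
        if ring is not None:
            ring_charge = sum(mol.atoms[i].formal_charge for i in ring)
            is_donor = _lone_pair_donor(mol, idx, ring)
            if term_o:
                return {1: "N5AX", 2: "N5BX"}.get(d, "N5OX")
            if ring_charge > 0:
                # positive charge delocalized over the ring nitrogens
                ring_n = [i for i in ring if mol.atoms[i].element == 7]
                if len(ring_n) >= 2:
                    # the two N flanking the shared carbon carry the charge
                    flank = [i for i in ring_n if any(
                        mol.atoms[c].element == 6 and
                        sum(1 for x in mol.neighbors(c) if x in ring_n) == 2
                        for c in mol.neighbors(i) if c in ring)]
                    if idx in flank or len(ring_n) == 2:
                        return "NIM+"
                return {1: "N5A+", 2: "N5B+"}.get(d, "N5+")
            if ring_charge < 0 and e["deg"] == 2 and not is_donor and \
                    n_donors != 1:
                return "N5M"
            if e["q"] == -1 and e["deg"] == 2:
                return "N5M"
            if is_donor and n_donors == 1:
                return "NPYL"
            if d == 1:
                return "N5A"
            if d == 2:
                return "N5B"
            return "N5"
        if _in_aromatic_ring_of_size(mol, idx, 6):
            if term_o:
                return "NPOX"
            if e["q"] == 1:
                return "NPD+"
            return "NPYD"
    if len(term_o) >= 3:
        return "NO3"
    if len(term_o) == 2:
        return "NO2"
    if e["triples"]:
        if e["deg"] == 2:
            return "NR%"
        return "NSP"
    if len(e["doubles"]) == 2:
        return "=N="
    if len(e["doubles"]) == 1:
        other = e["doubles"][0]
        oel = mol.atoms[other].element
        if oel == 8 and e["deg"] == 2:
            return "N=O"
        if term_o and e["deg"] == 3:
            return "N2OX"
        if e["q"] == 1:
            if oel == 6:
                c_nbr_n = [n for n in mol.neighbors(other)
                           if mol.atoms[n].element == 7 and n != idx]
                if len(c_nbr_n) == 2:
                    return "NGD+"
                if len(c_nbr_n) == 1:
                    return "NCN+"
                return "N+=C"
            if oel == 7:
                return "N+=N"
        if oel == 6:
            return "N=C"
        if oel == 7:
            other_doubles = sum(
                1 for b in mol.bonds
                if other in (b.begin, b.end) and b.order == 2)
            if other_doubles == 2 and e["deg"] == 1:
                return "NAZT"           # terminal azide nitrogen
            return "N=N"
        if oel == 16:
            return "NSO"
    # single-bonded nitrogen
    if term_o and e["deg"] == 4:
        return "N3OX"
    if e["q"] == 1 and e["deg"] == 4:
        return "NR+"
    if e["q"] == 1 and e["deg"] == 3 and not e["doubles"]:
        # protonated amine written with explicit charge but 3 bonds (no H?)
        return "NR+"
    if e["q"] == -1 and e["deg"] == 2:
        return "NM"
    if e["q"] == 0:
        # delocalized lone pair contexts, checked most-specific first
        amide = thioamide = False
        amidine = amidinium = guanidinium = False
        enamine = False
        nitrile = False
        sulfonyl = 0
        phosphoryl = 0
        nn_deloc = False
        for n in e["nbrs"]:
            nel = mol.atoms[n].element
            if nel == 6:
                for b in mol.bonds:
                    if n not in (b.begin, b.end):
                        continue
                    o2 = b.other(n)
                    if o2 == idx:
                        continue
                    if b.order == 2 and mol.atoms[o2].element == 8:
                        amide = True
                    elif b.order == 2 and mol.atoms[o2].element == 16:
                        thioamide = True
                    elif b.order == 2 and mol.atoms[o2].element == 7:
                        # amidine N-C=N; cationic when the imine N carries +
                        c_n_nbrs = [x for x in mol.neighbors(n)
                                    if mol.atoms[x].element == 7]
                        if mol.atoms[o2].formal_charge > 0:
                            if len(c_n_nbrs) == 3:
                                guanidinium = True
                            else:
                                amidinium = True
                        else:
                            amidine = True
                    elif b.order == 2 and mol.atoms[o2].element == 6:
                        enamine = True
                    elif b.order == 3 and mol.atoms[o2].element == 7:
                        nitrile = True
                    elif b.order == 3 and mol.atoms[o2].element == 6:
                        enamine = True
                if mol.atoms[n].is_aromatic_mmff:
                    enamine = True
            elif nel == 7:
                for b in mol.bonds:
                    if n in (b.begin, b.end) and b.order == 2 and \
                            b.other(n) != idx:
                        nn_deloc = True
            elif nel == 16:
                sulfonyl = max(sulfonyl, len(_terminal_oxygens(mol, n)))
            elif nel == 15:
                phosphoryl = max(phosphoryl, len(_terminal_oxygens(mol, n)))
        if guanidinium:
            return "NGD+"
        if amidinium:
            return "NCN+"
        if amide or thioamide:
            return "NC=S" if (thioamide and not amide) else "NC=O"
        if sulfonyl >= 2:
            return "NSO2"
        if phosphoryl >= 2:
            return "NPO2"
        if nitrile:
            return "NC%N"
        if amidine:
            return "NC=N"
        if nn_deloc:
            return "NN=C"
        if enamine:
            return "NC=C"
        return "NR"
    raise TypingError(
        f"atom {idx}: nitrogen with charge {e['q']:+d}, degree {e['deg']} is "
        "outside the implemented MMFF typing domain")


def _type_oxygen(mol: Molecule, idx: int) -> str:
    e = _env(mol, idx)
    if mol.atoms[idx].is_aromatic_mmff:
        return "OFUR"
    if e["q"] == 1:
        if e["doubles"]:
            return "O=+"
        return "O+"
    if e["deg"] == 2 and all(el == 1 for el in e["nbr_el"]):
        return "OH2"
    if len(e["doubles"]) == 1 and e["deg"] == 1:
        other = e["doubles"][0]
        oel = mol.atoms[other].element
        if oel == 6:
            siblings = _terminal_oxygens(mol, other)
            sib_s = _terminal_oxygens(mol, other, 16)
            if len(siblings) + len(sib_s) >= 2 and (
                    sum(mol.atoms[o].formal_charge for o in siblings) +
                    sum(mol.atoms[s].formal_charge for s in sib_s)) < 0:
                return "O2CM"
            if any(mol.atoms[n].element == 7 for n in mol.neighbors(other)):
                return "O=CN"
            if any(mol.atoms[n].element == 8 and n != idx
                   for n in mol.neighbors(other)):
                return "O=CO"
            return "O=CR"
        if oel == 7:
            if len(_terminal_oxygens(mol, other)) >= 2:
                return "O2N"
            if mol.degree(other) == 2:
                return "O=N"
            return "OXN"
        if oel == 16:
            if len(_terminal_oxygens(mol, other)) >= 2:
                return "O2S"
            return "O=S"
        if oel == 15:
            return "OP" if len(_terminal_oxygens(mol, other)) == 1 else \
                {2: "O2P", 3: "O3P", 4: "O4P"}[len(_terminal_oxygens(mol, other))]
        return "O=C"
    if e["deg"] == 1:
        other = e["nbrs"][0]
        oel = mol.atoms[other].element
        n_term = len(_terminal_oxygens(mol, other))
        if oel == 6:
            siblings = _terminal_oxygens(mol, other)
            sib_s = _terminal_oxygens(mol, other, 16)
            has_double_o = any(
                b.order == 2 and mol.atoms[b.other(other)].element in (8, 16)
                for b in mol.bonds if other in (b.begin, b.end))
            if (len(siblings) + len(sib_s) >= 2 or has_double_o) and \
                    mol.atoms[idx].formal_charge < 0:
                return "O2CM"
            return "OM"
        if oel == 7:
            if n_term >= 3:
                return "O3N"
            if n_term == 2:
                return "O2N"
            return "OXN"
        if oel == 16:
            return {1: "O-S", 2: "O2S", 3: "O3S", 4: "O4S"}[max(n_term, 1)]
        if oel == 15:
            return {1: "OP", 2: "O2P", 3: "O3P", 4: "O4P"}[max(n_term, 1)]
        if oel == 17:
            return "O4CL"
        if oel == 1:
            return "OM"          # hydroxide anion
        return "OM"
    if e["deg"] == 2:
        # divalent oxygen; choose the most specific published label
        labels = []
        for n in e["nbrs"]:
            nel = mol.atoms[n].element
            if nel == 1:
                continue
            if nel == 6:
                if any(b.order == 2 and mol.atoms[b.other(n)].element == 8
                       for b in mol.bonds if n in (b.begin, b.end)):
                    labels.append("OC=O")
                elif any(b.order == 2 and mol.atoms[b.other(n)].element == 7
                         for b in mol.bonds if n in (b.begin, b.end)):
                    labels.append("OC=N")
                elif any(b.order == 2 and mol.atoms[b.other(n)].element == 16
                         for b in mol.bonds if n in (b.begin, b.end)):
                    labels.append("OC=S")
                elif mol.atoms[n].is_aromatic_mmff or any(
                        b.order == 2 and mol.atoms[b.other(n)].element == 6
                        for b in mol.bonds if n in (b.begin, b.end)):
                    labels.append("OC=C")
                else:
                    labels.append("OR")
            elif nel == 7:
                nt = len(_terminal_oxygens(mol, n))
                labels.append("ONO2" if nt >= 2 else "ON=O")
            elif nel == 16:
                nt = len(_terminal_oxygens(mol, n))
                labels.append({0: "-OS", 1: "OS=O", 2: "OSO2",
                               3: "OSO3"}.get(nt, "OSO3"))
            elif nel == 15:
                nt = len(_terminal_oxygens(mol, n))
                labels.append({0: "-OP", 1: "OPO", 2: "OPO2",
                               3: "OPO3"}.get(nt, "OPO3"))
            else:
                labels.append("-O-")
        priority = ["ONO2", "ON=O", "OSO3", "OSO2", "OS=O", "-OS", "OPO3",
                    "OPO2", "OPO", "-OP", "OC=O", "OC=S", "OC=N", "OC=C",
                    "OR", "-O-"]
        for p in priority:
            if p in labels:
                return p
        return "OR"
    raise TypingError(
        f"atom {idx}: oxygen with charge {e['q']:+d}, degree {e['deg']} is "
        "outside the implemented MMFF typing domain")


def _type_sulfur(mol: Molecule, idx: int) -> str:
    e = _env(mol, idx)
    if mol.atoms[idx].is_aromatic_mmff:
        return "STHI"
    term_o = _terminal_oxygens(mol, idx)
    if e["deg"] == 1:
        other = e["nbrs"][0]
        oel = mol.atoms[other].element
        if oel == 15:
            return "S-P"
        if oel == 6:
            sib_s = _terminal_oxygens(mol, other, 16)
            if len(sib_s) >= 2 and (
                    sum(mol.atoms[s].formal_charge for s in sib_s) < 0):
                return "S2CM"
            if e["doubles"]:
                return "S=C"
            return "SM"
        if e["doubles"]:
            return "S=C"
        return "SM"
    if e["deg"] == 4 or len(term_o) >= 2:
        return {2: "SO2", 3: "SO3", 4: "SO4"}.get(len(term_o), "SO2")
    if len(term_o) == 1 and e["deg"] == 3:
        if e["q"] == -1 or any(mol.atoms[o].formal_charge < 0 for o in term_o):
            return "SO2M"
        return "S=O"
    if len(e["doubles"]) == 1 and mol.atoms[e["doubles"][0]].element == 7:
        return ">S=N"
    if len(e["doubles"]) == 1 and mol.atoms[e["doubles"][0]].element == 6:
        return "S=C"
    if e["deg"] == 2 and not e["doubles"]:
        return "S"
    raise TypingError(
        f"atom {idx}: sulfur environment outside the implemented MMFF domain")


def _type_phosphorus(mol: Molecule, idx: int) -> str:
    e = _env(mol, idx)
    if e["deg"] == 4:
        n_o = len(_terminal_oxygens(mol, idx))
        return {0: "PTET", 1: "PO", 2: "PO2", 3: "PO3", 4: "PO4"}[n_o]
    if len(e["doubles"]) == 1 and mol.atoms[e["doubles"][0]].element == 6:
        return "-P=C"
    if e["deg"] == 3:
        return "P"
    raise TypingError(
        f"atom {idx}: phosphorus environment outside the implemented MMFF domain")


_SIMPLE_ELEMENTS = {
    9: ("F", "F-"), 17: ("CL", "CL-"), 35: ("BR", "BR-"), 53: ("I", None),
}
_METALS = {3: "LI+", 11: "NA+", 19: "K+", 12: "MG+2", 20: "CA+2", 30: "ZN+2"}


def _type_heavy(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    el = a.element
    if el == 6:
        return _type_carbon(mol, idx)
    if el == 7:
        return _type_nitrogen(mol, idx)
    if el == 8:
        return _type_oxygen(mol, idx)
    if el == 16:
        return _type_sulfur(mol, idx)
    if el == 15:
        return _type_phosphorus(mol, idx)
    if el == 14:
        return "SI"
    if el in _SIMPLE_ELEMENTS:
        bonded, anion = _SIMPLE_ELEMENTS[el]
        if mol.degree(idx) == 0 and a.formal_charge == -1:
            if anion is None:
                raise TypingError(f"atom {idx}: no MMFF type for iodide anion")
            return anion
        if el == 17 and len(_terminal_oxygens(mol, idx)) == 4:
            return "CLO4"
        return bonded
    if el in _METALS and mol.degree(idx) == 0:
        return _METALS[el]
    if el == 26:
        return "FE+2" if a.formal_charge == 2 else "FE+3"
    if el == 29:
        return "CU+1" if a.formal_charge == 1 else "CU+2"
    raise TypingError(
        f"atom {idx}: element {a.symbol} (degree {mol.degree(idx)}, charge "
        f"{a.formal_charge:+d}) is outside the implemented MMFF typing domain")


# ----------------------------------------------------------------------
# hydrogen typing (pure function of the heavy neighbor's type)
# ----------------------------------------------------------------------

_H_FROM_HEAVY_NUMERIC = {
    8: "HNR", 39: "HPYL", 62: "HNM", 67: "HNOX", 68: "HNOX",
    34: "HNR+", 58: "HPD+", 81: "HIM+", 55: "HNN+", 56: "HGD+", 54: "HNC+",
    9: "HN=C", 10: "HNCO", 40: "HNCC", 43: "HNSO2", 48: "HNSO2",
    70: "HOH", 49: "HO+", 51: "HO=+",
    15: "HS", 17: "HS=N", 72: "HS",
    26: "HP", 19: "HSI", 25: "HOP",
}

_H_FROM_HEAVY_SYMBOLIC = {
    "OR": "HOR", "-O-": "HO", "OM": "HO",
    "OC=O": "HOCO", "-OP": "HOP", "OPO": "HOP", "OPO2": "HOP", "OPO3": "HOP",
    "OC=C": "HOCC", "OC=N": "HOCN", "OC=S": "HOCC",
    "-OS": "HOS", "OS=O": "HOS", "OSO2": "HOS", "OSO3": "HOS", "OSO": "HOS",
    "N=N": "HN=N", "N=C": "HN=C",
    "NC=S": "HNCS", "NN=C": "HNNC", "NN=N": "HNNN",
    "NC=N": "HNCN", "NC%N": "HSP2", "NSO": "HSP2",
}

# sulfonamide N-H has no dedicated published symbol; the generic sp2 label
_H_FALLBACK_SYMBOL = {"HNSO2": "HSP2"}


def _type_hydrogen(mol: Molecule, idx: int, heavy_symbolic: str,
                   heavy_numeric: int) -> str:
    if heavy_symbolic in _H_FROM_HEAVY_SYMBOLIC:
        return _H_FROM_HEAVY_SYMBOLIC[heavy_symbolic]
    if heavy_numeric in _H_FROM_HEAVY_NUMERIC:
        h = _H_FROM_HEAVY_NUMERIC[heavy_numeric]
        return _H_FALLBACK_SYMBOL.get(h, h)
    # all carbon and silicon types
    return "HC"


# ----------------------------------------------------------------------
# the typing operation
# ----------------------------------------------------------------------

def assign_atom_types(mol: Molecule, tables: ParameterTables) -> MMFFAtomAssignment:
    """Assign symbolic and numeric MMFF types: heavy atoms, then hydrogens.

    Requires kekulized input with MMFF aromaticity perceived (the aromatic
    perception is run automatically when flags are absent).  The result is
    invariant under atom-order permutation and under degenerate kekule forms.
    """
    _aromatic_rings(mol)  # ensure flags exist
    n = mol.n_atoms
    symbolic: list[str | None] = [None] * n
    for i, a in enumerate(mol.atoms):
        if a.element != 1:
            symbolic[i] = _type_heavy(mol, i)
    for i, a in enumerate(mol.atoms):
        if a.element != 1:
            continue
        nbrs = mol.neighbors(i)
        if len(nbrs) != 1:
            raise TypingError(
                f"atom {i}: hydrogen with degree {len(nbrs)} (must be 1)")
        heavy = nbrs[0]
        if mol.atoms[heavy].element == 1:
            raise TypingError(f"atom {i}: H-H bond is not typable")
        hs = symbolic[heavy]
        symbolic[i] = _type_hydrogen(
            mol, i, hs, tables.symbolic_map.get(hs, 0))

    numeric = []
    for i, s in enumerate(symbolic):
        code = tables.symbolic_map.get(s)
        if code is None:
            raise TypingError(
                f"atom {i}: symbolic type {s!r} has no numeric code in the "
                "bundled type map")
        numeric.append(code)
    return MMFFAtomAssignment(
        symbolic_types=list(symbolic), numeric_types=numeric,
        properties=tables.properties)


# ----------------------------------------------------------------------
# charge model
# ----------------------------------------------------------------------

def assign_fractional_formal_charges(
        mol: Molecule, assignment: MMFFAtomAssignment,
        tables: ParameterTables) -> MMFFAtomAssignment:
    """Redistribute integer formal charges over resonant groups.

    Terminal-atom groups (carboxylate, nitro, phosphate, ...) share the sum
    of the formal charges of the equivalent terminal atoms equally; fixed
    resonance positions (amidinium +1/2, guanidinium +1/3, imidazolium +1/2)
    receive their tabulated share; aromatic anion nitrogens share the ring
    charge.  The total charge is conserved exactly.
    """
    n = mol.n_atoms
    q0 = [float(a.formal_charge) for a in mol.atoms]
    types = assignment.numeric_types

    terminal_share = {t for name, mode, t, v in tables.resonant_groups
                      if mode == "terminal"}
    pair_value = {t: v for name, mode, t, v in tables.resonant_groups
                  if mode == "pair"}
    ring_share = {t for name, mode, t, v in tables.resonant_groups
                  if mode == "ring"}

    done: set[int] = set()
    for i in range(n):
        if i in done or types[i] not in terminal_share:
            continue
        center = mol.neighbors(i)[0]
        group = [j for j in mol.neighbors(center)
                 if types[j] == types[i] and mol.degree(j) == 1]
        # charge-separated (dative) notation is normalized: a positive charge
        # written on the center is absorbed into the terminal pool
        total = sum(float(mol.atoms[j].formal_charge) for j in group)
        center_q = float(mol.atoms[center].formal_charge)
        if center_q != 0.0:
            total += center_q
            q0[center] = 0.0
        for j in group:
            q0[j] = total / len(group)
            done.add(j)

    # dipolar groups written with charge separation but modeled neutral
    # (azide, isonitrile)
    for i in range(n):
        if types[i] in (47, 53, 60, 61):
            q0[i] = 0.0

    for i in range(n):
        if types[i] in pair_value:
            q0[i] = pair_value[types[i]]

    for ring in _aromatic_rings(mol):
        members = [i for i in ring if types[i] in ring_share]
        if members:
            total = sum(float(mol.atoms[i].formal_charge) for i in members)
            for i in members:
                q0[i] = total / len(members)

    assignment.fractional_formal_charges = q0
    return assignment


def compute_partial_charges(
        mol: Molecule, assignment: MMFFAtomAssignment,
        tables: ParameterTables) -> MMFFAtomAssignment:
    """MMFF partial charges: adjusted formal charge plus bond-charge
    increments.

    An atom first shares the fraction ``fcadj`` of its fractional formal
    charge with each bonded neighbor, then accumulates the signed bond charge
    increment over each of its bonds (missing increments are estimated from
    the difference of partial increments).  The sum of partial charges equals
    the net formal charge to floating precision.
    """
    if not assignment.fractional_formal_charges:
        assign_fractional_formal_charges(mol, assignment, tables)
    q0 = assignment.fractional_formal_charges
    types = assignment.numeric_types
    n = mol.n_atoms

    q = [0.0] * n
    for i in range(n):
        v = tables.fcadj.get(types[i], 0.0)
        crd = tables.properties[types[i]].crd
        q[i] = (1.0 - crd * v) * q0[i]
        for k in mol.neighbors(i):
            vk = tables.fcadj.get(types[k], 0.0)
            q[i] += vk * q0[k]

    failures = []
    for b in mol.bonds:
        bt = bond_type_index(mol, assignment, b)
        ti, tj = types[b.begin], types[b.end]
        res = bci_for_bond(tables, bt, ti, tj)
        if res.provenance == PROV_MISSING:
            failures.append(
                f"bond {b.begin}-{b.end} (types {ti},{tj}, bond type {bt})")
            continue
        inc = res.params[0]
        q[b.end] += inc
        q[b.begin] -= inc
    if failures:
        from .param_store import MissingParameterError
        raise MissingParameterError(
            "no bond charge increment (and no partial increments) for: "
            + "; ".join(failures), failures)

    assignment.partial_charges = q
    return assignment


def atom_assignment(mol: Molecule, tables: ParameterTables) -> MMFFAtomAssignment:
    """Full perception pipeline: aromaticity, types, charges."""
    perceive_aromaticity_mmff(mol)
    assignment = assign_atom_types(mol, tables)
    assign_fractional_formal_charges(mol, assignment, tables)
    compute_partial_charges(mol, assignment, tables)
    return assignment
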