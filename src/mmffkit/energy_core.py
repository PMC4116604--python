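"""The seven-term MMFF energy expression and its analytic Cartesian gradient.

    E = E_bond + E_angle + E_stretch_bend + E_oop + E_torsion
        + E_vdw + E_electrostatic            (+ restraints)

Functional forms (energies in kcal/mol, lengths in A, angles in degrees):

* bond stretch: quartic-corrected harmonic,
  ``143.9325/2 * kb * dr^2 * (1 + cs*dr + 7/12 cs^2 dr^2)`` with cs = -2 1/A
* angle bend: cubic-corrected harmonic,
  ``0.043844/2 * ka * dt^2 * (1 + cb*dt)`` with cb = -0.007 1/deg; linear
  types use ``143.9325 * ka * (1 + cos t)``
* stretch-bend: ``2.51210 * (kba_ijk dr_ij + kba_kji dr_kj) * dt``
* out-of-plane: harmonic in the Wilson angle,
  ``0.043844/2 * koop * chi^2``
* torsion: ``0.5*(V1(1+cos p) + V2(1-cos 2p) + V3(1+cos 3p))``
* van der Waals: buffered 14-7,
  ``eps * (1.07 R*/(R+0.07R*))^7 * (1.12 R*^7/(R^7+0.12R*^7) - 2)``
* electrostatic: buffered Coulomb ``332.0716 qi qj / (D (R + 0.05)^n)``
  with n = 1 (constant dielectric) or 2 (distance-dependent); 1-4 pairs are
  scaled by 0.75 (1-4 vdW is unscaled).

All constants live in the CONSTANTS section below; nothing is hard-coded at
the point of use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_model import Molecule
from .param_store import (
    MissingParameterError,
    ParameterTables,
    PROV_MISSING,
    angle_type_index,
    bond_type_index,
    canonical_key,
    lookup,
    stretch_bend_type_index,
    torsion_type_index,
    vdw_pair_parameters,
)
from .perception import MMFFAtomAssignment

__all__ = [
    "EnergyOptions",
    "EnergyBreakdown",
    "ForceFieldSystem",
    "enumerate_interactions",
    "calc_energy",
    "calc_gradient",
    "electrostatic_pair_energy",
    "TERM_NAMES",
]

# ----------------------------- CONSTANTS ------------------------------
RAD_ = 3.141592653589793 / 180.0
MDYNE_A_TO_KCAL = 143.9325       # md*A -> kcal/mol
CUBIC_STRETCH = -2.0             # cs, 1/A
ANGLE_PREFACTOR = MDYNE_A_TO_KCAL * RAD_ * RAD_   # 0.043844..., per deg^2
CUBIC_BEND = -0.4 * RAD_         # cb = -0.4/rad, i.e. -0.006981317/deg
STRETCH_BEND_PREFACTOR = MDYNE_A_TO_KCAL * RAD_   # 2.51207...
ELEC_CONSTANT = 332.0716         # e^2/A -> kcal/mol
ELEC_BUFFER = 0.05               # A
ELEC_SCALE_14 = 0.75
VDW_B7 = 1.07                    # buffering constants of the 14-7 form
VDW_GAMMA7 = 0.12

RAD = np.pi / 180.0
TERM_NAMES = ("bond", "angle", "stretch_bend", "oop", "torsion",
              "vdw", "electrostatic")


class GeometryError(ValueError):
    """Degenerate geometry a numeric guard refuses to evaluate."""


@dataclass
class EnergyOptions:
    """Term toggles and electrostatic model options."""
    bond: bool = True
    angle: bool = True
    stretch_bend: bool = True
    oop: bool = True
    torsion: bool = True
    vdw: bool = True
    electrostatic: bool = True
    dielectric_model: str = "constant"          # or "distance-dependent"
    dielectric_constant: float = 1.0

    def __post_init__(self):
        if self.dielectric_model not in ("constant", "distance-dependent"):
            raise ValueError(
                f"unknown dielectric model {self.dielectric_model!r}")
        if self.dielectric_constant <= 0:
            raise ValueError("dielectric constant must be positive")

    def enabled(self, term: str) -> bool:
        return getattr(self, term)

    @classmethod
    def none(cls) -> "EnergyOptions":
        return cls(**{t: False for t in TERM_NAMES})

    @classmethod
    def only(cls, *terms: str) -> "EnergyOptions":
        o = cls.none()
        for t in terms:
            setattr(o, t, True)
        return o


@dataclass
class EnergyBreakdown:
    e_bond: float = 0.0
    e_angle: float = 0.0
    e_stretch_bend: float = 0.0
    e_oop: float = 0.0
    e_torsion: float = 0.0
    e_vdw: float = 0.0
    e_electrostatic: float = 0.0
    e_restraints: float = 0.0

    @property
    def components(self) -> dict[str, float]:
        return {
            "bond": self.e_bond, "angle": self.e_angle,
            "stretch_bend": self.e_stretch_bend, "oop": self.e_oop,
            "torsion": self.e_torsion, "vdw": self.e_vdw,
            "electrostatic": self.e_electrostatic,
            "restraints": self.e_restraints,
        }

    @property
    def total(self) -> float:
        return sum(self.components.values())

    def __str__(self) -> str:
        rows = [f"  {k:<14s} {v:14.4f}" for k, v in self.components.items()]
        rows.append(f"  {'total':<14s} {self.total:14.4f}")
        return "\n".join(rows)


@dataclass
class ForceFieldSystem:
    """Enumerated interaction lists plus options; the evaluatable system."""
    n_atoms: int
    bonds: list = field(default_factory=list)          # (i,j,kb,r0)
    angles: list = field(default_factory=list)         # (i,j,k,ka,theta0,lin)
    stretch_bends: list = field(default_factory=list)  # (i,j,k,kba1,kba2,r0ij,r0kj,theta0)
    oops: list = field(default_factory=list)           # (i,j,k,l,koop) j=center
    torsions: list = field(default_factory=list)       # (i,j,k,l,V1,V2,V3)
    nonbonded: list = field(default_factory=list)      # (i,j,rstar,eps,qq,is14)
    restraints: list = field(default_factory=list)
    options: EnergyOptions = field(default_factory=EnergyOptions)
    provenance: dict = field(default_factory=dict)     # (kind, key) -> label

    # numpy caches for the nonbonded loop
    _nb_arrays: tuple | None = field(default=None, repr=False)

    def add_restraint(self, restraint) -> None:
        self.restraints.append(restraint)

    def _nb(self):
        if self._nb_arrays is None:
            if self.nonbonded:
                arr = np.array([(i, j, rs, eps, qq, s14)
                                for i, j, rs, eps, qq, s14 in self.nonbonded])
                idx_i = arr[:, 0].astype(int)
                idx_j = arr[:, 1].astype(int)
                self._nb_arrays = (idx_i, idx_j, arr[:, 2], arr[:, 3],
                                   arr[:, 4], arr[:, 5].astype(bool))
            else:
                z = np.zeros(0)
                self._nb_arrays = (z.astype(int), z.astype(int), z, z, z,
                                   z.astype(bool))
        return self._nb_arrays

    # convenience mirrors of the module-level API
    def calc_energy(self, coords) -> EnergyBreakdown:
        return calc_energy(self, coords)

    def calc_gradient(self, coords) -> np.ndarray:
        return calc_gradient(self, coords)

    def energy_and_gradient(self, coords):
        bd = calc_energy(self, coords)
        return bd, calc_gradient(self, coords)


# ----------------------------------------------------------------------
# interaction enumeration
# ----------------------------------------------------------------------

def enumerate_interactions(
        mol: Molecule, assignment: MMFFAtomAssignment,
        tables: ParameterTables,
        options: EnergyOptions | None = None) -> ForceFieldSystem:
    """Build every bonded and non-bonded interaction of the molecule.

    Bonds map one-to-one onto molecular bonds; angles are all bonded triples;
    stretch-bends are the non-linear angles with non-zero couplings;
    out-of-plane terms come in threes per tricoordinate center (each ligand
    serving once as the out-of-plane atom); torsions are all non-degenerate
    bonded quadruples; the nonbonded list is every atom pair minus 1-2 and
    1-3, with 1-4 pairs flagged.

    Raises :class:`MissingParameterError` listing every interaction that
    remains unparameterized after the step-down.
    """
    sys = ForceFieldSystem(n_atoms=mol.n_atoms,
                           options=options or EnergyOptions())
    types = assignment.numeric_types
    props = tables.properties
    failures: list[str] = []

    # bonds ------------------------------------------------------------
    for b in mol.bonds:
        bt = bond_type_index(mol, assignment, b)
        key = canonical_key("bond", (types[b.begin], types[b.end]), bt)
        res = lookup(tables, "bond", key)
        if not res.found:
            failures.append(f"bond {b.begin}-{b.end} key={key}")
            continue
        kb, r0 = res.params
        sys.bonds.append((b.begin, b.end, kb, r0))
        sys.provenance[("bond", (b.begin, b.end))] = res.provenance

    bond_r0 = {}
    for i, j, kb, r0 in sys.bonds:
        bond_r0[(i, j)] = r0
        bond_r0[(j, i)] = r0

    # angles and stretch-bends ------------------------------------------
    angle_params = {}
    for j in range(mol.n_atoms):
        nbrs = mol.neighbors(j)
        for a_i in range(len(nbrs)):
            for a_k in range(a_i + 1, len(nbrs)):
                i, k = nbrs[a_i], nbrs[a_k]
                at = angle_type_index(mol, assignment, i, j, k)
                key = canonical_key("angle", (types[i], types[j], types[k]), at)
                res = lookup(tables, "angle", key)
                if not res.found or res.params[0] == 0.0 and res.params[1] == 0.0:
                    failures.append(f"angle {i}-{j}-{k} key={key}")
                    continue
                ka, theta0 = res.params
                linear = props[types[j]].lin
                sys.angles.append((i, j, k, ka, theta0, linear))
                sys.provenance[("angle", (i, j, k))] = res.provenance
                angle_params[(i, j, k)] = (ka, theta0, linear)

                if linear:
                    continue
                sbt = stretch_bend_type_index(mol, assignment, i, j, k)
                sres = lookup(tables, "sb", (sbt, types[i], types[j], types[k]))
                if not sres.found:
                    continue
                kba1, kba2 = sres.params
                if kba1 == 0.0 and kba2 == 0.0:
                    continue
                if (i, j) not in bond_r0 or (k, j) not in bond_r0:
                    continue
                sys.stretch_bends.append(
                    (i, j, k, kba1, kba2, bond_r0[(i, j)], bond_r0[(k, j)],
                     theta0))
                sys.provenance[("sb", (i, j, k))] = sres.provenance

    # out-of-plane ------------------------------------------------------
    for j in range(mol.n_atoms):
        nbrs = mol.neighbors(j)
        if len(nbrs) != 3:
            continue
        key = canonical_key(
            "oop", (types[j], types[nbrs[0]], types[nbrs[1]], types[nbrs[2]]))
        res = lookup(tables, "oop", key)
        if not res.found:
            # no out-of-plane interaction is defined for this center
            sys.provenance[("oop", (j,))] = PROV_MISSING
            continue
        koop = res.params[0]
        a, b, c = nbrs
        for (p, q, out) in ((a, b, c), (a, c, b), (b, c, a)):
            sys.oops.append((p, j, q, out, koop))
        sys.provenance[("oop", (j,))] = res.provenance

    # torsions ----------------------------------------------------------
    for bd in mol.bonds:
        j, k = bd.begin, bd.end
        if props[types[j]].lin or props[types[k]].lin:
            continue
        for i in mol.neighbors(j):
            if i == k:
                continue
            for l in mol.neighbors(k):
                if l == j or l == i:
                    continue
                tt = torsion_type_index(mol, assignment, i, j, k, l)
                key = canonical_key(
                    "torsion", (types[i], types[j], types[k], types[l]), tt)
                res = lookup(tables, "torsion", key)
                if not res.found and tt == 5:
                    key0 = canonical_key(
                        "torsion", (types[i], types[j], types[k], types[l]), 0)
                    res = lookup(tables, "torsion", key0)
                if not res.found:
                    failures.append(f"torsion {i}-{j}-{k}-{l} key={key}")
                    continue
                v1, v2, v3 = res.params
                sys.torsions.append((i, j, k, l, v1, v2, v3))
                sys.provenance[("torsion", (i, j, k, l))] = res.provenance

    # nonbonded ---------------------------------------------------------
    n = mol.n_atoms
    excluded = {frozenset((b.begin, b.end)) for b in mol.bonds}
    onethree = set()
    onefour = set()
    for j in range(n):
        nb = mol.neighbors(j)
        for a_i in range(len(nb)):
            for a_k in range(a_i + 1, len(nb)):
                onethree.add(frozenset((nb[a_i], nb[a_k])))
    for i, j, k, l, *_ in sys.torsions:
        onefour.add(frozenset((i, l)))
    q = assignment.partial_charges
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((i, j))
            if pair in excluded or pair in onethree:
                continue
            rs, eps = vdw_pair_parameters(tables, types[i], types[j])
            is14 = pair in onefour
            sys.nonbonded.append((i, j, rs, eps, q[i] * q[j], is14))

    if failures:
        raise MissingParameterError(
            "unparameterized interactions after step-down: "
            + "; ".join(failures), failures)
    return sys


# ----------------------------------------------------------------------
# geometry kernels (value + analytic derivative)
# ----------------------------------------------------------------------

def _bond_geom(coords, i, j):
    d = coords[i] - coords[j]
    r = float(np.linalg.norm(d))
    return r, d / r if r > 1e-12 else np.array([1.0, 0.0, 0.0])


def _angle_geom(coords, i, j, k):
    """Angle in degrees and d(theta_deg)/d(x) for atoms i, j, k."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0 + 1e-12, 1.0 - 1e-12))
    s = np.sqrt(1.0 - c * c)
    theta = np.degrees(np.arccos(c))
    # d(theta_rad)
    gi = (c * uh - vh) / (nu * s)
    gk = (c * vh - uh) / (nv * s)
    gj = -(gi + gk)
    f = 1.0 / RAD   # to degrees
    return theta, gi * f, gj * f, gk * f


def _dihedral_geom(coords, i, j, k, l):
    """Signed dihedral in degrees, in (-180, 180], with d(phi_deg)/dx.

    Returns None when either bond angle is degenerate (collinear), in which
    case the torsion contributes zero energy.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    nb2 = float(np.linalg.norm(b2))
    if sq1 < 1e-18 or sq2 < 1e-18 or nb2 < 1e-12:
        return None
    phi = float(np.degrees(np.arctan2(
        np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))))
    gi = -(nb2 / sq1) * n1
    gl = (nb2 / sq2) * n2
    f1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    f2 = float(np.dot(b3, b2)) / (nb2 * nb2)
    gj = -gi - f1 * gi + f2 * gl
    gk = -gl + f1 * gi - f2 * gl
    f = 1.0 / RAD
    return phi, gi * f, gj * f, gk * f, gl * f


def _skew(v):
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def _wilson_geom(coords, i, j, k, l):
    """Wilson out-of-plane angle (degrees) of bond j-l vs plane (i,j,k),
    with d(chi_deg)/dx for all four atoms."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    w = coords[l] - coords[j]
    nu, nv, nw = (np.linalg.norm(u), np.linalg.norm(v), np.linalg.norm(w))
    if min(nu, nv, nw) < 1e-12:
        raise GeometryError("zero-length bond in out-of-plane term")
    uh, vh, wh = u / nu, v / nv, w / nw
    c = np.cross(uh, vh)
    st = float(np.linalg.norm(c))
    if st < 1e-12:
        # ligands i,k collinear: plane undefined; no restoring direction
        z = np.zeros(3)
        return 0.0, z, z, z, z
    d = float(np.dot(c, wh))
    s = d / st
    s = float(np.clip(s, -1.0 + 1e-12, 1.0 - 1e-12))
    chi = float(np.degrees(np.arcsin(s)))
    coschi = np.sqrt(1.0 - s * s)

    dc_duh = -_skew(vh)          # d(c)/d(uh)
    dc_dvh = _skew(uh)
    chat = c / st
    dd_duh = dc_duh.T @ wh
    dd_dvh = dc_dvh.T @ wh
    dd_dwh = c
    dst_duh = dc_duh.T @ chat
    dst_dvh = dc_dvh.T @ chat
    ds_duh = (dd_duh - s * dst_duh) / st
    ds_dvh = (dd_dvh - s * dst_dvh) / st
    ds_dwh = dd_dwh / st

    def through_unit(ds_dh, h, nrm):
        return (ds_dh - h * float(np.dot(h, ds_dh))) / nrm

    ds_du = through_unit(ds_duh, uh, nu)
    ds_dv = through_unit(ds_dvh, vh, nv)
    ds_dw = through_unit(ds_dwh, wh, nw)
    f = 1.0 / (coschi * RAD)     # d(chi_deg)/ds
    gi = ds_du * f
    gk = ds_dv * f
    gl = ds_dw * f
    gj = -(gi + gk + gl)
    return chi, gi, gj, gk, gl


# ----------------------------------------------------------------------
# term evaluation
# ----------------------------------------------------------------------

def _eval_bonds(sys, coords, grad):
    e = 0.0
    cs = CUBIC_STRETCH
    for i, j, kb, r0 in sys.bonds:
        r, u = _bond_geom(coords, i, j)
        dr = r - r0
        e += (MDYNE_A_TO_KCAL / 2.0) * kb * dr * dr * (
            1.0 + cs * dr + (7.0 / 12.0) * cs * cs * dr * dr)
        if grad is not None:
            de = MDYNE_A_TO_KCAL * kb * dr * (
                1.0 + 1.5 * cs * dr + 2.0 * (7.0 / 12.0) * cs * cs * dr * dr)
            grad[i] += de * u
            grad[j] -= de * u
    return e


def _eval_angles(sys, coords, grad):
    e = 0.0
    for i, j, k, ka, theta0, linear in sys.angles:
        theta, gi, gj, gk = _angle_geom(coords, i, j, k)
        if linear:
            ct = np.cos(theta * RAD)
            e += MDYNE_A_TO_KCAL * ka * (1.0 + ct)
            if grad is not None:
                de = -MDYNE_A_TO_KCAL * ka * np.sin(theta * RAD) * RAD
                grad[i] += de * gi
                grad[j] += de * gj
                grad[k] += de * gk
            continue
        dt = theta - theta0
        e += (ANGLE_PREFACTOR / 2.0) * ka * dt * dt * (1.0 + CUBIC_BEND * dt)
        if grad is not None:
            de = ANGLE_PREFACTOR * ka * dt * (1.0 + 1.5 * CUBIC_BEND * dt)
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
    return e


def _eval_stretch_bends(sys, coords, grad):
    e = 0.0
    for i, j, k, kba1, kba2, r0ij, r0kj, theta0 in sys.stretch_bends:
        rij, uij = _bond_geom(coords, i, j)
        rkj, ukj = _bond_geom(coords, k, j)
        theta, gi, gj, gk = _angle_geom(coords, i, j, k)
        dt = theta - theta0
        dij = rij - r0ij
        dkj = rkj - r0kj
        e += STRETCH_BEND_PREFACTOR * (kba1 * dij + kba2 * dkj) * dt
        if grad is not None:
            pref = STRETCH_BEND_PREFACTOR
            # stretch parts
            grad[i] += pref * kba1 * dt * uij
            grad[j] -= pref * kba1 * dt * uij
            grad[k] += pref * kba2 * dt * ukj
            grad[j] -= pref * kba2 * dt * ukj
            # bend part
            de = pref * (kba1 * dij + kba2 * dkj)
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
    return e


def _eval_oops(sys, coords, grad):
    e = 0.0
    for i, j, k, l, koop in sys.oops:
        chi, gi, gj, gk, gl = _wilson_geom(coords, i, j, k, l)
        e += (ANGLE_PREFACTOR / 2.0) * koop * chi * chi
        if grad is not None:
            de = ANGLE_PREFACTOR * koop * chi
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
            grad[l] += de * gl
    return e


_warned_degenerate_torsion = False


def _eval_torsions(sys, coords, grad):
    global _warned_degenerate_torsion
    e = 0.0
    for i, j, k, l, v1, v2, v3 in sys.torsions:
        geom = _dihedral_geom(coords, i, j, k, l)
        if geom is None:
            if not _warned_degenerate_torsion:
                warnings.warn(
                    "degenerate dihedral geometry; torsion term contributes 0",
                    RuntimeWarning, stacklevel=2)
                _warned_degenerate_torsion = True
            continue
        phi, gi, gj, gk, gl = geom
        p = phi * RAD
        e += 0.5 * (v1 * (1.0 + np.cos(p)) + v2 * (1.0 - np.cos(2 * p))
                    + v3 * (1.0 + np.cos(3 * p)))
        if grad is not None:
            de = 0.5 * (-v1 * np.sin(p) + 2 * v2 * np.sin(2 * p)
                        - 3 * v3 * np.sin(3 * p)) * RAD
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
            grad[l] += de * gl
    return e


def _nb_distances(sys, coords):
    idx_i, idx_j, rs, eps, qq, is14 = sys._nb()
    d = coords[idx_i] - coords[idx_j]
    r = np.sqrt(np.sum(d * d, axis=1))
    if len(r) and float(r.min()) < 1e-8:
        bad = int(np.argmin(r))
        raise GeometryError(
            f"overlapping atoms {idx_i[bad]} and {idx_j[bad]} in nonbonded "
            f"pair (r = {r[bad]:.2e} A)")
    return idx_i, idx_j, rs, eps, qq, is14, d, r


def _eval_vdw(sys, coords, grad):
    idx_i, idx_j, rs, eps, qq, is14, d, r = _nb_distances(sys, coords)
    if not len(r):
        return 0.0
    t1 = VDW_B7 * rs / (r + 0.07 * rs)            # (1.07 R*/(R+0.07R*))
    r7 = r ** 7
    rs7 = rs ** 7
    frac = 1.12 * rs7 / (r7 + VDW_GAMMA7 * rs7)
    e_pair = eps * t1 ** 7 * (frac - 2.0)
    if grad is not None:
        dt1 = -VDW_B7 * rs / (r + 0.07 * rs) ** 2
        dfrac = -1.12 * rs7 * 7.0 * r ** 6 / (r7 + VDW_GAMMA7 * rs7) ** 2
        de = eps * (7.0 * t1 ** 6 * dt1 * (frac - 2.0) + t1 ** 7 * dfrac)
        g = (de / r)[:, None] * d
        np.add.at(grad, idx_i, g)
        np.add.at(grad, idx_j, -g)
    return float(np.sum(e_pair))


def _eval_electrostatics(sys, coords, grad):
    idx_i, idx_j, rs, eps, qq, is14, d, r = _nb_distances(sys, coords)
    if not len(r):
        return 0.0
    opt = sys.options
    n = 2 if opt.dielectric_model == "distance-dependent" else 1
    scale = np.where(is14, ELEC_SCALE_14, 1.0)
    pref = ELEC_CONSTANT * qq * scale / opt.dielectric_constant
    rb = r + ELEC_BUFFER
    e_pair = pref / rb ** n
    if grad is not None:
        de = -n * pref / rb ** (n + 1)
        g = (de / r)[:, None] * d
        np.add.at(grad, idx_i, g)
        np.add.at(grad, idx_j, -g)
    return float(np.sum(e_pair))


def electrostatic_pair_energy(q_i: float, q_j: float, r: float,
                              options: EnergyOptions | None = None) -> float:
    """Buffered-Coulomb energy of one charge pair (no 1-4 scaling)."""
    options = options or EnergyOptions()
    if r <= 0:
        raise GeometryError("electrostatic pair distance must be positive")
    n = 2 if options.dielectric_model == "distance-dependent" else 1
    return (ELEC_CONSTANT * q_i * q_j
            / (options.dielectric_constant * (r + ELEC_BUFFER) ** n))


_TERM_EVAL = {
    "bond": _eval_bonds,
    "angle": _eval_angles,
    "stretch_bend": _eval_stretch_bends,
    "oop": _eval_oops,
    "torsion": _eval_torsions,
    "vdw": _eval_vdw,
    "electrostatic": _eval_electrostatics,
}


def _evaluate(sys: ForceFieldSystem, coords, with_grad: bool):
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (sys.n_atoms, 3):
        raise ValueError(
            f"coordinates must have shape ({sys.n_atoms}, 3), "
            f"got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    grad = np.zeros_like(coords) if with_grad else None
    bd = EnergyBreakdown()
    for term in TERM_NAMES:
        if sys.options.enabled(term):
            setattr(bd, "e_" + term, _TERM_EVAL[term](sys, coords, grad))
    e_res = 0.0
    for restraint in sys.restraints:
        e_res += restraint.energy_and_gradient(coords, grad)
    bd.e_restraints = e_res
    return bd, grad


def calc_energy(sys: ForceFieldSystem, coords) -> EnergyBreakdown:
    """Evaluate the enabled force-field terms plus restraints (kcal/mol)."""
    bd, _ = _evaluate(sys, coords, with_grad=False)
    return bd


def calc_gradient(sys: ForceFieldSystem, coords) -> np.ndarray:
    """Analytic gradient of the enabled total, kcal/mol/A, shape (n, 3)."""
    _, grad = _evaluate(sys, coords, with_grad=True)
    return grad
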