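"""Flat-bottomed restraint potentials for constrained optimization.

Each restraint is zero inside a user-defined window [minimum, maximum] of an
internal coordinate (or of the distance from a reference point) and grows as
``1/2 k d^2`` outside it, where ``d`` is the distance to the nearer window
edge.  The value and first derivative are continuous at both edges, so the
potentials can be mixed freely with the force-field terms during gradient
minimization.

Units: distances in A with k in kcal/mol/A^2; angles and torsions quadratic
in degrees with k in kcal/mol/deg^2 (a documented convention of this
package).  Torsion windows live on the circle (-180, 180]: deviations are
minimal signed circular differences, continuous across the +-180 seam.

Bounds may be given relative to the current geometry
(:func:`resolve_relative_bounds` turns them into absolute ones).  Positional
restraints may tether a single atom or a dummy point (the mass-weighted
center of an atom set); the gradient is distributed over the constituent
atoms by mass weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .energy_core import _angle_geom, _bond_geom, _dihedral_geom

__all__ = [
    "Restraint",
    "DistanceRestraint",
    "AngleRestraint",
    "TorsionRestraint",
    "PositionalRestraint",
    "flat_bottom_energy",
    "distance_restraint_energy",
    "angle_restraint_energy",
    "torsion_restraint_energy",
    "positional_restraint_energy",
    "resolve_relative_bounds",
    "read_restraints",
    "parse_restraint_line",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES = {
    1: 1.008, 3: 6.94, 5: 10.81, 6: 12.011, 7: 14.007, 8: 15.999,
    9: 18.998, 11: 22.990, 12: 24.305, 14: 28.085, 15: 30.974, 16: 32.06,
    17: 35.45, 19: 39.098, 20: 40.078, 26: 55.845, 29: 63.546, 30: 65.38,
    35: 79.904, 53: 126.904,
}


# ----------------------------------------------------------------------
# scalar branch algebra
# ----------------------------------------------------------------------

def flat_bottom_energy(x: float, k: float, lo: float, hi: float):
    """``(energy, dE/dx)`` of the three-branch flat-bottomed quadratic."""
    if k < 0:
        raise ValueError("restraint force constant must be non-negative")
    if lo > hi:
        raise ValueError(f"flat-bottom window is empty: [{lo}, {hi}]")
    if x < lo:
        d = x - lo
    elif x > hi:
        d = x - hi
    else:
        return 0.0, 0.0
    return 0.5 * k * d * d, k * d


def distance_restraint_energy(r_ij: float, k: float, r_min: float,
                              r_max: float):
    """Three-branch flat-bottomed penalty on an interatomic distance (A)."""
    if r_min < 0:
        raise ValueError("distance bounds must be non-negative")
    return flat_bottom_energy(r_ij, k, r_min, r_max)


def angle_restraint_energy(theta_ijk: float, k: float, theta_min: float,
                           theta_max: float):
    """Three-branch penalty on a bond angle (degrees, window in [0, 180])."""
    if not (0.0 <= theta_min <= 180.0 and 0.0 <= theta_max <= 180.0):
        raise ValueError("angle bounds must lie in [0, 180] degrees")
    return flat_bottom_energy(theta_ijk, k, theta_min, theta_max)


def _wrap(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def torsion_restraint_energy(phi: float, k: float, phi_min: float,
                             phi_max: float):
    """Flat-bottomed penalty on the circle.

    The window runs counterclockwise from ``phi_min`` to ``phi_max`` (both
    wrapped); a dihedral inside it costs nothing, outside it is penalized
    through the nearer edge with the minimal signed circular deviation.
    """
    if k < 0:
        raise ValueError("restraint force constant must be non-negative")
    phi = _wrap(phi)
    lo = _wrap(phi_min)
    hi = _wrap(phi_max)
    width = (hi - lo) % 360.0
    pos = (phi - lo) % 360.0
    if pos <= width:
        return 0.0, 0.0
    d_hi = _wrap(phi - hi)
    d_lo = _wrap(phi - lo)
    d = d_hi if abs(d_hi) <= abs(d_lo) else d_lo
    return 0.5 * k * d * d, k * d


def positional_restraint_energy(p_i, p_ref, k: float, r_max: float):
    """Penalty once a point strays farther than ``r_max`` from its reference."""
    if r_max < 0:
        raise ValueError("r_max must be non-negative")
    d = np.asarray(p_i, dtype=float) - np.asarray(p_ref, dtype=float)
    r = float(np.linalg.norm(d))
    e, de = flat_bottom_energy(r, k, 0.0, r_max)
    return e, de


# ----------------------------------------------------------------------
# restraint objects
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Restraint:
    kind: str = ""
    atoms: tuple = ()
    k: float = 0.0
    minimum: float = 0.0
    maximum: float = 0.0
    relative: bool = False

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("restraint force constant must be non-negative")

    def current_value(self, coords) -> float:
        raise NotImplementedError

    def energy_and_gradient(self, coords, grad) -> float:
        raise NotImplementedError

    def violation(self, coords) -> float:
        """Distance of the current value from the flat bottom (0 if inside)."""
        x = self.current_value(coords)
        if self.kind == "torsion":
            e, _ = torsion_restraint_energy(x, 1.0, self.minimum, self.maximum)
            return float(np.sqrt(2.0 * e))
        if x < self.minimum:
            return self.minimum - x
        if x > self.maximum:
            return x - self.maximum
        return 0.0


@dataclass(frozen=True)
class DistanceRestraint(Restraint):
    kind: str = "distance"

    def current_value(self, coords) -> float:
        i, j = self.atoms
        r, _ = _bond_geom(np.asarray(coords, float), i, j)
        return r

    def energy_and_gradient(self, coords, grad) -> float:
        i, j = self.atoms
        r, u = _bond_geom(coords, i, j)
        e, de = distance_restraint_energy(r, self.k, self.minimum, self.maximum)
        if grad is not None and de != 0.0:
            grad[i] += de * u
            grad[j] -= de * u
        return e


@dataclass(frozen=True)
class AngleRestraint(Restraint):
    kind: str = "angle"

    def current_value(self, coords) -> float:
        i, j, k = self.atoms
        theta, *_ = _angle_geom(np.asarray(coords, float), i, j, k)
        return theta

    def energy_and_gradient(self, coords, grad) -> float:
        i, j, k = self.atoms
        theta, gi, gj, gk = _angle_geom(coords, i, j, k)
        e, de = angle_restraint_energy(theta, self.k, self.minimum,
                                       self.maximum)
        if grad is not None and de != 0.0:
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
        return e


@dataclass(frozen=True)
class TorsionRestraint(Restraint):
    kind: str = "torsion"

    def current_value(self, coords) -> float:
        i, j, k, l = self.atoms
        geom = _dihedral_geom(np.asarray(coords, float), i, j, k, l)
        if geom is None:
            raise ValueError(
                f"dihedral {self.atoms} undefined (collinear bond angle)")
        return geom[0]

    def energy_and_gradient(self, coords, grad) -> float:
        i, j, k, l = self.atoms
        geom = _dihedral_geom(coords, i, j, k, l)
        if geom is None:
            return 0.0
        phi, gi, gj, gk, gl = geom
        e, de = torsion_restraint_energy(phi, self.k, self.minimum,
                                         self.maximum)
        if grad is not None and de != 0.0:
            grad[i] += de * gi
            grad[j] += de * gj
            grad[k] += de * gk
            grad[l] += de * gl
        return e


@dataclass(frozen=True)
class PositionalRestraint(Restraint):
    """Tether an atom -- or the mass-weighted center of an atom set -- to a
    fixed reference point; ``maximum`` plays the role of r_max."""
    kind: str = "positional"
    reference: tuple = (0.0, 0.0, 0.0)
    weights: tuple = ()          # per-atom mass weights, normalized lazily

    def _weights(self) -> np.ndarray:
        if self.weights:
            w = np.asarray(self.weights, dtype=float)
        else:
            w = np.ones(len(self.atoms))
        return w / w.sum()

    def current_point(self, coords) -> np.ndarray:
        w = self._weights()
        return np.sum(w[:, None] * np.asarray(coords, float)[list(self.atoms)],
                      axis=0)

    def current_value(self, coords) -> float:
        return float(np.linalg.norm(
            self.current_point(coords) - np.asarray(self.reference)))

    def energy_and_gradient(self, coords, grad) -> float:
        p = self.current_point(coords)
        d = p - np.asarray(self.reference, dtype=float)
        r = float(np.linalg.norm(d))
        e, de = flat_bottom_energy(r, self.k, 0.0, self.maximum)
        if grad is not None and de != 0.0 and r > 1e-12:
            u = d / r
            w = self._weights()
            for wi, a in zip(w, self.atoms):
                grad[a] += de * wi * u
        return e


_KIND_TO_CLASS = {
    "distance": DistanceRestraint,
    "angle": AngleRestraint,
    "torsion": TorsionRestraint,
    "positional": PositionalRestraint,
}
_ARITY = {"distance": 2, "angle": 3, "torsion": 4}


def resolve_relative_bounds(restraint: Restraint, coords) -> Restraint:
    """Turn bounds given as offsets from the current geometry into absolute
    bounds.  Idempotent: an absolute restraint is returned unchanged."""
    if not restraint.relative:
        return restraint
    coords = np.asarray(coords, dtype=float)
    if max(restraint.atoms) >= len(coords):
        raise ValueError("restraint references atoms without coordinates")
    if restraint.kind == "positional":
        ref = tuple(float(x) for x in restraint.current_point(coords))
        return replace(restraint, reference=ref, relative=False)
    x = restraint.current_value(coords)
    lo, hi = x + restraint.minimum, x + restraint.maximum
    if restraint.kind == "torsion":
        pass  # wrapping handled by the energy function
    elif restraint.kind == "angle":
        lo, hi = max(lo, 0.0), min(hi, 180.0)
    else:
        lo = max(lo, 0.0)
    return replace(restraint, minimum=lo, maximum=hi, relative=False)


# ----------------------------------------------------------------------
# restraint file (one restraint per line)
# ----------------------------------------------------------------------

def parse_restraint_line(line: str, masses=None) -> Restraint:
    """Parse ``kind atoms(1-based, comma-separated for a dummy center) k min
    max abs|rel``.

    Examples::

        distance 1 4      50.0   1.4   1.6  abs
        torsion  1 2 3 4  0.05  -10.0  10.0 rel
        positional 3      10.0   0.0   0.5  abs
        positional 1,2,3  10.0   0.0   1.0  abs    # center of mass
    """
    f = line.split()
    kind = f[0].lower()
    if kind not in _KIND_TO_CLASS:
        raise ValueError(f"unknown restraint kind {kind!r}")
    if kind == "positional":
        atoms = tuple(int(x) - 1 for x in f[1].split(","))
        k, lo, hi = (float(x) for x in f[2:5])
        relative = f[5].lower() in ("rel", "relative", "1", "true")
        weights = tuple(masses[a] for a in atoms) if masses else ()
        return PositionalRestraint(atoms=atoms, k=k, minimum=lo, maximum=hi,
                                   relative=relative, weights=weights)
    arity = _ARITY[kind]
    atoms = tuple(int(x) - 1 for x in f[1:1 + arity])
    k, lo, hi = (float(x) for x in f[1 + arity:4 + arity])
    relative = f[4 + arity].lower() in ("rel", "relative", "1", "true")
    return _KIND_TO_CLASS[kind](atoms=atoms, k=k, minimum=lo, maximum=hi,
                                relative=relative)


def read_restraints(path, mol=None) -> list[Restraint]:
    """Read a restraint specification file (``#`` comments allowed)."""
    masses = None
    if mol is not None:
        masses = [ATOMIC_MASSES.get(a.element, 12.0) for a in mol.atoms]
    out = []
    with open(path) as fh:
        for raw in fh:
            s = raw.split("#", 1)[0].strip()
            if s:
                out.append(parse_restraint_line(s, masses))
    return out
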