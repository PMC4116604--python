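"""Gradient-based geometry optimization over Cartesian coordinates.

A limited-memory quasi-Newton (L-BFGS) descent with a strong-Wolfe line
search drives the MMFF energy (restraints included in the objective) to a
stationary point.  Convergence is declared on the root-mean-square Cartesian
gradient.  The same machinery powers constrained minimization (restraint
penalties in the objective) and the torsional-scan driver, which pins a
dihedral with a narrow flat-bottomed window while everything else relaxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy_core import EnergyBreakdown, ForceFieldSystem, calc_energy
from .restraints import Restraint, TorsionRestraint, resolve_relative_bounds

__all__ = [
    "MinimizationResult",
    "ScanPoint",
    "minimize",
    "minimize_constrained",
    "torsional_scan",
    "set_dihedral",
]

#: default flat-bottom pinning for torsional scans, kcal/mol/deg^2
DEFAULT_SCAN_K = 1000.0
DEFAULT_SCAN_HALF_WIDTH = 0.5   # degrees


@dataclass
class MinimizationResult:
    coordinates: np.ndarray
    breakdown: EnergyBreakdown
    converged: bool
    iterations: int
    gradient_norm: float            # RMS, kcal/mol/A
    energy_trace: list = field(default_factory=list)
    restraint_violations: list = field(default_factory=list)

    @property
    def energy(self) -> float:
        return self.breakdown.total


def _rms(g: np.ndarray) -> float:
    return float(np.sqrt(np.mean(g * g)))


def minimize(system: ForceFieldSystem, coords,
             max_iterations: int = 200,
             grad_tolerance: float = 1e-4) -> MinimizationResult:
    """Minimize the enabled energy (plus any attached restraints).

    Deterministic for fixed inputs.  The energy trace records the objective
    at every accepted iterate and is monotone non-increasing to within the
    line-search tolerance.
    """
    x0 = np.asarray(coords, dtype=float).copy()
    n = system.n_atoms
    shape = (n, 3)
    if x0.shape != shape:
        raise ValueError(f"coordinates must have shape {shape}")

    def objective(x):
        xyz = x.reshape(shape)
        bd, grad = system.energy_and_gradient(xyz)
        e = bd.total
        if not np.isfinite(e) or not np.all(np.isfinite(grad)):
            raise FloatingPointError(
                "non-finite energy or gradient during minimization at "
                f"coordinates with norm {np.linalg.norm(xyz):.3g}")
        return e, grad.ravel()

    e0, g0 = objective(x0.ravel())
    trace = [e0]
    if _rms(g0.reshape(shape)) <= grad_tolerance:
        return MinimizationResult(
            coordinates=x0, breakdown=calc_energy(system, x0), converged=True,
            iterations=0, gradient_norm=_rms(g0.reshape(shape)),
            energy_trace=trace)

    class _Converged(Exception):
        pass

    state = {"iter": 0, "x": x0.ravel().copy()}

    def callback(xk):
        state["iter"] += 1
        state["x"] = xk.copy()
        e, g = objective(xk)
        trace.append(e)
        if _rms(g.reshape(shape)) <= grad_tolerance:
            raise _Converged

    try:
        res = _scipy_minimize(
            objective, x0.ravel(), jac=True, method="L-BFGS-B",
            callback=callback,
            options={"maxiter": max_iterations, "ftol": 1e-14,
                     "gtol": 1e-12, "maxls": 60})
        xf = res.x
    except _Converged:
        xf = state["x"]
    xyz = xf.reshape(shape)
    _, gf = objective(xf)
    rms = _rms(gf.reshape(shape))
    return MinimizationResult(
        coordinates=xyz, breakdown=calc_energy(system, xyz),
        converged=rms <= grad_tolerance, iterations=state["iter"],
        gradient_norm=rms, energy_trace=trace)


def minimize_constrained(system: ForceFieldSystem, coords,
                         restraints: list[Restraint],
                         max_iterations: int = 200,
                         grad_tolerance: float = 1e-4) -> MinimizationResult:
    """Minimize with extra flat-bottomed restraints in the objective.

    Relative bounds are resolved against the starting geometry.  The report
    carries the final violation (distance from the flat bottom) of every
    restraint.
    """
    coords = np.asarray(coords, dtype=float)
    resolved = [resolve_relative_bounds(r, coords) for r in restraints]
    saved = system.restraints
    system.restraints = saved + resolved
    try:
        result = minimize(system, coords, max_iterations, grad_tolerance)
    finally:
        system.restraints = saved
    result.restraint_violations = [
        r.violation(result.coordinates) for r in resolved]
    return result


# ----------------------------------------------------------------------
# torsional scan
# ----------------------------------------------------------------------

def set_dihedral(system: ForceFieldSystem, coords, dihedral, target_deg):
    """Rotate the l-side of bond j-k so dihedral i-j-k-l equals ``target``.

    Connectivity is taken from the system's bond list; the rotated set is
    the connected component of k after deleting bond j-k.
    """
    from .energy_core import _dihedral_geom

    i, j, k, l = dihedral
    coords = np.asarray(coords, dtype=float).copy()
    geom = _dihedral_geom(coords, i, j, k, l)
    if geom is None:
        raise ValueError("dihedral undefined at this geometry")
    delta = np.radians(target_deg - geom[0])

    adj: dict[int, set] = {}
    for bi, bj, *_ in system.bonds:
        adj.setdefault(bi, set()).add(bj)
        adj.setdefault(bj, set()).add(bi)
    moving = set()
    stack = [k]
    while stack:
        a = stack.pop()
        if a in moving:
            continue
        moving.add(a)
        for nb in adj.get(a, ()):
            if not (a == k and nb == j) and nb not in moving and nb != j:
                stack.append(nb)

    axis = coords[k] - coords[j]
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(delta), np.sin(delta)
    for a in moving:
        v = coords[a] - coords[j]
        coords[a] = coords[j] + (v * c + np.cross(axis, v) * s
                                 + axis * np.dot(axis, v) * (1 - c))
    return coords


@dataclass
class ScanPoint:
    angle: float                 # target dihedral, degrees
    breakdown: EnergyBreakdown
    converged: bool
    coordinates: np.ndarray

    @property
    def energy(self) -> float:
        return self.breakdown.total


def torsional_scan(system: ForceFieldSystem, coords, dihedral,
                   start: float, step: float, n_steps: int,
                   k_scan: float = DEFAULT_SCAN_K,
                   half_width: float = DEFAULT_SCAN_HALF_WIDTH,
                   max_iterations: int = 200,
                   grad_tolerance: float = 1e-4) -> list[ScanPoint]:
    """Drive a dihedral over ``start + m*step`` while relaxing everything else.

    At each step the dihedral is rotated to the target and pinned by a narrow
    flat-bottomed torsion restraint of strength ``k_scan`` and half-width
    ``half_width`` degrees; the rest of the molecule relaxes.  A failed
    minimization flags the point and the scan continues.
    """
    coords = np.asarray(coords, dtype=float)
    points: list[ScanPoint] = []
    current = coords
    for m in range(n_steps):
        target = start + m * step
        work = set_dihedral(system, current, dihedral, target)
        pin = TorsionRestraint(
            atoms=tuple(dihedral), k=k_scan,
            minimum=target - half_width, maximum=target + half_width)
        result = minimize_constrained(
            system, work, [pin], max_iterations, grad_tolerance)
        points.append(ScanPoint(
            angle=float(target), breakdown=calc_energy(
                system, result.coordinates),
            converged=result.converged, coordinates=result.coordinates))
        current = result.coordinates
    return points
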