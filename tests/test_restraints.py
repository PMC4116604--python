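"""Flat-bottomed restraint algebra, continuity and gradients."""

import numpy as np
import pytest

from mmffkit import (
    AngleRestraint,
    DistanceRestraint,
    PositionalRestraint,
    TorsionRestraint,
    angle_restraint_energy,
    calc_energy,
    distance_restraint_energy,
    positional_restraint_energy,
    resolve_relative_bounds,
    torsion_restraint_energy,
)
from mmffkit.restraints import flat_bottom_energy, parse_restraint_line
from conftest import finite_difference_gradient


class TestBranchAlgebra:
    @pytest.mark.parametrize("fn,inside,below,above", [
        (distance_restraint_energy, 2.0, 1.3, 2.9),
        (angle_restraint_energy, 100.0, 80.0, 150.0),
    ])
    def test_three_branches(self, fn, inside, below, above):
        k, lo, hi = 7.0, inside - 0.5, inside + 0.5
        assert fn(inside, k, lo, hi) == (0.0, 0.0)
        e, de = fn(below, k, lo, hi)
        d = below - lo
        assert e == pytest.approx(0.5 * k * d * d)
        assert de == pytest.approx(k * d)
        e, de = fn(above, k, lo, hi)
        d = above - hi
        assert e == pytest.approx(0.5 * k * d * d)

    def test_exact_boundary_values(self):
        # at the window edges both the value and the derivative vanish
        for x in (1.5, 2.5):
            e, de = distance_restraint_energy(x, 11.0, 1.5, 2.5)
            assert e == 0.0 and de == 0.0

    @pytest.mark.parametrize("fn,args", [
        (distance_restraint_energy, (2.0, 1.0, 1.5, 2.5)),
        (angle_restraint_energy, (100.0, 1.0, 90.0, 110.0)),
        (torsion_restraint_energy, (60.0, 1.0, 50.0, 70.0)),
    ])
    def test_c1_continuity_at_boundaries(self, fn, args):
        """Value and derivative continuous at min and max (probe +-1e-7)."""
        x, k, lo, hi = args
        h = 1e-7
        for edge in (lo, hi):
            e_in, de_in = fn(edge - h if edge == hi else edge + h, k, lo, hi)
            e_out, de_out = fn(edge + h if edge == hi else edge - h, k, lo, hi)
            assert abs(e_out - e_in) < 1e-12
            assert abs(de_out - de_in) < 1e-5

    def test_zero_force_constant_is_free(self):
        assert angle_restraint_energy(179.0, 0.0, 10.0, 20.0) == (0.0, 0.0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            flat_bottom_energy(1.0, -1.0, 0.0, 2.0)

    def test_angle_bounds_validated(self):
        with pytest.raises(ValueError, match="0, 180"):
            angle_restraint_energy(90.0, 1.0, -10.0, 190.0)

    def test_strictly_positive_outside_bottom(self):
        for x in np.linspace(-3, 3, 61):
            e, _ = flat_bottom_energy(float(x), 2.0, -1.0, 1.0)
            if -1.0 <= x <= 1.0:
                assert e == 0.0
            else:
                assert e > 0.0


class TestTorsionWrap:
    def test_inside_simple_window(self):
        assert torsion_restraint_energy(0.0, 5.0, -10.0, 10.0) == (0.0, 0.0)

    def test_quadratic_just_outside(self):
        e, de = torsion_restraint_energy(15.0, 5.0, -10.0, 10.0)
        assert e == pytest.approx(0.5 * 5.0 * 25.0)
        assert de == pytest.approx(5.0 * 5.0)

    def test_window_spanning_the_seam(self):
        # window from 170 to -170 (i.e. across 180): 179 lies inside
        assert torsion_restraint_energy(179.0, 3.0, 170.0, -170.0) == (0.0, 0.0)
        assert torsion_restraint_energy(-175.0, 3.0, 170.0, -170.0) == (0.0, 0.0)
        e, de = torsion_restraint_energy(160.0, 3.0, 170.0, -170.0)
        assert e == pytest.approx(0.5 * 3.0 * 100.0)

    def test_deviation_equals_exhaustive_shift_search(self):
        """Circular deviation == minimum over all +-360 shifted linear
        deviations (brute-force oracle)."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            phi = float(rng.uniform(-180, 180))
            lo = float(rng.uniform(-180, 180))
            hi = lo + float(rng.uniform(0, 300))
            e, _ = torsion_restraint_energy(phi, 2.0, lo, hi)
            best = np.inf
            for shift in (-720, -360, 0, 360, 720):
                x = phi + shift
                if lo <= x <= hi:
                    best = 0.0
                else:
                    d = min(abs(x - lo), abs(x - hi))
                    best = min(best, 0.5 * 2.0 * d * d)
            assert e == pytest.approx(best, abs=1e-9)


class TestPositional:
    def test_zero_at_reference(self):
        e, _ = positional_restraint_energy([1, 2, 3], [1, 2, 3], 10.0, 0.5)
        assert e == 0.0

    def test_quadratic_beyond_rmax(self):
        e, _ = positional_restraint_energy([0, 0, 1.7], [0, 0, 0], 4.0, 1.0)
        assert e == pytest.approx(0.5 * 4.0 * 0.7 ** 2)

    def test_rmax_zero_is_pure_harmonic_tether(self):
        e, _ = positional_restraint_energy([0.3, 0, 0], [0, 0, 0], 2.0, 0.0)
        assert e == pytest.approx(0.5 * 2.0 * 0.09)

    def test_center_of_mass_gradient_distributes_by_weight(self):
        r = PositionalRestraint(atoms=(0, 1), k=5.0, minimum=0.0, maximum=0.0,
                                reference=(0.0, 0.0, 0.0),
                                weights=(12.011, 1.008))
        coords = np.array([[0.5, 0, 0], [1.5, 0, 0], [9.0, 9.0, 9.0]])
        grad = np.zeros_like(coords)
        e = r.energy_and_gradient(coords, grad)
        assert e > 0
        fd = finite_difference_gradient(
            lambda c: r.energy_and_gradient(c, None), coords)
        assert np.allclose(grad, fd, atol=1e-6)
        # heavier atom takes proportionally more of the gradient
        assert abs(grad[0, 0]) / abs(grad[1, 0]) == pytest.approx(
            12.011 / 1.008)


class TestRestraintObjects:
    @pytest.mark.parametrize("restraint", [
        DistanceRestraint(atoms=(0, 3), k=25.0, minimum=1.0, maximum=1.2),
        AngleRestraint(atoms=(0, 1, 2), k=0.02, minimum=95.0, maximum=100.0),
        TorsionRestraint(atoms=(0, 1, 2, 3), k=0.05, minimum=10.0,
                         maximum=20.0),
    ])
    def test_gradients_match_finite_differences(self, restraint):
        rng = np.random.default_rng(8)
        coords = rng.normal(scale=1.5, size=(4, 3))
        grad = np.zeros_like(coords)
        restraint.energy_and_gradient(coords, grad)
        fd = finite_difference_gradient(
            lambda c: restraint.energy_and_gradient(c, None), coords)
        assert np.allclose(grad, fd, atol=5e-6)

    def test_restraint_only_adds_to_restraint_channel(self, fixture_mol,
                                                      make_system):
        mol = fixture_mol("alkane")
        _, sys = make_system(mol)
        before = calc_energy(sys, mol.coordinates)
        sys.restraints = [DistanceRestraint(atoms=(0, 1), k=100.0,
                                            minimum=0.0, maximum=0.5)]
        after = calc_energy(sys, mol.coordinates)
        sys.restraints = []
        for term, v in before.components.items():
            if term != "restraints":
                assert after.components[term] == v
        assert after.e_restraints > 0.0
        assert after.total == pytest.approx(before.total + after.e_restraints)


class TestRelativeBounds:
    def test_offsets_resolve_against_current_geometry(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        r = DistanceRestraint(atoms=(0, 1), k=1.0, minimum=-0.25,
                              maximum=0.25, relative=True)
        absolute = resolve_relative_bounds(r, coords)
        assert absolute.minimum == pytest.approx(1.75)
        assert absolute.maximum == pytest.approx(2.25)
        assert not absolute.relative

    def test_zero_offsets_collapse_to_current_value(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(4, 3))
        r = TorsionRestraint(atoms=(0, 1, 2, 3), k=1.0, minimum=0.0,
                             maximum=0.0, relative=True)
        absolute = resolve_relative_bounds(r, coords)
        assert absolute.minimum == absolute.maximum
        assert absolute.energy_and_gradient(coords, None) == pytest.approx(
            0.0, abs=1e-18)

    def test_resolution_is_idempotent(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        r = DistanceRestraint(atoms=(0, 1), k=1.0, minimum=-0.5, maximum=0.5,
                              relative=True)
        once = resolve_relative_bounds(r, coords)
        twice = resolve_relative_bounds(once, coords)
        assert once == twice

    def test_missing_coordinates_rejected(self):
        r = DistanceRestraint(atoms=(0, 9), k=1.0, minimum=0.0, maximum=1.0,
                              relative=True)
        with pytest.raises(ValueError, match="without coordinates"):
            resolve_relative_bounds(r, np.zeros((3, 3)))


class TestSpecFile:
    def test_round_trip_of_each_kind(self):
        lines = [
            "distance 1 4 50.0 1.4 1.6 abs",
            "angle 1 2 3 0.02 100 120 rel",
            "torsion 1 2 3 4 0.05 -10 10 abs",
            "positional 2 10.0 0.0 0.5 abs",
            "positional 1,2,3 10.0 0.0 1.0 abs",
        ]
        parsed = [parse_restraint_line(s) for s in lines]
        kinds = [r.kind for r in parsed]
        assert kinds == ["distance", "angle", "torsion", "positional",
                         "positional"]
        assert parsed[0].atoms == (0, 3)
        assert parsed[1].relative is True
        assert parsed[4].atoms == (0, 1, 2)


class TestHypothesisProperties:
    """Randomized algebraic properties of the flat-bottom potentials."""

    from hypothesis import given, settings, strategies as st

    @given(x=st.floats(-50, 50), k=st.floats(0, 100),
           lo=st.floats(-20, 0), width=st.floats(0, 20))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_zero_inside_positive_outside(self, x, k, lo, width):
        e, de = flat_bottom_energy(x, k, lo, lo + width)
        if lo <= x <= lo + width:
            assert e == 0.0 and de == 0.0
        else:
            assert e >= 0.0
            if k > 0 and e > 0:
                d = x - (lo if x < lo else lo + width)
                assert e == pytest.approx(0.5 * k * d * d)

    @given(phi=st.floats(-180, 180), lo=st.floats(-180, 180),
           width=st.floats(0, 359), k=st.floats(0.01, 10))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_torsion_energy_periodic_in_360(self, phi, lo, width, k):
        e1, _ = torsion_restraint_energy(phi, k, lo, lo + width)
        e2, _ = torsion_restraint_energy(phi + 360.0, k, lo, lo + width)
        e3, _ = torsion_restraint_energy(phi, k, lo + 360.0,
                                         lo + width + 360.0)
        assert e1 == pytest.approx(e2, abs=1e-9)
        assert e1 == pytest.approx(e3, abs=1e-9)
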