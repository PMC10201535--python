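import math

import numpy as np
import pytest
from scipy.integrate import quad as scipy_quad
from scipy.optimize import brentq

from dscft import (E_CHARGE, IonSpec, PairGeometry, SolventSpec,
                   cavity_fraction, cavity_profile, enclosed_charge,
                   gaussian_charge_density, smeared_displacement,
                   solvent_density, superposed_displacement)
from dscft.units import ANGSTROM

ION = IonSpec(z=1, sigma_i=3.0)       # b defaults to 0.6 A
ANION = IonSpec(z=-1, sigma_i=3.0)


def radial_charge_integral(ion, s_max_A):
    """Brute-force cumulative charge by spherical quadrature (C)."""
    val, _ = scipy_quad(
        lambda s: 4.0 * math.pi * (s * ANGSTROM) ** 2
        * gaussian_charge_density(s, ion) * ANGSTROM,
        0.0, s_max_A, limit=200)
    return val


class TestGaussianCharge:
    def test_normalization(self):
        assert radial_charge_integral(ION, 12.0 * ION.b) == pytest.approx(
            E_CHARGE, rel=1e-8)

    def test_peak_value(self):
        b = ION.b * ANGSTROM
        assert gaussian_charge_density(0.0, ION) == pytest.approx(
            E_CHARGE * (2.0 * math.pi * b * b) ** -1.5, rel=1e-12)

    def test_half_charge_radius_matches_cumulative_integral(self):
        r_half = brentq(
            lambda s: enclosed_charge(s, ION) - 0.5 * E_CHARGE, 0.1, 5.0)
        assert radial_charge_integral(ION, r_half) == pytest.approx(
            0.5 * E_CHARGE, rel=1e-6)


class TestSmearedDisplacement:
    def test_point_charge_limit(self):
        s = 10.0 * ION.b
        expect = E_CHARGE / (4.0 * math.pi * (s * ANGSTROM) ** 2)
        assert smeared_displacement(s, ION) == pytest.approx(expect, rel=1e-10)

    def test_regular_at_origin(self):
        tiny = np.array([1e-9, 2e-9, 4e-9])
        D = smeared_displacement(tiny, ION)
        assert D[0] > 0.0
        assert D[1] / D[0] == pytest.approx(2.0, rel=1e-5)
        assert D[2] / D[1] == pytest.approx(2.0, rel=1e-5)

    def test_enclosed_charge_against_quadrature(self):
        assert enclosed_charge(ION.b, ION) == pytest.approx(
            radial_charge_integral(ION, ION.b), rel=1e-8)

    def test_nonnegative_continuous_single_maximum(self):
        s = np.linspace(1e-4, 10.0, 4000)
        D = smeared_displacement(s, ION)
        assert np.all(D >= 0.0)
        peak = int(np.argmax(D))
        assert np.all(np.diff(D[:peak]) > 0)
        assert np.all(np.diff(D[peak:]) < 0)


class TestSuperposition:
    GEOM = PairGeometry(ION, ANION, 9.0)

    def test_midpoint_field_parallel_to_axis(self):
        D = superposed_displacement(np.array([2.0, 1.5, 0.0]), self.GEOM)
        # opposite charges at +/- z: transverse components cancel at z = 0
        assert abs(D[2]) > 0.0
        assert abs(D[0]) < 1e-12 * abs(D[2]) + 1e-30
        assert abs(D[1]) < 1e-12 * abs(D[2]) + 1e-30

    def test_neutral_partner_reduces_to_single_ion(self):
        geom = PairGeometry(ION, IonSpec(z=0, sigma_i=3.0), 9.0)
        pt = np.array([1.0, 2.0, 3.0])
        D = superposed_displacement(pt, geom)
        rvec = pt - geom.positions[0]
        s = float(np.linalg.norm(rvec))
        expect = smeared_displacement(s, ION) * rvec / s
        assert np.allclose(D, expect, rtol=1e-12)

    def test_off_axis_vector_sum_oracle(self):
        pt = np.array([2.5, -1.0, 1.75])
        D = superposed_displacement(pt, self.GEOM)
        expect = np.zeros(3)
        for pos, ion in zip(self.GEOM.positions, (ION, ANION)):
            rv = pt - pos
            s = float(np.linalg.norm(rv))
            expect += smeared_displacement(s, ion) * rv / s
        assert np.allclose(D, expect, rtol=1e-12)


class TestCavity:
    GEOM = PairGeometry(ION, ANION, 18.0)

    def test_unity_at_ion_center(self):
        phi = cavity_fraction(self.GEOM.positions[0], self.GEOM)
        assert phi == pytest.approx(1.0, abs=1e-6)

    def test_half_at_midpoint_radius(self):
        assert cavity_profile(ION.m * ION.sigma_i, ION) == pytest.approx(0.5)

    def test_practically_zero_by_sigma(self):
        s = np.linspace(ION.sigma_i, 3.0 * ION.sigma_i, 50)
        assert np.all(cavity_profile(s, ION) < 1e-2)

    def test_total_cavity_volume_independent_of_separation(self):
        # superposition of fixed profiles: int phi0 d3r is the same for
        # every separation (checked by spherical quadrature per ion)
        def cavity_volume(ion):
            val, _ = scipy_quad(
                lambda s: 4.0 * math.pi * s**2 * cavity_profile(s, ion),
                0.0, 2.0 * ion.sigma_i, limit=200)
            return val
        total = cavity_volume(ION) + cavity_volume(ANION)
        for sep in (6.0, 12.0, 24.0):
            geom = PairGeometry(ION, ANION, sep)
            zs = np.linspace(-40.0, 40.0, 1601)
            ss = np.linspace(0.0, 12.0, 241)
            S, Z = np.meshgrid(ss, zs, indexing="ij")
            pts = np.stack([S, np.zeros_like(S), Z], axis=-1)
            phi = cavity_fraction(pts, geom)
            integral = np.trapezoid(
                np.trapezoid(2.0 * math.pi * S * phi, zs, axis=1), ss)
            assert integral == pytest.approx(total, rel=1e-3)


class TestSolventDensity:
    SOLVENT = SolventSpec(mu_bar=1.0)

    def test_bulk_far_from_ions(self):
        geom = PairGeometry(ION, ANION, 9.0)
        n = solvent_density(np.array([50.0, 0.0, 10.0]), geom, self.SOLVENT)
        assert n == pytest.approx(self.SOLVENT.n_bulk, rel=1e-10)

    def test_vanishes_at_ion_center(self):
        geom = PairGeometry(ION, ANION, 9.0)
        n = solvent_density(geom.positions[0], geom, self.SOLVENT)
        assert n < 1e-4 * self.SOLVENT.n_bulk

    def test_clipped_in_overlap_region(self):
        geom = PairGeometry(ION, ANION, 3.0)  # cavities overlap at midplane
        n = solvent_density(np.array([0.0, 0.0, 0.0]), geom, self.SOLVENT)
        assert n == 0.0

    def test_matches_direct_formula_at_midpoint(self):
        geom = PairGeometry(ION, ANION, 3.0)
        pt = np.array([1.8, 0.0, 0.0])
        h1 = cavity_profile(float(np.linalg.norm(pt - geom.positions[0])), ION)
        h2 = cavity_profile(float(np.linalg.norm(pt - geom.positions[1])), ANION)
        expect = max(0.0, 1.0 - h1 - h2) / self.SOLVENT.v_si
        assert solvent_density(pt, geom, self.SOLVENT) == pytest.approx(
            expect, rel=1e-12)


def test_ion_spec_defaults_and_validation():
    ion = IonSpec(z=1, sigma_i=3.0)
    assert ion.b == pytest.approx(0.6)
    assert ion.m == 0.95 and ion.c == 0.01
    with pytest.raises(ValueError):
        IonSpec(z=1, sigma_i=-1.0)
    with pytest.raises(ValueError):
        IonSpec(z=1, sigma_i=3.0, m=1.5)
    with pytest.raises(ValueError):
        PairGeometry(ION, ANION, 0.0)
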