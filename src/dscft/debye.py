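"""Closed-form ion-pair thermodynamics in the Debye dielectric approximation.

A polar solvent with permanent dipole moment mu_bar, molecular volume v and
temperature T has, at the Debye (non-interacting dipole) level, the bulk
relative permittivity 1 + xi with

    xi = beta * mu_bar^2 / (3 v eps0),

a dimensionless measure of the dipole strength.  Because xi carries the
only temperature dependence of the permittivity, the free energy of
bringing two ions from infinity to a separation r,

    dF = q1 q2 / (4 pi eps0 (1 + xi) r),

splits into an energetic part dU = dF / (1 + xi) and an entropic part
-T dS = dF - dU = dF * xi / (1 + xi).  The entropic fraction xi/(1+xi)
crosses one half at xi = 1: for xi > 1 the effective Coulomb attraction
between opposite ions is mostly an entropy gain of the solvent dipoles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .units import ANGSTROM, DEBYE, EPS0, KB, thermal_beta


def _volume_A3(v: float | None, rho: float | None) -> float:
    if (v is None) == (rho is None):
        raise ValueError("exactly one of molecular volume v (A^3) or number "
                         "density rho (1/A^3) must be given")
    if v is None:
        if rho <= 0:
            raise ValueError(f"rho must be positive, got {rho}")
        return 1.0 / rho
    if v <= 0:
        raise ValueError(f"v must be positive, got {v}")
    return v


def xi_parameter(mu_bar: float, T: float, v: float | None = None,
                 rho: float | None = None) -> float:
    """Dimensionless dipole parameter xi = beta mu_bar^2 / (3 v eps0).

    Parameters: ``mu_bar`` in debye, ``T`` in kelvin, ``v`` in A^3 (or
    ``rho`` in 1/A^3; give exactly one).
    """
    if mu_bar < 0:
        raise ValueError(f"mu_bar must be non-negative, got {mu_bar}")
    v_si = _volume_A3(v, rho) * ANGSTROM**3
    mu_si = mu_bar * DEBYE
    return thermal_beta(T) * mu_si**2 / (3.0 * v_si * EPS0)


def mu_bar_from_xi(xi: float, T: float, v: float | None = None,
                   rho: float | None = None) -> float:
    """Dipole moment (debye) that realizes ``xi`` at the given T and v."""
    if xi < 0:
        raise ValueError(f"xi must be non-negative, got {xi}")
    v_si = _volume_A3(v, rho) * ANGSTROM**3
    return math.sqrt(3.0 * v_si * EPS0 * xi * KB * T) / DEBYE


@dataclass(frozen=True)
class DebyeResult:
    """Energy decomposition of the Debye-level PMF at one separation.

    Energies are per ion pair, in joules.  ``t_delta_s`` is T*dS, so that
    ``delta_f = delta_u - t_delta_s``.
    """

    xi: float
    delta_f: float
    delta_u: float
    t_delta_s: float
    entropy_fraction: float


def debye_decomposition(r: float, q1: float, q2: float, mu_bar: float,
                        T: float, v: float | None = None,
                        rho: float | None = None) -> DebyeResult:
    """Free energy, internal energy and entropy of ion-pair formation.

    ``r`` in A, charges in coulomb, ``mu_bar`` in debye, ``T`` in K,
    ``v`` in A^3 (or ``rho`` in 1/A^3).
    """
    if r <= 0:
        raise ValueError(f"separation must be positive, got {r}")
    xi = xi_parameter(mu_bar, T, v=v, rho=rho)
    delta_f = q1 * q2 / (4.0 * math.pi * EPS0 * (1.0 + xi) * r * ANGSTROM)
    delta_u = delta_f / (1.0 + xi)
    t_delta_s = delta_u - delta_f
    fraction = xi / (1.0 + xi)
    return DebyeResult(xi=xi, delta_f=delta_f, delta_u=delta_u,
                       t_delta_s=t_delta_s, entropy_fraction=fraction)


def entropy_dominance_threshold(T: float = 300.0, v: float = 30.0) -> float:
    """xi at which the entropic and energetic parts of dF are equal.

    Found by root-finding on the decomposition itself (the entropy
    fraction as a function of xi), not from the closed-form xi/(1+xi).
    """
    e = 1.602176634e-19

    def fraction_minus_half(xi: float) -> float:
        mu = mu_bar_from_xi(xi, T, v=v)
        res = debye_decomposition(5.0, e, -e, mu, T, v=v)
        return res.entropy_fraction - 0.5

    return brentq(fraction_minus_half, 1e-6, 1e6, xtol=1e-12, rtol=8.9e-16)


def entropy_from_uniform_dielectric(deps_dT: float, E: float, V: float,
                                    T: float) -> float:
    """Electrostatic entropy of a uniform dielectric in a fixed field.

    dS_el = (1/2) (d eps / dT) V E^2, the temperature derivative of
    dF = -(1/2) eps V E^2 at fixed E.  A medium whose permittivity falls
    with temperature (d eps/dT < 0, the generic polar case) loses entropy
    when a field is applied: the field orders the dipoles.

    ``deps_dT`` in F/(m K), ``E`` in V/m, ``V`` in m^3, ``T`` in K;
    result in J/K.
    """
    if V <= 0:
        raise ValueError(f"volume must be positive, got {V}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 0.5 * deps_dT * V * E**2
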