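"""Pointwise nonlinear Langevin dielectric closure.

The solvent is a fluid of molecules carrying a permanent point dipole
mu_bar (and optionally an induced dipole with polarizability alpha).  At
the mean-field saddle point every spatial point obeys a local, scalar
constitutive relation between the electric displacement D (fixed by the
free charges alone, via Gauss's law) and the electric field E:

    D = eps0 E + n mu_bar L(x) + n alpha E,        x = beta mu_bar E,

where L(x) = coth(x) - 1/x is the Langevin function giving the mean
alignment of a classical dipole in a field, and n is the local solvent
number density.  Equivalently D = eps0 (1 + chi_or + chi_el) E with the
orientational susceptibility chi_or = n mu_bar L(x) / (eps0 E) and the
electronic susceptibility chi_el = n alpha / eps0.

Closure reconstruction note: the susceptibilities are stated here through
the Langevin function; the algebraically identical fugacity-weighted form
uses G(x) = L(x) sinh(x)/x^2 (the orientational response factor of the
saddle-point equations).  Both reduce, as E -> 0 with bulk density
n = 1/v, to the Debye susceptibility beta n mu_bar^2/(3 eps0) = xi, so
the effective bulk dielectric constant is exactly the Debye 1 + xi.  At
strong fields chi_or falls off as dipoles saturate (dielectric
saturation), the hallmark of the nonlinear closure.

The free-energy density obtained by substituting the saddle-point
equations back into the Hamiltonian is, up to separation-independent
solvent terms (which cancel in any PMF difference),

    f = E D - eps0 E^2/2 - n alpha E^2/2 - n kT ln(sinh x / x),

which is stationary in E at fixed D on the constitutive solution and
reduces to D^2/(2 eps) in the weak-field limit.  Its temperature
derivative at fixed D gives the orientational entropy density

    s = n k [ln(sinh x / x) - x L(x)]  <=  0,

zero only for randomly oriented dipoles (x = 0).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import ANGSTROM, DEBYE, EPS0, KB, thermal_beta


@dataclass(frozen=True)
class SolventSpec:
    """Dipolar solvent parameters.

    ``mu_bar`` permanent dipole moment in debye; ``v`` molecular volume in
    A^3; ``alpha`` electronic polarizability in C m^2/V (default 0, the
    induced-dipole term is inessential); ``T`` temperature in K.
    """

    mu_bar: float
    v: float = 30.0
    alpha: float = 0.0
    T: float = 300.0

    def __post_init__(self) -> None:
        if self.mu_bar < 0:
            raise ValueError(f"mu_bar must be non-negative, got {self.mu_bar}")
        if self.v <= 0:
            raise ValueError(f"v must be positive, got {self.v}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")

    @property
    def mu_si(self) -> float:
        return self.mu_bar * DEBYE

    @property
    def v_si(self) -> float:
        return self.v * ANGSTROM**3

    @property
    def n_bulk(self) -> float:
        """Bulk number density 1/v, in 1/m^3."""
        return 1.0 / self.v_si

    @property
    def beta(self) -> float:
        return thermal_beta(self.T)

    @property
    def xi(self) -> float:
        """Dimensionless dipole parameter beta mu_bar^2/(3 v eps0)."""
        return self.beta * self.mu_si**2 / (3.0 * self.v_si * EPS0)

    @property
    def chi_el_bulk(self) -> float:
        return self.n_bulk * self.alpha / EPS0

    def with_temperature(self, T: float) -> "SolventSpec":
        return replace(self, T=T)


@dataclass(frozen=True)
class LocalResponse:
    """Converged local dielectric state (scalar or array fields)."""

    chi_or: np.ndarray | float
    chi_el: np.ndarray | float
    E_mag: np.ndarray | float
    n: np.ndarray | float
    iterations: int | None = None
    residual: float | None = None

    @property
    def eps_r(self):
        return 1.0 + self.chi_or + self.chi_el


class FieldConvergenceError(RuntimeError):
    """Fixed-point solve did not reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def langevin_L(x):
    """Langevin function L(x) = coth(x) - 1/x for x >= 0.

    The series branch extends to x = 0.05: below that, the direct
    coth(x) - 1/x evaluation loses ~eps/x^2 relative accuracy to
    cancellation, which would put noise above the 1e-13 stopping
    tolerance of the field solve.
    """
    x = np.asarray(x, dtype=float)
    small = x < 0.05
    x2 = x * x
    series = x * (1.0 / 3.0 + x2 * (-1.0 / 45.0 + x2 * (2.0 / 945.0
                                                        - x2 / 4725.0)))
    xsafe = np.where(small, 1.0, x)
    exact = 1.0 / np.tanh(xsafe) - 1.0 / xsafe
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def orientation_factor_G(x):
    """G(x) = [1/tanh(x) - 1/x] sinh(x)/x^2 = L(x) sinh(x)/x^2.

    The fugacity-weighted orientational response factor; G -> 1/3 as
    x -> 0.  For large x it is evaluated as exp(x - ln(2 x^2) + ln L)
    to avoid intermediate sinh overflow.
    """
    x = np.asarray(x, dtype=float)
    small = x < 1e-2
    big = x > 30.0
    mid = ~small & ~big
    out = np.empty_like(x)
    out[small] = 1.0 / 3.0 + x[small] ** 2 / 30.0
    xm = x[mid]
    out[mid] = langevin_L(xm) * np.sinh(xm) / xm**2
    xb = x[big]
    with np.errstate(over="ignore"):
        # sinh(x) ~ e^x/2 to double precision for x > 30
        out[big] = langevin_L(xb) * np.exp(xb - np.log(2.0 * xb**2))
    return out if out.ndim else float(out)


def _chi_or(n, E_mag, solvent: SolventSpec):
    """Orientational susceptibility n mu L(x)/(eps0 E), with the E -> 0
    limit beta n mu^2/(3 eps0) taken through the series of L(x)/x."""
    n = np.asarray(n, dtype=float)
    E = np.asarray(E_mag, dtype=float)
    x = solvent.beta * solvent.mu_si * E
    chi0 = solvent.beta * n * solvent.mu_si**2 / (3.0 * EPS0)
    small = x < 0.1
    # 3 L(x)/x = 1 - x^2/15 + 2 x^4/315 - x^6/1575 + 2 x^8/31185
    x2 = x * x
    series = chi0 * (1.0 + x2 * (-1.0 / 15.0 + x2 * (2.0 / 315.0
                     + x2 * (-1.0 / 1575.0 + x2 * (2.0 / 31185.0)))))
    xsafe = np.where(small, 1.0, x)
    exact = n * solvent.mu_si * langevin_L(xsafe) / (EPS0 * np.where(small, 1.0, E))
    return np.where(small, series, exact)


def susceptibilities(n, E_mag, solvent: SolventSpec) -> LocalResponse:
    """Local susceptibilities at density ``n`` (1/m^3) and field ``E_mag``
    (V/m)."""
    n = np.asarray(n, dtype=float)
    E = np.asarray(E_mag, dtype=float)
    if np.any(n < 0):
        raise ValueError("number density must be non-negative")
    if np.any(E < 0):
        raise ValueError("field magnitude must be non-negative")
    chi_or = _chi_or(n, E, solvent)
    chi_el = n * solvent.alpha / EPS0
    if chi_or.ndim == 0:
        return LocalResponse(float(chi_or), float(chi_el), float(E), float(n))
    return LocalResponse(chi_or, chi_el + np.zeros_like(chi_or), E, n + np.zeros_like(chi_or))


def solve_field_from_displacement(D_mag, n, solvent: SolventSpec,
                                  tol: float = 1e-13,
                                  max_iter: int = 800) -> LocalResponse:
    """Invert the constitutive relation: find |E| with
    eps0 E + n mu_bar L(beta mu_bar E) + n alpha E = D.

    The scalar fixed point E <- D/(eps0 (1 + chi(E))) is iterated per
    point (the map derivative lies in (0,1), so plain iteration
    converges; an under-relaxation factor 1/2 engages on any detected
    oscillation as a safeguard).  Convergence is a relative change in
    |E| between sweeps below ``tol``.  Vectorized over arrays.
    """
    D = np.atleast_1d(np.asarray(D_mag, dtype=float))
    nn = np.broadcast_to(np.asarray(n, dtype=float), D.shape).copy()
    scalar = np.asarray(D_mag).ndim == 0
    if np.any(D < 0) or np.any(nn < 0):
        raise ValueError("D and n must be non-negative")

    chi_el = nn * solvent.alpha / EPS0
    chi0 = solvent.beta * nn * solvent.mu_si**2 / (3.0 * EPS0)
    E = D / (EPS0 * (1.0 + chi0 + chi_el))
    relax = np.ones_like(E)
    prev_delta = np.zeros_like(E)
    it = 0
    for it in range(1, max_iter + 1):
        chi_or = _chi_or(nn, E, solvent)
        E_new = D / (EPS0 * (1.0 + chi_or + chi_el))
        delta = E_new - E
        osc = delta * prev_delta < 0.0
        relax = np.where(osc, np.maximum(0.25, relax * 0.5), relax)
        E = E + relax * delta
        prev_delta = delta
        rel = np.abs(delta) / (np.abs(E) + 1e-300)
        if float(np.max(rel)) < tol:
            break
    else:
        worst = float(np.max(np.abs(prev_delta) / (np.abs(E) + 1e-300)))
        raise FieldConvergenceError(
            f"field solve did not converge in {max_iter} sweeps "
            f"(worst relative change {worst:.3e})", worst)

    chi_or = _chi_or(nn, E, solvent)
    resid = np.abs(EPS0 * (1.0 + chi_or + chi_el) * E - D) / (D + 1e-300)
    residual = float(np.max(resid)) if resid.size else 0.0
    if scalar:
        return LocalResponse(float(chi_or[0]), float(chi_el[0]), float(E[0]),
                             float(nn[0]), iterations=it, residual=residual)
    return LocalResponse(chi_or, chi_el, E, nn, iterations=it, residual=residual)


def _ln_sinhc(x):
    """ln(sinh(x)/x), overflow-safe, series-continuous at 0."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-2
    big = x > 30.0
    mid = ~small & ~big
    out = np.empty_like(x)
    xs2 = x[small] ** 2
    out[small] = xs2 * (1.0 / 6.0 + xs2 * (-1.0 / 180.0 + xs2 / 2835.0))
    out[mid] = np.log(np.sinh(x[mid]) / x[mid])
    xb = x[big]
    out[big] = xb - np.log(2.0 * xb) + np.log1p(-np.exp(-2.0 * xb))
    return out


def field_free_energy_density(response: LocalResponse,
                              solvent: SolventSpec):
    """Grand-potential density (J/m^3) of the converged local state.

    f = E D - eps0 E^2/2 - n alpha E^2/2 - n kT ln(sinh x / x), with D
    reconstructed from the converged susceptibilities.  Separation-
    independent solvent terms are omitted: under the cavity-superposition
    construction the integral of the ion volume fraction does not depend
    on separation, so those terms cancel in any PMF difference.
    """
    E = np.asarray(response.E_mag, dtype=float)
    n = np.asarray(response.n, dtype=float)
    D = EPS0 * (1.0 + response.chi_or + response.chi_el) * E
    x = solvent.beta * solvent.mu_si * E
    return (E * D - 0.5 * EPS0 * E**2 - 0.5 * n * solvent.alpha * E**2
            - n * KB * solvent.T * _ln_sinhc(x))


def field_entropy_density(response: LocalResponse, solvent: SolventSpec):
    """Orientational entropy density s = n k [ln(sinh x/x) - x L(x)]
    (J/(K m^3)); non-positive, with equality only at x = 0."""
    E = np.asarray(response.E_mag, dtype=float)
    n = np.asarray(response.n, dtype=float)
    x = solvent.beta * solvent.mu_si * E
    return n * KB * (_ln_sinhc(x) - x * langevin_L(x))
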