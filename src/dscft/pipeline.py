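"""PMF assembly: grand free energy, entropy decomposition, polarization.

The pipeline combines the fixed sources (superposed smeared-charge
displacement, cavity-derived solvent density) with the pointwise
Langevin closure and the axisymmetric quadrature into the observables of
interest:

* ``pair_excess`` — the grand-potential (and analytic entropy) excess of
  the pair at separation r over two isolated ions, Omega(r) - Omega(inf).
  The isolated-ion free-energy densities are subtracted *pointwise on
  the same quadrature nodes*, so the large self-energy contributions
  cancel before summation and the integrand is everywhere of the order
  of the ion-ion interaction.  Outside the gridded ball the cross term
  is linear-response to high accuracy and is added analytically (shell
  quadrature of D1.D2/eps_bulk plus a closed-form remainder).
* ``entropy_decomposition`` — dS = -d(dOmega)/dT by central finite
  difference at fixed v and mu_bar (the closure's only explicit
  temperature dependence is through beta), cross-checked against the
  analytic orientational-entropy-density integral.
* ``excess_polarization`` / ``polarization_map`` — Gamma, the volume
  integral of the local orientational polarization chi_or |grad phi|,
  and its axisymmetric map.  Gamma grows with the domain (the single-ion
  polarization decays only as 1/r^2), so it is defined on a fixed
  midpoint-centred sphere.
* ``fit_effective_dielectric`` — Coulomb-tail fit of a PMF curve.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .units import ANGSTROM, EPS0, UnitSystem, joules_to_kJmol, joules_to_reduced
from .debye import mu_bar_from_xi, xi_parameter
from .response import (FieldConvergenceError, LocalResponse, SolventSpec,
                       field_entropy_density, field_free_energy_density,
                       solve_field_from_displacement)
from .sources import IonSpec, PairGeometry, cavity_profile, smeared_displacement
from .quadrature import (QuadratureConfig, RayGrid, central_grid,
                         half_space_grid, shell_grid)

DEFAULT_QUAD = QuadratureConfig()


class EntropyConsistencyError(RuntimeError):
    """Finite-difference and analytic entropies disagree beyond tolerance,
    which signals a closure or quadrature bug."""


def default_ion_pair(sigma: float = 3.0) -> tuple[IonSpec, IonSpec]:
    """Monovalent, oppositely charged ions of diameter ``sigma`` (A)."""
    return IonSpec(z=1, sigma_i=sigma), IonSpec(z=-1, sigma_i=sigma)


# ---------------------------------------------------------------------------
# geometry-dependent, temperature-independent grid fields

@dataclass(frozen=True)
class GridFields:
    """Source fields evaluated once per grid: displacement magnitudes of
    the pair and of each isolated ion, and the matching solvent volume
    fractions (pair cavity vs single cavities)."""

    grid: RayGrid
    D_pair: np.ndarray
    D_iso1: np.ndarray
    D_iso2: np.ndarray
    frac_pair: np.ndarray
    frac_iso1: np.ndarray
    frac_iso2: np.ndarray


def _grid_fields(grid: RayGrid, geometry: PairGeometry) -> GridFields:
    pts = grid.points()
    D_total = np.zeros_like(pts)
    mags, cavities = [], []
    for pos, ion in zip(geometry.positions, (geometry.ion1, geometry.ion2)):
        rvec = pts - pos
        s = np.sqrt(np.sum(rvec**2, axis=-1))
        s_safe = np.where(s < 1e-12, 1.0, s)
        Dr = np.asarray(smeared_displacement(s, ion))
        D_total += Dr[:, None] * rvec / s_safe[:, None]
        mags.append(np.abs(Dr))
        cavities.append(cavity_profile(s, ion))
    D_pair = np.sqrt(np.sum(D_total**2, axis=-1))
    h1, h2 = cavities
    return GridFields(
        grid=grid, D_pair=D_pair, D_iso1=mags[0], D_iso2=mags[1],
        frac_pair=np.clip(1.0 - h1 - h2, 0.0, None),
        frac_iso1=np.clip(1.0 - h1, 0.0, None),
        frac_iso2=np.clip(1.0 - h2, 0.0, None),
    )


def prepare_pair_grids(separation: float, ions: tuple[IonSpec, IonSpec],
                       quad: QuadratureConfig | None = None
                       ) -> list[tuple[GridFields, float]]:
    """Half-space grids (with multiplicity) for one pair geometry.

    Building these is temperature-independent, so one set serves every
    solvent state at the same geometry — which also guarantees the
    finite-difference entropy sees identical discretizations at T +/- dT.
    """
    quad = quad or DEFAULT_QUAD
    geometry = PairGeometry(ions[0], ions[1], separation)
    if geometry.mirror_symmetric:
        return [(_grid_fields(half_space_grid(geometry, 1, quad), geometry), 2.0)]
    return [(_grid_fields(half_space_grid(geometry, 1, quad), geometry), 1.0),
            (_grid_fields(half_space_grid(geometry, 2, quad), geometry), 1.0)]


# ---------------------------------------------------------------------------
# excess grand potential / entropy versus infinite separation

@dataclass(frozen=True)
class PairExcess:
    """Omega(r) - Omega(inf) and the analytic entropy excess, per pair."""

    separation: float          # A
    omega: float               # J
    entropy: float             # J/K
    n_points: int
    iterations: int
    max_residual: float


def _excess_on_fields(gf: GridFields, solvent: SolventSpec,
                      quad: QuadratureConfig) -> tuple[float, float, int, float]:
    w = gf.grid.w
    inv_v = 1.0 / solvent.v_si
    omega = 0.0
    entropy = 0.0
    iters = 0
    resid = 0.0
    for D, frac, sign in ((gf.D_pair, gf.frac_pair, 1.0),
                          (gf.D_iso1, gf.frac_iso1, -1.0),
                          (gf.D_iso2, gf.frac_iso2, -1.0)):
        resp = solve_field_from_displacement(D, frac * inv_v, solvent,
                                             tol=quad.field_tol,
                                             max_iter=quad.max_iter)
        omega += sign * float(np.sum(w * field_free_energy_density(resp, solvent)))
        entropy += sign * float(np.sum(w * field_entropy_density(resp, solvent)))
        iters = max(iters, resp.iterations or 0)
        resid = max(resid, resp.residual or 0.0)
    return omega, entropy, iters, resid


def _linear_tail(separation: float, ions: tuple[IonSpec, IonSpec],
                 solvent: SolventSpec, quad: QuadratureConfig
                 ) -> tuple[float, float]:
    """Cross-term contribution outside the gridded ball, in linear bulk
    response: Omega_tail = J/eps_b and the matching entropy tail, where
    J = int_{R..R'} D1.D2 plus the closed-form remainder q1 q2/(4 pi R')."""
    sigma_ref = max(ions[0].sigma_i, ions[1].sigma_i)
    r_in = quad.r_max_factor * sigma_ref
    r_out = quad.far_cutoff_factor * r_in
    shell = shell_grid(r_in, r_out)
    h = 0.5 * separation
    q1, q2 = ions[0].charge, ions[1].charge
    pts = shell.points()
    fields = []
    for zpos, q in ((-h, q1), (h, q2)):
        rvec = pts - np.array([0.0, 0.0, zpos])
        r2 = np.sum(rvec**2, axis=-1) * ANGSTROM**2
        fields.append(q * rvec * ANGSTROM / (4.0 * math.pi * r2[:, None] ** 1.5))
    dots = np.sum(fields[0] * fields[1], axis=-1)
    J = float(np.sum(shell.w * dots))
    J += q1 * q2 / (4.0 * math.pi * r_out * ANGSTROM)
    chi0 = solvent.xi + solvent.chi_el_bulk
    eps_b = EPS0 * (1.0 + chi0)
    omega_tail = J / eps_b
    # s = -df/dT with d eps_b/dT = -eps0 xi / T (only xi carries T)
    entropy_tail = -(EPS0 * solvent.xi / (solvent.T * eps_b**2)) * J
    return omega_tail, entropy_tail


def pair_excess(separation: float, solvent: SolventSpec,
                ions: tuple[IonSpec, IonSpec] | None = None,
                quad: QuadratureConfig | None = None,
                grids: list[tuple[GridFields, float]] | None = None
                ) -> PairExcess:
    """Omega(separation) - Omega(inf) for the ion pair, by pointwise
    subtraction of the isolated-ion integrands plus the analytic tail.

    ``separation`` in A; energies in J per pair.  Pass ``grids`` from
    :func:`prepare_pair_grids` to reuse discretizations across solvent
    states.
    """
    quad = quad or DEFAULT_QUAD
    ions = ions or default_ion_pair()
    if grids is None:
        grids = prepare_pair_grids(separation, ions, quad)
    omega = 0.0
    entropy = 0.0
    npts = 0
    iters = 0
    resid = 0.0
    for gf, mult in grids:
        o, s, it, rs = _excess_on_fields(gf, solvent, quad)
        omega += mult * o
        entropy += mult * s
        npts += gf.grid.n_points
        iters = max(iters, it)
        resid = max(resid, rs)
    o_tail, s_tail = _linear_tail(separation, ions, solvent, quad)
    return PairExcess(separation=separation, omega=omega + o_tail,
                      entropy=entropy + s_tail, n_points=npts,
                      iterations=iters, max_residual=resid)


def grand_free_energy_difference(separation: float,
                                 ref_separation: float | None,
                                 solvent: SolventSpec,
                                 ions: tuple[IonSpec, IonSpec] | None = None,
                                 quad: QuadratureConfig | None = None) -> float:
    """dOmega = Omega(separation) - Omega(ref_separation), in J.

    ``ref_separation=None`` references infinite separation.
    """
    if separation <= 0 or (ref_separation is not None and ref_separation <= 0):
        raise ValueError("separations must be positive")
    ions = ions or default_ion_pair()
    a = pair_excess(separation, solvent, ions, quad)
    if ref_separation is None:
        return a.omega
    if separation == ref_separation:
        return 0.0
    b = pair_excess(ref_separation, solvent, ions, quad)
    return a.omega - b.omega


# ---------------------------------------------------------------------------
# entropy decomposition

@dataclass(frozen=True)
class PMFRecord:
    """One separation of the decomposed PMF; energies in J per pair,
    relative to the reference separation."""

    separation: float
    ref_separation: float | None   # None: referenced to infinite separation
    delta_omega: float
    delta_u: float
    minus_t_delta_s: float
    gamma_excess: float | None = None

    @property
    def entropy_fraction(self) -> float:
        return self.minus_t_delta_s / self.delta_omega


def entropy_decomposition(separation: float, ref_separation: float | None,
                          solvent: SolventSpec,
                          ions: tuple[IonSpec, IonSpec] | None = None,
                          quad: QuadratureConfig | None = None,
                          delta_T: float = 1.0, check: bool = True,
                          check_tol: float = 5e-3,
                          _grids_sep=None, _grids_ref=None) -> PMFRecord:
    """Decompose dOmega(separation; ref) into dU and -T dS.

    dS = -[dOmega(T+dT) - dOmega(T-dT)]/(2 dT) at fixed v and mu_bar
    (central difference, default dT = 1 K), then dU = dOmega + T dS.
    ``ref_separation=None`` references infinite separation (the natural
    convention for fixed-r entropy-fraction analyses; a finite reference
    like 8 sigma matches the PMF-curve convention instead).  When
    ``check`` is set the finite-difference entropy is compared with the
    analytic entropy-density integral; disagreement beyond ``check_tol``
    (relative) raises :class:`EntropyConsistencyError`.
    """
    if not (0.0 < delta_T < solvent.T):
        raise ValueError("need 0 < delta_T << T")
    quad = quad or DEFAULT_QUAD
    ions = ions or default_ion_pair()
    grids_sep = _grids_sep or prepare_pair_grids(separation, ions, quad)
    if ref_separation is None:
        grids_ref = None
    else:
        grids_ref = _grids_ref or prepare_pair_grids(ref_separation, ions, quad)

    def d_omega(sv: SolventSpec) -> tuple[float, float]:
        a = pair_excess(separation, sv, ions, quad, grids=grids_sep)
        if ref_separation is None:
            return a.omega, a.entropy
        b = pair_excess(ref_separation, sv, ions, quad, grids=grids_ref)
        return a.omega - b.omega, a.entropy - b.entropy

    d_omega_0, d_s_analytic = d_omega(solvent)
    d_omega_p, _ = d_omega(solvent.with_temperature(solvent.T + delta_T))
    d_omega_m, _ = d_omega(solvent.with_temperature(solvent.T - delta_T))
    d_s = -(d_omega_p - d_omega_m) / (2.0 * delta_T)

    if check and abs(solvent.T * d_s_analytic) > 1e-3 * abs(d_omega_0):
        rel = abs(d_s - d_s_analytic) / abs(d_s_analytic)
        if rel > check_tol:
            raise EntropyConsistencyError(
                f"finite-difference entropy {d_s:.6e} J/K deviates from the "
                f"analytic entropy integral {d_s_analytic:.6e} J/K by "
                f"{rel:.2%} (> {check_tol:.2%})")

    return PMFRecord(separation=separation, ref_separation=ref_separation,
                     delta_omega=d_omega_0,
                     delta_u=d_omega_0 + solvent.T * d_s,
                     minus_t_delta_s=-solvent.T * d_s)


def analytic_entropy_difference(separation: float, ref_separation: float,
                                solvent: SolventSpec,
                                ions: tuple[IonSpec, IonSpec] | None = None,
                                quad: QuadratureConfig | None = None) -> float:
    """dS from the analytic orientational-entropy-density integral (J/K);
    the independent oracle for the finite-difference route."""
    ions = ions or default_ion_pair()
    a = pair_excess(separation, solvent, ions, quad)
    b = pair_excess(ref_separation, solvent, ions, quad)
    return a.entropy - b.entropy


# ---------------------------------------------------------------------------
# PMF curves and scans

def pmf_curve(separations, solvent: SolventSpec,
              ions: tuple[IonSpec, IonSpec] | None = None,
              ref_separation: float | None = None,
              quad: QuadratureConfig | None = None,
              decompose: bool = True, delta_T: float = 1.0,
              include_gamma: bool = False,
              units: UnitSystem | None = None) -> pd.DataFrame:
    """PMF table over ``separations`` (A), relative to ``ref_separation``
    (default 8 sigma).  Energies reported in kJ/mol and reduced eps
    units; separations in A and sigma.  Rows whose solve fails are
    reported as NaN with a warning, and the remaining rows continue.
    """
    ions = ions or default_ion_pair()
    units = units or UnitSystem()
    quad = quad or DEFAULT_QUAD
    seps = sorted(float(s) for s in separations)
    if any(s <= 0 for s in seps):
        raise ValueError("separations must be positive")
    ref = ref_separation if ref_separation is not None else 8.0 * units.length_A

    grids_ref = prepare_pair_grids(ref, ions, quad)
    rows = []
    for sep in seps:
        row = {"separation_A": sep, "separation_sigma": sep / units.length_A}
        try:
            if decompose:
                rec = entropy_decomposition(sep, ref, solvent, ions, quad,
                                            delta_T=delta_T,
                                            _grids_ref=grids_ref)
                d_omega, d_u, m_tds = rec.delta_omega, rec.delta_u, rec.minus_t_delta_s
            else:
                a = pair_excess(sep, solvent, ions, quad)
                b = pair_excess(ref, solvent, ions, quad, grids=grids_ref)
                d_omega, d_u, m_tds = a.omega - b.omega, math.nan, math.nan
            row.update(
                delta_omega_kJmol=joules_to_kJmol(d_omega),
                delta_u_kJmol=joules_to_kJmol(d_u),
                minus_T_dS_kJmol=joules_to_kJmol(m_tds),
                delta_omega_eps=joules_to_reduced(d_omega, units),
                delta_u_eps=joules_to_reduced(d_u, units),
                minus_T_dS_eps=joules_to_reduced(m_tds, units),
                entropy_fraction=(m_tds / d_omega if d_omega else math.nan),
            )
            if include_gamma:
                sol = solve_fields(PairGeometry(ions[0], ions[1], sep),
                                   solvent, quad)
                row["gamma_excess"] = excess_polarization(sol)
        except (FieldConvergenceError, EntropyConsistencyError) as err:
            warnings.warn(f"separation {sep} A failed: {err}")
            row.update({k: math.nan for k in
                        ("delta_omega_kJmol", "delta_u_kJmol",
                         "minus_T_dS_kJmol", "delta_omega_eps", "delta_u_eps",
                         "minus_T_dS_eps", "entropy_fraction")})
        rows.append(row)
    return pd.DataFrame(rows)


def entropy_fraction_scan(sep: float, ref_separation: float | None,
                          solvent: SolventSpec,
                          ions: tuple[IonSpec, IonSpec] | None = None,
                          xi_values=None, mu_T_pairs=None,
                          quad: QuadratureConfig | None = None,
                          delta_T: float = 1.0) -> pd.DataFrame:
    """Entropy fraction (-T dS)/dOmega at fixed separation, swept either
    over ``xi_values`` (realized by varying mu_bar at the solvent's T and
    v) or over explicit ``(mu_bar, T)`` pairs.  In the Debye picture the
    fraction depends on (mu_bar, T) only through xi = beta mu^2/(3 v eps0).
    ``ref_separation=None`` references infinite separation.
    """
    if (xi_values is None) == (mu_T_pairs is None):
        raise ValueError("give exactly one of xi_values or mu_T_pairs")
    ions = ions or default_ion_pair()
    quad = quad or DEFAULT_QUAD
    grids_sep = prepare_pair_grids(sep, ions, quad)
    grids_ref = (None if ref_separation is None
                 else prepare_pair_grids(ref_separation, ions, quad))
    if xi_values is not None:
        states = [(mu_bar_from_xi(x, solvent.T, v=solvent.v), solvent.T)
                  for x in xi_values]
    else:
        states = [(float(mu), float(T)) for mu, T in mu_T_pairs]
    rows = []
    for mu, T in states:
        sv = SolventSpec(mu_bar=mu, v=solvent.v, alpha=solvent.alpha, T=T)
        rec = entropy_decomposition(sep, ref_separation, sv, ions, quad,
                                    delta_T=delta_T,
                                    _grids_sep=grids_sep, _grids_ref=grids_ref)
        rows.append({"xi": sv.xi, "mu_bar_D": mu, "T_K": T,
                     "delta_omega_kJmol": joules_to_kJmol(rec.delta_omega),
                     "minus_T_dS_kJmol": joules_to_kJmol(rec.minus_t_delta_s),
                     "entropy_fraction": rec.entropy_fraction})
    return pd.DataFrame(rows)


def entropy_crossover_xi(sep: float, ref_separation: float | None = None,
                         solvent_template: SolventSpec | None = None,
                         ions: tuple[IonSpec, IonSpec] | None = None,
                         quad: QuadratureConfig | None = None,
                         bracket: tuple[float, float] = (0.5, 2.0),
                         xtol: float = 1e-3, delta_T: float = 1.0) -> float:
    """xi at which the entropy fraction of the SCF PMF at separation
    ``sep`` equals 1/2, found by bisecting the dipole moment at fixed T
    and v.  Default reference is infinite separation (the fixed-r
    fraction-versus-xi convention); pass a finite ``ref_separation``
    for the windowed variant."""
    tmpl = solvent_template or SolventSpec(mu_bar=1.0)
    ions = ions or default_ion_pair()
    quad = quad or DEFAULT_QUAD
    grids_sep = prepare_pair_grids(sep, ions, quad)
    grids_ref = (None if ref_separation is None
                 else prepare_pair_grids(ref_separation, ions, quad))

    def fraction_minus_half(xi: float) -> float:
        mu = mu_bar_from_xi(xi, tmpl.T, v=tmpl.v)
        sv = SolventSpec(mu_bar=mu, v=tmpl.v, alpha=tmpl.alpha, T=tmpl.T)
        rec = entropy_decomposition(sep, ref_separation, sv, ions, quad,
                                    delta_T=delta_T,
                                    _grids_sep=grids_sep, _grids_ref=grids_ref)
        return rec.entropy_fraction - 0.5

    return brentq(fraction_minus_half, bracket[0], bracket[1], xtol=xtol)


# ---------------------------------------------------------------------------
# field solutions, polarization, dielectric fit

@dataclass(frozen=True)
class FieldSolution:
    """Converged fields on the axisymmetric evaluation set (a fixed
    midpoint-centred sphere).  ``s``/``z`` in A, weights in m^3."""

    geometry: PairGeometry
    solvent: SolventSpec
    quad: QuadratureConfig
    s: np.ndarray
    z: np.ndarray
    w: np.ndarray
    D_mag: np.ndarray
    response: LocalResponse

    @property
    def eps_r(self) -> np.ndarray:
        return np.asarray(self.response.eps_r)


def solve_fields(geometry: PairGeometry, solvent: SolventSpec,
                 quad: QuadratureConfig | None = None,
                 radius: float | None = None) -> FieldSolution:
    """Solve the pointwise constitutive relation on a midpoint-centred
    spherical domain (default radius ``map_radius_factor * sigma``)."""
    quad = quad or DEFAULT_QUAD
    grid = central_grid(geometry, quad, radius=radius)
    gf = _grid_fields(grid, geometry)
    resp = solve_field_from_displacement(gf.D_pair, gf.frac_pair / solvent.v_si,
                                         solvent, tol=quad.field_tol,
                                         max_iter=quad.max_iter)
    return FieldSolution(geometry=geometry, solvent=solvent, quad=quad,
                         s=grid.s, z=grid.z, w=grid.w, D_mag=gf.D_pair,
                         response=resp)


def excess_polarization(solution: FieldSolution) -> float:
    """Gamma = int chi_or |grad phi| d3r over the solution's domain
    (V m^2); the dipole-release measure.  Non-negative; decreases as the
    ions approach and their polarization clouds cancel."""
    return float(np.sum(solution.w * np.asarray(solution.response.chi_or)
                        * np.asarray(solution.response.E_mag)))


def gamma_curve(separations, solvent: SolventSpec,
                ions: tuple[IonSpec, IonSpec] | None = None,
                quad: QuadratureConfig | None = None,
                units: UnitSystem | None = None) -> pd.DataFrame:
    """Excess polarization versus separation on the fixed Gamma domain."""
    ions = ions or default_ion_pair()
    units = units or UnitSystem()
    rows = []
    for sep in separations:
        sol = solve_fields(PairGeometry(ions[0], ions[1], float(sep)),
                           solvent, quad)
        rows.append({"separation_A": float(sep),
                     "separation_sigma": float(sep) / units.length_A,
                     "gamma_excess": excess_polarization(sol)})
    return pd.DataFrame(rows)


def polarization_map(solution: FieldSolution, s_values, z_values,
                     normalize: bool = False) -> pd.DataFrame:
    """|P| = chi_or |grad phi| on a regular (radial, axial) grid.

    Returns a long-format table with columns radial_A, axial_A, E, eps_r,
    chi_or, P (and P_normalized when ``normalize``), evaluated by fresh
    pointwise solves at the map nodes.
    """
    s_vals = np.asarray(s_values, dtype=float)
    z_vals = np.asarray(z_values, dtype=float)
    S, Z = np.meshgrid(s_vals, z_vals, indexing="ij")
    pts = np.column_stack([S.ravel(), np.zeros(S.size), Z.ravel()])
    gf_geometry = solution.geometry
    D_total = np.zeros_like(pts)
    phi0 = np.zeros(pts.shape[0])
    for pos, ion in zip(gf_geometry.positions,
                        (gf_geometry.ion1, gf_geometry.ion2)):
        rvec = pts - pos
        dist = np.sqrt(np.sum(rvec**2, axis=-1))
        dist_safe = np.where(dist < 1e-12, 1.0, dist)
        Dr = np.asarray(smeared_displacement(dist, ion))
        D_total += Dr[:, None] * rvec / dist_safe[:, None]
        phi0 += cavity_profile(dist, ion)
    D_mag = np.sqrt(np.sum(D_total**2, axis=-1))
    n = np.clip(1.0 - phi0, 0.0, None) / solution.solvent.v_si
    resp = solve_field_from_displacement(D_mag, n, solution.solvent,
                                         tol=solution.quad.field_tol,
                                         max_iter=solution.quad.max_iter)
    P = np.asarray(resp.chi_or) * np.asarray(resp.E_mag)
    out = pd.DataFrame({
        "radial_A": S.ravel(), "axial_A": Z.ravel(),
        "E": np.asarray(resp.E_mag), "eps_r": np.asarray(resp.eps_r),
        "chi_or": np.asarray(resp.chi_or), "P": P,
    })
    if normalize:
        pmax = out["P"].max()
        out["P_normalized"] = out["P"] / pmax if pmax > 0 else 0.0
    return out


def fit_effective_dielectric(separations, delta_omega, q1: float, q2: float,
                             r_min: float | None = None) -> float:
    """Relative permittivity from the Coulomb tail of a PMF curve.

    Least-squares fit of dOmega(r) = q1 q2/(4 pi eps r) + C over rows with
    r >= r_min (A); the constant absorbs the reference convention.
    Returns eps/eps0.
    """
    r = np.asarray(separations, dtype=float)
    dO = np.asarray(delta_omega, dtype=float)
    mask = np.isfinite(dO)
    if r_min is not None:
        mask &= r >= r_min
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 usable rows with r >= r_min")
    slope, _ = np.polyfit(1.0 / (r[mask] * ANGSTROM), dO[mask], 1)
    return q1 * q2 / (4.0 * math.pi * slope) / EPS0


__all__ = [
    "DEFAULT_QUAD", "EntropyConsistencyError", "FieldSolution", "GridFields",
    "PMFRecord", "PairExcess", "analytic_entropy_difference", "default_ion_pair",
    "entropy_crossover_xi", "entropy_decomposition", "entropy_fraction_scan",
    "excess_polarization", "fit_effective_dielectric", "gamma_curve",
    "grand_free_energy_difference", "pair_excess", "pmf_curve",
    "polarization_map", "prepare_pair_grids", "solve_fields",
]
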