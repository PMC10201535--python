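"""Axisymmetric quadrature grids for the two-ion field problem.

The system is rotationally symmetric about the inter-ion axis, so every
volume integral reduces to the (radial, axial) half-plane with weight
2 pi s.  Grids are built from spherical rays: panels of Gauss-Legendre
nodes along each ray, with panel edges placed analytically at every
sharp feature the ray crosses — the Gaussian charge core and the
tanh cavity interface of the ion the grid is centred on (features at
fixed radius), and the interface/core spheres of the *other* ion
(crossing radii found per ray by solving the ray-sphere quadratic).
Between structural edges, panels grow geometrically so the far field is
covered in O(log r) panels.

Two grid families are provided:

* ``half_space_grid`` — spherical rays centred on one ion, restricted to
  that ion's side of the midplane.  The two half-space grids partition
  space; when the ions are mirror images one half integral is doubled.
* ``central_grid`` — rays from the midpoint covering a full sphere of
  fixed radius, used for polarization maps and the excess-polarization
  integral (whose domain must not change with separation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .sources import IonSpec, PairGeometry

_INTERFACE_OFFSETS = (-8.0, -3.0, -1.0, 1.0, 3.0, 8.0)
_CORE_OFFSETS = (-2.0, -1.0, 1.0, 2.0)


@dataclass(frozen=True)
class QuadratureConfig:
    """Grid resolution knobs.

    ``r_max_factor`` — half-space domain radius in units of the largest
    ion diameter (the evaluation set then spans twice this across the
    pair).  ``far_cutoff_factor`` — the linear-response tail shell
    extends to ``far_cutoff_factor * r_max`` before the closed-form
    remainder takes over.  ``growth`` bounds the geometric panel growth
    (panel length <= growth * r).  ``field_tol`` is the relative
    per-sweep change in |E| at which the constitutive solve stops,
    matching the self-consistent stopping criterion of 1e-13.
    """

    r_max_factor: float = 60.0
    far_cutoff_factor: float = 50.0
    n_theta: int = 24
    theta_order: int = 8
    radial_order: int = 8
    growth: float = 0.5
    min_step_sigma: float = 0.3
    field_tol: float = 1e-13
    max_iter: int = 800
    map_radius_factor: float = 25.0

    @staticmethod
    def fast() -> "QuadratureConfig":
        """Coarser preset for scans and tests; accuracy is still well
        inside the tolerances asserted by the test-suite oracles."""
        return QuadratureConfig(n_theta=14, theta_order=6, radial_order=6,
                                growth=0.8, min_step_sigma=0.45)


@dataclass(frozen=True)
class RayGrid:
    """Flattened axisymmetric node set: cylindrical radius ``s`` and
    axial coordinate ``z`` in A, volume weights ``w`` in m^3."""

    s: np.ndarray
    z: np.ndarray
    w: np.ndarray

    @property
    def n_points(self) -> int:
        return self.s.size

    def points(self) -> np.ndarray:
        """(N, 3) cartesian coordinates in A (y = 0 plane)."""
        return np.column_stack([self.s, np.zeros_like(self.s), self.z])


@lru_cache(maxsize=32)
def _gl(order: int):
    return np.polynomial.legendre.leggauss(order)


def _panel_nodes(edges: np.ndarray, order: int):
    """Gauss-Legendre nodes/weights on consecutive panels of ``edges``."""
    x, wgt = _gl(order)
    a = edges[:-1][:, None]
    b = edges[1:][:, None]
    half = 0.5 * (b - a)
    nodes = (0.5 * (a + b) + half * x[None, :]).ravel()
    weights = (half * wgt[None, :]).ravel()
    return nodes, weights


def _sphere_crossings(d: float, cospsi: float, R: float):
    """Radii r > 0 at which a ray crosses the sphere of radius ``R``
    centred a distance ``d`` away, ``cospsi`` the cosine of the angle
    between the ray and the direction to the centre.  Returns a list of
    (r, transversality) with transversality = |dr_sphere/dr| in (0, 1]."""
    disc = R * R - d * d * (1.0 - cospsi * cospsi)
    if disc <= 0.0:
        return []
    root = math.sqrt(disc)
    out = []
    for r0 in (d * cospsi - root, d * cospsi + root):
        if r0 > 1e-12:
            out.append((r0, root / R))
    return out


def _ion_fixed_radii(ion: IonSpec):
    """Structural radii of an ion's own (concentric) features."""
    pts = [0.5 * ion.b, ion.b, 2.0 * ion.b, 3.5 * ion.b]
    mid = ion.m * ion.sigma_i
    width = ion.c * ion.sigma_i
    pts.extend(mid + width * off for off in _INTERFACE_OFFSETS)
    return pts


def _ion_sphere_features(ion: IonSpec):
    """(radius, window width, offsets) for the spheres of a remote ion."""
    return [
        (ion.m * ion.sigma_i, ion.c * ion.sigma_i, _INTERFACE_OFFSETS),
        (2.0 * ion.b, ion.b, _CORE_OFFSETS),
    ]


def _ray_edges(r_max: float, sigma_ref: float, fixed: list[float],
               spheres: list[tuple[float, float]], quad: QuadratureConfig,
               features) -> np.ndarray:
    """Panel edges along one ray.

    ``spheres`` carries (d, cospsi) per remote ion; ``features`` the
    matching list of that ion's (R, width, offsets) triples.
    """
    pts: list[float] = [p for p in fixed if 0.0 < p < r_max]
    for (d, cospsi), feats in zip(spheres, features):
        for R, w0, offsets in feats:
            for r0, trans in _sphere_crossings(d, cospsi, R):
                if r0 >= r_max:
                    continue
                w = w0 / max(trans, 0.2)
                pts.extend(r0 + w * off for off in offsets)
    pts = sorted(p for p in pts if 0.0 < p < r_max)
    # merge near-duplicates
    merged: list[float] = []
    for p in pts:
        if not merged or p - merged[-1] > 1e-9 * sigma_ref:
            merged.append(p)
    merged.append(r_max)

    edges = [0.0]
    for target in merged:
        while True:
            a = edges[-1]
            step = max(quad.min_step_sigma * sigma_ref, quad.growth * a)
            if target - a <= step * (1.0 + 1e-12):
                edges.append(target)
                break
            edges.append(a + step)
    return np.asarray(edges)


def _theta_edges(breaks: list[float], n_theta: int) -> np.ndarray:
    """Subdivide [0, pi] into ~n_theta panels honouring the breakpoints."""
    base = sorted({0.0, math.pi} | {b for b in breaks if 0.0 < b < math.pi})
    edges: list[float] = []
    for a, b in zip(base[:-1], base[1:]):
        k = max(1, round(n_theta * (b - a) / math.pi))
        edges.extend(np.linspace(a, b, k + 1)[:-1])
    edges.append(math.pi)
    return np.asarray(edges)


def _assemble(theta_edges: np.ndarray, quad: QuadratureConfig,
              radial_edges_fn) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (r, theta, weight) flat arrays; weight = 2 pi r^2 sin(th) dr dth
    in A^3."""
    th_nodes, th_w = _panel_nodes(theta_edges, quad.theta_order)
    rs, ths, ws = [], [], []
    for th, wth in zip(th_nodes, th_w):
        redges = radial_edges_fn(th)
        rn, rw = _panel_nodes(redges, quad.radial_order)
        rs.append(rn)
        ths.append(np.full_like(rn, th))
        ws.append(2.0 * math.pi * rn**2 * math.sin(th) * rw * wth)
    return np.concatenate(rs), np.concatenate(ths), np.concatenate(ws)


def half_space_grid(geometry: PairGeometry, center: int,
                    quad: QuadratureConfig) -> RayGrid:
    """Spherical-ray grid centred on ion ``center`` (1 or 2), covering that
    ion's half-space within the midpoint-centred ball of radius
    ``r_max_factor * max(sigma_i)``."""
    ions = (geometry.ion1, geometry.ion2)
    ion_a = ions[center - 1]
    ion_b = ions[2 - center]
    d = geometry.separation
    h = 0.5 * d
    sigma_ref = max(ion_a.sigma_i, ion_b.sigma_i)
    r_dom = quad.r_max_factor * sigma_ref
    if r_dom <= h:
        raise ValueError("separation exceeds the quadrature domain; "
                         "increase r_max_factor")

    breaks = [math.pi / 2.0]
    for R, _w0, _off in _ion_sphere_features(ion_b):
        if R < d:
            breaks.append(math.asin(min(1.0, R / d)))
    th_edges = _theta_edges(breaks, quad.n_theta)

    fixed = _ion_fixed_radii(ion_a)
    feats = [_ion_sphere_features(ion_b)]

    def radial_edges(th: float) -> np.ndarray:
        c = math.cos(th)
        r_plane = h / c if c > 1e-12 else math.inf
        # clip to the midpoint-centred sphere of radius r_dom so the two
        # half-space grids tile exactly that ball (the analytic tail
        # starts on its surface); the midpoint lies at distance h along
        # the local axis
        r_sphere = h * c + math.sqrt(r_dom**2 - h * h * (1.0 - c * c))
        r_max = min(r_plane, r_sphere)
        return _ray_edges(r_max, sigma_ref, fixed, [(d, c)], quad, feats)

    r, th, w = _assemble(th_edges, quad, radial_edges)

    za = geometry.positions[center - 1][2]
    sign = 1.0 if center == 1 else -1.0  # local +axis points toward the other ion
    s = r * np.sin(th)
    z = za + sign * r * np.cos(th)
    return RayGrid(s=s, z=z, w=w * 1e-30)


def central_grid(geometry: PairGeometry, quad: QuadratureConfig,
                 radius: float | None = None) -> RayGrid:
    """Full-sphere ray grid centred at the midpoint, radius
    ``map_radius_factor * max(sigma_i)`` unless overridden (A)."""
    h = 0.5 * geometry.separation
    sigma_ref = max(geometry.ion1.sigma_i, geometry.ion2.sigma_i)
    r_dom = radius if radius is not None else quad.map_radius_factor * sigma_ref

    breaks = [math.pi / 2.0]
    for ion in (geometry.ion1, geometry.ion2):
        for R, _w0, _off in _ion_sphere_features(ion):
            if R < h:
                t = math.asin(min(1.0, R / h))
                breaks.extend([t, math.pi - t])
    th_edges = _theta_edges(breaks, quad.n_theta)

    feats = [_ion_sphere_features(geometry.ion1),
             _ion_sphere_features(geometry.ion2)]

    def radial_edges(th: float) -> np.ndarray:
        c = math.cos(th)
        spheres = [(h, -c), (h, c)]  # ion1 at -h, ion2 at +h on the axis
        return _ray_edges(r_dom, sigma_ref, [], spheres, quad, feats)

    r, th, w = _assemble(th_edges, quad, radial_edges)
    return RayGrid(s=r * np.sin(th), z=r * np.cos(th), w=w * 1e-30)


def shell_grid(r_in: float, r_out: float, n_log_panels: int = 24,
               n_theta_panels: int = 12, order: int = 8) -> RayGrid:
    """Log-radial x angular tensor grid on the spherical shell
    r_in <= r <= r_out (A), centred at the origin.  Used for the smooth
    linear-response tail integral."""
    redges = np.geomspace(r_in, r_out, n_log_panels + 1)
    rn, rw = _panel_nodes(redges, order)
    tedges = np.linspace(0.0, math.pi, n_theta_panels + 1)
    tn, tw = _panel_nodes(tedges, order)
    R, TH = np.meshgrid(rn, tn, indexing="ij")
    W = 2.0 * math.pi * R**2 * np.sin(TH) * rw[:, None] * tw[None, :]
    return RayGrid(s=(R * np.sin(TH)).ravel(), z=(R * np.cos(TH)).ravel(),
                   w=W.ravel() * 1e-30)
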