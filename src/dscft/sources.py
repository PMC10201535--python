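"""Fixed source terms: smeared ion charges, cavities, superposed displacement.

Each ion is a Gaussian-smeared point charge (smearing radius b, which
regularizes the self-energy) sitting inside a spherical solute cavity
from which solvent is excluded.  The cavity is a smooth sigmoid profile
h(s) with midpoint at radius m*sigma_i and interface width c*sigma_i;
with the defaults m = 0.95 and c = 0.01 the ion volume fraction decays
rapidly but continuously and is practically zero by s = sigma_i.  Any
reasonable sigmoid with these properties gives the same qualitative
results.

Because the electric displacement is fixed by the free charges alone,
the two-ion displacement is approximated by superposing the isolated-ion
(radial) displacements.  The superposition is exact at infinite
separation and degrades at close approach, where nonlinearity couples
the two sources.

Distances and coordinates are in angstroms; charge density, displacement
and number density are returned in SI.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .units import ANGSTROM, E_CHARGE
from .response import SolventSpec


@dataclass(frozen=True)
class IonSpec:
    """One ion: valence ``z``, diameter ``sigma_i`` (A), Gaussian smearing
    radius ``b`` (A, default 0.2 sigma_i), cavity midpoint shift ``m`` and
    interface width ``c`` (both dimensionless fractions of sigma_i)."""

    z: int
    sigma_i: float = 3.0
    b: float | None = None
    m: float = 0.95
    c: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_i <= 0:
            raise ValueError(f"sigma_i must be positive, got {self.sigma_i}")
        if self.b is None:
            object.__setattr__(self, "b", 0.2 * self.sigma_i)
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if not (0.0 < self.m < 1.2):
            raise ValueError(f"m must lie in (0, 1.2), got {self.m}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")

    @property
    def charge(self) -> float:
        """Total charge in coulomb."""
        return self.z * E_CHARGE

    def mirror_equivalent(self, other: "IonSpec") -> bool:
        """True when swapping the two ions is a mirror symmetry of all
        field magnitudes (equal geometry and |z|)."""
        return (abs(self.z) == abs(other.z) and self.sigma_i == other.sigma_i
                and self.b == other.b and self.m == other.m and self.c == other.c)


@dataclass(frozen=True)
class PairGeometry:
    """Two ions on the z axis at -separation/2 and +separation/2 (A)."""

    ion1: IonSpec
    ion2: IonSpec
    separation: float

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError(f"separation must be positive, got {self.separation}")

    @property
    def positions(self) -> np.ndarray:
        h = 0.5 * self.separation
        return np.array([[0.0, 0.0, -h], [0.0, 0.0, h]])

    @property
    def mirror_symmetric(self) -> bool:
        return self.ion1.mirror_equivalent(self.ion2)


def gaussian_charge_density(s, ion: IonSpec):
    """rho(s) = z e (2 pi b^2)^(-3/2) exp(-s^2 / 2 b^2), C/m^3; ``s`` in A."""
    s_m = np.asarray(s, dtype=float) * ANGSTROM
    if np.any(s_m < 0):
        raise ValueError("distance must be non-negative")
    b = ion.b * ANGSTROM
    norm = ion.charge * (2.0 * math.pi * b * b) ** -1.5
    return norm * np.exp(-s_m**2 / (2.0 * b * b))


def enclosed_charge(s, ion: IonSpec):
    """Charge (C) enclosed within radius ``s`` (A) of the Gaussian source:
    Q(s) = z e [erf(s/(sqrt2 b)) - sqrt(2/pi) (s/b) exp(-s^2/2b^2)]."""
    s_m = np.asarray(s, dtype=float) * ANGSTROM
    b = ion.b * ANGSTROM
    t = s_m / b
    return ion.charge * (erf(t / math.sqrt(2.0))
                         - math.sqrt(2.0 / math.pi) * t * np.exp(-0.5 * t * t))


def smeared_displacement(s, ion: IonSpec):
    """Radial electric displacement D(s) = Q_enc(s)/(4 pi s^2) in C/m^2.

    Signed with the ion valence; vanishes linearly at the origin and
    tends to the point-charge z e/(4 pi s^2) for s >> b.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("distance must be non-negative")
    s_m = s_arr * ANGSTROM
    b = ion.b * ANGSTROM
    tiny = s_m < 1e-6 * b
    s_safe = np.where(tiny, b, s_m)
    D = enclosed_charge(np.where(tiny, ion.b, s_arr), ion) / (4.0 * math.pi * s_safe**2)
    # Q_enc ~ rho(0) * 4 pi s^3 / 3 near the origin
    rho0 = ion.charge * (2.0 * math.pi * b * b) ** -1.5
    D = np.where(tiny, rho0 * s_m / 3.0, D)
    return D if D.ndim else float(D)


def superposed_displacement(points, geometry: PairGeometry):
    """Vector displacement D1 + D2 (C/m^2) at ``points`` (..., 3) in A."""
    pts = np.asarray(points, dtype=float)
    out = np.zeros(pts.shape, dtype=float)
    for pos, ion in zip(geometry.positions, (geometry.ion1, geometry.ion2)):
        rvec = pts - pos
        s = np.sqrt(np.sum(rvec**2, axis=-1))
        s_safe = np.where(s < 1e-12, 1.0, s)
        Dr = smeared_displacement(s, ion)
        out += np.asarray(Dr)[..., None] * rvec / s_safe[..., None]
    return out


def cavity_profile(s, ion: IonSpec):
    """Single-ion cavity function h(s) = [1 - tanh((s - m sigma)/(c sigma))]/2."""
    s = np.asarray(s, dtype=float)
    return 0.5 * (1.0 - np.tanh((s - ion.m * ion.sigma_i) / (ion.c * ion.sigma_i)))


def cavity_fraction(points, geometry: PairGeometry):
    """Ion volume fraction phi0 = h1 + h2 at ``points`` (..., 3) in A.

    Values in [0, 2]; phi0 > 1 only where the two cavities overlap.
    """
    pts = np.asarray(points, dtype=float)
    total = np.zeros(pts.shape[:-1], dtype=float)
    for pos, ion in zip(geometry.positions, (geometry.ion1, geometry.ion2)):
        s = np.sqrt(np.sum((pts - pos) ** 2, axis=-1))
        total += cavity_profile(s, ion)
    return total if total.ndim else float(total)


def solvent_density(points, geometry: PairGeometry, solvent: SolventSpec):
    """Coarse-grained solvent number density n = max(0, 1 - phi0)/v in
    1/m^3 (clipped where the cavities overlap; negative density is
    unphysical)."""
    frac = np.clip(1.0 - cavity_fraction(points, geometry), 0.0, None)
    return frac / solvent.v_si
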