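"""Physical constants and reduced-unit conversions.

The reduced system used throughout the package mirrors a coarse-grained,
water-like solvent bead: length scale 1 sigma = 3 A, energy scale
1 eps = 2.49 kJ/mol, mass scale 1 m = 18.015 g/mol, with the derived time
scale tau = sqrt(m sigma^2 / eps).  All internal computation is carried
out in SI; reduced units appear only at the I/O boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

# CODATA 2018 (exact where the SI defines them so)
EPS0 = 8.8541878128e-12      # vacuum permittivity, F/m
KB = 1.380649e-23            # Boltzmann constant, J/K
E_CHARGE = 1.602176634e-19   # elementary charge, C
N_A = 6.02214076e23          # Avogadro constant, 1/mol
DEBYE = 3.335640952e-30      # 1 debye in C m
ANGSTROM = 1.0e-10           # 1 A in m


class UnknownUnitTagError(KeyError):
    """Raised when :func:`convert` receives a quantity tag it does not know."""


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit scales.

    Physical-side units per tag: length in A, energy in kJ/mol, mass in
    g/mol, temperature in K, dipole in debye, charge in C, time in s.
    """

    length_A: float = 3.0
    energy_kJmol: float = 2.49
    mass_gmol: float = 18.015

    def __post_init__(self) -> None:
        for name in ("length_A", "energy_kJmol", "mass_gmol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    # -- derived SI scales (per molecule) ---------------------------------
    @property
    def length_m(self) -> float:
        return self.length_A * ANGSTROM

    @property
    def energy_J(self) -> float:
        return self.energy_kJmol * 1e3 / N_A

    @property
    def mass_kg(self) -> float:
        return self.mass_gmol * 1e-3 / N_A

    @property
    def time_s(self) -> float:
        """tau = sqrt(m sigma^2 / eps)."""
        return math.sqrt(self.mass_kg * self.length_m**2 / self.energy_J)

    @property
    def temperature_K(self) -> float:
        return self.energy_J / KB

    @property
    def charge_C(self) -> float:
        """Charge unit of the Gaussian-style reduced electrostatics,
        sqrt(4 pi eps0 sigma eps)."""
        return math.sqrt(4 * math.pi * EPS0 * self.length_m * self.energy_J)

    @property
    def dipole_debye(self) -> float:
        """Reduced dipole unit sqrt(4 pi eps0 sigma^3 eps), in debye."""
        return math.sqrt(4 * math.pi * EPS0 * self.length_m**3 * self.energy_J) / DEBYE

    def scale_for(self, tag: str) -> float:
        """Physical value of one reduced unit of the tagged quantity."""
        scales = {
            "length": self.length_A,
            "energy": self.energy_kJmol,
            "mass": self.mass_gmol,
            "temperature": self.temperature_K,
            "dipole": self.dipole_debye,
            "charge": self.charge_C,
            "time": self.time_s,
        }
        try:
            return scales[tag]
        except KeyError:
            raise UnknownUnitTagError(
                f"unknown unit tag {tag!r}; expected one of {sorted(scales)}"
            ) from None


def convert(value, tag: str, direction: str, units: UnitSystem | None = None):
    """Convert ``value`` between physical and reduced units.

    ``direction`` is ``"to_reduced"`` or ``"to_physical"``.  The physical
    units per tag are documented on :class:`UnitSystem`.
    """
    units = units or UnitSystem()
    scale = units.scale_for(tag)
    if direction == "to_reduced":
        return value / scale
    if direction == "to_physical":
        return value * scale
    raise ValueError(f"direction must be 'to_reduced' or 'to_physical', got {direction!r}")


def thermal_beta(T: float) -> float:
    """beta = 1/(k_B T) in 1/J; ``T`` in kelvin."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return 1.0 / (KB * T)


def joules_to_kJmol(x):
    """Per-particle energy in J -> kJ/mol."""
    return x * N_A / 1e3


def joules_to_reduced(x, units: UnitSystem | None = None):
    """Per-particle energy in J -> reduced eps units."""
    units = units or UnitSystem()
    return x / units.energy_J


def cubic_box_edge(n_particles: int, rho_A3: float, sigma_A: float = 3.0) -> float:
    """Edge length, in sigma, of a cubic box holding ``n_particles`` at
    number density ``rho_A3`` (1/A^3)."""
    if n_particles <= 0 or rho_A3 <= 0 or sigma_A <= 0:
        raise ValueError("n_particles, rho_A3 and sigma_A must be positive")
    return (n_particles / rho_A3) ** (1.0 / 3.0) / sigma_A
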