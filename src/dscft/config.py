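"""Run configuration: plain-text (TOML/JSON) loading, defaults, validation.

A minimal configuration is just ``mu_bar = 1.0``; everything else fills
in from the standard water-like parameter set (sigma = 3 A, T = 300 K,
v = 30 A^3, monovalent opposite charges, m = 0.95, c = 0.01, field
tolerance 1e-13, reference separation 8 sigma).  Separations are given
in sigma units, either as a list or as an inclusive ``start:stop:step``
range string.
"""
from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .quadrature import QuadratureConfig
from .response import SolventSpec
from .sources import IonSpec


class ConfigError(ValueError):
    """Invalid or contradictory configuration, naming the offending key."""


_KNOWN_KEYS = {
    "mu_bar", "v", "rho", "alpha", "T", "temperature",
    "z1", "z2", "sigma", "b", "m", "c",
    "separations", "ref_sep", "tol", "delta_T", "units", "out",
}


def parse_separations(spec) -> list[float]:
    """Separations in sigma units from a list or ``start:stop:step``
    (inclusive range) string."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ConfigError(f"separations range must be start:stop:step, got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0 or stop < start:
            raise ConfigError(f"bad separations range {spec!r}")
        out = []
        k = 0
        while True:
            val = start + k * step
            if val > stop + 1e-9 * step:
                break
            out.append(round(val, 12))
            k += 1
        return out
    return [float(s) for s in spec]


@dataclass(frozen=True)
class RunConfig:
    """Resolved run parameters (separations in sigma units)."""

    mu_bar: float = 1.0
    v: float = 30.0
    alpha: float = 0.0
    T: float = 300.0
    z1: int = 1
    z2: int = -1
    sigma: float = 3.0
    b: float = 0.6
    m: float = 0.95
    c: float = 0.01
    separations: tuple[float, ...] = field(
        default_factory=lambda: tuple(parse_separations("1.0:8.0:0.5")))
    ref_sep: float = 8.0
    tol: float = 1e-13
    delta_T: float = 1.0
    units: str = "si"
    out: str = "dscft_out"

    def __post_init__(self) -> None:
        seps = tuple(float(s) for s in self.separations)
        if any(s <= 0 for s in seps):
            raise ConfigError("separations: all values must be positive")
        if len(set(seps)) != len(seps):
            raise ConfigError("separations: values must be unique")
        object.__setattr__(self, "separations", seps)
        if self.units not in ("si", "reduced"):
            raise ConfigError(f"units: must be 'si' or 'reduced', got {self.units!r}")
        if self.ref_sep <= 0:
            raise ConfigError("ref_sep: must be positive")

    # -- factories --------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # nested sections are flattened
                flat.update(val)
            else:
                flat[key] = val
        unknown = set(flat) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "temperature" in flat:
            flat["T"] = flat.pop("temperature")
        if "rho" in flat:
            if "v" in flat:
                raise ConfigError("give exactly one of v and rho, not both")
            rho = float(flat.pop("rho"))
            if rho <= 0:
                raise ConfigError("rho: must be positive")
            flat["v"] = 1.0 / rho
        if "separations" in flat:
            flat["separations"] = tuple(parse_separations(flat["separations"]))
        if flat.get("b") is None:
            flat["b"] = 0.2 * float(flat.get("sigma", 3.0))
        return cls(**flat)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["separations"] = list(d["separations"])
        return d

    # -- domain objects ---------------------------------------------------
    def solvent(self) -> SolventSpec:
        return SolventSpec(mu_bar=self.mu_bar, v=self.v, alpha=self.alpha,
                           T=self.T)

    def ions(self) -> tuple[IonSpec, IonSpec]:
        return (IonSpec(z=self.z1, sigma_i=self.sigma, b=self.b, m=self.m,
                        c=self.c),
                IonSpec(z=self.z2, sigma_i=self.sigma, b=self.b, m=self.m,
                        c=self.c))

    def quadrature(self) -> QuadratureConfig:
        return QuadratureConfig(field_tol=self.tol)

    def separations_A(self) -> list[float]:
        return [s * self.sigma for s in self.separations]

    def ref_sep_A(self) -> float:
        return self.ref_sep * self.sigma


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    return RunConfig.from_dict(raw)


def save_resolved(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as JSON (reloadable with
    :func:`load_config` to an identical RunConfig)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2,
                                     sort_keys=True) + "\n")
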