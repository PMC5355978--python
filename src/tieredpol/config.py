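"""TOML configuration for the model chain.

A study configuration groups the optical constants, the microvillar
transduction parameters, the opponent-unit noise settings and the sweep
grids.  Every key has a default taken from the measured blowfly values, so
an empty file is a valid configuration.  Unknown keys are rejected with an
error naming the offending key path.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .optics import DichroicAbsorption, OpticalGeometry
from .transduction import MicrovillarArray

__all__ = [
    "ConfigError",
    "OpticsConfig",
    "TransductionConfig",
    "OpponentSettings",
    "ExperimentsConfig",
    "StudyConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Malformed study configuration."""


@dataclass(frozen=True)
class OpticsConfig:
    F: float = 2.0
    D_r: float = 1.55            # rhabdomere diameter, um
    k: float = 0.0075            # unpolarized peak absorption coefficient, um^-1
    delta: float = 10.0          # dichroic ratio k_par / k_perp
    lambda_max: float = 335.0    # pigment peak wavelength, nm


@dataclass(frozen=True)
class TransductionConfig:
    microvilli_per_um: float = 360.0
    t_d_ms: float = 30.0
    tau_ms: float = 90.0
    segment_um: float = 1.0
    saturation: bool = False


@dataclass(frozen=True)
class OpponentSettings:
    d: float = 0.1
    sigma_in_sq: float = 5e-5    # contrast variance per 1 s of integration
    tau_ms: float = 90.0
    theta_grid_n: int = 900
    mi_q_grid: int = 2001


@dataclass(frozen=True)
class ExperimentsConfig:
    total_length_um: float = 100.0
    ni_values: tuple[float, ...] = (1e5, 3e5, 1e6, 3e6)


@dataclass(frozen=True)
class StudyConfig:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    transduction: TransductionConfig = field(default_factory=TransductionConfig)
    opponent: OpponentSettings = field(default_factory=OpponentSettings)
    experiments: ExperimentsConfig = field(default_factory=ExperimentsConfig)

    def dichroic(self) -> DichroicAbsorption:
        return DichroicAbsorption(
            k_mean_peak=self.optics.k,
            dichroic_ratio=self.optics.delta,
            lambda_max_nm=self.optics.lambda_max,
        )

    def geometry(self) -> OpticalGeometry:
        return OpticalGeometry(self.optics.F, self.optics.D_r)

    def microvillar_array(self) -> MicrovillarArray:
        return MicrovillarArray(
            microvilli_per_um=self.transduction.microvilli_per_um,
            dead_time_ms=self.transduction.t_d_ms,
            segment_thickness_um=self.transduction.segment_um,
        )

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "optics": OpticsConfig,
    "transduction": TransductionConfig,
    "opponent": OpponentSettings,
    "experiments": ExperimentsConfig,
}


def _build_section(name: str, cls, raw: dict):
    known = set(cls.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown configuration key '{name}.{key}'")
    kwargs = dict(raw)
    if "ni_values" in kwargs:
        kwargs["ni_values"] = tuple(float(v) for v in kwargs["ni_values"])
    return cls(**kwargs)


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a TOML study configuration."""
    raw = tomllib.loads(Path(path).read_text())
    for section in raw:
        if section not in _SECTIONS:
            raise ConfigError(f"unknown configuration section '{section}'")
        if not isinstance(raw[section], dict):
            raise ConfigError(f"configuration section '{section}' must be a table")
    parts = {
        name: _build_section(name, cls, raw.get(name, {}))
        for name, cls in _SECTIONS.items()
    }
    return StudyConfig(**parts)
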