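"""Run configuration: YAML parsing, validation, and round-tripping.

Configuration units are conventional (Pa, µm, mg/mL); the mechanical core
converts to its internal µm/nN/kPa system at assembly time. Defaults
reproduce the baseline scaffold: a 10 µm cube with a 50³ brick matrix mesh,
698 fibers (1.5 mg/mL) of 62 nm diameter and 50 MPa modulus meshed with
100 nm beam elements, matrix shear modulus 11 Pa, and 5% applied
compressive strain.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .beam_fe import BeamSection, FiberMaterial
from .coupling import LoadCase
from .geometry import RVEGeometry
from .matrix_fe import MatrixMaterial


class ConfigError(ValueError):
    """Invalid or unknown configuration entry (message carries the key path)."""


@dataclass
class FiberConfig:
    concentration: float = 1.5  # mg/mL
    diameter: float = 0.062  # µm
    youngs_modulus: float = 5.0e7  # Pa
    poisson_ratio: float = 0.3
    element_length: float = 0.1  # µm


@dataclass
class MatrixConfig:
    shear_modulus: float = 11.0  # Pa
    bulk_ratio: float = 1.0e4


@dataclass
class GeometryConfig:
    edge_length: float = 10.0  # µm
    mesh_divisions: int = 50


@dataclass
class LoadConfig:
    strain: float = 0.05
    increments: int = 5
    mode: str = "linear"


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fiber: FiberConfig = field(default_factory=FiberConfig)
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    load: LoadConfig = field(default_factory=LoadConfig)
    seed: int = 0
    output_dir: str = "rvenet_out"

    def __post_init__(self) -> None:
        self.validate()

    # -- constructed domain objects (validation happens in their constructors)
    def rve_geometry(self) -> RVEGeometry:
        return RVEGeometry(self.geometry.edge_length, self.geometry.mesh_divisions)

    def beam_section(self) -> BeamSection:
        return BeamSection(self.fiber.diameter)

    def fiber_material(self) -> FiberMaterial:
        return FiberMaterial(self.fiber.youngs_modulus, self.fiber.poisson_ratio)

    def matrix_material(self) -> MatrixMaterial:
        return MatrixMaterial(self.matrix.shear_modulus, self.matrix.bulk_ratio)

    def load_case(self) -> LoadCase:
        return LoadCase(self.load.strain, self.load.increments, self.load.mode)

    def validate(self) -> None:
        try:
            self.rve_geometry()
            self.beam_section()
            self.fiber_material()
            self.matrix_material()
            self.load_case()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.fiber.concentration < 0:
            raise ConfigError("fiber.concentration: must be non-negative")
        if self.fiber.element_length <= 0:
            raise ConfigError("fiber.element_length: must be positive")
        if int(self.seed) != self.seed:
            raise ConfigError("seed: must be an integer")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "geometry": GeometryConfig,
            "fiber": FiberConfig,
            "matrix": MatrixConfig,
            "load": LoadConfig,
        }
        kwargs = {}
        for key, value in (data or {}).items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"{key}: expected a mapping")
                known = sections[key].__dataclass_fields__
                for sub in value:
                    if sub not in known:
                        raise ConfigError(f"{key}.{sub}: unknown configuration key")
                kwargs[key] = sections[key](**value)
            elif key in ("seed", "output_dir"):
                kwargs[key] = value
            else:
                raise ConfigError(f"{key}: unknown configuration key")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
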