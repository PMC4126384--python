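"""Schema-validated run configuration.

All defaults reproduce the study conditions: a 0.4 x 10 x 5.68 um cuboid,
0.4 um axon diameter, 53% axon volume fraction, the 1.08 undulation
threshold with 8/20/44% coupling at stage stretches 1.06/1.12/1.25, Ogden
exponent 8.22 with the axon three times stiffer than the matrix, and an
inverse bracket of (20, 50) kPa with 1.0 kPa tolerance and 20 curve sample
points.  Unknown keys are rejected.

Units: lengths um, stresses/moduli kPa.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError
from .fe import LoadProgram, SolverOptions
from .geometry import BoxDomain
from .kinematics import CouplingRule

__all__ = [
    "GeometryConfig",
    "KinematicsConfig",
    "MaterialConfig",
    "LoadConfig",
    "MeshConfig",
    "InverseConfig",
    "SolverConfig",
    "RunConfig",
    "read_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Strict):
    domain: tuple[float, float, float] = (0.4, 10.0, 5.68)
    radius: float = Field(0.2, gt=0)
    target_volume_fraction: float = Field(0.53, ge=0.0)
    packing_bound: float = Field(0.85, gt=0.0)
    undulation_mean: float = 1.13
    undulation_sd: float = Field(0.06, gt=0)
    undulation_low: float = Field(1.02, ge=1.0)
    undulation_high: float = 1.30
    n_waypoints: int = Field(8, ge=1)
    n_subsegments: int = Field(50, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if min(self.domain) <= 0:
            raise ValueError("domain sizes must be positive")
        if self.undulation_high <= self.undulation_low:
            raise ValueError("undulation_high must exceed undulation_low")
        if self.target_volume_fraction > self.packing_bound:
            raise ValueError("target_volume_fraction exceeds packing_bound")
        return self

    @property
    def box(self) -> BoxDomain:
        return BoxDomain(*self.domain)


class KinematicsConfig(_Strict):
    threshold_undulation: float = 1.08
    stage_breaks: tuple[float, ...] = (1.06, 1.12, 1.25)
    stage_fractions: tuple[float, ...] = (0.08, 0.20, 0.44)
    selection_policy: str = "straightest"

    @property
    def rule(self) -> CouplingRule:
        return CouplingRule(
            threshold_undulation=self.threshold_undulation,
            stage_breaks=self.stage_breaks,
            stage_fractions=self.stage_fractions,
        )


class MaterialConfig(_Strict):
    mu_axon_kPa: float = Field(33.28, gt=0)
    mu_ratio_axon_to_ecm: float = Field(3.0, gt=0)
    alpha: float = 8.22
    bulk_penalty_factor: float = Field(100.0, ge=10.0)


class LoadConfig(_Strict):
    stage_stretches: tuple[float, ...] = (1.06, 1.12, 1.25)
    substeps: int = Field(6, ge=1)

    @property
    def program(self) -> LoadProgram:
        return LoadProgram(stage_stretches=self.stage_stretches,
                           substeps=self.substeps)


class MeshConfig(_Strict):
    element_size: float = Field(0.4, gt=0)


class SolverConfig(_Strict):
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)
    max_iterations: int = Field(25, ge=1)
    tie_factor_high: float = Field(1e3, gt=0)
    tie_factor_low: float = Field(1e-3, gt=0)

    @property
    def options(self) -> SolverOptions:
        return SolverOptions(
            rtol=self.rtol, atol=self.atol, max_iterations=self.max_iterations,
            tie_factor_high=self.tie_factor_high,
            tie_factor_low=self.tie_factor_low,
        )


class InverseConfig(_Strict):
    bracket: tuple[float, float] = (20.0, 50.0)
    tol_kPa: float = Field(1.0, gt=0)
    m: int = Field(20, ge=1)
    # synthetic target (stands in for an untabulated experimental curve)
    target_mu_kPa: float = Field(32.8, gt=0)
    target_alpha: float = 8.22
    target_lambda_max: float = Field(1.25, gt=1.0)
    target_n_points: int = Field(50, ge=2)
    sensitivity_alphas: tuple[float, ...] = (6.95, 8.22, 9.49)


class RunConfig(_Strict):
    geometry: GeometryConfig = GeometryConfig()
    kinematics: KinematicsConfig = KinematicsConfig()
    material: MaterialConfig = MaterialConfig()
    load: LoadConfig = LoadConfig()
    mesh: MeshConfig = MeshConfig()
    inverse: InverseConfig = InverseConfig()
    solver: SolverConfig = SolverConfig()
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def read_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    An empty file or ``None`` yields the full default configuration.
    Unknown or invalid keys raise :class:`ConfigurationError` naming them.
    """
    if path_or_dict is None:
        data = {}
    elif isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        data = yaml.safe_load(text) or {}
    try:
        return RunConfig(**data)
    except ValidationError as err:
        keys = ", ".join(
            ".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ConfigurationError(
            f"invalid configuration (offending keys: {keys}):\n{err}"
        ) from err
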