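"""Study configuration: schema, defaults, loading and resolution.

The configuration is a YAML (or JSON) document validated against a pydantic
schema; unknown keys are rejected.  Every physical quantity carries its unit
in the field name or description.  Defaults encode the reference study
conditions: wall parameters of an elderly healthy aorta (HGO and its
linearized orthotropic counterpart), three-patient brachial blood pressures,
probe levels 2/15/30 kPa, and surrounding-tissue shear moduli 5/10/20 kPa.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .constitutive import (HGOWallParams, LinearWallParams)
from .errors import ConfigError
from .geometry import GeometrySpec, patient_archetypes
from .solver import SolverControls

__all__ = ["StudyConfig", "load_config", "default_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HGOConfig(_Strict):
    """HGO wall parameters (Gasser dispersion form)."""

    C10_kPa: float = 100.9
    k1_MPa: float = 4.07
    k2: float = 165.55
    kappa: float = 0.16
    theta_deg: float = 48.4

    @field_validator("kappa")
    @classmethod
    def _kappa_range(cls, v):
        if not 0.0 <= v <= 1.0 / 3.0:
            raise ValueError(f"kappa must lie in [0, 1/3], got {v}")
        return v

    def to_params(self) -> HGOWallParams:
        return HGOWallParams.from_k1_mpa(self.C10_kPa, self.k1_MPa, self.k2,
                                         self.kappa, self.theta_deg)


class LinearWallConfig(_Strict):
    """Linearized orthotropic wall parameters."""

    E_theta_MPa: float = 1.11
    E_z_MPa: float = 3.58
    G_MPa: float = 4.0
    nu: float = 0.44

    def to_params(self) -> LinearWallParams:
        return LinearWallParams(E_theta=self.E_theta_MPa * 1000.0,
                                E_z=self.E_z_MPa * 1000.0,
                                G=self.G_MPa * 1000.0, nu=self.nu)


class GeometryConfig(_Strict):
    """One patient archetype; see :class:`aaaprobe.geometry.GeometrySpec`."""

    d_max_mm: float
    wall_thickness_mm: float = 2.0
    lumen_ellipticity: float = 1.0
    abdomen_semi_axes_mm: tuple[float, float] = (160.0, 110.0)
    aorta_depth_mm: float = 45.0
    spine_gap_mm: float = 8.0
    spine_radius_mm: float = 15.0
    probe_width_mm: float = 70.0
    mesh_size_mm: float = 2.0
    n_wall: int = 82
    perturb_amplitude: float = 0.0

    def to_spec(self, seed: int) -> GeometrySpec:
        return GeometrySpec(
            d_max=self.d_max_mm, wall_thickness=self.wall_thickness_mm,
            lumen_ellipticity=self.lumen_ellipticity,
            abdomen_semi_axes=self.abdomen_semi_axes_mm,
            aorta_depth=self.aorta_depth_mm, spine_gap=self.spine_gap_mm,
            spine_radius=self.spine_radius_mm,
            probe_width=self.probe_width_mm, mesh_size=self.mesh_size_mm,
            n_wall=self.n_wall, perturb_amplitude=self.perturb_amplitude,
            seed=seed)


class SolverConfig(_Strict):
    rtol: float = 1.0e-8
    atol_kPa_mm: float = 1.0e-7
    max_newton: int = 30
    n_steps: int = 10
    max_halvings: int = 4

    def to_controls(self) -> SolverControls:
        return SolverControls(rtol=self.rtol, atol=self.atol_kPa_mm,
                              max_newton=self.max_newton,
                              n_steps=self.n_steps,
                              max_halvings=self.max_halvings)


class ZeroPressureConfig(_Strict):
    tol_mm: float = 0.05
    max_iter: int = 15
    include_tissue: bool = True
    accelerate: bool = True


def _default_geometries() -> dict[str, GeometryConfig]:
    out = {}
    for name, spec in patient_archetypes().items():
        out[name] = GeometryConfig(
            d_max_mm=spec.d_max, wall_thickness_mm=spec.wall_thickness,
            lumen_ellipticity=spec.lumen_ellipticity,
            abdomen_semi_axes_mm=spec.abdomen_semi_axes,
            aorta_depth_mm=spec.aorta_depth, spine_gap_mm=spec.spine_gap,
            spine_radius_mm=spec.spine_radius,
            probe_width_mm=spec.probe_width, mesh_size_mm=spec.mesh_size,
            n_wall=spec.n_wall, perturb_amplitude=spec.perturb_amplitude)
    return out


class StudyConfig(_Strict):
    """Top-level study configuration (all defaults = reference conditions)."""

    seed: int = 0
    patients: dict[str, GeometryConfig] = Field(
        default_factory=_default_geometries)
    blood_pressures_mmHg: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"P1": (76.0, 138.0), "P2": (90.0, 153.0),
                                 "P3": (88.0, 144.0)})
    probe_levels_kPa: dict[str, float] = Field(
        default_factory=lambda: {"LPP": 2.0, "MPP": 15.0, "FPP": 30.0})
    st_moduli_kPa: tuple[float, ...] = (5.0, 10.0, 20.0)
    wall_models: tuple[str, ...] = ("hgo", "linear")
    hgo: HGOConfig = Field(default_factory=HGOConfig)
    linear_wall: LinearWallConfig = Field(default_factory=LinearWallConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    zero_pressure: ZeroPressureConfig = Field(
        default_factory=ZeroPressureConfig)

    @field_validator("blood_pressures_mmHg")
    @classmethod
    def _bp_order(cls, v):
        for pat, (d, s) in v.items():
            if not s > d > 0:
                raise ValueError(
                    f"blood pressure for {pat} must satisfy sys > dias > 0")
        return v

    def archetype_specs(self) -> dict[str, GeometrySpec]:
        return {name: g.to_spec(self.seed)
                for name, g in self.patients.items()}

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=True)


def default_config(seed: int = 0) -> StudyConfig:
    return StudyConfig(seed=seed)


def load_config(path: str | Path | None) -> StudyConfig:
    """Load and validate a YAML/JSON study config; ``None`` → all defaults.

    Raises :class:`ConfigError` with the offending key path on schema
    violations.
    """
    if path is None:
        return StudyConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = (json.loads(text) if path.suffix == ".json"
               else yaml.safe_load(text)) or {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return StudyConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"invalid config {path}: {exc}") from exc
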