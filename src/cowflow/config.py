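"""Run configuration: a single YAML document with validated defaults.

An empty configuration file reproduces the study's default
parameterization (resting vitals, ICP 3 mmHg, CBF 12.5 ml/s split
22/45/33, standard Carreau constants, nominal synthetic geometry, the
full variant-by-degree grid).  Unknown keys are rejected so typos fail
loudly, and the effective configuration can be re-serialized verbatim
next to the outputs.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .network import CANONICAL_SEGMENTS, Variant

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class VitalsConfig(_Strict):
    diastolic_pressure: float = 80.0
    systolic_pressure: float = 120.0
    heart_rate: float = 80.0


class PerfusionConfig(_Strict):
    intracranial_pressure: float = 3.0
    total_cbf: float = 12.5
    fraction_aca: float = 0.22
    fraction_mca: float = 0.45
    fraction_pca: float = 0.33


class CarreauConfig(_Strict):
    relaxation_time: float = 3.313
    power_index: float = 0.3568
    mu_zero: float = 0.056
    mu_inf: float = 0.00345


class OutletPressureConfig(_Strict):
    aca: float = 46.0
    mca: float = 56.0
    pca: float = 43.5


class GeometryConfig(_Strict):
    source: Literal["fixture", "file", "synthetic"] = "fixture"
    path: str | None = None          # required for source == "file"
    seed: int = 0                    # synthetic only
    jitter_fraction: float = 0.0     # synthetic only

    @field_validator("jitter_fraction")
    @classmethod
    def _jitter_range(cls, v: float) -> float:
        if not 0.0 <= v < 0.3:
            raise ValueError("jitter_fraction must lie in [0, 0.3)")
        return v


class StenosisConfig(_Strict):
    target_segment: str = "RICA"
    stenotic_length: float = 10.0

    @field_validator("target_segment")
    @classmethod
    def _known_segment(cls, v: str) -> str:
        if v not in CANONICAL_SEGMENTS:
            raise ValueError(f"unknown segment {v!r}")
        return v


class SolverConfig(_Strict):
    max_iterations: int = 200
    relative_tolerance: float = 1e-8
    under_relaxation: float = 0.5


class RunConfig(_Strict):
    """Complete run specification; defaults reproduce the study setup."""

    vitals: VitalsConfig = VitalsConfig()
    perfusion: PerfusionConfig = PerfusionConfig()
    carreau: CarreauConfig = CarreauConfig()
    outlet_pressures: OutletPressureConfig = OutletPressureConfig()
    geometry: GeometryConfig = GeometryConfig()
    stenosis: StenosisConfig = StenosisConfig()
    solver: SolverConfig = SolverConfig()
    variants: tuple[str, ...] = tuple(v.value for v in Variant)
    degrees: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 90.0, 100.0)
    output_dir: str = "cowflow-output"

    @field_validator("variants")
    @classmethod
    def _known_variants(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        for name in v:
            Variant(name)  # raises on unknown
        return v

    @field_validator("degrees")
    @classmethod
    def _degree_range(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        for d in v:
            if not 0.0 <= d <= 100.0:
                raise ValueError(f"stenosis degree {d} outside [0, 100]")
        return v

    # -- bridges to the domain objects --------------------------------
    def vital_signs(self):
        from .boundary import VitalSigns
        return VitalSigns(**self.vitals.model_dump())

    def perfusion_constants(self):
        from .boundary import PerfusionConstants
        return PerfusionConstants(**self.perfusion.model_dump())

    def carreau_parameters(self):
        from .rheology import CarreauParameters
        return CarreauParameters(**self.carreau.model_dump())

    def boundary_set(self):
        from .boundary import build_boundary_set
        return build_boundary_set(
            self.vital_signs(), self.perfusion_constants(),
            outlet_pressures={"ACA": self.outlet_pressures.aca,
                              "MCA": self.outlet_pressures.mca,
                              "PCA": self.outlet_pressures.pca})

    def solver_settings(self):
        from .solver import SolverSettings
        return SolverSettings(**self.solver.model_dump())

    def dimension_table(self):
        from .network import (load_dimension_table, nominal_geometry,
                              synthetic_geometry)
        if self.geometry.source == "fixture":
            return nominal_geometry()
        if self.geometry.source == "synthetic":
            return synthetic_geometry(self.geometry.seed,
                                      self.geometry.jitter_fraction)
        if self.geometry.path is None:
            raise ValueError("geometry.source 'file' requires geometry.path")
        return load_dimension_table(self.geometry.path)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the full default run specification.
    Referenced geometry files must exist at load time.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    cfg = RunConfig.model_validate(raw or {})
    if cfg.geometry.source == "file":
        if cfg.geometry.path is None:
            raise ValueError("geometry.source 'file' requires geometry.path")
        if not Path(cfg.geometry.path).exists():
            raise FileNotFoundError(cfg.geometry.path)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as YAML (round-trips losslessly)."""
    payload = cfg.model_dump()
    payload["variants"] = list(payload["variants"])
    payload["degrees"] = list(payload["degrees"])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
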