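"""Run configuration.

A single schema-validated :class:`RunConfig` drives the whole pipeline.
Physiological defaults: 100 mmHg inlet pressure, 715 mL/min total
cerebral flow, 65 mmHg cortical pressure drop, blood viscosity
3.5e-3 Pa.s, 40 um pial/penetrating diameters, 8.7 /mm^2 penetrating
density, N1 = 2000 coarse and N2 = 37 fine subregions, 99% diameter
occlusion.  Unknown keys are rejected so parameter-study typos fail
loudly.  ``scaled_fixture_config`` returns the reduced synthetic-sphere
configuration used throughout the tests and worked examples.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_triangle_count: int = Field(default=20480, ge=20)
    semi_axes_mm: tuple[float, float, float] = (60.0, 60.0, 60.0)
    wrinkle_amplitude_mm: float = Field(default=0.0, ge=0.0)
    wrinkle_frequency: int = Field(default=6, ge=1)
    mesh_path: str | None = None  # load instead of generating

    @field_validator("semi_axes_mm")
    @classmethod
    def _positive_axes(cls, v):
        if min(v) <= 0:
            raise ValueError("semi-axes must be positive")
        return v


class TreeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n1: int = Field(default=2000, ge=6, description="number of coarse subregions")
    n2: int = Field(default=37, ge=1, description="fine subregions per coarse region")
    murray_exponent: float = Field(default=3.0, ge=2.0, le=4.0)
    terminal_diameter_floor_um: float = Field(default=30.0, gt=0)
    cco_candidate_connections: int = Field(default=5, ge=1)
    root_diameter_mode: str = Field(
        default="murray",
        description=(
            "'murray': size territory roots from their area shares so "
            "root hydraulics follow the same minimum-energy law as the "
            "trees (reference diameters provide the total cube); "
            "'fixed': use root_diameters_um verbatim"
        ),
    )
    root_diameters_um: dict[str, float] = Field(
        default_factory=lambda: {
            "LACA": 2000.0,
            "RACA": 2000.0,
            "LMCA": 2500.0,
            "RMCA": 2500.0,
            "LPCA": 2000.0,
            "RPCA": 2000.0,
        }
    )

    @field_validator("root_diameter_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("murray", "fixed"):
            raise ValueError("root_diameter_mode must be 'murray' or 'fixed'")
        return v


class PialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pial_diameter_um: float = Field(default=40.0, gt=0)
    penetrating_diameter_um: float = Field(default=40.0, gt=0)
    target_density_per_mm2: float = Field(default=8.7, gt=0)


class FlowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    inlet_pressure_mmhg: float = Field(default=100.0, gt=0)
    total_flow_ml_min: float = Field(default=715.0, gt=0)
    cortical_drop_mmhg: float = Field(default=65.0, gt=0)
    viscosity_pa_s: float = Field(default=3.5e-3, gt=0)
    bed_pressure_mmhg: float | None = None  # None -> calibrate to total flow
    calibration_tolerance_ml_min: float = Field(default=1.0, gt=0)
    solver: str = "auto"

    @field_validator("solver")
    @classmethod
    def _solver(cls, v):
        if v not in ("auto", "direct", "iterative"):
            raise ValueError("solver must be auto, direct or iterative")
        return v


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    occlusion_diameter_scale: float = Field(default=0.01, gt=0, le=1.0)
    run_selection: bool = False
    max_candidates: int | None = None  # cap N for the greedy procedure


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    tree: TreeConfig = Field(default_factory=TreeConfig)
    pial: PialConfig = Field(default_factory=PialConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)
    seed: int = 0
    output_dir: str = "cerebroflow_output"

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        return cls.model_validate(data or {})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def scaled_fixture_config(seed: int = 1) -> RunConfig:
    """Reduced whole-network configuration on a synthetic sphere cortex:
    N1 = 200 coarse regions, N2 = 10 fine subregions each, and a pial
    layer of ~20k nodes (icosphere at 20480 triangles).  Small enough to
    solve in minutes on one CPU while keeping all structural tiers."""
    return RunConfig(
        geometry=GeometryConfig(target_triangle_count=20480),
        tree=TreeConfig(n1=200, n2=10),
        seed=seed,
    )


def smoke_config(seed: int = 0) -> RunConfig:
    """Minimal end-to-end configuration (sphere, N1=12, N2=3) for smoke
    tests; runs in seconds."""
    return RunConfig(
        geometry=GeometryConfig(target_triangle_count=1280),
        tree=TreeConfig(n1=12, n2=3),
        seed=seed,
    )
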