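"""Validated pipeline configuration.

One flat declarative object carries every tunable of the pipeline;
unknown keys are rejected and ranges are validated before any compute.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All tunables of the margin pipeline with their defaults."""

    model_config = ConfigDict(extra="forbid")

    # landmark stage
    ncc_threshold: float = Field(0.7, ge=-1.0, le=1.0)
    mahalanobis_head: float = Field(15.0, gt=0)
    mahalanobis_shoulder: float = Field(60.0, gt=0)
    shoulder_direction: str = Field("higher", pattern="^(higher|lower)$")
    reference_region: str = Field("skull", pattern="^(skull|spine|shoulder)$")

    # biomechanical model
    young_modulus_mpa: float = Field(10.0, gt=0)
    poisson_ratio: float = Field(0.45, ge=0.0, lt=0.5)
    spring_stiffness: float = Field(1000.0, gt=0)  # N/mm
    solver_tolerance: float = Field(1e-3, gt=0)  # N
    #: looser force tolerance for the many scenario solves of approach 3
    #: (0.5 N imbalance moves a landmark by <1e-3 mm at k = 1000 N/mm)
    scenario_tolerance: float = Field(0.5, gt=0)
    max_iterations: int = Field(60, ge=1)
    load_step_mm: float = Field(25.0, gt=0)
    calibration_fit_target_mm: float = Field(0.5, gt=0)

    # pose model
    n_components: int = Field(5, ge=1)
    n_scenarios: int = Field(400, ge=1)

    # margin engines
    constant_radius_mm: float = Field(3.0, ge=0)
    margin_mode: str = Field("ci", pattern="^(ci|yang)$")
    ci_z: float = Field(1.96, gt=0)
    weight_exponent: float = Field(3.0, gt=0)
    hit_threshold: float = Field(0.05, ge=0.0, lt=1.0)

    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        data = self.model_dump()
        data.update(overrides)
        return PipelineConfig(**data)
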