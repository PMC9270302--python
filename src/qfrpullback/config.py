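"""Pipeline configuration: a single versioned, human-readable JSON schema.

Every published threshold is a default here and is never hard-coded at call
sites; the synthetic-cohort block mirrors :class:`~qfrpullback.simulate.CohortSpec`.
Configurations round-trip losslessly through ``save``/``load``.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .metrics import Thresholds
from .simulate import DEFAULT_PATTERN_MIX, STENT_FOCAL, CohortSpec


class ClassifierConfig(BaseModel):
    """Qualitative-method thresholds (QFR units / mm)."""

    focal_min_drop: float = 0.05
    focal_max_span_mm: float = 10.0
    diffuse_min_len_mm: float = 15.0
    diffuse_min_drop: float = 0.05
    separation_mm: float = 5.0


class ThresholdConfig(BaseModel):
    """Published QVP/QFR decision cutoffs."""

    focal_pred_cutoff: float = 0.71
    diffuse_pred_cutoff: float = 0.51
    suboptimal_qvp_cutoff: float = 0.57
    tertile_bounds: tuple[float, float] = (0.54, 0.71)
    suboptimal_post_qfr: float = 0.89

    def to_thresholds(self) -> Thresholds:
        return Thresholds(
            focal_pred_cutoff=self.focal_pred_cutoff,
            diffuse_pred_cutoff=self.diffuse_pred_cutoff,
            suboptimal_qvp_cutoff=self.suboptimal_qvp_cutoff,
            tertile_bounds=tuple(self.tertile_bounds),
            suboptimal_post_qfr=self.suboptimal_post_qfr,
        )


class CohortConfig(BaseModel):
    """Synthetic-cohort generating conditions."""

    n_vessels: int = 120
    pattern_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PATTERN_MIX)
    )
    tvl_range_mm: tuple[float, float] = (55.0, 80.0)
    distal_qfr_range: tuple[float, float] = (0.70, 0.77)
    noise_sd: float = 0.005
    multi_vessel_fraction: float = 0.08
    stent_strategy: str = STENT_FOCAL
    max_stent_mm: float = 40.0
    instent_loss_max: float = 0.012

    def to_spec(self, seed: int, step_mm: float) -> CohortSpec:
        return CohortSpec(
            seed=seed,
            n_vessels=self.n_vessels,
            pattern_mix=dict(self.pattern_mix),
            tvl_range_mm=tuple(self.tvl_range_mm),
            distal_qfr_range=tuple(self.distal_qfr_range),
            noise_sd=self.noise_sd,
            step_mm=step_mm,
            multi_vessel_fraction=self.multi_vessel_fraction,
            stent_strategy=self.stent_strategy,
            max_stent_mm=self.max_stent_mm,
            instent_loss_max=self.instent_loss_max,
        )


class PipelineConfig(BaseModel):
    """Top-level configuration for the full pipeline."""

    schema_version: int = 1
    seed: int = 0
    step_mm: float = 0.5
    slope_eps: float = 0.002
    merge_gap_mm: float = 2.0
    window_mm: float = 20.0
    min_delta: float = 0.02
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    out_dir: str = "qfrpull_output"

    @model_validator(mode="after")
    def _check(self):
        if self.step_mm <= 0 or self.window_mm <= 0:
            raise ValueError("step_mm and window_mm must be positive")
        return self

    def cohort_spec(self) -> CohortSpec:
        return self.cohort.to_spec(seed=self.seed, step_mm=self.step_mm)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))
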