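"""Validated pipeline configuration (YAML-backed, schema-checked).

Defaults encode the study layout, so an empty config runs the full-shape
experiment on synthetic data: 46/45 subjects, C=38 fMRI / C=32 MEG
components, T=149/300 samples, window 31 samples with sigma-3 taper,
k=5 states per group, q=0.05 FDR. Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dataio import Band
from .synthetic import DEFAULT_EFFECT_PAIRS, SimulationConfig

__all__ = ["PipelineConfig", "validate_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_per_group: tuple[int, int] = (46, 45)
    c_fmri: int = Field(38, ge=2)
    c_meg: int = Field(32, ge=2)
    t_fmri: int = Field(149, ge=2)
    t_meg: int = Field(300, ge=2)
    bands: list[str] = ["delta", "theta", "alpha", "beta", "gamma"]
    include_fmri: bool = True
    effect_pairs: list[tuple[str, tuple[int, int], float]] = [
        list(e) for e in DEFAULT_EFFECT_PAIRS  # type: ignore[list-item]
    ]
    n_states_per_group: int = Field(5, ge=1)
    state_strength: float = Field(0.4, ge=0)
    state_divergence: float = Field(0.5, ge=0, le=1)
    mix_dynamic: float = Field(0.5, ge=0, le=1)
    dwell: float = Field(0.9, gt=0, le=1)
    smoothing: dict[str, float] = {"fmri": 0.6, "meg": 0.3}

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_per_group=tuple(self.n_per_group),
            c_fmri=self.c_fmri,
            c_meg=self.c_meg,
            t_fmri=self.t_fmri,
            t_meg=self.t_meg,
            bands=tuple(Band(b) for b in self.bands),
            include_fmri=self.include_fmri,
            effect_pairs=tuple((t, tuple(p), d) for t, p, d in self.effect_pairs),
            n_states_per_group=self.n_states_per_group,
            state_strength=self.state_strength,
            state_divergence=self.state_divergence,
            mix_dynamic=self.mix_dynamic,
            dwell=self.dwell,
            smoothing=dict(self.smoothing),
            seed=seed,
        )


class StaticSection(_Section):
    q: float = Field(0.05, ge=0, le=1)
    max_lag: int = Field(0, ge=0)


class DynamicSection(_Section):
    width: int = Field(31, ge=3)
    step: int = Field(1, ge=1)
    sigma: float = Field(3.0, ge=0)
    k: int = Field(5, ge=1)
    lam: float | str = "cv"
    lambda_grid: list[float] = Field(
        default_factory=lambda: [round(x, 6) for x in
                                 [0.01, 0.0167, 0.0278, 0.0464, 0.0774, 0.129, 0.215, 0.359, 0.599, 1.0]]
    )

    @field_validator("lam")
    @classmethod
    def _check_lam(cls, v):
        if isinstance(v, str) and v != "cv":
            raise ValueError("lam must be a number or 'cv'")
        return v


class ClassifySection(_Section):
    classifiers: list[str] = ["NBC", "nSVM", "LDC"]


class EnsembleSection(_Section):
    tie_break: str = "confidence"

    @field_validator("tie_break")
    @classmethod
    def _check_tb(cls, v):
        if v not in ("confidence", "class-order"):
            raise ValueError("tie_break must be 'confidence' or 'class-order'")
        return v


class PipelineConfig(_Section):
    seed: int = 0
    out: str | None = None
    simulate: SimulateSection = SimulateSection()
    static: StaticSection = StaticSection()
    dynamic: DynamicSection = DynamicSection()
    classify: ClassifySection = ClassifySection()
    ensemble: EnsembleSection = EnsembleSection()


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load, default and schema-validate a YAML config; reject unknown keys."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
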