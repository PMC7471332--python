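"""Pipeline configuration: YAML/JSON schema with validated defaults.

Every analysis constant the pipeline uses is configurable here; defaults
reproduce the study protocol (TR 16 ms / TE 3 ms, flip angles 2-30 deg,
double angles 70/140 deg, GS-cluster bounds 1-1800 ms, 90th-percentile
trim, FWHM 0.4 mm, FDR q 0.05). The relaxivity ``r1`` has no universal
value and must be stated explicitly. Unknown keys are rejected by name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    tr_ms: float = 16.0
    te_ms: float = 3.0
    flip_angles_deg: list[float] = Field(default=[2, 5, 10, 15, 20, 30])
    dam_angles_deg: list[float] = Field(default=[70, 140])

    @field_validator("flip_angles_deg")
    @classmethod
    def _increasing(cls, v):
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("flip_angles_deg must be strictly increasing with >= 2 entries")
        return v

    @field_validator("dam_angles_deg")
    @classmethod
    def _double(cls, v):
        if len(v) != 2 or abs(v[1] - 2 * v[0]) > 1e-9:
            raise ValueError("dam_angles_deg must be a pair (alpha, 2*alpha)")
        return v


class PhantomConfig(_Strict):
    grid_shape: list[int] = Field(default=[100, 100, 100])
    fov_mm: float = 18.0

    @field_validator("grid_shape")
    @classmethod
    def _shape(cls, v):
        if len(v) != 3 or any(n < 4 for n in v):
            raise ValueError("grid_shape must be three integers >= 4")
        return v


class GroupConfig(_Strict):
    name: str
    n_subjects: int = Field(ge=1)
    reductions: dict[str, float] = Field(default_factory=dict)
    t1_jitter_frac: float = 0.03
    c_jitter_frac: float = 0.03

    @field_validator("reductions")
    @classmethod
    def _fracs(cls, v):
        for k, f in v.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"reduction for {k!r} must lie in [0, 1)")
        return v


class AnalysisConfig(_Strict):
    r1: float = Field(gt=0)  # L mmol^-1 s^-1; no default — must be stated
    cluster_lo_ms: float = 1.0
    cluster_hi_ms: float = 1800.0
    trim_percentile: float = 90.0
    fdr_q: float = 0.05
    smoothing_fwhm_mm: float = 0.4


class SimulationConfig(_Strict):
    noise_snr: float | None = 50.0  # null = noiseless
    b1_amplitude: float = 0.2
    b1_length_scale_mm: float = 4.0


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str | None = None
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    analysis: AnalysisConfig
    groups: list[GroupConfig] = Field(default_factory=lambda: _default_group_configs())

    @field_validator("groups")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("at least one group is required")
        names = [g.name for g in v]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        return v


def _default_group_configs() -> list[GroupConfig]:
    """The three-group study design: control n=9, KX+Gd n=7, ISO+Gd n=7."""
    from .phantom import ISO_REDUCTIONS, KX_REDUCTIONS

    return [
        GroupConfig(name="control", n_subjects=9),
        GroupConfig(name="KX+Gd", n_subjects=7, reductions=dict(KX_REDUCTIONS)),
        GroupConfig(name="ISO+Gd", n_subjects=7, reductions=dict(ISO_REDUCTIONS)),
    ]


def default_config(r1: float = 3.5, **overrides) -> PipelineConfig:
    """The default three-group study configuration."""
    cfg = {"analysis": {"r1": r1}}
    cfg.update(overrides)
    return PipelineConfig(**cfg)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline config.

    Defaults are injected for every optional block and echoed to the log;
    unknown keys raise a :class:`ConfigError` listing them.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {details}") from exc
    logger.info("config loaded: %s", cfg.model_dump_json())
    return cfg
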