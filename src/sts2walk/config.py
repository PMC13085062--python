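"""Pipeline configuration: dataclass defaults, YAML overrides, validation.

Every default that is not dictated by the measurement protocol (sampling
rate, test length) is an explicit, documented analysis choice; the shipped
``configs/default.yaml`` mirrors this structure with comments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .features import FEATURE_SET_VERSION, SampEnParams
from .preprocess import FilterSpec
from .segmentation import ScreeningConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class SelectionOptions:
    r_threshold: float = 0.90
    k_features: int = 7
    rfe_estimator: str = "linear"
    interaction_top_k: int = 3


@dataclass(frozen=True)
class ModelingOptions:
    models: tuple[str, ...] = ("rf", "lr", "svm", "xgb", "lgbm")
    folds: int = 5
    inner_folds: int = 3
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: FilterSpec = field(default_factory=FilterSpec)
    segmentation: ScreeningConfig = field(default_factory=ScreeningConfig)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    selection: SelectionOptions = field(default_factory=SelectionOptions)
    modeling: ModelingOptions = field(default_factory=ModelingOptions)
    feature_set: str = FEATURE_SET_VERSION

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "preprocess": FilterSpec,
    "segmentation": ScreeningConfig,
    "sampen": SampEnParams,
    "selection": SelectionOptions,
    "modeling": ModelingOptions,
}


def _build_section(cls, payload: dict, section: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise KeyError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )
    # YAML gives lists where dataclasses want tuples
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    return cls(**coerced)


def load_config(path: str | None = None) -> PipelineConfig:
    """Load a pipeline configuration; omitted sections keep their defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TypeError("config file must contain a mapping")
    kwargs = {}
    for key, payload in raw.items():
        if key == "feature_set":
            kwargs["feature_set"] = str(payload)
            continue
        if key not in _SECTIONS:
            raise KeyError(f"unknown config section {key!r}")
        kwargs[key] = _build_section(_SECTIONS[key], payload or {}, key)
    return PipelineConfig(**kwargs)
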