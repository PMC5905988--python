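"""Pipeline configuration: one structure, one human-readable file.

All thresholds of the profile-extent rules, the model choice and Gaussian
convention, the regressor hyperparameters, the validation scheme and the
single random seed live here and round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .profiles import ClrRuleConfig
from .regression import RegressorConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    #: profile model fitted to the cross-sections: hermite | dogl7 | dogl8
    model_id: str = "dogl7"
    #: Gaussian exponent form: "printed" (exp(-((x-mu)/(2 sigma))^2)) or
    #: "standard" (exp(-(x-mu)^2 / (2 sigma^2)))
    gaussian_convention: str = "printed"
    #: validation scheme when annotations are provided: kfold | loso
    validation: str = "kfold"
    k: int = 10
    seed: int = 0
    #: centerline segments shorter than this many pixels are pruned
    min_segment_len: int = 10
    #: neighboring profiles pooled on each side for 2D fitting / mean profiles
    neighbors_per_side: int = 5
    #: fit every n-th centerline point (1 = all)
    profile_step: int = 1
    #: profiles with more than this fraction of out-of-image samples are
    #: excluded from length statistics
    max_outside_fraction: float = 0.25
    #: anisotropic smoothing spreads as fractions of the profile length
    sigma_across_factor: float = 0.1
    sigma_along_factor: float = 1.5
    #: ground-truth matching radius (px, strict)
    match_max_dist: float = 5.0
    clr_rules: ClrRuleConfig = field(default_factory=ClrRuleConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)

    def __post_init__(self):
        if self.model_id not in ("hermite", "dogl7", "dogl8"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.validation not in ("kfold", "loso"):
            raise ValueError(f"unknown validation {self.validation!r}")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "clr_rules" in raw:
        raw["clr_rules"] = ClrRuleConfig(**raw["clr_rules"])
    if "regressor" in raw:
        raw["regressor"] = RegressorConfig(**raw["regressor"])
    return PipelineConfig(**raw)
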