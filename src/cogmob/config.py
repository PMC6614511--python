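"""Pipeline configuration and YAML (de)serialization."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .generate import GeneratorConfig, config_from_dict, config_to_dict

__all__ = ["PipelineConfig", "load_pipeline_config", "load_generator_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the two-stage analysis.

    ``outlier_cutoff_numerator`` gives the Bonferroni outlier cutoff as
    numerator/n (4/n by default).  ``selection_adjusted_bh`` switches on the
    hierarchical q*(#selected/#families) within-family level; the default is
    plain per-family BH.
    """

    screening_alpha: float = 0.05
    bh_q: float = 0.05
    outlier_cutoff_numerator: float = 4.0
    range_filter_threshold: float = 0.80
    selection_adjusted_bh: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("screening_alpha", "bh_q", "range_filter_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(name, "must be in (0, 1)")
        if self.outlier_cutoff_numerator < 1:
            raise ConfigurationError("outlier_cutoff_numerator", "must be >= 1")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def load_pipeline_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def load_generator_config(path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = config_from_dict(raw)
    cfg.validate()
    return cfg


def save_generator_config(cfg: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg)))
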