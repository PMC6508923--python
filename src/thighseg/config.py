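"""YAML-backed run configuration covering the pipeline's tunable constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .fusion import FusionConfig
from .register import RegistrationConfig


@dataclass
class PipelineConfig:
    levels: int = 256  # gray levels Q
    n_add: int = 4  # global LCDG deviation components
    n_sub: int = 4
    min_component_vox: int = 1000
    gate_threshold: float = 0.5
    laplace_alpha: float = 0.5
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reg = RegistrationConfig(**{
            k: tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v
            for k, v in raw.pop("registration", {}).items()
        })
        fus = FusionConfig(**raw.pop("fusion", {}))
        return cls(registration=reg, fusion=fus, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
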