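"""Pipeline configuration: one YAML file carrying every threshold.

Defaults are the analysis constants used throughout: significance alpha 0.05
with fold change > 2, expression thresholds at RPKM 3 (RPKM 0.1 for
single-cell tables), co-expression correlation 0.9, singleton shared-target
fraction 0.05.  Unknown keys are rejected on load.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .datamodel import DEFAULT_STAGE_ORDER, ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    min_fc: float = 2.0
    maternal_rpkm: float = 3.0
    expressed_rpkm: float = 3.0
    icm_min_rpkm: float = 3.0
    singlecell_expressed_rpkm: float = 0.1
    correlation_threshold: float = 0.9
    singleton_min_shared: float = 0.05
    singleton_denominator: str = "min"
    network_expression_floor: float = 3.0
    log_base: int = 10
    pseudocount: float = 1.0
    use_tmm: bool = True
    trim_m: float = 0.30
    trim_a: float = 0.05
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_fc <= 1:
            raise ValidationError("min_fc must exceed 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not (0 <= self.singleton_min_shared <= 1):
            raise ValidationError("singleton_min_shared must be in [0, 1]")
        if self.singleton_denominator not in ("min", "union"):
            raise ValidationError("singleton_denominator must be 'min' or 'union'")
        if self.log_base not in (2, 10):
            raise ValidationError("log_base must be 2 or 10")
        object.__setattr__(self, "stage_order", tuple(self.stage_order))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["stage_order"] = list(data["stage_order"])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path
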