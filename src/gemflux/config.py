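"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
import yaml

from .errors import ValidationError
from .fba import SOLVERS


@dataclass
class AnalysisConfig:
    growth_threshold: float = 1e-5
    flux_change_threshold: float = 0.01  # mmol/gDW/h, absolute mode
    relative_change_threshold: float = 0.01  # 1%, relative mode
    fva_fraction: float = 0.90
    k_max: int = 2
    solver: str = "highs"
    lethality_cutoff_mode: str = "absolute"  # or "fractional"
    combo_cap: int = 200_000
    include_fva: bool = False
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> "AnalysisConfig":
        if self.growth_threshold <= 0:
            raise ValidationError("growth_threshold must be > 0")
        if self.flux_change_threshold <= 0:
            raise ValidationError("flux_change_threshold must be > 0")
        if self.relative_change_threshold <= 0:
            raise ValidationError("relative_change_threshold must be > 0")
        if not (0.0 < self.fva_fraction <= 1.0):
            raise ValidationError(
                f"fva_fraction must be in (0, 1], got {self.fva_fraction}"
            )
        if not (1 <= self.k_max <= 3):
            raise ValidationError(f"k_max must be in 1..3, got {self.k_max}")
        if self.solver not in SOLVERS:
            raise ValidationError(f"solver must be one of {SOLVERS}")
        if self.lethality_cutoff_mode not in ("absolute", "fractional"):
            raise ValidationError("lethality_cutoff_mode: 'absolute' or 'fractional'")
        if self.combo_cap <= 0:
            raise ValidationError("combo_cap must be > 0")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
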