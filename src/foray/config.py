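"""Pipeline configuration.

Defaults encode the analysis constants: 15 m GPS-accuracy threshold
(strictly exceeded to call an excursion), 95% MCP retention, June-August
summer months for territory estimation, an 18:00-06:00 night window, the
Juvenile (0-1) / Young Adult (2-3) / Older Adult (>3) cohort cuts and the
April-September high / October-March low season split.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class StatsOptions:
    month_coding: str = "categorical"   # categorical (11 df) | linear (1 df)
    fit_models: bool = False            # fit the GLMMs during run_pipeline
    model_selection: bool = False       # full AICc subset ranking (slow)

    def __post_init__(self) -> None:
        if self.month_coding not in ("categorical", "linear"):
            raise ValueError("month_coding must be 'categorical' or 'linear'")


@dataclass
class PipelineConfig:
    fixes_path: str = "fixes.csv"
    animals_path: str = "animals.csv"
    exclusions_path: str | None = None
    territories_path: str | None = None   # provided polygons; None -> build MCPs
    out_dir: str = "out"

    threshold_m: float = 15.0
    retention_fraction: float = 0.95
    summer_months: tuple[int, ...] = (6, 7, 8)
    night_start_hour: int = 18
    night_end_hour: int = 6
    fallback_full_year: bool = True
    juvenile_max_age: int = 1
    young_adult_max_age: int = 3
    high_season_months: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.stats, dict):
            self.stats = StatsOptions(**self.stats)
        if self.threshold_m < 0:
            raise ValueError("threshold_m must be non-negative")
        if not 0 < self.retention_fraction <= 1:
            raise ValueError("retention_fraction must be in (0, 1]")
        self.summer_months = tuple(int(m) for m in self.summer_months)
        self.high_season_months = tuple(int(m) for m in self.high_season_months)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["summer_months"] = list(self.summer_months)
        doc["high_season_months"] = list(self.high_season_months)
        return yaml.safe_dump(doc, sort_keys=True)
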