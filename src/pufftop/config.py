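"""Pipeline configuration.

Every study constant appears exactly once here (or in
:class:`~pufftop.cleansing.CleansingConfig`): the 0.5 s / 3.3 V false-puff
rule, the 0.95 nonuse quantile, the 10/40/70 percentile bin edges, the
14-day evaluation period, alpha=.05 for the ANOVA and alpha=.016 for the
PES t tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cleansing import CleansingConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class PipelineConfig:
    cleansing: CleansingConfig = field(default_factory=CleansingConfig)
    evaluation_days: int = 14
    percentile_method: str = "linear"  # or "nearest"
    group_bins: tuple[float, float, float] = (10.0, 40.0, 70.0)
    min_total_puffs: int = 10
    weighting: str = "session"  # or "puff"
    alpha: float = 0.05
    pes_alpha: float = 0.016
    seed: int = 0

    def __post_init__(self) -> None:
        lo, mid, hi = self.group_bins
        if not 0 <= lo < mid < hi <= 100:
            raise ConfigurationError(
                f"group_bins must be strictly increasing within [0, 100]: {self.group_bins}"
            )
        if self.evaluation_days < 1:
            raise ConfigurationError("evaluation_days must be >= 1")
        for name in ("alpha", "pes_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.percentile_method not in ("linear", "nearest"):
            raise ConfigurationError(f"unknown percentile_method {self.percentile_method!r}")
        if self.weighting not in ("session", "puff"):
            raise ConfigurationError(f"unknown weighting {self.weighting!r}")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["group_bins"] = list(self.group_bins)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "cleansing" in doc and isinstance(doc["cleansing"], dict):
            doc["cleansing"] = CleansingConfig(**doc["cleansing"])
        if "group_bins" in doc:
            doc["group_bins"] = tuple(doc["group_bins"])
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
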