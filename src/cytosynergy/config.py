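"""Pipeline configuration: thresholds, options, and file paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .interaction import ELIGIBILITY_MODES


@dataclass
class PipelineConfig:
    """Everything needed to run the full analysis end to end.

    Thresholds default to the study's DE rule (fold change > 1.5, adjusted
    p < 0.05) with Wald-test alpha 0.05 for the interaction cascade.
    """

    counts: str = "counts.tsv"
    metadata: str = "metadata.tsv"
    gene_sets: str | None = None
    pairs: str | None = None
    out_dir: str = "results"
    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    test_alpha: float = 0.05
    normalization: str = "median-of-ratios"
    pseudocount: float = 0.5
    eligibility: str = "ab_de"
    adjust_interaction_tests: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        for name in ("de_alpha", "test_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.normalization not in ("median-of-ratios", "total-count"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.eligibility not in ELIGIBILITY_MODES:
            raise ValueError(f"eligibility must be one of {ELIGIBILITY_MODES}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)
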