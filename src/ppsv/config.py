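"""Pipeline configuration: every tunable with its default value.

Defaults correspond to the published analysis settings; a YAML config
file overrides defaults and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    concordance_window: int = 200
    min_pass_ratio: float = 0.5
    min_gq: int = 20
    max_missing: float = 0.2
    rare_max_maf: float = 0.01
    common_min_maf: float = 0.05
    promoter_size: int = 1_000
    max_span: int = 1_000_000
    catalog_window: int = 200
    catalog_max_af: float = 0.01
    score_thresholds: dict = field(
        default_factory=lambda: {
            "strvctvre": 0.37,
            "cadd_sv": 10.0,
            "postre": 0.8,
            "phenosv": 0.5,
        }
    )
    min_tools: int = 2
    min_genesets: int = 2
    gg_cut: int = 3

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
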