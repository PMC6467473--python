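"""Pipeline configuration.

Defaults reproduce the printed analysis parameters: DE filter padj < 0.01
with fold change > 2, five temporal clusters, deconvolution onto the
EPI / post-E / post-L epiblast stages. Everything else (expression floor,
pseudocount, variable-gene thresholds, fuzzifier, restart count) is an
exposed operational choice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # input paths
    timecourse: str = ""
    sample_sheet: str = ""
    reference: str = ""
    reference_sheet: str = ""
    orthologs: str = ""
    gene_sets: str = ""
    out_dir: str = "runs/run"

    # expression handling
    min_fpkm: float = 1.0
    min_samples: int = 1
    pseudocount: float = 1.0

    # DE filter (printed thresholds)
    alpha: float = 0.01
    min_fc: float = 2.0

    # variable genes
    hvg_min_log2fpkm: float = 0.5
    hvg_min_excess: float = 1.0

    # clustering
    k: int | str = 5           # integer, or "auto" for elbow selection
    k_range: tuple[int, int] = (2, 9)
    m: float = 1.25
    n_starts: int = 10

    # correspondence / deconvolution
    scheme: str = "hpsc_vs_hpsc"
    stages: list[str] = field(default_factory=lambda: ["EPI", "post-E", "post-L"])

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.k, str) and self.k != "auto":
            raise ConfigError(f"k must be an integer or 'auto', got {self.k!r}")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_fc < 1:
            raise ConfigError("min_fc must be >= 1")
        lo, hi = self.k_range
        if hi - lo < 2:
            raise ConfigError("k_range must span at least 3 values")

    @classmethod
    def paper_defaults(cls, **overrides) -> "PipelineConfig":
        """The frozen default profile: padj < 0.01, fold change > 2, k = 5,
        stages EPI / post-E / post-L."""
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as e:
            raise ConfigError(f"config file not found: {path}") from e
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def content_hash(self) -> str:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    def require_inputs(self, *keys: str) -> None:
        for key in keys:
            path = getattr(self, key)
            if not path:
                raise ConfigError(f"config key {key!r} is required but empty")
            if not Path(path).exists():
                raise ConfigError(f"config key {key!r}: path does not exist: {path}")
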