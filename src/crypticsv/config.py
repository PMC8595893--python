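"""Run configuration: YAML-backed, strict about unknown keys.

The effective (fully resolved) configuration is echoed into every run
directory so outputs are reproducible from the artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .annotation import FilterConfig
from .splitread import ReadFilterParams


@dataclass
class RunConfig:
    seed: int = 1
    reference: str | None = None
    repeat_panel: str | None = None
    gene_model: str | None = None
    gene_modes: str | None = None
    panel_freqs: str | None = None
    cluster_tolerance: int = 2
    min_support: int = 5
    model_path: str | None = None
    score_threshold: float | None = None
    min_parent_clips: int = 2
    min_parent_depth: int = 10
    min_identity: float = 0.9
    min_hit_len: int = 20
    max_event_span: int = 10_000
    min_ins_len: int = 20
    log_level: str = "INFO"
    read_filters: ReadFilterParams = field(default_factory=ReadFilterParams)
    filter: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "read_filters" in data and isinstance(data["read_filters"], dict):
            sub = data["read_filters"]
            bad = set(sub) - {f.name for f in fields(ReadFilterParams)}
            if bad:
                raise ValueError(f"unknown read_filters keys: {sorted(bad)}")
            data["read_filters"] = ReadFilterParams(**sub)
        if "filter" in data and isinstance(data["filter"], dict):
            sub = dict(data["filter"])
            bad = set(sub) - {f.name for f in fields(FilterConfig)}
            if bad:
                raise ValueError(f"unknown filter keys: {sorted(bad)}")
            if sub.get("allowed_modes") is not None:
                sub["allowed_modes"] = tuple(sub["allowed_modes"])
            data["filter"] = FilterConfig(**sub)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["filter"].get("allowed_modes") is not None:
            d["filter"]["allowed_modes"] = list(d["filter"]["allowed_modes"])
        return d

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
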