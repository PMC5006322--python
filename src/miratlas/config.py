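"""Pipeline configuration: a single YAML-serializable parameter block.

All stage parameters (trimming profile, adapter, organ map, classifier
thresholds, seeds) live in one structure so a run is reproducible from
its config file and seed alone.  ``load(save(cfg)) == cfg``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .organs import DEFAULT_ORGAN_MAP


@dataclass
class PipelineConfig:
    trim_profile: str = "maastricht"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 16
    max_len: int = 35
    organ_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))
    expressed_threshold: float = 1.0
    quorum_frac: float = 0.8
    enriched_max_tissues: int = 5
    specific_pct: float = 90.0
    enriched_pct: float = 50.0
    nmf_rank: int = 14
    nmf_dominance: float = 0.5
    demir_alpha: float = 0.01
    demir_d0: float = 10.0
    demir_adjust: str | None = None
    low_count_threshold: float = 10.0
    seed: int = 0
    methods: list[str] = field(default_factory=lambda: ["rule", "percentage", "demir"])
    out_dir: str = "miratlas_out"

    def __post_init__(self) -> None:
        if not (0 < self.quorum_frac <= 1):
            raise ValueError("quorum_frac must be in (0, 1]")
        if not (0 < self.demir_alpha < 1):
            raise ValueError("demir_alpha must be in (0, 1)")
        if self.min_len < 1 or (self.max_len is not None and self.max_len < self.min_len):
            raise ValueError("invalid length window")
        for m in self.methods:
            if m not in ("rule", "nmf", "percentage", "demir"):
                raise ValueError(f"unknown classification method {m!r}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        """Stable short hash identifying this parameter set."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
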