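"""Run configuration: every analysis threshold in one validated object.

Defaults are the published thresholds of the analysis this pipeline
implements: a gene is expressed above RPKM 5, the non-mantle rule asks for
a twofold margin, per-date differential calls use p < 1e-3, persistence
asks for at least 6 of the 7 sampling dates, and term enrichment is
reported at p < 0.05.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .expression import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "shellseq_results"
    expressed_min_rpkm: float = 5.0
    fold_min: float = 2.0
    alpha: float = 1e-3
    k_min: int = 6
    enrich_alpha: float = 0.05
    null_mode: str = "permutation"
    n_permutations: int = 1000
    mantle_label: str = "Man"
    hemolymph_label: str = "Hem"
    # Input sections: each either points at files or configures a simulation.
    # atlas: {"scenario": {...}} or {"counts": path, "smp_genes": path}
    # timecourse: {"scenario": {...}} or {"counts": path, "manifest": path}
    # annotations: {"simulate": {...}} or {"path": path, "term_meta": path}
    atlas: dict = field(default_factory=lambda: {"scenario": {}})
    timecourse: dict = field(default_factory=lambda: {"scenario": {}})
    annotations: dict = field(default_factory=lambda: {"simulate": {}})

    def __post_init__(self) -> None:
        for name in ("expressed_min_rpkm", "fold_min", "alpha", "enrich_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not self.alpha < 1:
            raise ValidationError("alpha must be < 1")
        if self.k_min < 0:
            raise ValidationError("k_min must be non-negative")
        if self.null_mode not in ("binomial", "permutation"):
            raise ValidationError(f"unknown null_mode {self.null_mode!r}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
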