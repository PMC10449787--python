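"""Pipeline configuration: every tunable with a published default lives here.

The config file (YAML) provides defaults; command-line flags only override.
A snapshot of the effective config is embedded in every artifact the CLI
writes so any output is reproducible from its own metadata plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .homology import SearchThresholds


@dataclass
class PipelineConfig:
    # homology e-value ceilings (strict <)
    protein_evalue_max: float = 1e-5
    hmm_fullseq_evalue_max: float = 1e-10
    iterative_evalue_max: float = 1e-5
    # feature table
    correlation_threshold: float = 0.95
    # model
    split_ratio: float = 0.7
    cv_folds: int = 5
    min_features: int = 5
    n_trees: int = 1000
    seed: int = 0
    prediction_threshold: float = 0.80
    # benchmark grids
    fragment_sizes_bp: list = field(default_factory=lambda: [1_000, 2_500, 5_000, 7_500, 10_000, None])
    contamination_proportions: list = field(default_factory=lambda: [0.10, 0.25, 0.50, 0.75, 0.95])
    subsample_fractions: list = field(default_factory=lambda: [0.05, 0.25, 0.50, 0.75])
    # reference databases (optional; searches also run from precomputed files)
    reference_dbs: dict = field(default_factory=dict)

    def search_thresholds(self) -> SearchThresholds:
        return SearchThresholds(
            protein_evalue_max=self.protein_evalue_max,
            hmm_fullseq_evalue_max=self.hmm_fullseq_evalue_max,
            iterative_evalue_max=self.iterative_evalue_max,
        )

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.snapshot(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("protein_evalue_max", "hmm_fullseq_evalue_max", "iterative_evalue_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if not 0 <= self.prediction_threshold <= 1:
            raise ValueError("prediction_threshold must be in [0, 1]")
        if self.cv_folds < 2 or self.min_features < 1 or self.n_trees < 1:
            raise ValueError("cv_folds >= 2, min_features >= 1, n_trees >= 1 required")

    def embed_in(self, payload: dict) -> dict:
        return {**payload, "config": self.snapshot()}
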