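"""Flat key/value configuration with documented defaults.

One YAML file, no nesting.  CLI flags override file values; unknown keys
are an error so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class Config:
    #: master random seed for every stochastic stage
    seed: int = 1
    #: k-mer size for the built-in similarity scorer on unequal-length pairs
    kmer_size: int = 4
    #: nuisance-parameter grid step for Barnard's unconditional test
    barnard_grid_step: float = 0.001
    #: gamma shape for rate-heterogeneity-corrected protein distances
    gamma_shape: float = 0.77
    #: bootstrap replicates for split supports
    bootstrap_replicates: int = 1000
    #: bit-score cutoff applied to external similarity tables
    score_cutoff: float = 200.0
    #: score cutoff for the built-in scorer (no cutoff by default)
    min_score_builtin: float = 0.0
    #: output directory for pipeline stages
    out_dir: str = "ohnoscope_out"

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "Config":
        values: dict = {}
        if path is not None:
            raw = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(raw, dict):
                raise ValueError(f"{path}: config must be a flat mapping")
            values.update(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)
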