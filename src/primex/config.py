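"""Pipeline configuration: every tunable constant with its default.

Defaults encode the study's operating point: block substitutions are >= 6
mismatches in a 9 bp window; orthologs need >= 6 intact taxa; capture
targets get 100 bp flanks and merge when aligned pairs mismatch at < 3 bp;
gene coverage counts bases at depth >= 20, with < 20% coverage a failed
gene and > 80% a successful one; selection calls need FDR < 0.1 on both
trees; beta site-class models use 10 classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    mask_window: int = 9  # nt window for block-substitution masking
    mask_min_subs: int = 6  # mismatches within the window that trigger masking
    min_intact_species: int = 6  # taxa free of nonsense/frameshift required
    flank: int = 100  # bp added to each side of capture targets
    merge_max_mismatch: int = 2  # merge orthologous target pairs at < 3 mismatches
    depth_threshold: int = 20  # reads for a base to count as covered
    failed_below: float = 0.20  # gene coverage below this => failed gene
    success_above: float = 0.80  # gene coverage above this => successful gene
    fdr_cutoff: float = 0.1  # q-value threshold for both scan stages
    ncat: int = 10  # beta discretization classes (M7/M8)
    rng_seed: int = 0

    def __post_init__(self):
        for f in fields(self):
            if f.name == "rng_seed":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if self.failed_below >= self.success_above:
            raise ValueError("failed_below must be < success_above")
        if self.mask_window < self.mask_min_subs:
            raise ValueError("mask_window must be >= mask_min_subs")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a YAML (or key: value) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_CONFIG = PipelineConfig()
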