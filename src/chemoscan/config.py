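"""Pipeline configuration: every numeric threshold in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .sixframe import ScoringScheme
from .splicedmodel import SplicedParams


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-5
    flank_bp: int = 2000
    min_partial_aa: int = 190  # retention requires strictly more than this
    half_length_fraction: float = 0.5
    full_length_fraction: float = 0.9
    completeness_aa: dict = field(default_factory=lambda: {"OR": 120, "GR": 120, "IR": 190})
    tree_min_aa: dict = field(default_factory=lambda: {"OR": 230, "GR": 250})
    n_bootstrap: int = 200
    lrt_alpha: float = 0.01
    posterior_cutoff: float = 0.95
    df: int = 1
    max_intron: int = 15_000
    max_locus_span: int = 50_000
    family_margin_bits: float = 5.0
    completeness_identity: float = 0.9
    top_n_references: int = 5
    rng_seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    spliced: SplicedParams = field(default_factory=SplicedParams)

    def __post_init__(self):
        for name in ("evalue_cutoff", "flank_bp", "min_partial_aa", "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("half_length_fraction", "full_length_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        known.pop("scoring", None)
        known.pop("spliced", None)
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("scoring", None)
        spl = d.pop("spliced", None)
        if spl:
            d.update({f"spliced_{k}": v for k, v in spl.items()})
        return d
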