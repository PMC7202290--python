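"""Pipeline configuration.

All analysis thresholds live here as defaults; stage logic receives them as
arguments, never as hidden constants.  Config files are YAML with the exact
field names of :class:`PipelineConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # intron similarity ("higher than", exclusive)
    intron_min_coverage: float = 60.0
    intron_min_identity: float = 50.0
    # within-genome gene duplication ("at least", inclusive)
    duplication_min_identity: float = 50.0
    duplication_min_coverage: float = 50.0
    # NUMT rule ("at least 50% ... with E-value < 1e-10")
    numt_min_identity: float = 50.0
    numt_min_coverage: float = 50.0
    numt_max_evalue: float = 1e-10
    numt_nulls: int = 100
    # insertion-site conservation
    flank_length: int = 11
    flank_max_mismatch: int = 1
    # nucleotide alignment scoring
    dna_match: float = 2.0
    dna_mismatch: float = -3.0
    dna_gap_open: float = -5.0
    dna_gap_extend: float = -2.0
    prefilter: bool = True
    # misc
    rounding_fraction_decimals: int = 2
    rounding_share_decimals: int = 1
    seed: int = 0
    outdir: str = "mitocompare_out"

    def __post_init__(self) -> None:
        for name in ("intron_min_coverage", "intron_min_identity",
                     "duplication_min_identity", "duplication_min_coverage",
                     "numt_min_identity", "numt_min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"PipelineConfig.{name} must lie in [0, 100]")
        if self.flank_length < 1:
            raise ValueError("PipelineConfig.flank_length must be >= 1")

    @property
    def dna_scoring(self) -> dict:
        return {"match": self.dna_match, "mismatch": self.dna_mismatch,
                "gap_open": self.dna_gap_open, "gap_extend": self.dna_gap_extend}

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
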