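"""Run configuration shared by every pipeline stage.

Defaults reproduce the thresholds of the study design this package
implements: trio and eQTL significance at P < 1e-5, hotspots defined as
SNPs associated with at least 20 transcripts, sample and SNP call-rate
minima of 95%, Hardy-Weinberg alpha 0.001 and a 10% minor-allele-frequency
floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    trio_p_cutoff: float = 1e-5
    eqtl_p_cutoff: float = 1e-5
    hotspot_min_probes: int = 20
    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    hwe_alpha: float = 0.001
    maf_min: float = 0.10
    permutations: int = 0        # B; 0 means analytic Sobel p only
    seed: int = 0
    cis_window: int = 1_000_000  # bp, inclusive bound
    hotspot_p0: float | None = None   # None -> use eqtl_p_cutoff
    hwe_method: str = "exact"         # "exact" or "chisq"
    int_offset: str = "half"          # rank offset: "half" or "blom"
    emit_all: bool = False            # emit every trio, not just significant
    block_size: int = 64              # SNPs per scan block

    def __post_init__(self) -> None:
        for name in ("trio_p_cutoff", "eqtl_p_cutoff", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("sample_call_rate_min", "snp_call_rate_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min!r}")
        if self.hotspot_min_probes < 1:
            raise ValueError("hotspot_min_probes must be >= 1")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.cis_window < 0:
            raise ValueError("cis_window must be >= 0")
        if self.hotspot_p0 is not None and not (0.0 < self.hotspot_p0 < 1.0):
            raise ValueError("hotspot_p0 must be in (0, 1)")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")
        if self.int_offset not in ("half", "blom"):
            raise ValueError("int_offset must be 'half' or 'blom'")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must hold a key-value mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
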