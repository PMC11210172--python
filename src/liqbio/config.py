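"""Run configuration: every numeric constant of the assay in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Assay and pipeline parameters.

    Defaults are the validated operating point of the assay: 140 bp
    amplicon cap, 15 bp exact flanks, 500,000x coverage per amplicon per
    replicate, triplicate outlier exclusion at mean + 1 SD, LOD at the
    nine-control-point mean + 3 SD from three healthy donors, MRD
    positivity at 1e-4, and input minima of 15 ng (cfDNA) / 660 ng (gDNA)
    with a gDNA/cfDNA contamination ratio cap of 1.
    """

    max_len: int = 140
    min_flank: int = 15
    coverage: int = 500_000
    threshold: float = 1e-4
    sd_multiplier_triplicate: float = 1.0
    sd_multiplier_lod: float = 3.0
    n_control_donors: int = 3
    min_cfdna_ng: float = 15.0
    min_gdna_ng: float = 660.0
    max_gdna_ratio: float = 1.0
    seed: int = 0
    strict_controls: bool = True
    alt_error_rate: float = 1e-5
    per_base_error: float = 1e-3
    check_rc: bool = True

    def __post_init__(self):
        if self.max_len < 2 * self.min_flank + 1:
            raise ValueError("max_len too small for the flank requirement")
        for name in ("coverage", "n_control_donors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("threshold", "alt_error_rate", "per_base_error"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def with_overrides(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **clean)


def load_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides
    (flags beat file values; file values beat defaults)."""
    base: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base.update(loaded)
    base.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**base)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
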