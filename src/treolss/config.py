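"""Run configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .cohort import CANDIDATE_TIMES, LOQ_DEFAULT

__all__ = ["GroupSpec", "RunConfig", "stage_seed"]

#: The three dosing groups of the limited-sampling study.
DEFAULT_GROUPS = [
    {"label": "12g-1h", "dose_per_bsa": 12.0, "t_inf": 1.0, "n": 100},
    {"label": "12g-2h", "dose_per_bsa": 12.0, "t_inf": 2.0, "n": 100},
    {"label": "14g-2h", "dose_per_bsa": 14.0, "t_inf": 2.0, "n": 100},
]


def stage_seed(master_seed: int, *tags) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    ss = np.random.SeedSequence([int(master_seed), int(h)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class GroupSpec(BaseModel):
    label: str
    dose_per_bsa: float
    t_inf: float
    n: int = Field(100, ge=1)


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration."""

    master_seed: int = 1
    groups: list[GroupSpec] = Field(default_factory=lambda: [GroupSpec(**g) for g in DEFAULT_GROUPS])
    candidate_times: list[float] = Field(default_factory=lambda: list(CANDIDATE_TIMES))
    loq: float = LOQ_DEFAULT
    split_fraction: float = 0.5
    estimator: Literal["map", "conditional_mean"] = "map"
    output_dir: str = "results"

    @field_validator("split_fraction")
    @classmethod
    def _frac(cls, v):
        if not (0 < v < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self, **extra) -> dict:
        out = {"config": self.model_dump(), "config_hash": self.config_hash(),
               "master_seed": self.master_seed}
        out.update(extra)
        return out
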