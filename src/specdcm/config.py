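"""Run configuration for the pipeline CLI.

A single YAML file configures every stage; all randomness flows from one
root seed through named per-stage substreams, so reruns with the same
config are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig

__all__ = ["RunConfig", "stage_rng", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream of the root seed for one pipeline stage."""
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF,
                                   zlib.crc32(stage.encode()) & 0x7FFFFFFF])


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(root_seed, stage))


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "runs/demo"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_freqs: int = 32
    fmax: float = 0.1
    mar_order: int = 8
    space_nodes: int = 3
    space_rules: tuple[str, ...] = ("self", "connected")
    max_models: int | None = None
    bms_method: str = "random"
    bms_alpha0: float = 1.0
    bms_samples: int = 100_000
    n_perm: int = 500

    def __post_init__(self) -> None:
        if self.bms_method not in ("random", "fixed"):
            raise ValueError("bms_method must be 'random' or 'fixed'")
        for r in self.space_rules:
            if r not in ("self", "connected"):
                raise ValueError(f"unknown model-space rule {r!r}")
        # the cohort generator draws its stream from the root seed
        self.cohort.seed = int(np.random.default_rng(
            stage_seed(self.seed, "cohort")).integers(0, 2 ** 31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        cohort_raw = raw.pop("cohort", {})
        known = {f.name for f in fields(CohortConfig)}
        bad = set(cohort_raw) - known
        if bad:
            raise ValueError(f"unknown cohort options: {sorted(bad)}")
        if "age_range" in cohort_raw:
            cohort_raw["age_range"] = tuple(cohort_raw["age_range"])
        for key in ("cognition_weights", "cognition_age_slopes", "cognition_noise_sd"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        kwargs["cohort"] = CohortConfig(**cohort_raw)
        known_run = {f.name for f in fields(cls)}
        bad = set(raw) - known_run
        if bad:
            raise ValueError(f"unknown config options: {sorted(bad)}")
        if "space_rules" in raw:
            raw["space_rules"] = tuple(raw["space_rules"])
        kwargs.update(raw)
        return cls(**kwargs)

    @property
    def out(self) -> Path:
        return Path(self.outdir)
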