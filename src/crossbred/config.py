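"""Run configuration for the command-line workflow.

A flat YAML mapping, checked strictly: unknown keys are errors, and every
stochastic stage draws from a reproducible generator derived from the one
master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .breedspace import BreedSet

__all__ = ["RunConfig", "stage_rng", "stage_seed"]

# fixed stage indices so per-stage streams never collide or drift
_STAGES = {"freqs": 1, "founders": 2, "testset": 3, "alpha0": 4, "train": 5, "classify": 6}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    if stage not in _STAGES:
        raise KeyError(f"unknown pipeline stage {stage!r}")
    return np.random.SeedSequence([int(master_seed), _STAGES[stage]])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class RunConfig:
    """Configuration of a full simulate/train/classify/evaluate run."""

    breeds: list[str] = field(default_factory=lambda: ["D", "H", "L", "W"])
    breed_names: list[str] | None = None
    p: int = 2000
    fst: float = 0.15
    maf_min: float = 0.045
    admix_mean: float = 0.09
    n_per_breed: list[int] = field(default_factory=lambda: [200, 14, 200, 200])
    n_chrom: int = 18
    cm_per_mb: float = 1.0
    map_path: str | None = None
    m: int | None = None
    alpha0: float | str = "estimate"
    alpha0_sims: int = 1000
    prior: str = "flat"  # "flat" or a path to a (label, probability) CSV
    pi_unknown: float | None = None
    n_per_combo: int = 100
    filter_maf_min: float = 0.01
    filter_callrate_min: float = 0.9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat YAML mapping")
        allowed = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = sorted(set(raw) - allowed)
        if unknown:
            raise KeyError(f"unknown config key(s): {', '.join(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def breed_set(self) -> BreedSet:
        return BreedSet(tuple(self.breeds), None if self.breed_names is None else tuple(self.breed_names))

    def recombination_map(self):
        from .recomb import RecombinationMap, default_pig_like_map

        if self.map_path:
            return RecombinationMap.from_tsv(self.map_path)
        return default_pig_like_map(self.n_chrom, self.cm_per_mb)

    def validate(self) -> None:
        if len(self.n_per_breed) != len(self.breeds):
            raise ValueError("n_per_breed must give one count per breed")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if isinstance(self.alpha0, str) and self.alpha0 != "estimate":
            raise ValueError("alpha0 must be a positive number or 'estimate'")
        if not isinstance(self.alpha0, str) and self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
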