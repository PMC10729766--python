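"""Recombination maps: monotone correspondence between physical position
(bp) and genetic position (cM) per chromosome."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RecombinationMap", "default_pig_like_map"]

# Autosome physical lengths (Mb) loosely following the pig karyotype
# (18 autosomes, ~2.26 Gb); with the default 1 cM/Mb this gives a total
# genetic length of ~2264 cM, of the order of published pig linkage maps.
_DEFAULT_LENGTHS_MB = (
    274, 152, 133, 131, 105, 171, 122, 139, 139,
    69, 79, 61, 208, 142, 140, 80, 63, 56,
)


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-linear genetic map.

    For each chromosome: strictly increasing physical breakpoints
    ``pos_bp`` (starting at 0) and non-decreasing cumulative genetic
    positions ``cm`` (starting at 0).  Genetic <-> physical conversion is
    linear interpolation between breakpoints.
    """

    chrom_names: tuple[str, ...]
    pos_bp: tuple[np.ndarray, ...]
    cm: tuple[np.ndarray, ...]

    def __post_init__(self):
        if not (len(self.chrom_names) == len(self.pos_bp) == len(self.cm)):
            raise ValueError("per-chromosome fields must have equal length")
        for name, bp, cm in zip(self.chrom_names, self.pos_bp, self.cm):
            if len(bp) < 2 or len(bp) != len(cm):
                raise ValueError(f"chromosome {name}: need >= 2 (bp, cM) anchor points")
            if bp[0] != 0 or cm[0] != 0:
                raise ValueError(f"chromosome {name}: map must start at 0 bp / 0 cM")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {name}: bp anchors must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {name}: cM must be non-decreasing in bp")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_names)

    def length_bp(self, i: int) -> int:
        return int(self.pos_bp[i][-1])

    def length_cm(self, i: int) -> float:
        return float(self.cm[i][-1])

    @property
    def total_bp(self) -> int:
        return sum(self.length_bp(i) for i in range(self.n_chrom))

    @property
    def total_cm(self) -> float:
        return sum(self.length_cm(i) for i in range(self.n_chrom))

    def cm_to_bp(self, i: int, cm: np.ndarray) -> np.ndarray:
        return np.interp(cm, self.cm[i], self.pos_bp[i])

    def bp_to_cm(self, i: int, bp: np.ndarray) -> np.ndarray:
        return np.interp(bp, self.pos_bp[i], self.cm[i])

    @classmethod
    def from_tsv(cls, path) -> "RecombinationMap":
        """Read a 3-column TSV (chrom, pos_bp, cum_cM).  A (0, 0) anchor is
        prepended per chromosome when absent."""
        df = pd.read_csv(path, sep="\t", header=0)
        df.columns = [c.lower() for c in df.columns]
        names, bps, cms = [], [], []
        for chrom, grp in df.groupby(df.columns[0], sort=False):
            grp = grp.sort_values(grp.columns[1])
            bp = grp.iloc[:, 1].to_numpy(dtype=float)
            cm = grp.iloc[:, 2].to_numpy(dtype=float)
            if bp[0] != 0:
                bp = np.concatenate([[0.0], bp])
                cm = np.concatenate([[0.0], cm - cm[0] if cm[0] > 0 else cm])
            names.append(str(chrom))
            bps.append(bp)
            cms.append(cm)
        return cls(chrom_names=tuple(names), pos_bp=tuple(bps), cm=tuple(cms))

    @classmethod
    def uniform(cls, lengths_bp, cm_per_mb: float = 1.0, names=None) -> "RecombinationMap":
        """Uniform-rate map: constant ``cm_per_mb`` on every chromosome."""
        lengths_bp = [int(x) for x in lengths_bp]
        if names is None:
            names = tuple(str(i + 1) for i in range(len(lengths_bp)))
        bps = tuple(np.array([0.0, L]) for L in lengths_bp)
        cms = tuple(np.array([0.0, L / 1e6 * cm_per_mb]) for L in lengths_bp)
        return cls(chrom_names=tuple(names), pos_bp=bps, cm=cms)


def default_pig_like_map(n_chrom: int = 18, cm_per_mb: float = 1.0) -> RecombinationMap:
    """The package's default synthetic map: ``n_chrom`` autosomes with
    pig-like physical lengths at a uniform ``cm_per_mb`` rate."""
    if not 1 <= n_chrom <= len(_DEFAULT_LENGTHS_MB):
        raise ValueError(f"n_chrom must be in 1..{len(_DEFAULT_LENGTHS_MB)}")
    lengths = [mb * 1_000_000 for mb in _DEFAULT_LENGTHS_MB[:n_chrom]]
    return RecombinationMap.uniform(lengths, cm_per_mb=cm_per_mb)
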