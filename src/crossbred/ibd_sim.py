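"""Identity-by-descent simulation from purebred F0 grandparents to F2
crossbreds.

Meiosis follows a Haldane model: crossover counts per chromosome are
Poisson with mean equal to the genetic length in Morgans, crossover
positions are uniform on the cM scale (no interference) and mapped to bp
through the recombination map.  Two rounds of meiosis (F0 -> F1 -> F2)
yield an IBD pattern: a tiling of each F2 homolog into segments labelled
by the grandparent (1..4) and founder haplotype (1..2) they descend from.
Grandparents 1-2 are the maternal, 3-4 the paternal grandparents.

From the IBD pattern one obtains the realized inheritance proportions
``theta`` (fractions of the diploid genome, measured in physical bp,
descending from each grandparent/breed) and, by transferring founder
alleles along segments, simulated crossbred SNP genotypes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breedspace import BreedSet, N_GRANDPARENTS
from .genotype_io import CodedGenotypes, SnpMap
from .recomb import RecombinationMap

__all__ = [
    "IBDPattern",
    "Theta",
    "Alpha0",
    "simulate_gamete",
    "simulate_f2_ibd",
    "realized_theta",
    "synthesize_f2_genotypes",
    "simulate_testset",
    "estimate_alpha0",
    "alpha0_from_theta",
    "grandparent_at",
]

# a segment is (start_bp, end_bp, grandparent 1..4, founder haplotype 1..2),
# half-open [start, end); a homolog is a list of segments per chromosome.
Segment = tuple[int, int, int, int]


def _slice_segments(segs: list[Segment], a: int, b: int) -> list[Segment]:
    out = []
    for s, e, gp, hap in segs:
        lo, hi = max(s, a), min(e, b)
        if lo < hi:
            out.append((lo, hi, gp, hap))
    return out


def _merge_segments(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if out and out[-1][1] == seg[0] and out[-1][2:] == seg[2:]:
            out[-1] = (out[-1][0], seg[1], seg[2], seg[3])
        else:
            out.append(seg)
    return out


def simulate_gamete(
    rmap: RecombinationMap,
    parent: tuple[list[list[Segment]], list[list[Segment]]],
    rng: np.random.Generator,
) -> list[list[Segment]]:
    """Simulate one gamete from a parent given as a pair of homologs.

    Per chromosome the crossover count is Poisson(length in Morgans),
    positions are uniform on the cM scale, and the gamete alternates
    between the parent's homologs starting from a fair coin flip.  Segment
    annotations (grandparent, founder haplotype) are inherited from the
    chosen parental homolog.
    """
    gamete: list[list[Segment]] = []
    for i in range(rmap.n_chrom):
        L_bp = rmap.length_bp(i)
        L_cm = rmap.length_cm(i)
        n_xo = rng.poisson(L_cm / 100.0) if L_cm > 0 else 0
        if n_xo:
            xo_cm = rng.uniform(0.0, L_cm, size=n_xo)
            xo_bp = np.unique(np.round(rmap.cm_to_bp(i, np.sort(xo_cm))).astype(np.int64))
            xo_bp = xo_bp[(xo_bp > 0) & (xo_bp < L_bp)]
        else:
            xo_bp = np.empty(0, dtype=np.int64)
        cuts = np.concatenate([[0], xo_bp, [L_bp]]).astype(np.int64)
        start = int(rng.integers(2))
        segs: list[Segment] = []
        for k in range(len(cuts) - 1):
            src = parent[(start + k) % 2][i]
            segs.extend(_slice_segments(src, int(cuts[k]), int(cuts[k + 1])))
        gamete.append(_merge_segments(segs))
    return gamete


@dataclass(frozen=True)
class IBDPattern:
    """F2 IBD pattern: per chromosome, a maternal and a paternal homolog,
    each tiled by half-open grandparent-labelled segments.  The maternal
    homolog carries only grandparents {1, 2}, the paternal only {3, 4}."""

    maternal: list[list[Segment]]
    paternal: list[list[Segment]]

    def validate(self, rmap: RecombinationMap) -> None:
        for hom, allowed in ((self.maternal, {1, 2}), (self.paternal, {3, 4})):
            for i, segs in enumerate(hom):
                L = rmap.length_bp(i)
                if segs[0][0] != 0 or segs[-1][1] != L:
                    raise AssertionError("segments do not span the chromosome")
                for a, b in zip(segs, segs[1:]):
                    if a[1] != b[0]:
                        raise AssertionError("segments do not tile the chromosome")
                if any(s[2] not in allowed for s in segs):
                    raise AssertionError("homolog carries a grandparent from the wrong parental side")


def _founder_parent(rmap: RecombinationMap, gp: int):
    """An F0 individual: two homologs fully labelled (gp, hap)."""
    return tuple(
        [[(0, rmap.length_bp(i), gp, hap)] for i in range(rmap.n_chrom)] for hap in (1, 2)
    )


def simulate_f2_ibd(rmap: RecombinationMap, rng: np.random.Generator) -> IBDPattern:
    """Two-generation IBD chain: each F1 parent is formed from one gamete
    of each of its two F0 parents; the F2 receives one recombined gamete
    from each F1 parent."""
    f1_mother = (
        simulate_gamete(rmap, _founder_parent(rmap, 1), rng),
        simulate_gamete(rmap, _founder_parent(rmap, 2), rng),
    )
    f1_father = (
        simulate_gamete(rmap, _founder_parent(rmap, 3), rng),
        simulate_gamete(rmap, _founder_parent(rmap, 4), rng),
    )
    return IBDPattern(
        maternal=simulate_gamete(rmap, f1_mother, rng),
        paternal=simulate_gamete(rmap, f1_father, rng),
    )


def grandparent_at(segs: list[Segment], pos: int) -> int:
    """Grandparent index covering physical position ``pos`` on a homolog."""
    for s, e, gp, _ in segs:
        if s <= pos < e:
            return gp
    raise ValueError(f"position {pos} not covered by any segment")


@dataclass(frozen=True)
class Theta:
    """Realized inheritance proportions of one F2 individual, measured as
    summed physical segment length over the diploid autosome length."""

    by_grandparent: np.ndarray  # length 4, sums to 1; slots 1+2 = 3+4 = 0.5
    by_breed: np.ndarray  # length q, grandparent proportions pooled by breed


def realized_theta(
    ibd: IBDPattern, rmap: RecombinationMap, permutation_label: str, breeds: BreedSet
) -> Theta:
    """Genome fraction inherited from each grandparent and, via the
    permutation label assigning a breed to each grandparent slot, from
    each breed."""
    if len(permutation_label) != N_GRANDPARENTS:
        raise ValueError("permutation label must assign a breed to each of the 4 grandparents")
    lengths = np.zeros(N_GRANDPARENTS, dtype=np.int64)
    for hom in (ibd.maternal, ibd.paternal):
        for segs in hom:
            for s, e, gp, _ in segs:
                lengths[gp - 1] += e - s
    total = 2 * rmap.total_bp
    by_gp = lengths / total
    by_breed = np.zeros(breeds.q)
    for slot, code in enumerate(permutation_label):
        by_breed[breeds.index(code)] += by_gp[slot]
    return Theta(by_grandparent=by_gp, by_breed=by_breed)


def _snp_layout(snps: SnpMap, rmap: RecombinationMap):
    """Positions and global column offsets of SNPs per map chromosome.

    Requires the SnpMap to be grouped by chromosome in map order (the
    layout produced by the founder simulator)."""
    layout = []
    offset = 0
    chrom_arr = np.asarray(snps.chrom, dtype=str)
    for i, name in enumerate(rmap.chrom_names):
        mask = chrom_arr == str(name)
        idx = np.flatnonzero(mask)
        if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[0] + idx.size)):
            raise ValueError("SNPs must be grouped by chromosome in map order")
        pos = np.asarray(snps.pos_bp)[idx]
        if idx.size and pos.max() > rmap.length_bp(i):
            raise ValueError(f"SNP position beyond chromosome {name} length in the map")
        layout.append((i, int(idx[0]) if idx.size else offset, pos))
        offset += idx.size
    n_mapped = sum(len(pos) for _, _, pos in layout)
    if n_mapped != len(snps):
        raise ValueError("some SNPs lie on chromosomes absent from the recombination map")
    return layout


def _draw_founder_slots(pool, permutation_label: str, rng: np.random.Generator) -> dict[int, tuple[str, int]]:
    """Assign a founder individual to each grandparent slot, sampling
    without replacement within a breed so repeated breeds use distinct
    founders."""
    by_breed: dict[str, list[int]] = defaultdict(list)
    for slot, code in enumerate(permutation_label, start=1):
        by_breed[code].append(slot)
    slots: dict[int, tuple[str, int]] = {}
    for code, slot_list in by_breed.items():
        if code not in pool.haplotypes:
            raise KeyError(f"breed {code!r} not present in the founder pool")
        n_avail = pool.haplotypes[code].shape[0] // 2
        if n_avail < len(slot_list):
            raise ValueError(f"breed {code!r} has only {n_avail} founders for {len(slot_list)} slots")
        for slot, ix in zip(slot_list, rng.choice(n_avail, size=len(slot_list), replace=False)):
            slots[slot] = (code, int(ix))
    return slots


def synthesize_f2_genotypes(
    ibd: IBDPattern,
    pool,
    permutation_label: str,
    rng: np.random.Generator,
    rmap: RecombinationMap | None = None,
) -> np.ndarray:
    """Transfer founder alleles to an F2 individual along its IBD pattern.

    Four founders are drawn without replacement from the breed pools named
    by the permutation; each SNP's two alleles are copied from the founder
    haplotype covering its position.  Returns a length-p coded genotype row.
    """
    rmap = rmap if rmap is not None else pool.rmap
    layout = _snp_layout(pool.snps, rmap)
    slots = _draw_founder_slots(pool, permutation_label, rng)
    p = len(pool.snps)
    geno = np.zeros(p, dtype=np.int8)
    for hom in (ibd.maternal, ibd.paternal):
        for i, base, pos in layout:
            if pos.size == 0:
                continue
            for s, e, gp, hap in hom[i]:
                lo = int(np.searchsorted(pos, s, side="left"))
                hi = int(np.searchsorted(pos, e, side="left"))
                if hi > lo:
                    code, ix = slots[gp]
                    row = pool.haplotypes[code][2 * ix + (hap - 1)]
                    geno[base + lo : base + hi] += row[base + lo : base + hi]
    return geno


def simulate_testset(
    pool,
    combos,
    n_per_combo: int,
    breeds: BreedSet,
    rng: np.random.Generator,
    rmap: RecombinationMap | None = None,
) -> tuple[CodedGenotypes, pd.DataFrame]:
    """Simulate ``n_per_combo`` F2 individuals for every breed combination.

    The grandparent permutation is drawn uniformly among the distinct
    permutations of each combination.  Returns coded genotypes and a truth
    table (sample id, permutation, combination, delta and realized theta
    per breed).
    """
    rmap = rmap if rmap is not None else pool.rmap
    rows, truth = [], []
    sample_ids = []
    for combo in combos:
        for r in range(n_per_combo):
            perm = "".join(rng.permutation(list(combo.label)))
            ibd = simulate_f2_ibd(rmap, rng)
            geno = synthesize_f2_genotypes(ibd, pool, perm, rng, rmap=rmap)
            theta = realized_theta(ibd, rmap, perm, breeds)
            sid = f"{combo.label}_{r:04d}"
            sample_ids.append(sid)
            rows.append(geno)
            rec = {"sample_id": sid, "permutation": perm, "combination": combo.label}
            for j, code in enumerate(breeds.codes):
                rec[f"delta_{code}"] = combo.delta[j]
            for j, code in enumerate(breeds.codes):
                rec[f"theta_{code}"] = theta.by_breed[j]
            truth.append(rec)
    geno = CodedGenotypes(
        matrix=np.vstack(rows),
        snps=pool.snps,
        sample_ids=sample_ids,
        labels=[t["combination"] for t in truth],
    )
    return geno, pd.DataFrame(truth)


@dataclass(frozen=True)
class Alpha0:
    """Method-of-moments estimate of the Dirichlet concentration alpha0
    governing the spread of theta around its expectation delta."""

    value: float
    n_sims: int
    var_mean: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("alpha0 must be positive")


def alpha0_from_theta(thetas: np.ndarray) -> Alpha0:
    """Moment estimator from realized theta vectors at delta = quarters.

    With theta ~ Dirichlet(alpha0/4 * 1) the diagonal of V(theta) is
    3 / (16 (alpha0 + 1)); solving with the mean empirical diagonal
    variance V gives alpha0 = 3 / (16 V) - 1.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[0] < 2:
        raise ValueError("need at least two theta vectors")
    var_mean = float(np.mean(np.var(thetas, axis=0, ddof=1)))
    if var_mean <= 0:
        raise ValueError("degenerate theta samples: zero variance (map has no recombination variation?)")
    return Alpha0(value=3.0 / (16.0 * var_mean) - 1.0, n_sims=thetas.shape[0], var_mean=var_mean)


def estimate_alpha0(rmap: RecombinationMap, n_sims: int = 1000, seed=None) -> Alpha0:
    """Estimate alpha0 by IBD simulation with four distinct grandparent
    breeds (delta = quarters), the configuration under which the
    grandparent and breed proportions coincide."""
    if n_sims < 2:
        raise ValueError("n_sims must be at least 2")
    rng = np.random.default_rng(seed)
    breeds = BreedSet(("A", "B", "C", "D"))
    thetas = np.empty((n_sims, 4))
    for k in range(n_sims):
        ibd = simulate_f2_ibd(rmap, rng)
        thetas[k] = realized_theta(ibd, rmap, "ABCD", breeds).by_grandparent
    return alpha0_from_theta(thetas)
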