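"""Synthetic purebred founder populations.

Real purebred chip data are proprietary, so training material is emulated
in two layers:

* between breeds, per-SNP ancestral allele frequencies are drawn uniformly
  and per-breed frequencies diverge from them under the Balding-Nichols
  model, ``freq_b ~ Beta(f (1-Fst)/Fst, (1-f)(1-Fst)/Fst)``, whose single
  knob Fst controls breed differentiation;
* within breeds, each founder carries a small individual amount of
  residual admixture from the other breeds (total ~ Gamma with mean
  ``admix_mean``, split uniformly across sources).  This reproduces the
  genome-wide coherent within-breed variation of real purebred panels —
  lines are never perfectly sorted, and individual ancestry variation is
  the dominant structural axis of within-line spread on SNP chips.  It is
  what makes a crossbred's score deviation scale with the genome fraction
  inherited from each founder, the regime the mixture-covariance
  derivation assumes.  Set ``admix_mean=0`` for idealized, fully sorted
  breeds.

Given its personal frequencies, a founder's haplotype alleles are sampled
independently per SNP (no local LD) — classification here rests on
marginal breed structure, not on short-range haplotype structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breedspace import BreedSet
from .genotype_io import CodedGenotypes, SnpMap
from .recomb import RecombinationMap

__all__ = [
    "BreedFreqs",
    "FounderPool",
    "make_snp_map",
    "sample_breed_freqs",
    "sample_founders",
    "phase_genotypes",
]

_FREQ_EPS = 1e-6  # keep Beta draws strictly inside (0, 1)


@dataclass(frozen=True)
class BreedFreqs:
    """Per-breed minor-allele frequencies (q x p), the ancestral
    frequencies they diverged from, and the Fst used."""

    freqs: np.ndarray
    ancestral: np.ndarray
    fst: float
    breeds: BreedSet

    def __post_init__(self):
        f = np.asarray(self.freqs)
        if f.shape != (self.breeds.q, len(self.ancestral)):
            raise ValueError("freqs must be q x p")
        if np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("frequencies must lie strictly in (0, 1)")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")

    @property
    def p(self) -> int:
        return self.freqs.shape[1]


@dataclass(frozen=True)
class FounderPool:
    """Phased founder haplotypes per breed (2 n_b x p binary matrices),
    with the SNP map and recombination map they were simulated on."""

    haplotypes: dict[str, np.ndarray]
    snps: SnpMap
    breeds: BreedSet
    rmap: RecombinationMap
    sample_ids: dict[str, list[str]]

    def __post_init__(self):
        for code, hap in self.haplotypes.items():
            if hap.ndim != 2 or hap.shape[0] % 2 or hap.shape[1] != len(self.snps):
                raise ValueError(f"haplotype matrix for breed {code!r} has wrong shape")
            if not np.isin(hap, (0, 1)).all():
                raise ValueError("haplotypes must be binary")

    def n_founders(self, code: str) -> int:
        return self.haplotypes[code].shape[0] // 2

    def genotypes(self) -> CodedGenotypes:
        """All founders as one coded genotype matrix with breed labels."""
        mats, ids, labels = [], [], []
        for code in self.breeds.codes:
            hap = self.haplotypes[code]
            mats.append((hap[0::2] + hap[1::2]).astype(np.int8))
            ids.extend(self.sample_ids[code])
            labels.extend([code] * (hap.shape[0] // 2))
        return CodedGenotypes(matrix=np.vstack(mats), snps=self.snps, sample_ids=ids, labels=labels)


def make_snp_map(p: int, rmap: RecombinationMap) -> SnpMap:
    """Place ``p`` SNPs on the map's chromosomes, counts proportional to
    physical length and positions evenly spaced within each chromosome."""
    if p < 1:
        raise ValueError("p must be >= 1")
    lengths = np.array([rmap.length_bp(i) for i in range(rmap.n_chrom)], dtype=float)
    raw = p * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the chromosomes with largest fractional part
    for i in np.argsort(raw - counts)[::-1][: p - counts.sum()]:
        counts[i] += 1
    ids, chroms, poss = [], [], []
    for i, name in enumerate(rmap.chrom_names):
        n_c = counts[i]
        if n_c == 0:
            continue
        L = rmap.length_bp(i)
        pos = np.unique(((np.arange(n_c) + 0.5) / n_c * L).astype(np.int64))
        pos = np.clip(pos, 1, L - 1)
        for k, x in enumerate(pos):
            ids.append(f"snp_{name}_{x}")
        chroms.extend([name] * len(pos))
        poss.extend(pos.tolist())
    return SnpMap(
        ids=np.asarray(ids),
        chrom=np.asarray(chroms),
        pos_bp=np.asarray(poss, dtype=np.int64),
        counted_allele=np.asarray(["B"] * len(ids)),
        ref_major=np.asarray(["A"] * len(ids)),
    )


def sample_breed_freqs(
    p: int, breeds: BreedSet, fst: float = 0.15, maf_min: float = 0.045, seed=None
) -> BreedFreqs:
    """Draw ancestral frequencies uniform on [maf_min, 1 - maf_min] and
    per-breed frequencies from the Balding-Nichols Beta around them."""
    if not 0 < fst < 1:
        raise ValueError("fst must lie strictly in (0, 1)")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(maf_min, 1 - maf_min, size=p)
    scale = (1 - fst) / fst
    freqs = rng.beta(anc * scale, (1 - anc) * scale, size=(breeds.q, p))
    freqs = np.clip(freqs, _FREQ_EPS, 1 - _FREQ_EPS)
    return BreedFreqs(freqs=freqs, ancestral=anc, fst=fst, breeds=breeds)


#: Gamma shape of the per-founder total residual admixture; mean/shape
#: fixes the scale.  Shape 3 keeps individual totals right-skewed but
#: rarely extreme.
_ADMIX_SHAPE = 3.0


def sample_founders(
    freqs: BreedFreqs,
    n_per_breed,
    rmap: RecombinationMap,
    seed=None,
    snps: SnpMap | None = None,
    admix_mean: float = 0.09,
) -> FounderPool:
    """Sample phased founder haplotypes.

    ``n_per_breed`` follows canonical breed order and may be unbalanced
    (e.g. one breed with n = 14).  Each founder's personal allele
    frequencies are its breed's frequencies blended with a small,
    individual residual-admixture contribution from the other breeds
    (total ~ Gamma(3, admix_mean/3), shares Dirichlet-uniform); haplotype
    alleles are then drawn independently per SNP from the personal
    frequencies.  ``admix_mean=0`` gives idealized fully sorted breeds
    whose per-SNP expected genotype is exactly twice the breed frequency.
    """
    n_per_breed = list(n_per_breed)
    if len(n_per_breed) != freqs.breeds.q:
        raise ValueError("n_per_breed must give one count per breed")
    if not 0 <= admix_mean < 0.5:
        raise ValueError("admix_mean must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    snps = snps if snps is not None else make_snp_map(freqs.p, rmap)
    if len(snps) != freqs.p:
        raise ValueError("SNP map length does not match frequency matrix")
    q = freqs.breeds.q
    haplotypes, sample_ids = {}, {}
    for j, code in enumerate(freqs.breeds.codes):
        n_b = int(n_per_breed[j])
        if admix_mean > 0 and q > 1:
            total = rng.gamma(_ADMIX_SHAPE, admix_mean / _ADMIX_SHAPE, size=n_b)
            total = np.minimum(total, 0.9)  # guard pathological tail draws
            shares = rng.dirichlet(np.ones(q - 1), size=n_b)
            a = np.zeros((n_b, q))
            a[:, [k for k in range(q) if k != j]] = shares * total[:, None]
            pi = (1.0 - total)[:, None] * freqs.freqs[j] + a @ freqs.freqs
            pi = np.clip(pi, _FREQ_EPS, 1 - _FREQ_EPS)
            hap = (rng.random((2 * n_b, freqs.p)) < np.repeat(pi, 2, axis=0)).astype(np.int8)
        else:
            hap = (rng.random((2 * n_b, freqs.p)) < freqs.freqs[j]).astype(np.int8)
        haplotypes[code] = hap
        sample_ids[code] = [f"{code}{k:05d}" for k in range(n_b)]
    return FounderPool(haplotypes=haplotypes, snps=snps, breeds=freqs.breeds, rmap=rmap, sample_ids=sample_ids)


def phase_genotypes(geno: CodedGenotypes, seed=None) -> np.ndarray:
    """Random phasing of unphased 0/1/2 genotypes into a 2n x p haplotype
    matrix: heterozygous alleles are assigned to the two homologs
    uniformly at random, once per individual per SNP."""
    rng = np.random.default_rng(seed)
    n, p = geno.matrix.shape
    hap = np.zeros((2 * n, p), dtype=np.int8)
    g = geno.matrix
    hap[0::2] = (g == 2).astype(np.int8)
    hap[1::2] = (g == 2).astype(np.int8)
    het = g == 1
    coin = rng.integers(2, size=(n, p)).astype(np.int8)
    hap[0::2][het] = coin[het]
    hap[1::2][het] = (1 - coin)[het]
    return hap
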