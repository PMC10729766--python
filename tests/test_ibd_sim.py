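"""IBD recombination simulation: segment-tiling invariants, Poisson/Haldane
crossover statistics, inheritance-proportion conservation, allele transfer
and the alpha0 moment estimator."""

import numpy as np
import pytest

import crossbred as cb
from crossbred.founder_sim import make_snp_map
from crossbred.ibd_sim import _founder_parent, grandparent_at
from crossbred.recomb import RecombinationMap


@pytest.fixture(scope="module")
def one_chrom_100cm():
    return RecombinationMap.uniform([100_000_000], cm_per_mb=1.0)


def test_zero_cm_chromosome_passes_intact():
    rmap = RecombinationMap.uniform([10_000_000], cm_per_mb=0.0)
    rng = np.random.default_rng(0)
    parent = _founder_parent(rmap, 1)
    for _ in range(20):
        gam = cb.simulate_gamete(rmap, parent, rng)
        assert len(gam[0]) == 1  # whole homolog, no crossover ever
        assert gam[0][0][:2] == (0, 10_000_000)


def test_poisson_crossover_count(one_chrom_100cm):
    """A 100 cM chromosome sees on average one crossover per meiosis."""
    rng = np.random.default_rng(1)
    parent = _founder_parent(one_chrom_100cm, 1)  # homolog labels hap 1 vs 2
    counts = []
    for _ in range(10_000):
        gam = cb.simulate_gamete(one_chrom_100cm, parent, rng)
        counts.append(len(gam[0]) - 1)  # each crossover starts a new segment
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - 1.0) < 4 * se


def test_haldane_recombination_fraction(one_chrom_100cm):
    """Loci 50 cM apart recombine with frequency (1 - e^-1)/2 = 0.316."""
    rng = np.random.default_rng(2)
    parent = _founder_parent(one_chrom_100cm, 1)
    a, b = 25_000_000, 75_000_000  # 50 cM apart on the uniform map
    rec = 0
    n = 20_000
    for _ in range(n):
        gam = cb.simulate_gamete(one_chrom_100cm, parent, rng)[0]
        ha = next(h for s, e, g, h in gam if s <= a < e)
        hb = next(h for s, e, g, h in gam if s <= b < e)
        rec += ha != hb
    expect = 0.5 * (1 - np.exp(-1.0))
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(rec / n - expect) < 4 * se


def test_ibd_pattern_invariants(rmap_small):
    rng = np.random.default_rng(3)
    for _ in range(50):
        ibd = cb.simulate_f2_ibd(rmap_small, rng)
        ibd.validate(rmap_small)  # tiling, spans, parental-side grandparents


def test_theta_conservation_and_expectation(rmap_small, breeds4):
    rng = np.random.default_rng(4)
    thetas = []
    for _ in range(1000):
        ibd = cb.simulate_f2_ibd(rmap_small, rng)
        th = cb.realized_theta(ibd, rmap_small, "DHLW", breeds4)
        assert abs(th.by_grandparent.sum() - 1) < 1e-12
        assert th.by_grandparent[0] + th.by_grandparent[1] == 0.5  # exact halves
        assert th.by_grandparent[2] + th.by_grandparent[3] == 0.5
        thetas.append(th.by_breed)
    thetas = np.asarray(thetas)
    se = thetas.std(axis=0) / np.sqrt(len(thetas))
    assert np.all(np.abs(thetas.mean(axis=0) - 0.25) < 4 * se)


def test_realized_theta_labels(rmap_small, breeds4):
    rng = np.random.default_rng(5)
    ibd = cb.simulate_f2_ibd(rmap_small, rng)
    th = cb.realized_theta(ibd, rmap_small, "LLWW", breeds4)
    assert th.by_breed[breeds4.index("L")] == 0.5  # both maternal grandparents L
    th = cb.realized_theta(ibd, rmap_small, "DDDD", breeds4)
    np.testing.assert_array_equal(th.by_breed, [1, 0, 0, 0])


class TestAlleleTransfer:
    def _pool(self, fill_by_breed, rmap, p=60):
        breeds = cb.BreedSet(tuple(fill_by_breed))
        snps = make_snp_map(p, rmap)
        haplotypes = {
            code: np.full((8, p), fill, dtype=np.int8)
            for code, fill in fill_by_breed.items()
        }
        ids = {code: [f"{code}{i}" for i in range(4)] for code in fill_by_breed}
        return cb.FounderPool(haplotypes=haplotypes, snps=snps, breeds=breeds,
                              rmap=rmap, sample_ids=ids), breeds

    def test_forced_heterozygote(self, rmap_small):
        pool, breeds = self._pool({"A": 0, "B": 1}, rmap_small)
        rng = np.random.default_rng(6)
        ibd = cb.simulate_f2_ibd(rmap_small, rng)
        geno = cb.synthesize_f2_genotypes(ibd, pool, "AABB", rng)
        assert np.all(geno == 1)  # one all-0 and one all-1 homolog everywhere

    def test_purebred_equals_founders(self, rmap_small):
        pool, breeds = self._pool({"A": 1, "B": 0}, rmap_small)
        rng = np.random.default_rng(7)
        ibd = cb.simulate_f2_ibd(rmap_small, rng)
        geno = cb.synthesize_f2_genotypes(ibd, pool, "AAAA", rng)
        assert np.all(geno == 2)

    def test_mixture_mean_matches_frequencies(self, breeds4, rmap_small):
        """Mean coded value of an F2 from breeds A and B approaches
        freq_A + freq_B per SNP."""
        freqs = cb.sample_breed_freqs(60, breeds4, 0.3, seed=8)
        pool = cb.sample_founders(freqs, [40, 40, 40, 40], rmap_small, seed=9,
                                  admix_mean=0.0)
        rng = np.random.default_rng(10)
        acc = np.zeros(60)
        n = 400
        for _ in range(n):
            ibd = cb.simulate_f2_ibd(rmap_small, rng)
            acc += cb.synthesize_f2_genotypes(ibd, pool, "DDHH", rng)
        fa = freqs.freqs[breeds4.index("D")]
        fb = freqs.freqs[breeds4.index("H")]
        expect = fa + fb
        se = np.sqrt(fa * (1 - fa) + fb * (1 - fb)) / np.sqrt(n)
        assert np.mean(np.abs(acc / n - expect) < 4 * se + 0.05) > 0.95


def test_simulate_testset_shapes_and_truth(small_testset, breeds4):
    geno, truth = small_testset
    assert len(truth) == 35 * 4 and geno.n == 140
    for _, row in truth.sample(10, random_state=0).iterrows():
        assert "".join(sorted(row["permutation"])) == row["combination"]
        delta = np.array([row[f"delta_{c}"] for c in breeds4.codes])
        np.testing.assert_allclose(delta, cb.delta_from_label(row["combination"], breeds4))
        theta = np.array([row[f"theta_{c}"] for c in breeds4.codes])
        assert abs(theta.sum() - 1) < 1e-12


class TestAlpha0:
    def test_recovery_from_dirichlet_draws(self):
        """The moment formula inverts Dirichlet(alpha0/4) sampling."""
        rng = np.random.default_rng(11)
        thetas = rng.dirichlet(np.full(4, 50.0 / 4), size=50_000)
        est = cb.alpha0_from_theta(thetas)
        assert abs(est.value - 50.0) / 50.0 < 0.10

    def test_quarters_variance_arithmetic(self):
        # diagonal of V(theta) at quarters: 3 / (16 (alpha0 + 1))
        v = cb.dirichlet_variance(np.full(4, 0.25), 73.58)
        np.testing.assert_allclose(np.diag(v), 3 / (16 * 74.58), rtol=1e-12)
        assert round(float(v[0, 0]), 6) == 0.002514

    def test_more_recombination_raises_alpha0(self):
        lo = cb.estimate_alpha0(cb.default_pig_like_map(6, cm_per_mb=1.0), 300, seed=12)
        hi = cb.estimate_alpha0(cb.default_pig_like_map(6, cm_per_mb=6.0), 300, seed=12)
        assert hi.value > lo.value

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            cb.alpha0_from_theta(np.full((1, 4), 0.25))
        with pytest.raises(ValueError, match="zero variance"):
            cb.alpha0_from_theta(np.full((10, 4), 0.25))


def test_grandparent_lookup(rmap_small):
    rng = np.random.default_rng(13)
    ibd = cb.simulate_f2_ibd(rmap_small, rng)
    segs = ibd.maternal[0]
    assert grandparent_at(segs, 0) in (1, 2)
    with pytest.raises(ValueError):
        grandparent_at(segs, rmap_small.length_bp(0) + 5)
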