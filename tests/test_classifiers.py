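"""Classifier core: purebred moments, Dirichlet variance, the derived
crossbred moments (with a Monte-Carlo law-of-total-variance oracle), the
unknown class, priors, posteriors and the PLSR baseline."""

import numpy as np
import pytest
from scipy.linalg import cholesky

import crossbred as cb
from crossbred.classifiers import (
    PBParams,
    TRUNC_EPS,
    build_prior,
    derive_cb_params,
    log_densities,
    soft_from_posterior,
)


def _toy_pb(m=3, q=4, spread=1.0, noise=0.05, seed=0):
    """Well-separated synthetic purebred moments: simplex-corner centroids
    at scale `spread`, within-breed SD `noise`."""
    rng = np.random.default_rng(seed)
    mu = np.zeros((q, m))
    if m == q - 1:
        mu[1:, :] = np.eye(q - 1) * spread  # simplex corners
    else:
        mu = rng.normal(scale=spread, size=(q, m))
    sigma = np.stack([
        np.diag(noise**2 * (1 + 0.3 * rng.random(m))) for _ in range(q)
    ])
    return PBParams(mu=mu, sigma=sigma, n=np.full(q, 100),
                    breeds=cb.BreedSet(tuple("ABCD"[:q])))


class TestPBParams:
    def test_hand_computed_moments(self):
        scores = np.array([[0.0, 0], [2, 0], [1, 3], [1, 1],
                           [10, 10], [12, 10], [11, 13], [11, 11]])
        labels = ["A"] * 4 + ["B"] * 4
        pb = cb.estimate_pb_params(scores, labels, cb.BreedSet(("A", "B")))
        np.testing.assert_allclose(pb.mu[0], [1, 1])
        np.testing.assert_allclose(pb.mu[1], [11, 11])
        np.testing.assert_allclose(pb.sigma[0], np.cov(scores[:4].T, ddof=1))
        assert list(pb.n) == [4, 4]

    def test_point_mass_rejected(self):
        scores = np.vstack([np.tile([1.0, 2.0], (4, 1)), np.random.default_rng(0).normal(size=(4, 2))])
        labels = ["A"] * 4 + ["B"] * 4
        with pytest.raises(ValueError, match="'A'"):
            cb.estimate_pb_params(scores, labels, cb.BreedSet(("A", "B")))

    def test_small_class_still_positive_definite(self, fitted_small):
        # the n=14 breed (as for Hampshire) must yield a valid covariance
        j = fitted_small.model.breeds.index("H")
        assert fitted_small.pb_params.n[j] == 14
        cholesky(fitted_small.pb_params.sigma[j], lower=True)

    def test_too_few_individuals_rejected(self):
        scores = np.random.default_rng(1).normal(size=(6, 3))
        labels = ["A"] * 3 + ["B"] * 3  # need m + 2 = 5 per breed
        with pytest.raises(ValueError, match="at least"):
            cb.estimate_pb_params(scores, labels, cb.BreedSet(("A", "B")))


class TestDirichletVariance:
    def test_purebred_delta_gives_zero(self):
        v = cb.dirichlet_variance(np.array([0, 1.0, 0, 0]), 73.58)
        np.testing.assert_array_equal(v, 0.0)

    def test_rows_sum_to_zero(self):
        v = cb.dirichlet_variance(np.array([0.5, 0.25, 0.25]), 10.0)
        np.testing.assert_allclose(v.sum(axis=1), 0.0, atol=1e-15)

    def test_matches_sampled_covariance(self):
        alpha0, delta = 30.0, np.array([0.5, 0.25, 0.25, 0.0])
        rng = np.random.default_rng(2)
        draws = rng.dirichlet(np.maximum(alpha0 * delta, 1e-12)[:3], size=200_000)
        emp = np.cov(draws, rowvar=False, ddof=1)
        v = cb.dirichlet_variance(delta, alpha0)[:3, :3]
        assert np.max(np.abs(emp - v)) < 0.03 * np.max(np.abs(v))

    def test_alpha0_positive_required(self):
        with pytest.raises(ValueError):
            cb.dirichlet_variance(np.array([0.5, 0.5]), 0.0)


class TestCBMoments:
    def test_purebred_reduction_exact(self):
        pb = _toy_pb()
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1.0
            cbp = cb.cb_moments(e, pb, alpha0=73.58)
            np.testing.assert_array_equal(cbp.mean, pb.mu[j])
            np.testing.assert_array_equal(cbp.cov, pb.sigma[j])

    def test_monte_carlo_law_of_total_variance(self):
        """Sample theta ~ Dirichlet(alpha0 delta), then t ~ N(sum theta_j
        mu_j, sum theta_j^2 Sigma_j); the derived moments must match."""
        pb = _toy_pb(m=2, q=3, spread=2.0, noise=0.3, seed=3)
        alpha0 = 40.0
        delta = np.array([0.5, 0.25, 0.25])
        cbp = cb.cb_moments(delta, pb, alpha0)
        rng = np.random.default_rng(4)
        n = 300_000
        theta = rng.dirichlet(alpha0 * delta, size=n)
        mean = theta @ pb.mu
        chol = [cholesky(pb.sigma[j], lower=True) for j in range(3)]
        t = mean.copy()
        for j in range(3):
            z = rng.normal(size=(n, 2))
            t += theta[:, [j]] * (z @ chol[j].T)
        scale = np.mean(np.diag(cbp.cov))
        np.testing.assert_allclose(t.mean(axis=0), cbp.mean, atol=4 * np.sqrt(scale / n) * 3)
        assert np.max(np.abs(np.cov(t, rowvar=False, ddof=1) - cbp.cov)) < 0.05 * scale

    def test_generalized_variance_ordering(self):
        """On well-separated purebred moments the log generalized variance
        grows with the number of breeds in the combination:
        XXXX < XXYY < XXXY < XXYL < XYLK."""
        pb = _toy_pb(m=3, q=4, spread=1.0, noise=0.02)
        combos = cb.enumerate_combinations(pb.breeds)
        cbs = derive_cb_params(combos, pb, alpha0=73.58)
        table = cb.generalized_variance_table(cbs)
        means = dict(zip(table["pattern"], table["theoretical_mean"]))
        assert means["XXXX"] < means["XXYY"] < means["XXXY"] < means["XXYL"] < means["XYLK"]

    def test_permutation_symmetry(self):
        """Relabelling the breeds permutes nothing observable: moments of a
        permuted delta against permuted purebred moments are unchanged."""
        pb = _toy_pb(m=2, q=4, spread=1.5, noise=0.2, seed=5)
        delta = np.array([0.5, 0.25, 0.25, 0.0])
        perm = np.array([2, 0, 3, 1])
        # pb_perm[k] holds the moments of original breed perm[k], and
        # delta_perm[k] = delta[perm[k]], so the mixture is identical
        pb_perm = PBParams(mu=pb.mu[perm], sigma=pb.sigma[perm], n=pb.n[perm], breeds=pb.breeds)
        a = cb.cb_moments(delta, pb, 50.0)
        c = cb.cb_moments(delta[perm], pb_perm, 50.0)
        np.testing.assert_allclose(a.mean, c.mean, atol=1e-12)
        np.testing.assert_allclose(a.cov, c.cov, atol=1e-12)


class TestUnknownClass:
    def test_one_dimensional_range(self):
        u = cb.build_unknown(np.array([[0.0], [10.0], [4.0]]))
        assert u.log_density == pytest.approx(-np.log(10))

    def test_box_volume(self):
        scores = np.array([[0, 0, 0], [2.0, 5.0, 10.0]])
        u = cb.build_unknown(scores)
        assert np.exp(u.log_density) == pytest.approx(1 / 100)

    def test_doubling_ranges_halves_density_per_dimension(self):
        scores = np.random.default_rng(6).normal(size=(50, 3))
        u1 = cb.build_unknown(scores)
        u2 = cb.build_unknown(scores * 2)
        assert u2.log_density == pytest.approx(u1.log_density - 3 * np.log(2))

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            cb.build_unknown(np.array([[1.0, 2.0], [1.0, 3.0]]))


class TestPrior:
    def test_flat(self):
        combos = cb.enumerate_combinations(cb.BreedSet(tuple("ABCD")))
        pi = build_prior(combos, "flat")
        assert pi.shape == (36,)
        np.testing.assert_allclose(pi, 1 / 36)

    def test_informative_leftover_goes_to_unknown(self):
        combos = cb.enumerate_combinations(cb.BreedSet(tuple("ABCD")))
        pi = build_prior(combos, "informative", table={"AADD": 0.6, "AABB": 0.3})
        labels = [c.label for c in combos]
        assert pi[labels.index("AADD")] == pytest.approx(0.6)
        assert pi[-1] == pytest.approx(0.1)
        assert pi.sum() == pytest.approx(1.0)

    def test_pi_unknown_override_rescales(self):
        combos = cb.enumerate_combinations(cb.BreedSet(tuple("ABCD")))
        pi = build_prior(combos, "informative", table={"AADD": 0.5, "AABB": 0.5}, pi_unknown=0.2)
        assert pi[-1] == pytest.approx(0.2)
        assert pi[:-1].sum() == pytest.approx(0.8)

    def test_unknown_label_rejected(self):
        combos = cb.enumerate_combinations(cb.BreedSet(tuple("ABCD")))
        with pytest.raises(KeyError):
            build_prior(combos, "informative", table={"ZZZZ": 1.0})


@pytest.fixture(scope="module")
def machinery():
    pb = _toy_pb(m=3, q=4, spread=1.0, noise=0.03, seed=7)
    combos = cb.enumerate_combinations(pb.breeds)
    cbs = derive_cb_params(combos, pb, 73.58)
    scores = np.vstack([pb.mu + 0.2, pb.mu - 0.2])  # synthetic training box
    unknown = cb.build_unknown(scores)
    prior = build_prior(combos, "flat")
    return pb, combos, cbs, unknown, prior


class TestPosterior:
    def test_purebred_center_dominates(self, machinery):
        pb, combos, cbs, unknown, prior = machinery
        labels = [c.label for c in combos]
        for j, code in enumerate(pb.breeds.codes):
            post = cb.posterior(pb.mu[j], cbs, unknown, prior)[0]
            assert post[labels.index(code * 4)] > 0.99

    def test_degenerate_prior_forces_class(self, machinery):
        pb, combos, cbs, unknown, _ = machinery
        pi = np.zeros(len(combos) + 1)
        k = 17
        pi[k] = 1.0
        t = np.random.default_rng(8).normal(size=(5, 3))
        post = cb.posterior(t, cbs, unknown, pi)
        assert np.all(post.argmax(axis=1) == k)

    def test_rows_sum_to_one_even_for_remote_points(self, machinery):
        pb, combos, cbs, unknown, prior = machinery
        t = np.random.default_rng(9).normal(size=(20, 3)) * 50  # far outside
        post = cb.posterior(t, cbs, unknown, prior)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.isfinite(post))  # log-space: no underflow to NaN

    def test_nan_scores_rejected(self, machinery):
        pb, combos, cbs, unknown, prior = machinery
        with pytest.raises(ValueError, match="NaN"):
            cb.posterior(np.array([np.nan, 0, 0]), cbs, unknown, prior)

    def test_soft_delta_sums_to_one_minus_p_unknown(self, machinery):
        pb, combos, cbs, unknown, prior = machinery
        t = np.random.default_rng(10).normal(size=(10, 3))
        post = cb.posterior(t, cbs, unknown, prior)
        soft = soft_from_posterior(post, cbs)
        np.testing.assert_allclose(soft.sum(axis=1), 1 - post[:, -1], atol=1e-12)


class TestPLSRBaseline:
    def test_truncation_rule(self, fitted_small):
        raw = np.array([[-0.02, 0.5, 0.52, 0.0]])
        trunc = np.clip(raw, TRUNC_EPS, 1 - TRUNC_EPS)
        assert trunc[0, 0] == TRUNC_EPS and trunc[0, 3] == TRUNC_EPS

    def test_training_purebreds_recovered(self, small_pool, breeds4):
        geno = small_pool.genotypes()
        res = cb.BreedPLSR(geno, geno.labels, breeds4).fit()
        raw = res.soft_predict(geno, truncated=False)
        np.testing.assert_allclose(raw.sum(axis=1), 1.0, atol=1e-8)
        for i in (0, 70, 100):
            j = breeds4.index(geno.labels[i])
            assert raw[i, j] > 0.9


@pytest.fixture(scope="module")
def combos4(breeds4):
    return cb.enumerate_combinations(breeds4)


class TestHardFromSoft:
    def test_zero_loss_at_truth(self, combos4):
        soft = np.array([0.5, 0.0, 0.25, 0.25])
        assert cb.hard_from_soft(soft, combos4, "square") == ["DDLW"]
        assert cb.hard_from_soft(np.clip(soft, 1e-10, 1), combos4, "kl") == ["DDLW"]

    def test_uniform_goes_to_four_breed_combination(self, combos4):
        u = np.full(4, 0.25)
        assert cb.hard_from_soft(u, combos4, "kl") == ["DHLW"]
        assert cb.hard_from_soft(u, combos4, "square") == ["DHLW"]

    def test_square_and_kl_can_disagree(self, combos4):
        """The two discriminant rules differ on boundary points; document
        one found by random search over the simplex."""
        rng = np.random.default_rng(0)
        disagreements = 0
        for _ in range(2000):
            s = np.clip(rng.dirichlet(np.ones(4) * 0.8), 1e-10, 1)
            k = cb.hard_from_soft(s, combos4, "kl")[0]
            q = cb.hard_from_soft(s, combos4, "square")[0]
            if k != q:
                disagreements += 1
                # verify each rule's own loss prefers its own answer
                dk = cb.delta_from_label(k, cb.BreedSet(("D", "H", "L", "W")))
                dq = cb.delta_from_label(q, cb.BreedSet(("D", "H", "L", "W")))
                assert cb.kl_divergence(dk, s) <= cb.kl_divergence(dq, s)
                assert cb.square_loss(dq, s) <= cb.square_loss(dk, s)
        assert disagreements > 0


def test_unknown_calls_monotone_in_prior(fitted_small, small_testset):
    """Raising pi_unknown never decreases the number of hard 'unknown'
    calls on a fixed test set."""
    geno, _ = small_testset
    scores = fitted_small.transform(geno)
    counts = []
    for pi_u in (0.001, 0.01, 1 / 36, 0.1, 0.3, 0.6, 0.9):
        prior = build_prior(fitted_small.combos, "flat", pi_unknown=pi_u)
        post = cb.posterior(scores, fitted_small.cb_params, fitted_small.unknown, prior)
        counts.append(int((post.argmax(axis=1) == len(fitted_small.combos)).sum()))
    assert counts == sorted(counts)


def test_log_densities_shape(fitted_small):
    t = fitted_small.pls.scores[:5]
    ld = log_densities(t, fitted_small.cb_params, fitted_small.unknown)
    assert ld.shape == (5, 36)
    assert np.all(ld[:, -1] == fitted_small.unknown.log_density)
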