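# Methods

`crossbred` classifies the breed combination of a crossbred (F2) animal —
the multiset of its four purebred grandparents' breeds — from SNP
genotypes, training on purebred animals only. This note documents the
model, the simulation machinery used to generate test data, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Notation

With `q` breeds there are `q^4` ordered grandparent assignments
(permutations) and `C(q+3, 4)` unordered combinations (35 for q = 4, 70
for q = 5). Each combination is summarised by `Δ`, the length-`q` vector
of grandparent breed proportions (entries are quarters, summing to 1).
The realized genome fraction inherited from each breed, `θ`, is random
around `Δ` because of recombination. A soft prediction `Δ̂` is any
proportion vector; a hard prediction is a combination label.

## The classifier (PLS-QDA)

1. **Score space.** Multivariate PLS2 is fitted to the purebred training
   matrix X (n × p, counts of the training-minor allele, centered, not
   scaled) against the one-hot breed indicator Y (n × q), with
   `m = q − 1` components — enough to give each breed its own node point,
   and the reason PLS rather than PCA is used: with a severely
   unbalanced design (one breed with n = 14 here), PCA's leading axes
   follow within-breed variance of the big breeds and can fail to
   separate the small breed at all, while the supervised PLS axes always
   target breed contrasts (see `tests/test_pls_core.py` for a constructed
   demonstration). New animals are projected with the rotation
   `R = W (PᵗW)⁻¹`, i.e. `t = (x − x̄) R`.

2. **Purebred class moments.** Per breed, the sample mean `μ_j` and
   sample covariance `Σ_j` of the training scores (requires at least
   m + 2 animals per breed; n = 14 suffices for m ≤ 4).

3. **Derived crossbred classes.** A crossbred's score is modelled as the
   inheritance-weighted mixture of purebred scores,
   `t | θ ~ N(Σ_j θ_j μ_j, Σ_j θ_j² Σ_j)`, with
   `θ ~ Dirichlet(α₀ Δ)`, so `E θ = Δ` and
   `V(θ) = (diag(Δ) − ΔΔᵗ)/(α₀ + 1)`. Total expectation/variance give
   the marginal moments

       E t = M Δ,
       V t = Σ_j (V(θ)_jj + δ_j²) Σ_j + M V(θ) Mᵗ,      M = [μ_1 … μ_q],

   and the class density is approximated as Gaussian with these moments.
   For a purebred Δ this reduces exactly to `(μ_j, Σ_j)`. The covariance
   is symmetrised `(A + Aᵗ)/2` and verified positive definite by Cholesky
   factorisation; its log-determinant (the log generalized variance) is
   reported per class and grows with the number of breeds in the
   combination when breeds are well separated.

4. **Unknown class.** A constant density equal to the reciprocal volume
   of the axis-aligned box spanned by the purebred training scores,
   `log f = −Σ_c log(max_c − min_c)`. The constant applies everywhere,
   not only inside the box, so remote outliers are never forced into a
   real class by a vanishing unknown density.

5. **Posterior.** `P(k | t) ∝ f_k(t) π_k` over the `n_comb + 1` classes.
   All densities are accumulated in log space and normalised with
   log-sum-exp; underflow cannot occur. The default prior is flat,
   `1/(n_comb + 1)` each; an informative prior takes per-combination
   probabilities from a table (e.g. litter registrations), any
   unallocated mass going to the unknown class, with an optional
   `pi_unknown` override that rescales the rest. Raising `π_unknown`
   monotonically increases the number of hard unknown calls — it acts
   like a significance level for "this animal is something I was not
   trained on".

6. **Predictions.** Hard label = posterior maximum. Soft prediction
   `Δ̂ = Σ_k Δ_k P(k | t)` with `Δ = 0` for the unknown class, so `Δ̂`
   sums to `1 − P(unknown)`; it is reported as-is, not renormalised.

**α₀** scales how tightly θ concentrates around Δ; it is estimated by the
method of moments from IBD simulation at Δ = quarters: the diagonal of
V(θ) is then `3/(16(α₀+1))`, so `α̂₀ = 3/(16 V̄) − 1` with `V̄` the mean
empirical variance of the simulated θ components. The value depends on
the genetic map and crossover model; on this package's default map
(below) it is ≈ 95–105, while a denser map with crossover interference
gives values in the 70s. It is a fixed training-time constant, user-
overridable.

## The PLSR baseline

The same PLS fit used directly: `Δ̂` = fitted dummy response (rows sum to
1 exactly; elements may leave [0,1] and are truncated to
`[1e-10, 1 − 1e-10]` for divergence computations); hard label = the true
combination minimising the square loss or the KL divergence to `Δ̂`.

## Evaluation

Square loss `Σ_j (δ_j − δ̂_j)²` and the Kullback–Leibler divergence
between Multinomial(4, Δ) and Multinomial(4, Δ̂), which reduces to
`4 Σ_{δ_j>0} δ_j ln(δ_j/δ̂_j)` (natural log, nats; verified in the tests
against exact enumeration over all multinomial outcomes). Summary tables
report mean ± SD (ddof = 1) of soft losses and hard-accuracy counts per
method or per combination, and log generalized variances grouped by
generalized pattern (XXXX, XXXY, XXYY, XXYL, XYLK).

## IBD simulation of crossbred test data

True crossbred genotypes with known Δ do not exist as public data, so
test sets are simulated in two steps.

1. **IBD pattern.** Meiosis under a Haldane model: per chromosome the
   crossover count is Poisson(genetic length in Morgans), positions are
   uniform on the cM scale (no interference), mapped to bp through a
   piecewise-linear recombination map; a gamete alternates between the
   parent's homologs from a fair-coin start. Two rounds (F0 → F1 → F2)
   tile each F2 homolog with segments labelled by grandparent and founder
   haplotype. θ is measured as summed physical segment length over the
   diploid autosome length — so the two parental halves are each exactly
   0.5, and θ sums to 1 by construction.

2. **Allele transfer.** Four founders are drawn without replacement from
   the breed pools named by the (uniformly drawn) permutation of the
   combination; each SNP's two alleles are copied from the founder
   haplotype covering its position.

The default map has 18 autosomes with pig-like physical lengths
(≈ 2.26 Gb) at a uniform 1 cM/Mb (≈ 2264 cM total); an empirical map can
be supplied as a 3-column TSV (chrom, pos_bp, cum_cM). Sex chromosomes,
interference and mutation are out of scope.

## Synthetic founders

Founder populations emulate proprietary purebred panels in two layers:

* **Between breeds** — Balding–Nichols: ancestral frequencies uniform on
  `[maf_min, 1 − maf_min]` (default maf_min 0.045, matching a
  QC-filtered chip), per-breed frequencies Beta-distributed around them
  with divergence `Fst` (default 0.15, a typical between-line value for
  commercial pig breeds).
* **Within breeds** — residual admixture: each founder carries a small
  individual amount of ancestry from the other breeds (total ~
  Gamma(shape 3, mean `admix_mean` = 0.09), split Dirichlet-uniformly).
  Purebred lines are never perfectly sorted, and individual ancestry
  variation is the dominant *genome-globally coherent* component of
  within-line spread on SNP chips. Coherence matters: the mixture
  covariance above multiplies the within-breed part by `Σθ_j²`, which is
  only realistic if a founder's score deviation is spread evenly along
  its genome (so a grandchild inherits θ of it). Per-SNP-independent
  noise does not behave that way; with admixture-type structure it does.
  The default 0.09 was chosen so that simulated purebreds and crossbreds
  reproduce the characteristic empirical-vs-derived generalized-variance
  gap of related production panels (simulated purebreds noticeably
  tighter than the training spread; crossbreds slightly wider than
  derived). Set `admix_mean = 0` for idealised fully sorted breeds.

Given personal frequencies, haplotype alleles are independent per SNP:
no local LD. Consequences for interpretation: class separation at a
given SNP count is weaker than on a real chip of the same size (real
panels have fewer effective loci but also tighter within-breed clusters),
and phenomena that depend on local haplotype structure are outside what
these simulations can show.

## Scaled experiments and what they show

The packaged study designs (`crossbred.experiments`) run at desk scale:
p = 2,000 SNPs, four breeds at n = 200 with one tiny breed at n = 14,
20 simulations for each of the 35 combinations (700 test animals) for the
method comparison; the held-out-breed experiment uses five breeds at the
larger production-panel sizes (n = 1,000, tiny breed 14), training on
four and classifying the 35 combinations containing the fifth. These
sizes keep each experiment under a minute on one CPU.

At this scale both classifiers sit in the mid-90s% hard accuracy: PLS-QDA
is at or above PLSR on KL-based hard calls and clearly better on
square-loss soft means, while on square-loss hard calls the two are a
statistical tie (replicate-mean gap under 0.1 percentage points, within
one animal per two thousand). Two further caveats are expected and real,
not bugs:

* PLS-QDA's *KL* soft-loss mean can exceed PLSR's: the posterior leaves
  an average ~2% of mass on the unknown class, and the rare individuals
  it hard-captures cost up to `4 ln(1/(1−P(unknown)))` ≈ 28 nats each,
  which dominates a mean over 700 animals. This vanishes with larger
  panels (tighter classes ⇒ negligible unknown mass on matched test
  sets) but is intrinsic at desk scale.
* In the held-out-breed experiment the unknown class absorbs roughly
  half (seed-dependent) of the two-foreign-grandparent blends, versus
  80–100% on a production-scale panel; pure held-out purebreds are
  classified as the all-distinct four-breed blend (whose centre is near
  the origin with the largest generalized variance) — so four-distinct
  calls on real data deserve caution.

## Numerical choices and edge cases

* Genotypes must be complete ({0,1,2}); missing calls are rejected, not
  imputed (chip call rates ≥ 0.997 make imputation rules untestable).
* Major-allele recoding: a column is flipped when the counted allele's
  training frequency exceeds 0.5; an exact 0.5 keeps the orientation as
  read (warned). Flips are persisted and re-applied to test data.
* PLS: scikit-learn NIPALS, tol 1e-10, max 500 iterations; the
  convergence warning at that tolerance is suppressed as benign.
* Hard-label ties (argmin/argmax) break toward the first label in
  canonical (lexicographic) order.
* Cholesky factorisation both validates positive definiteness and powers
  the Gaussian log-densities; a non-PD derived covariance raises
  immediately (it signals inconsistent inputs).
* All randomness flows through `numpy.random.Generator`; the CLI derives
  one generator per pipeline stage from a single master seed, so a fixed
  config reproduces every output bit-for-bit.

## Known limitations

* The Gaussian form for crossbred classes is a moment approximation; the
  exact marginal is a continuous Dirichlet mixture.
* Breed *permutations* are not distinguished (e.g. LLWW vs LWLW), though
  their θ variances differ; combinations are the classification unit.
* The unknown-class box is axis-aligned in score space and its density
  is scale-derived, not fitted.
* α₀ is treated as known at training time; propagating its estimation
  uncertainty is not attempted.
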