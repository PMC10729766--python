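# crossbred

Classification of the **breed combination** of crossbred animals from SNP
genotypes, trained on purebred animals only.

Commercial finisher pigs are F2 crosses: each of their four grandparents
is a purebred (e.g. Duroc × (Landrace × Large White), written `DDLW`).
Slaughterhouses and breeders want to recover that grandparental breed
combination from a genotyping chip, but labelled crossbred training data
essentially never exist — only purebred reference panels do. `crossbred`
solves this with **PLS-QDA**: partial least squares scores fitted on
purebreds, plus a quadratic discriminant whose crossbred class densities
are *derived analytically* from the purebred moments, so every one of the
`C(q+3, 4)` combinations (35 for q = 4 breeds, 70 for q = 5) gets a class
without a single crossbred training animal. The package also contains the
IBD recombination simulator used to create truth-labelled crossbred test
sets from (real or synthetic) purebred founders, a PLSR baseline, and the
evaluation framework (square loss, Kullback–Leibler divergence,
generalized-variance diagnostics).

## The model

Purebred PLS score vectors are modelled per breed as
`t_j ~ N_m(μ_j, Σ_j)` with `m = q − 1` components. A crossbred's score is
the inheritance-weighted mixture `t | θ ~ N(Σ_j θ_j μ_j, Σ_j θ_j² Σ_j)`,
where `θ` — the realized genome fractions inherited from each breed — is
`Dirichlet(α₀ Δ)` around the combination's proportion vector `Δ`. Total
expectation and variance give the marginal class moments

    E t = M Δ
    V t = Σ_j (V(θ)_jj + δ_j²) Σ_j + M V(θ) Mᵗ,   V(θ) = (diag(Δ) − ΔΔᵗ)/(α₀+1)

with `M = [μ_1 … μ_q]`. A uniform "unknown" class over the range box of
the purebred scores catches animals whose ancestry was never in training,
and class priors (flat or informative, e.g. litter-registration
frequencies) complete the posterior
`P(k | t) ∝ f_k(t) π_k`. The concentration `α₀` is estimated by the
method of moments from IBD simulation on a recombination map
(`α̂₀ = 3/(16 V̄) − 1`). See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import crossbred as cb

breeds = cb.BreedSet(("D", "H", "L", "W"))          # Duroc, Hampshire, Landrace, Large White
rmap   = cb.default_pig_like_map()                   # 18 autosomes, ~2264 cM

# synthetic purebred founders standing in for a proprietary panel
freqs = cb.sample_breed_freqs(p=2000, breeds=breeds, fst=0.15, seed=11)
pool  = cb.sample_founders(freqs, [200, 14, 200, 200], rmap, seed=12)
geno  = pool.genotypes()

# train on purebreds only; alpha0 from 1,000 IBD simulations on the map
alpha0 = cb.estimate_alpha0(rmap, 1000, seed=13).value
res = cb.CrossbredQDA(geno, geno.labels, breeds, alpha0=alpha0).fit()
print(res.summary())

# simulate a truth-labelled crossbred test set and classify it
test, truth = cb.simulate_testset(pool, res.combos, 20, breeds,
                                  np.random.default_rng(14))
pred = res.predict(test)
acc = (pred["hard_label"].to_numpy() == truth["combination"].to_numpy()).mean()
print(f"hard accuracy over {len(truth)} crossbreds: {acc:.3f}")
print(pred.head(3)[["sample_id", "hard_label", "posterior_unknown", "delta_D"]])
```

Output (abridged):

```
Crossbred PLS-QDA classification model
======================================================
breeds (q):          4  [D, H, L, W]
components (m):      3
training n:          614  per breed: {'D': 200, 'H': 14, 'L': 200, 'W': 200}
SNPs (p):            2000
alpha0:              97.72
classes:             35 combinations + unknown
prior:               flat (pi_unknown = 0.02778)
unknown log-density: -9.125

cumulative R2 at m components:
  X:  0.158
  D:  0.986
  H:  0.912
  L:  0.986
  W:  0.988
...
hard accuracy over 700 crossbreds: 0.969
   sample_id hard_label  posterior_unknown   delta_D
0  DDDD_0000       DDDD           0.001639  0.998303
1  DDDD_0001       DDDD           0.001298  0.998626
2  DDDD_0002       DDDD           0.001619  0.998356
```

`hard_label` is the posterior-maximum combination; `posterior_unknown`
the mass on the catch-all class; `delta_D` the soft (posterior-averaged)
Duroc grandparent proportion — near 1 for a purebred Duroc, 0.5 for
`DDLW`, and so on.

The same workflow is available from the shell:

```bash
crossbred simulate-founders --config config.yaml --out founders/
crossbred simulate-testset  --config config.yaml --founders founders/founders.vcf --out test/
crossbred train             --config config.yaml --genotypes founders/founders.raw --out model.npz
crossbred classify          --model model.npz --genotypes test/testset.raw --out results.csv
crossbred evaluate          --results results.csv --truth test/truth.csv --out eval/run1
```

(`examples/config.yaml` is a ready-to-run configuration;
`examples/informative_prior_synthetic_example.csv` shows the
informative-prior format with illustrative, synthetic values — real use
would substitute registered litter frequencies for the target
population.)

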