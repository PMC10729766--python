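"""Reproducible study designs: the scaled method-comparison experiment and
the held-out-breed (unknown-class) experiment.

Both generate synthetic founders, simulate crossbred test sets by IBD
recombination, train on purebreds only, and score the classifiers.  Sizes
default to a desk-scale design (p = 2,000 SNPs, a few hundred animals per
breed with one deliberately tiny breed) that runs in well under a minute
per experiment on one CPU while preserving the qualitative regime of a
50K-chip study; the held-out experiment uses the larger training sizes of
a production panel because the unknown-class behaviour is sensitive to how
tightly the purebred moments are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breedspace import BreedSet, enumerate_combinations
from .evaluation import evaluate_records, generalized_pattern, summarize
from .founder_sim import sample_breed_freqs, sample_founders
from .ibd_sim import estimate_alpha0, simulate_testset
from .model import BreedPLSR, CrossbredQDA
from .recomb import default_pig_like_map

__all__ = ["scaled_comparison", "holdout_unknown_experiment"]


def _spawn(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ComparisonResult:
    """Outcome of the scaled PLS-QDA vs PLSR comparison."""

    records: pd.DataFrame
    by_method: pd.DataFrame
    alpha0: float
    n_test: int

    def metric(self, method: str, column: str) -> float:
        row = self.by_method[self.by_method["method"] == method].iloc[0]
        return float(row[column])


def scaled_comparison(
    seed: int = 1,
    *,
    p: int = 2000,
    fst: float = 0.15,
    n_per_breed: tuple = (200, 14, 200, 200),
    n_per_combo: int = 20,
    n_chrom: int = 18,
    alpha0_sims: int = 1000,
) -> ComparisonResult:
    """Train PLS-QDA and the PLSR baseline on synthetic purebred founders
    (four breeds, one of them tiny) and score both on an IBD-simulated
    crossbred test set covering all 35 combinations."""
    breeds = BreedSet(("D", "H", "L", "W"))
    rmap = default_pig_like_map(n_chrom)
    r_freq, r_found, r_test, r_alpha = _spawn(seed, 4)
    freqs = sample_breed_freqs(p, breeds, fst, seed=r_freq)
    pool = sample_founders(freqs, list(n_per_breed), rmap, seed=r_found)
    geno = pool.genotypes()

    alpha0 = estimate_alpha0(rmap, alpha0_sims, seed=r_alpha).value
    qda = CrossbredQDA(geno, geno.labels, breeds, alpha0=alpha0).fit()
    plsr = BreedPLSR(geno, geno.labels, breeds).fit()

    test, truth = simulate_testset(pool, qda.combos, n_per_combo, breeds, r_test)
    true_labels = truth["combination"].tolist()
    true_deltas = truth[[f"delta_{c}" for c in breeds.codes]].to_numpy()

    qda_pred = qda.predict(test)
    qda_hard = qda_pred["hard_label"].tolist()
    qda_soft = qda.soft_predict(test)
    rec_q = evaluate_records(true_labels, true_deltas, qda_soft, qda_hard, qda_hard,
                             method="plsqda", sample_ids=test.sample_ids)

    plsr_soft = plsr.soft_predict(test)
    rec_p = evaluate_records(true_labels, true_deltas, plsr_soft,
                             plsr.predict(test, loss="kl"), plsr.predict(test, loss="square"),
                             method="plsr", sample_ids=test.sample_ids)

    records = pd.concat([rec_q, rec_p], ignore_index=True)
    return ComparisonResult(records=records, by_method=summarize(records),
                            alpha0=alpha0, n_test=len(truth))


def _p_pattern(label: str, held_out: str) -> str:
    """Generalize a combination by its held-out-breed content: number of
    held-out grandparents and distinct other breeds (PPXX, PXXY, ...)."""
    k = label.count(held_out)
    rest = label.replace(held_out, "")
    names = {
        (4, 0): "PPPP", (3, 1): "PPPX", (2, 1): "PPXX", (2, 2): "PPXY",
        (1, 1): "PXXX", (1, 2): "PXXY", (1, 3): "PXYL",
    }
    return names[(k, len(set(rest)))]


def holdout_unknown_experiment(
    seed: int = 1,
    *,
    p: int = 2000,
    fst: float = 0.15,
    n_train: int = 1000,
    n_small: int = 14,
    n_per_combo: int = 20,
    n_chrom: int = 18,
    alpha0_sims: int = 1000,
    held_out: str = "P",
) -> pd.DataFrame:
    """Train on four breeds, classify crossbreds containing a fifth.

    Simulates five founder populations, trains PLS-QDA without the
    held-out breed, and classifies IBD-simulated crossbreds from every
    combination containing it.  Returns a table of predicted-class shares
    per held-out-content pattern (PPPP, PPPX, ..., PXYL), with an
    ``unknown`` column — the qualitative question being which blends the
    unknown class absorbs.
    """
    codes = tuple(sorted({"D", "H", "L", "W"} | {held_out}))
    breeds5 = BreedSet(codes)
    rmap = default_pig_like_map(n_chrom)
    r_freq, r_found, r_test, r_alpha = _spawn(seed, 4)
    freqs = sample_breed_freqs(p, breeds5, fst, seed=r_freq)
    sizes = [n_train] * breeds5.q
    sizes[breeds5.index("H")] = n_small
    pool = sample_founders(freqs, sizes, rmap, seed=r_found)

    geno = pool.genotypes()
    keep = np.asarray([lab != held_out for lab in geno.labels])
    train_breeds = BreedSet(tuple(c for c in codes if c != held_out))
    alpha0 = estimate_alpha0(rmap, alpha0_sims, seed=r_alpha).value
    qda = CrossbredQDA(geno.matrix[keep].astype(float),
                       [l for l in geno.labels if l != held_out],
                       train_breeds, alpha0=alpha0).fit()

    combos = [c for c in enumerate_combinations(breeds5) if held_out in c.label]
    test, truth = simulate_testset(pool, combos, n_per_combo, breeds5, r_test)
    hard = qda.predict(test.matrix.astype(float))["hard_label"].to_numpy()

    rows = []
    truth = truth.assign(p_pattern=[_p_pattern(l, held_out) for l in truth["combination"]])
    for pat, grp in truth.groupby("p_pattern"):
        preds = hard[grp.index.to_numpy()]
        counts = pd.Series(
            ["unknown" if h == "unknown" else generalized_pattern(h) for h in preds]
        ).value_counts()
        row = {"p_pattern": pat, "n": len(grp)}
        for cls in ("unknown", "XXXX", "XXXY", "XXYY", "XXYL", "XYLK"):
            row[cls] = counts.get(cls, 0) / len(grp)
        rows.append(row)
    order = ["PPPP", "PPPX", "PPXX", "PPXY", "PXXX", "PXXY", "PXYL"]
    return pd.DataFrame(rows).set_index("p_pattern").loc[[o for o in order if o in {r["p_pattern"] for r in rows}]].reset_index()
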