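"""Loss functions and summary tables for soft and hard breed-combination
predictions, plus generalized-variance (log-determinant) diagnostics.

Soft predictions are proportion vectors delta-hat; they are scored against
the true delta by the square loss ``sum_j (delta_j - deltahat_j)^2`` and by
the Kullback-Leibler divergence between the two multinomial distributions
of the four grandparent draws, which for Multinomial(4, .) reduces to
``4 * sum_{j: delta_j > 0} delta_j * ln(delta_j / deltahat_j)`` (natural
log, reported in nats).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breedspace import BreedCombination, N_GRANDPARENTS

__all__ = [
    "square_loss",
    "kl_divergence",
    "generalized_pattern",
    "evaluate_records",
    "summarize",
    "generalized_variance_table",
]


def square_loss(delta: np.ndarray, delta_hat: np.ndarray) -> float:
    """Sum of squared elementwise differences; in [0, 2] on the simplex."""
    delta = np.asarray(delta, dtype=float)
    delta_hat = np.asarray(delta_hat, dtype=float)
    if delta.shape != delta_hat.shape:
        raise ValueError(f"length mismatch: {delta.shape} vs {delta_hat.shape}")
    return float(((delta - delta_hat) ** 2).sum())


def kl_divergence(delta: np.ndarray, delta_hat: np.ndarray) -> float:
    """KL divergence (nats) between Multinomial(4, delta) and
    Multinomial(4, delta_hat): ``4 * sum_{delta_j > 0} delta_j
    ln(delta_j / deltahat_j)`` with the 0 ln 0 = 0 convention.

    ``delta_hat`` must be strictly positive wherever ``delta`` is —
    callers truncate soft predictions to [1e-10, 1 - 1e-10] first.
    """
    delta = np.asarray(delta, dtype=float)
    delta_hat = np.asarray(delta_hat, dtype=float)
    if delta.shape != delta_hat.shape:
        raise ValueError(f"length mismatch: {delta.shape} vs {delta_hat.shape}")
    pos = delta > 0
    if np.any(delta_hat[pos] <= 0):
        raise ValueError("delta_hat is zero where delta is positive; truncate the prediction first")
    return float(N_GRANDPARENTS * np.sum(delta[pos] * np.log(delta[pos] / delta_hat[pos])))


def generalized_pattern(label: str) -> str:
    """Generalize a combination label by the multiset of breed counts:
    XXXX (purebred), XXXY, XXYY, XXYL, XYLK."""
    counts = tuple(sorted((label.count(c) for c in set(label)), reverse=True))
    return {
        (4,): "XXXX",
        (3, 1): "XXXY",
        (2, 2): "XXYY",
        (2, 1, 1): "XXYL",
        (1, 1, 1, 1): "XYLK",
    }[counts]


def evaluate_records(
    true_labels,
    true_deltas: np.ndarray,
    soft: np.ndarray,
    hard_kl,
    hard_sq,
    method: str,
    sample_ids=None,
) -> pd.DataFrame:
    """Per-individual evaluation records for one method.

    ``soft`` rows are truncated internally for the KL computation; hard
    labels may come from posterior maxima (PLS-QDA) or loss minimization
    (PLSR), one per loss.
    """
    from .classifiers import TRUNC_EPS

    true_deltas = np.atleast_2d(np.asarray(true_deltas, dtype=float))
    soft = np.atleast_2d(np.asarray(soft, dtype=float))
    n = true_deltas.shape[0]
    true_labels = list(true_labels)
    if not (len(true_labels) == soft.shape[0] == len(hard_kl) == len(hard_sq) == n):
        raise ValueError("record inputs have mismatched lengths")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    trunc = np.clip(soft, TRUNC_EPS, 1 - TRUNC_EPS)
    recs = []
    for i in range(n):
        recs.append(
            {
                "sample_id": sample_ids[i],
                "method": method,
                "true_label": true_labels[i],
                "pattern": generalized_pattern(true_labels[i]),
                "kl_soft": kl_divergence(true_deltas[i], trunc[i]),
                "sq_soft": square_loss(true_deltas[i], soft[i]),
                "hard_kl": hard_kl[i],
                "hard_sq": hard_sq[i],
                "correct_kl": hard_kl[i] == true_labels[i],
                "correct_sq": hard_sq[i] == true_labels[i],
            }
        )
    return pd.DataFrame(recs)


def summarize(records: pd.DataFrame, by: str = "method") -> pd.DataFrame:
    """Mean +/- SD of soft losses and hard-accuracy counts/percent,
    grouped by ``"method"`` or ``"combination"`` (true label)."""
    if records.empty:
        raise ValueError("no evaluation records")
    key = {"method": "method", "combination": "true_label"}[by]
    rows = []
    for g, grp in records.groupby(key, sort=True):
        n = len(grp)
        rows.append(
            {
                key: g,
                "n": n,
                "kl_soft_mean": grp["kl_soft"].mean(),
                "kl_soft_sd": grp["kl_soft"].std(ddof=1),
                "sq_soft_mean": grp["sq_soft"].mean(),
                "sq_soft_sd": grp["sq_soft"].std(ddof=1),
                "kl_hard_correct": int(grp["correct_kl"].sum()),
                "kl_hard_pct": 100.0 * grp["correct_kl"].mean(),
                "sq_hard_correct": int(grp["correct_sq"].sum()),
                "sq_hard_pct": 100.0 * grp["correct_sq"].mean(),
            }
        )
    return pd.DataFrame(rows)


def generalized_variance_table(
    cbs,
    empirical_scores: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Log generalized variance (log |cov|) per generalized combination
    pattern: theoretical values from the derived class covariances and,
    when simulated score matrices are supplied per label, empirical
    log-determinants of their sample covariances (NaN when a group has
    fewer than m + 1 individuals)."""
    rows = []
    for cb in cbs:
        emp = np.nan
        if empirical_scores is not None and cb.label in empirical_scores:
            t = np.atleast_2d(empirical_scores[cb.label])
            m = t.shape[1]
            if t.shape[0] >= m + 1:
                sign, logdet = np.linalg.slogdet(np.cov(t, rowvar=False, ddof=1).reshape(m, m))
                emp = logdet if sign > 0 else np.nan
        rows.append(
            {
                "label": cb.label,
                "pattern": generalized_pattern(cb.label),
                "log_det_theoretical": cb.log_det,
                "log_det_empirical": emp,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("pattern")
        .agg(
            n=("label", "size"),
            theoretical_mean=("log_det_theoretical", "mean"),
            theoretical_sd=("log_det_theoretical", lambda s: s.std(ddof=1)),
            empirical_mean=("log_det_empirical", "mean"),
            empirical_sd=("log_det_empirical", lambda s: s.std(ddof=1)),
        )
        .reindex(["XXXX", "XXXY", "XXYL", "XXYY", "XYLK"])
        .dropna(how="all")
        .reset_index()
    )
    return out
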