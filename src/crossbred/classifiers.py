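"""PLS-QDA building blocks: purebred score moments, analytically derived
crossbred class densities, the unknown class, priors and posteriors, plus
the PLSR soft/hard baseline.

The central derivation: a crossbred's score vector is modelled as the
theta-weighted mixture of purebred scores, ``t | theta ~ N(sum_j theta_j
mu_j, sum_j theta_j^2 Sigma_j)``, where theta (the realized inheritance
proportions) is Dirichlet(alpha0 * delta) around the combination's delta.
Total expectation/variance give the marginal moments

    E t  = M delta                       (M = [mu_1 ... mu_q], m x q)
    V t  = sum_j (V(theta)_jj + delta_j^2) Sigma_j + M V(theta) M'

with ``V(theta) = (diag(delta) - delta delta') / (alpha0 + 1)``, and the
marginal is approximated as Gaussian with those moments.  Every breed
combination therefore gets a class density estimated from purebred data
alone; no crossbred training material is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import logsumexp

from .breedspace import BreedCombination, BreedSet, validate_delta

__all__ = [
    "PBParams",
    "CBParams",
    "UnknownClass",
    "estimate_pb_params",
    "dirichlet_variance",
    "cb_moments",
    "build_unknown",
    "build_prior",
    "log_densities",
    "posterior",
    "soft_from_posterior",
    "classify_plsr",
    "hard_from_soft",
    "TRUNC_EPS",
]

#: truncation bound for soft proportions entering divergence computations
TRUNC_EPS = 1e-10


@dataclass(frozen=True)
class PBParams:
    """Per-breed score-space moments: sample means ``mu`` (q x m), sample
    covariances ``sigma`` (q x m x m) and class sizes ``n``."""

    mu: np.ndarray
    sigma: np.ndarray
    n: np.ndarray
    breeds: BreedSet

    @property
    def m(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class CBParams:
    """Derived class density of one breed combination: Gaussian with
    mixture mean, recombination-inflated covariance, and its log
    generalized variance (log-determinant)."""

    label: str
    delta: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    log_det: float


@dataclass(frozen=True)
class UnknownClass:
    """Catch-all class: constant density equal to the reciprocal volume of
    the axis-aligned box spanned by the purebred training scores.  The
    constant applies everywhere (not only inside the box) so outliers are
    never forced into a real class by a vanishing unknown density."""

    box_min: np.ndarray
    box_max: np.ndarray
    log_density: float


def estimate_pb_params(scores: np.ndarray, labels, breeds: BreedSet) -> PBParams:
    """Sample mean and (unbiased) sample covariance of the purebred score
    vectors, per breed in canonical order."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(list(labels))
    m = scores.shape[1]
    mu = np.zeros((breeds.q, m))
    sigma = np.zeros((breeds.q, m, m))
    ns = np.zeros(breeds.q, dtype=int)
    for j, code in enumerate(breeds.codes):
        t = scores[labels == code]
        if t.shape[0] < m + 2:
            raise ValueError(f"breed {code!r} has {t.shape[0]} individuals; need at least m+2 = {m + 2}")
        mu[j] = t.mean(axis=0)
        sigma[j] = np.cov(t, rowvar=False, ddof=1).reshape(m, m)
        ns[j] = t.shape[0]
        try:
            cholesky(sigma[j], lower=True)
        except np.linalg.LinAlgError:
            raise ValueError(f"singular score covariance for breed {code!r}") from None
    return PBParams(mu=mu, sigma=sigma, n=ns, breeds=breeds)


def dirichlet_variance(delta: np.ndarray, alpha0: float) -> np.ndarray:
    """Covariance of theta ~ Dirichlet(alpha0 * delta):
    ``(diag(delta) - delta delta') / (alpha0 + 1)``.  Rows sum to zero
    (theta lives on the simplex); the zero matrix for a purebred delta."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    delta = validate_delta(delta)
    return (np.diag(delta) - np.outer(delta, delta)) / (alpha0 + 1.0)


def cb_moments(delta: np.ndarray, pb: PBParams, alpha0: float, label: str | None = None) -> CBParams:
    """Marginal Gaussian moments of a crossbred class from purebred moments
    and the Dirichlet model for inheritance proportions.

    For a purebred delta = e_j this reduces exactly to (mu_j, Sigma_j).
    """
    delta = validate_delta(delta, q=pb.breeds.q)
    V = dirichlet_variance(delta, alpha0)
    mean = delta @ pb.mu  # sum_j delta_j mu_j
    M = pb.mu.T  # m x q
    weights = np.diag(V) + delta**2  # E[theta_j^2]
    cov = np.einsum("j,jab->ab", weights, pb.sigma) + M @ V @ M.T
    cov = (cov + cov.T) / 2.0
    try:
        c = cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        raise ValueError(f"derived covariance for {label or delta} is not positive definite") from None
    log_det = 2.0 * float(np.sum(np.log(np.diag(c))))
    return CBParams(label=label or "", delta=delta, mean=mean, cov=cov, log_det=log_det)


def derive_cb_params(combos: list[BreedCombination], pb: PBParams, alpha0: float) -> list[CBParams]:
    """Class parameters for every breed combination."""
    return [cb_moments(c.delta, pb, alpha0, label=c.label) for c in combos]


def build_unknown(scores: np.ndarray) -> UnknownClass:
    """Uniform density over the per-component range box of the purebred
    training scores; log density = -sum log(range)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    rng = hi - lo
    if np.any(rng <= 0):
        raise ValueError("zero score range on a component; cannot build the unknown-class box")
    return UnknownClass(box_min=lo, box_max=hi, log_density=-float(np.sum(np.log(rng))))


def build_prior(
    combos: list[BreedCombination],
    kind: str = "flat",
    table: pd.DataFrame | dict | None = None,
    pi_unknown: float | None = None,
) -> np.ndarray:
    """Prior over the n_comb combinations plus the trailing unknown class.

    ``flat``: all n_comb + 1 classes equal.  ``informative``: per-label
    probabilities from ``table`` (label -> probability, e.g. litter
    frequencies); any mass not allocated goes to the unknown class unless
    ``pi_unknown`` overrides it (remaining mass then rescales the table).
    """
    n_comb = len(combos)
    if kind == "flat":
        pi = np.full(n_comb + 1, 1.0 / (n_comb + 1))
        if pi_unknown is not None:
            if not 0 <= pi_unknown < 1:
                raise ValueError("pi_unknown must lie in [0, 1)")
            pi = np.full(n_comb + 1, (1.0 - pi_unknown) / n_comb)
            pi[-1] = pi_unknown
        return pi
    if kind != "informative":
        raise ValueError(f"unknown prior kind {kind!r}; use 'flat' or 'informative'")
    if table is None:
        raise ValueError("informative prior requires a label -> probability table")
    if isinstance(table, pd.DataFrame):
        table = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(float)))
    labels = [c.label for c in combos]
    unknown_mass = 0.0
    pi = np.zeros(n_comb + 1)
    for lab, prob in table.items():
        if lab.lower() == "unknown":
            unknown_mass += float(prob)
            continue
        if lab not in labels:
            raise KeyError(f"prior table names unknown combination {lab!r}")
        pi[labels.index(lab)] = float(prob)
    assigned = pi[:-1].sum() + unknown_mass
    if assigned > 1 + 1e-9:
        raise ValueError(f"prior table mass {assigned} exceeds 1")
    pi[-1] = unknown_mass + max(0.0, 1.0 - assigned)  # leftover mass -> unknown
    if pi_unknown is not None:
        if not 0 <= pi_unknown < 1:
            raise ValueError("pi_unknown must lie in [0, 1)")
        if pi[:-1].sum() <= 0:
            raise ValueError("cannot rescale: no mass on combinations")
        pi[:-1] *= (1.0 - pi_unknown) / pi[:-1].sum()
        pi[-1] = pi_unknown
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("prior does not sum to 1")
    return pi / pi.sum()


def log_densities(scores: np.ndarray, cbs: list[CBParams], unknown: UnknownClass) -> np.ndarray:
    """Log class-conditional densities, n x (n_comb + 1), unknown last.

    Gaussian log-densities are evaluated via per-class Cholesky factors;
    everything stays in log space so small densities never underflow.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if np.isnan(scores).any():
        raise ValueError("NaN score vector")
    n, m = scores.shape
    out = np.empty((n, len(cbs) + 1))
    const = -0.5 * m * np.log(2 * np.pi)
    for k, cb in enumerate(cbs):
        cf = cho_factor(cb.cov, lower=True)
        d = scores - cb.mean
        maha = np.einsum("ij,ij->i", d, cho_solve(cf, d.T).T)
        out[:, k] = const - 0.5 * cb.log_det - 0.5 * maha
    out[:, -1] = unknown.log_density
    return out


def posterior(
    scores: np.ndarray, cbs: list[CBParams], unknown: UnknownClass, prior: np.ndarray
) -> np.ndarray:
    """Posterior class probabilities, n x (n_comb + 1), rows summing to 1."""
    prior = np.asarray(prior, dtype=float)
    if prior.shape[0] != len(cbs) + 1:
        raise ValueError(f"prior has length {prior.shape[0]}, expected {len(cbs) + 1}")
    logf = log_densities(scores, cbs, unknown)
    with np.errstate(divide="ignore"):
        logpost = logf + np.log(prior)
    return np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))


def soft_from_posterior(post: np.ndarray, cbs: list[CBParams]) -> np.ndarray:
    """Posterior-weighted breed proportions: sum_k delta_k P(k | t).

    The unknown class contributes delta = 0, so rows sum to
    1 - P(unknown); they are reported as-is, not renormalized.
    """
    deltas = np.stack([cb.delta for cb in cbs])
    return post[:, :-1] @ deltas


def classify_plsr(model, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PLSR baseline soft predictions.

    Returns the raw fitted dummy responses (rows sum to 1 but elements may
    fall outside [0, 1]) and a copy truncated to
    [TRUNC_EPS, 1 - TRUNC_EPS] for divergence computations.
    """
    from .pls_core import predict_response

    raw = predict_response(model, X_new)
    trunc = np.clip(raw, TRUNC_EPS, 1.0 - TRUNC_EPS)
    return raw, trunc


def hard_from_soft(soft: np.ndarray, combos: list[BreedCombination], loss: str = "kl") -> list[str]:
    """Nearest true combination to each soft proportion vector under the
    square loss or the Kullback-Leibler divergence.  Ties break in
    canonical label order."""
    from .evaluation import kl_divergence, square_loss

    soft = np.atleast_2d(np.asarray(soft, dtype=float))
    deltas = np.stack([c.delta for c in combos])
    labels = [c.label for c in combos]
    out = []
    for row in soft:
        if loss == "square":
            costs = [square_loss(d, row) for d in deltas]
        elif loss == "kl":
            row_t = np.clip(row, TRUNC_EPS, 1 - TRUNC_EPS)
            costs = [kl_divergence(d, row_t) for d in deltas]
        else:
            raise ValueError(f"unknown loss {loss!r}; use 'square' or 'kl'")
        out.append(labels[int(np.argmin(costs))])
    return out
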