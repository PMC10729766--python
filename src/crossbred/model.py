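"""Model/Results interface for crossbred breed-combination classification.

:class:`CrossbredQDA` is built from purebred training genotypes and breed
labels; ``fit()`` runs the PLS decomposition, estimates per-breed score
moments, derives a Gaussian class density for every breed combination from
those moments and the Dirichlet inheritance model, adds the uniform
"unknown" class, and returns a :class:`CrossbredQDAResults` carrying the
estimates, a ``summary()`` table, and prediction methods.

:class:`BreedPLSR` is the regression baseline: the same PLS fit used
directly as a soft predictor of breed proportions, with hard labels by
nearest true combination under a chosen loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import pls_core
from .breedspace import BreedCombination, BreedSet, enumerate_combinations
from .genotype_io import CodedGenotypes

__all__ = ["CrossbredQDA", "CrossbredQDAResults", "BreedPLSR", "BreedPLSRResults"]

#: concentration of the Dirichlet inheritance model estimated in the
#: source study from IBD simulation on a dense pig linkage map; users with
#: a different map should re-estimate via ibd_sim.estimate_alpha0.
DEFAULT_ALPHA0 = 73.58


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, CodedGenotypes):
        return X.matrix.astype(float), X.sample_ids
    return np.atleast_2d(np.asarray(X, dtype=float)), None


class CrossbredQDA:
    """PLS-QDA classifier of F2 breed combinations, trained on purebreds only.

    Parameters
    ----------
    genotypes : CodedGenotypes or ndarray
        n x p coded purebred genotypes (counts of the minor allele).
    labels : sequence of str
        Purebred breed code per training individual; crossbred labels are
        rejected (class densities for crossbreds are derived, not fitted).
    breeds : BreedSet
        The breed universe; its order indexes every delta vector.
    n_components : int, optional
        PLS component count, default q - 1.
    alpha0 : float
        Dirichlet concentration of the inheritance proportions.
    prior, prior_table, pi_unknown
        Prior specification over the n_comb + 1 classes; see
        :func:`crossbred.classifiers.build_prior`.
    """

    def __init__(
        self,
        genotypes,
        labels,
        breeds: BreedSet,
        *,
        n_components: int | None = None,
        alpha0: float = DEFAULT_ALPHA0,
        prior: str = "flat",
        prior_table=None,
        pi_unknown: float | None = None,
    ):
        X, _ = _as_matrix(genotypes)
        labels = list(labels)
        if len(labels) != X.shape[0]:
            raise ValueError("labels must match the number of training rows")
        bad = sorted({lab for lab in labels if lab not in breeds.codes})
        if bad:
            raise ValueError(
                f"training labels must be purebred codes; got {bad} "
                "(crossbred densities are derived analytically, never fitted)"
            )
        self.X = X
        self.labels = labels
        self.breeds = breeds
        self.m = n_components if n_components is not None else breeds.q - 1
        if alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        self.alpha0 = float(alpha0)
        self.prior_kind = prior
        self.prior_table = prior_table
        self.pi_unknown = pi_unknown

    def fit(self) -> "CrossbredQDAResults":
        Y = pls_core.build_dummy_response(self.labels, self.breeds)
        pls = pls_core.fit_pls(self.X, Y, self.m)
        scores = pls.scores
        pb = clf.estimate_pb_params(scores, self.labels, self.breeds)
        combos = enumerate_combinations(self.breeds)
        cbs = clf.derive_cb_params(combos, pb, self.alpha0)
        unknown = clf.build_unknown(scores)
        prior = clf.build_prior(combos, self.prior_kind, self.prior_table, self.pi_unknown)
        r2 = pls_core.r2_report(pls, self.X, Y, self.breeds)
        return CrossbredQDAResults(
            model=self, pls=pls, pb_params=pb, combos=combos, cb_params=cbs,
            unknown=unknown, prior=prior, r2=r2,
        )


@dataclass
class CrossbredQDAResults:
    """Fitted PLS-QDA classifier: decomposition, class moments, prior."""

    model: CrossbredQDA
    pls: pls_core.PLSModel
    pb_params: clf.PBParams
    combos: list[BreedCombination]
    cb_params: list[clf.CBParams]
    unknown: clf.UnknownClass
    prior: np.ndarray
    r2: pd.DataFrame

    @property
    def class_labels(self) -> list[str]:
        return [c.label for c in self.combos] + ["unknown"]

    def transform(self, X) -> np.ndarray:
        """Project genotypes into the m-dimensional score space."""
        X, _ = _as_matrix(X)
        return pls_core.project(self.pls, X)

    def predict_proba(self, X, prior: np.ndarray | None = None) -> np.ndarray:
        """Posterior probabilities, n x (n_comb + 1), unknown last."""
        return clf.posterior(
            self.transform(X), self.cb_params, self.unknown,
            self.prior if prior is None else prior,
        )

    def predict(self, X, prior: np.ndarray | None = None) -> pd.DataFrame:
        """Classification table: hard label (posterior maximum), posterior
        of the unknown class, soft breed proportions (summing to
        1 - P(unknown)) and the top-3 posterior classes."""
        X, sample_ids = _as_matrix(X)
        post = self.predict_proba(X, prior=prior)
        soft = clf.soft_from_posterior(post, self.cb_params)
        labels = self.class_labels
        hard = [labels[k] for k in post.argmax(axis=1)]
        n = post.shape[0]
        if sample_ids is None:
            sample_ids = [str(i) for i in range(n)]
        top3 = np.argsort(-post, axis=1)[:, :3]
        df = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "hard_label": hard,
                "posterior_unknown": post[:, -1],
            }
        )
        for j, code in enumerate(self.model.breeds.codes):
            df[f"delta_{code}"] = soft[:, j]
        for r in range(3):
            df[f"top{r + 1}"] = [labels[k] for k in top3[:, r]]
            df[f"top{r + 1}_p"] = post[np.arange(n), top3[:, r]]
        return df

    def soft_predict(self, X, prior: np.ndarray | None = None) -> np.ndarray:
        """Posterior-weighted breed proportion vectors (n x q)."""
        return clf.soft_from_posterior(self.predict_proba(X, prior=prior), self.cb_params)

    def generalized_variances(self, empirical_scores=None) -> pd.DataFrame:
        from .evaluation import generalized_variance_table

        return generalized_variance_table(self.cb_params, empirical_scores)

    def summary(self) -> str:
        b = self.model.breeds
        lines = [
            "Crossbred PLS-QDA classification model",
            "=" * 54,
            f"breeds (q):          {b.q}  [{', '.join(b.codes)}]",
            f"components (m):      {self.pls.m}",
            f"training n:          {int(self.pb_params.n.sum())}"
            f"  per breed: {dict(zip(b.codes, self.pb_params.n.tolist()))}",
            f"SNPs (p):            {self.pls.p}",
            f"alpha0:              {self.model.alpha0:.4g}",
            f"classes:             {len(self.combos)} combinations + unknown",
            f"prior:               {self.model.prior_kind}"
            f" (pi_unknown = {self.prior[-1]:.4g})",
            f"unknown log-density: {self.unknown.log_density:.4g}",
            "",
            "cumulative R2 at m components:",
        ]
        final = self.r2.iloc[-1]
        lines.append(f"  X:  {final['R2_X']:.3f}")
        for code in b.codes:
            lines.append(f"  {code}:  {final[f'R2_{code}']:.3f}")
        gv = self.generalized_variances()
        lines += ["", "log generalized variance by combination pattern:"]
        for _, row in gv.iterrows():
            sd = "" if np.isnan(row["theoretical_sd"]) else f" +/- {row['theoretical_sd']:.2f}"
            lines.append(f"  {row['pattern']} (n = {int(row['n'])}): {row['theoretical_mean']:.2f}{sd}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the full fitted classifier to a single .npz archive."""
        meta = {
            "breeds": list(self.model.breeds.codes),
            "alpha0": self.model.alpha0,
            "prior_kind": self.model.prior_kind,
            "labels": [c.label for c in self.combos],
        }
        np.savez(
            path,
            meta=np.asarray(json.dumps(meta)),
            x_mean=self.pls.x_mean, y_mean=self.pls.y_mean,
            weights=self.pls.weights, x_loadings=self.pls.x_loadings,
            y_loadings=self.pls.y_loadings, rotation=self.pls.rotation,
            scores=self.pls.scores, coef=self.pls.coef,
            pb_mu=self.pb_params.mu, pb_sigma=self.pb_params.sigma, pb_n=self.pb_params.n,
            prior=self.prior,
            unknown_min=self.unknown.box_min, unknown_max=self.unknown.box_max,
            r2=self.r2.to_numpy(), r2_cols=np.asarray(list(self.r2.columns)),
        )

    @classmethod
    def load(cls, path) -> "CrossbredQDAResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            breeds = BreedSet(tuple(meta["breeds"]))
            pls = pls_core.PLSModel(
                x_mean=z["x_mean"], y_mean=z["y_mean"], weights=z["weights"],
                x_loadings=z["x_loadings"], y_loadings=z["y_loadings"],
                rotation=z["rotation"], scores=z["scores"], coef=z["coef"],
                m=int(z["rotation"].shape[1]),
            )
            pb = clf.PBParams(mu=z["pb_mu"], sigma=z["pb_sigma"], n=z["pb_n"], breeds=breeds)
            combos = enumerate_combinations(breeds)
            cbs = clf.derive_cb_params(combos, pb, float(meta["alpha0"]))
            rng = z["unknown_max"] - z["unknown_min"]
            unknown = clf.UnknownClass(
                box_min=z["unknown_min"], box_max=z["unknown_max"],
                log_density=-float(np.sum(np.log(rng))),
            )
            r2 = pd.DataFrame(z["r2"], columns=[str(c) for c in z["r2_cols"]])
            prior = z["prior"]
        # training genotypes are not stored; rebuild a metadata-only shell
        shell = CrossbredQDA.__new__(CrossbredQDA)
        shell.breeds = breeds
        shell.m = pls.m
        shell.alpha0 = float(meta["alpha0"])
        shell.prior_kind = meta["prior_kind"]
        shell.prior_table = None
        shell.pi_unknown = None
        shell.labels = []
        shell.X = None
        return CrossbredQDAResults(
            model=shell, pls=pls, pb_params=pb, combos=combos, cb_params=cbs,
            unknown=unknown, prior=prior, r2=r2,
        )


class BreedPLSR:
    """PLSR baseline: the PLS dummy-response fit used directly as a soft
    predictor of breed proportions."""

    def __init__(self, genotypes, labels, breeds: BreedSet, *, n_components: int | None = None):
        X, _ = _as_matrix(genotypes)
        labels = list(labels)
        bad = sorted({lab for lab in labels if lab not in breeds.codes})
        if bad:
            raise ValueError(f"training labels must be purebred codes; got {bad}")
        self.X = X
        self.labels = labels
        self.breeds = breeds
        self.m = n_components if n_components is not None else breeds.q - 1

    def fit(self) -> "BreedPLSRResults":
        Y = pls_core.build_dummy_response(self.labels, self.breeds)
        pls = pls_core.fit_pls(self.X, Y, self.m)
        combos = enumerate_combinations(self.breeds)
        return BreedPLSRResults(model=self, pls=pls, combos=combos)


@dataclass
class BreedPLSRResults:
    model: BreedPLSR
    pls: pls_core.PLSModel
    combos: list[BreedCombination]

    def soft_predict(self, X, truncated: bool = True) -> np.ndarray:
        X, _ = _as_matrix(X)
        raw, trunc = clf.classify_plsr(self.pls, X)
        return trunc if truncated else raw

    def predict(self, X, loss: str = "kl") -> list[str]:
        """Hard labels: nearest true combination under the chosen loss."""
        return clf.hard_from_soft(self.soft_predict(X), self.combos, loss=loss)

    def summary(self) -> str:
        b = self.model.breeds
        return "\n".join(
            [
                "Crossbred PLSR baseline",
                "=" * 40,
                f"breeds (q):     {b.q}  [{', '.join(b.codes)}]",
                f"components (m): {self.pls.m}",
                f"SNPs (p):       {self.pls.p}",
                f"classes:        {len(self.combos)} combinations (no unknown class)",
            ]
        )
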