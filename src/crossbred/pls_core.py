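"""Multivariate partial least squares (PLS2) on coded SNPs with dummy
breed responses.

With ``q`` breeds the response is the n x q one-hot indicator matrix and
``m = q - 1`` components suffice to place each purebred at its own node
point in score space — two breeds separate on one axis, three on two, and
so on.  X and Y are centered but not scaled (the convention of the R
``pls`` package this mirrors).  The decomposition itself is delegated to
scikit-learn's NIPALS implementation; this module owns the projection
contract (rotation form ``t = (x - x_mean) R`` with
``R = W (P' W)^{-1}``), the diagnostics, and serialization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .breedspace import BreedSet

__all__ = [
    "PLSModel",
    "build_dummy_response",
    "fit_pls",
    "project",
    "predict_response",
    "r2_report",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS2 decomposition.

    ``scores`` = T (n x m), ``x_loadings`` = P (p x m), ``y_loadings`` = Q
    (q x m), ``rotation`` = R = W (P'W)^{-1} (p x m) so that projecting the
    centered training X reproduces T; ``coef`` = R Q' (p x q) gives
    responses as ``y_mean + (x - x_mean) coef``.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    rotation: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    m: int

    @property
    def p(self) -> int:
        return self.x_mean.shape[0]

    @property
    def q(self) -> int:
        return self.y_mean.shape[0]


def build_dummy_response(labels, breeds: BreedSet) -> np.ndarray:
    """One-hot n x q response matrix in canonical breed order."""
    labels = list(labels)
    Y = np.zeros((len(labels), breeds.q))
    for i, lab in enumerate(labels):
        Y[i, breeds.index(lab)] = 1.0
    return Y


def fit_pls(X: np.ndarray, Y: np.ndarray, m: int) -> PLSModel:
    """Fit centered, unscaled PLS2 with ``m`` components."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n, p = X.shape
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > min(n - 1, p):
        raise ValueError(f"m = {m} exceeds the rank bound min(n-1, p) = {min(n - 1, p)}")
    pls = PLSRegression(n_components=m, scale=False, tol=1e-10, max_iter=500)
    with warnings.catch_warnings():
        # the 1e-10 tolerance is tighter than NIPALS usually reaches in 500
        # iterations; the fixed point is attained to working precision anyway
        warnings.simplefilter("ignore", ConvergenceWarning)
        pls.fit(X, Y)
    return PLSModel(
        x_mean=X.mean(axis=0),
        y_mean=Y.mean(axis=0),
        weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        rotation=pls.x_rotations_,
        scores=pls.x_scores_,
        coef=pls.coef_.T,  # sklearn stores (q, p); keep (p, q)
        m=m,
    )


def project(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Score coordinates of new individuals: t = (x - x_mean) R."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.p:
        raise ValueError(f"X_new has {X_new.shape[1]} SNP columns, model expects {model.p}")
    return (X_new - model.x_mean) @ model.rotation


def predict_response(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Fitted dummy-response predictions: y_mean + (x - x_mean) coef."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.p:
        raise ValueError(f"X_new has {X_new.shape[1]} SNP columns, model expects {model.p}")
    return model.y_mean + (X_new - model.x_mean) @ model.coef


def r2_report(model: PLSModel, X: np.ndarray, Y: np.ndarray, breeds: BreedSet | None = None) -> pd.DataFrame:
    """Cumulative variance explained per component, for X and for each
    response column (breed)."""
    X = np.asarray(X, dtype=float) - model.x_mean
    Y = np.asarray(Y, dtype=float) - model.y_mean
    T = project(model, X + model.x_mean)
    ss_x = (X**2).sum()
    ss_y = (Y**2).sum(axis=0)
    rows = []
    for k in range(model.m + 1):
        Xhat = T[:, :k] @ model.x_loadings[:, :k].T
        Yhat = T[:, :k] @ model.y_loadings[:, :k].T
        row = {"n_components": k, "R2_X": 1 - ((X - Xhat) ** 2).sum() / ss_x}
        resid = ((Y - Yhat) ** 2).sum(axis=0)
        names = breeds.codes if breeds is not None else [f"y{j}" for j in range(Y.shape[1])]
        for j, name in enumerate(names):
            row[f"R2_{name}"] = 1 - resid[j] / ss_y[j] if ss_y[j] > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def save_model(model: PLSModel, path, extra_meta: dict | None = None) -> None:
    """Serialize the decomposition (plus optional JSON metadata) to one
    .npz archive so training and classification can be separate runs."""
    meta = json.dumps({"m": model.m, **(extra_meta or {})})
    np.savez(
        Path(path),
        meta=np.asarray(meta),
        x_mean=model.x_mean,
        y_mean=model.y_mean,
        weights=model.weights,
        x_loadings=model.x_loadings,
        y_loadings=model.y_loadings,
        rotation=model.rotation,
        scores=model.scores,
        coef=model.coef,
    )


def load_model(path) -> tuple[PLSModel, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        model = PLSModel(
            x_mean=z["x_mean"],
            y_mean=z["y_mean"],
            weights=z["weights"],
            x_loadings=z["x_loadings"],
            y_loadings=z["y_loadings"],
            rotation=z["rotation"],
            scores=z["scores"],
            coef=z["coef"],
            m=int(meta["m"]),
        )
    return model, meta
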