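"""Predictive validation: in-sample comparison and k-fold cross-validation.

Folds are random at the cluster level (never child level). Each fold's model
is fitted on the complement only, so held-out clusters' responses and
locations never enter the fitted latent field; their prevalence is predicted
by extending the latent field via conditional Gaussian-process draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import ModelSpec, fit, predict_latent
from .selection import ClusterDesign


def r_squared(observed: np.ndarray, predicted: np.ndarray,
              method: str = "correlation") -> float:
    """Coefficient of determination between observed and predicted proportions.

    ``method="correlation"`` (default) is the squared Pearson correlation,
    invariant to affine transformations of the predictions;
    ``method="sse"`` is the regression definition 1 - SSE/SST, which
    penalizes bias as well as scatter.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length with n >= 2")
    if np.var(obs) == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    if method == "correlation":
        if np.var(pred) == 0:
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if method == "sse":
        return float(1.0 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CVResult:
    """Fold assignments, per-cluster predictions and R-squared metrics."""

    fold: np.ndarray                 # fold index per cluster
    observed: np.ndarray             # n_sam / n_examined
    predicted_in_sample: np.ndarray  # posterior mean p from the full-data fit
    predicted_cv: np.ndarray         # out-of-fold posterior mean p
    r2_in_sample: float
    r2_cv: float
    r2_in_sample_sse: float
    r2_cv_sse: float
    cluster_ids: list[str]

    def metrics(self) -> dict:
        return {
            "r2_in_sample": self.r2_in_sample,
            "r2_cv": self.r2_cv,
            "r2_in_sample_sse": self.r2_in_sample_sse,
            "r2_cv_sse": self.r2_cv_sse,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster_id": self.cluster_ids,
            "fold": self.fold,
            "observed": self.observed,
            "predicted_in_sample": self.predicted_in_sample,
            "predicted_cv": self.predicted_cv,
        })


def _posterior_mean_p_at(model, design_rows: ClusterDesign,
                         rng: np.random.Generator) -> np.ndarray:
    """Posterior mean prevalence at new cluster locations (mean over draws of p)."""
    S = predict_latent(model, design_rows.coords, seed=rng)
    cols = [design_rows.names.index(n) for n in model.names]
    X = design_rows.X[:, cols]
    eta = model.beta[:, :1] + model.beta[:, 1:] @ X.T + S
    return expit(eta).mean(axis=0)


def kfold_cv(design: ClusterDesign, spec: ModelSpec, k: int = 10,
             seed: int = 0, full_model=None) -> CVResult:
    """Random k-fold cluster-level cross-validation of the spatial model.

    The model is refitted k times, each time omitting one fold of clusters and
    predicting their prevalence out-of-fold; an in-sample prediction from the
    full-data fit is recorded alongside. ``full_model`` can supply an already
    fitted full-data model to avoid refitting it.
    """
    n = design.n_clusters
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available clusters")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold[chunk] = f

    observed = design.observed_proportion
    if full_model is None:
        full_model = fit(design, spec)
    pred_in = full_model.cluster_probabilities().mean(axis=0)

    pred_cv = np.empty(n)
    for f in range(k):
        held = np.nonzero(fold == f)[0]
        train = np.nonzero(fold != f)[0]
        fold_spec = ModelSpec.from_dict(
            {**spec.to_dict(), "seed": int((spec.seed * 1000 + f) % 2**31)})
        m = fit(design.subset_clusters(train), fold_spec)
        pred_cv[held] = _posterior_mean_p_at(m, design.subset_clusters(held), rng)

    return CVResult(
        fold=fold,
        observed=observed,
        predicted_in_sample=pred_in,
        predicted_cv=pred_cv,
        r2_in_sample=r_squared(observed, pred_in),
        r2_cv=r_squared(observed, pred_cv),
        r2_in_sample_sse=r_squared(observed, pred_in, method="sse"),
        r2_cv_sse=r_squared(observed, pred_cv, method="sse"),
        cluster_ids=list(design.cluster_ids),
    )


def scatter_report(cv: CVResult) -> pd.DataFrame:
    """Tidy observed/predicted pairs for both panels of the validation plot."""
    frames = []
    for panel, pred in (("in_sample", cv.predicted_in_sample),
                        ("out_of_fold", cv.predicted_cv)):
        frames.append(pd.DataFrame({
            "cluster_id": cv.cluster_ids,
            "fold": cv.fold,
            "panel": panel,
            "observed": cv.observed,
            "predicted": pred,
        }))
    return pd.concat(frames, ignore_index=True)
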