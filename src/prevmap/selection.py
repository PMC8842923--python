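"""Covariate screening, correlation-based elimination and residual diagnostics.

The selection pipeline mirrors standard practice when building predictive
geospatial models: (1) a univariate non-spatial binomial GLM screen keeps
covariates whose single-covariate AIC beats the intercept-only AIC by more
than 2; (2) among pairs with |Pearson rho| > 0.8 (computed over cluster rows)
the member with the worse univariate AIC is dropped, iterating until no pair
exceeds the threshold; (3) the retained set is fitted jointly and the deviance
residuals are examined with an empirical variogram for leftover spatial
structure, which motivates the geostatistical model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .grids import CovariateStack, extract_at_points

AIC_MARGIN = 2.0          # single-covariate AIC must beat intercept-only by this
CORR_THRESHOLD = 0.8


@dataclass
class ClusterDesign:
    """Cluster-level responses and covariates extracted at PSU centroids."""

    cluster_ids: list[str]
    coords: np.ndarray       # (n, 2) projected km
    n_sam: np.ndarray        # successes
    n_examined: np.ndarray   # trials
    X: np.ndarray            # (n, p) covariate matrix, no intercept column
    names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.n_sam = np.asarray(self.n_sam, dtype=int)
        self.n_examined = np.asarray(self.n_examined, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X.reshape(-1, 1)
        n = len(self.cluster_ids)
        if not (self.coords.shape == (n, 2) and len(self.n_sam) == n
                and len(self.n_examined) == n):
            raise ValueError("design rows misaligned")
        if self.X.shape[1] != len(self.names):
            raise ValueError("covariate columns do not match names")
        if np.any(self.n_sam < 0) or np.any(self.n_sam > self.n_examined):
            raise ValueError("counts must satisfy 0 <= n_sam <= n_examined")
        if np.any(self.n_examined < 1):
            raise ValueError("each cluster must examine at least one child")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def observed_proportion(self) -> np.ndarray:
        return self.n_sam / self.n_examined

    def subset_covariates(self, names: list[str]) -> "ClusterDesign":
        idx = [self.names.index(n) for n in names]
        return ClusterDesign(self.cluster_ids, self.coords, self.n_sam,
                             self.n_examined, self.X[:, idx], list(names))

    def subset_clusters(self, rows: np.ndarray) -> "ClusterDesign":
        rows = np.asarray(rows)
        return ClusterDesign([self.cluster_ids[i] for i in rows],
                             self.coords[rows], self.n_sam[rows],
                             self.n_examined[rows], self.X[rows], list(self.names))


def build_design(survey: pd.DataFrame, stack: CovariateStack,
                 names: list[str] | None = None) -> ClusterDesign:
    """Associate each survey cluster with covariate values at its centroid cell."""
    names = list(names) if names is not None else list(stack.names)
    sub = stack.subset(names)
    pts = survey[["x", "y"]].to_numpy(dtype=float)
    X = extract_at_points(sub, pts)
    return ClusterDesign(
        cluster_ids=[str(c) for c in survey["cluster_id"]],
        coords=pts,
        n_sam=survey["n_sam"].to_numpy(),
        n_examined=survey["n_examined"].to_numpy(),
        X=X,
        names=names,
    )


def _binomial_endog(design: ClusterDesign) -> np.ndarray:
    return np.column_stack([design.n_sam, design.n_examined - design.n_sam])


def _fit_glm(design: ClusterDesign, cols: list[int]):
    """Binomial logit GLM with intercept plus the given covariate columns."""
    exog = sm.add_constant(design.X[:, cols], has_constant="add") if cols \
        else np.ones((design.n_clusters, 1))
    model = sm.GLM(_binomial_endog(design), exog, family=sm.families.Binomial())
    return model.fit()


@dataclass
class SelectionReport:
    """Record of the screening and elimination decisions."""

    univariate: pd.DataFrame             # name, coefficient, deviance, aic, screened_in, reason
    intercept_aic: float
    eliminated_pairs: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    final_aic: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "intercept_aic": self.intercept_aic,
            "univariate": self.univariate.to_dict(orient="records"),
            "eliminated_pairs": self.eliminated_pairs,
            "retained": self.retained,
            "final_aic": self.final_aic,
        }, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def univariate_screen(design: ClusterDesign) -> SelectionReport:
    """Screen each covariate with a single-covariate binomial GLM.

    A covariate passes when its AIC beats the intercept-only AIC by more than
    2. Zero-variance covariates and perfect-separation fits are flagged and
    excluded with a reason.
    """
    if design.n_clusters < 2:
        raise ValueError("screening needs at least 2 clusters")
    null_fit = _fit_glm(design, [])
    rows = []
    for j, name in enumerate(design.names):
        col = design.X[:, j]
        if np.std(col) == 0:
            rows.append(dict(name=name, coefficient=np.nan, deviance=np.nan,
                             aic=np.nan, screened_in=False, reason="zero variance"))
            continue
        try:
            with np.errstate(all="ignore"):
                res = _fit_glm(design, [j])
            coef = float(res.params[1])
            if not np.all(np.isfinite(res.params)) or abs(coef) > 50:
                raise ValueError("perfect separation")
            rows.append(dict(name=name, coefficient=coef,
                             deviance=float(res.deviance), aic=float(res.aic),
                             screened_in=bool(res.aic < null_fit.aic - AIC_MARGIN),
                             reason=""))
        except Exception:
            rows.append(dict(name=name, coefficient=np.nan, deviance=np.nan,
                             aic=np.nan, screened_in=False,
                             reason="perfect separation or failed fit"))
    return SelectionReport(univariate=pd.DataFrame(rows),
                           intercept_aic=float(null_fit.aic))


def correlation_filter(design: ClusterDesign, report: SelectionReport,
                       threshold: float = CORR_THRESHOLD,
                       candidates: list[str] | None = None) -> SelectionReport:
    """Drop the worse-AIC member of each highly correlated covariate pair.

    Pearson correlations are computed over cluster rows. Pairs are processed
    by descending |rho| with ties broken by name, so the outcome is invariant
    to input column order; the filter iterates until no retained pair exceeds
    the threshold, and re-running it on its own output is a no-op.
    """
    uni = report.univariate.set_index("name")
    if candidates is None:
        candidates = [n for n in design.names if bool(uni.loc[n, "screened_in"])]
    alive = sorted(candidates)
    # drop zero-variance or unfittable covariates up front
    for name in list(alive):
        if not np.isfinite(uni.loc[name, "aic"]):
            alive.remove(name)
            report.eliminated_pairs.append(
                {"dropped": name, "kept": None, "rho": None,
                 "reason": str(uni.loc[name, "reason"]) or "no valid univariate fit"})
    while len(alive) >= 2:
        sub = design.subset_covariates(alive)
        corr = np.corrcoef(sub.X, rowvar=False)
        pairs = []
        for a in range(len(alive)):
            for b in range(a + 1, len(alive)):
                rho = abs(corr[a, b])
                if rho > threshold:
                    pairs.append((rho, alive[a], alive[b]))
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, na, nb = pairs[0]
        drop = na if uni.loc[na, "aic"] > uni.loc[nb, "aic"] else nb
        keep = nb if drop == na else na
        report.eliminated_pairs.append(
            {"dropped": drop, "kept": keep,
             "rho": float(np.corrcoef(design.X[:, design.names.index(na)],
                                      design.X[:, design.names.index(nb)])[0, 1]),
             "reason": f"|rho| > {threshold} with {keep}"})
        alive.remove(drop)
    report.retained = alive
    return report


def fit_nonspatial_glm(design: ClusterDesign, retained: list[str] | None = None):
    """Multivariable binomial logit fit on the retained covariates.

    Returns (result, deviance_residuals, fitted_probabilities); ``result`` is
    the statsmodels GLM results object (coefficients, AIC, covariance).
    """
    names = list(retained) if retained is not None else list(design.names)
    cols = [design.names.index(n) for n in names]
    res = _fit_glm(design, cols)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("non-spatial GLM did not converge to finite coefficients")
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = np.asarray(res.resid_deviance, dtype=float)
    return res, resid, fitted


def empirical_variogram(residuals: np.ndarray, locations: np.ndarray,
                        n_bins: int = 12, max_dist: float | None = None) -> pd.DataFrame:
    """Classical Matheron semivariogram of per-cluster residuals.

    gamma(h) = mean over pairs in bin h of (z_i - z_j)^2 / 2, with equal-width
    half-open distance bins on [0, max_dist). Empty bins report NaN, never 0.

    Returns a DataFrame with columns bin_center, count, semivariance.
    """
    z = np.asarray(residuals, dtype=float)
    loc = np.atleast_2d(np.asarray(locations, dtype=float))
    if len(z) < 2:
        raise ValueError("variogram needs at least 2 locations")
    d = pdist(loc)
    if max_dist is None:
        max_dist = float(d.max())
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    ii, jj = np.triu_indices(len(z), k=1)
    sq = 0.5 * (z[ii] - z[jj]) ** 2
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges) - 1          # half-open [lo, hi) bins
    rows = []
    for b in range(n_bins):
        m = which == b
        cnt = int(m.sum())
        rows.append({
            "bin_center": 0.5 * (edges[b] + edges[b + 1]),
            "count": cnt,
            "semivariance": float(sq[m].mean()) if cnt else np.nan,
        })
    return pd.DataFrame(rows)


def select_covariates(design: ClusterDesign,
                      threshold: float = CORR_THRESHOLD) -> SelectionReport:
    """Full selection: univariate screen, correlation filter, final joint fit."""
    report = univariate_screen(design)
    report = correlation_filter(design, report, threshold=threshold)
    res, _, _ = fit_nonspatial_glm(design, report.retained)
    report.final_aic = float(res.aic)
    return report
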