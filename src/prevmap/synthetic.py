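"""Seeded synthetic study regions for end-to-end testing of the pipeline.

Emulates the statistical structure the analysis assumes: a latent Matérn
Gaussian field driving spatially autocorrelated risk on a 1 km grid, a small
set of smooth standardized covariates (with one engineered highly-correlated
pair to exercise the selection filter), a clustered binomial survey, a
heterogeneous population-at-risk raster, and a rectangular partition of the
region into administrative units.

The default scenario mirrors the scale of a province-level cluster survey:
123 primary sampling units of ~12 children each, overall prevalence around
7%, cluster-level fractions ranging from 0 to ~77%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import box, mapping, shape

from .grids import GridDefinition, CovariateStack, PopulationRaster
from .kernels import GridKernel, chol_with_jitter, JITTER


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_matern_field(
    grid: GridDefinition,
    sigma: float,
    range_: float,
    nu: float = 1.0,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Draw realization(s) of a zero-mean Matérn Gaussian field at cell centers.

    Uses a dense Cholesky factorization (exact at the grid sizes this package
    targets). ``size=None`` returns one field of shape (n_cells,); an integer
    returns (size, n_cells) sharing one factorization.
    """
    if sigma <= 0 or range_ <= 0 or nu <= 0:
        raise ValueError("sigma, range and nu must all be positive")
    rng = _rng(seed)
    corr = GridKernel(grid).correlation(range_, nu, jitter=JITTER)
    chol = chol_with_jitter(corr)
    n_draws = 1 if size is None else int(size)
    z = rng.standard_normal((n_draws, grid.n_cells))
    fields = sigma * (z @ chol.T)
    return fields[0] if size is None else fields


def generate_covariate_surfaces(
    grid: GridDefinition,
    n_covariates: int,
    seed: int | np.random.Generator = 0,
) -> CovariateStack:
    """Smooth standardized covariate surfaces with distinct spatial scales.

    Each layer is a Matérn field rescaled to mean 0 and sd 1 over cells.
    When ``n_covariates >= 4`` the last layer is built as a noisy copy of the
    first so at least one pair has |rho| > 0.8, exercising the correlation
    filter downstream.
    """
    if n_covariates < 1:
        raise ValueError("n_covariates must be at least 1")
    rng = _rng(seed)
    diam = grid.diameter
    ranges = np.linspace(0.15 * diam, 0.5 * diam, max(n_covariates, 2))[:n_covariates]
    layers = []
    for r in ranges:
        f = simulate_matern_field(grid, sigma=1.0, range_=float(r), nu=1.5, seed=rng)
        layers.append(f)
    if n_covariates >= 4:
        # near-duplicate of layer 0: corr ~ 0.95 by construction
        noise = simulate_matern_field(grid, 1.0, float(ranges[0]), nu=1.5, seed=rng)
        layers[-1] = 0.95 * layers[0] + np.sqrt(1 - 0.95**2) * noise
    vals = np.array(layers)
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    names = [f"cov{i + 1:02d}" for i in range(n_covariates)]
    return CovariateStack(grid, names, vals)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study region.

    ``prevalence_surface`` is inverse-logit(intercept + covariate effects +
    latent field), elementwise over cells.
    """

    grid: GridDefinition
    covariates: CovariateStack
    beta_true: np.ndarray          # intercept first, log-odds units
    matern_sigma: float
    matern_range: float
    matern_nu: float
    field_values: np.ndarray       # latent field per cell
    prevalence_surface: np.ndarray

    def params_dict(self) -> dict:
        return {
            "beta_true": list(map(float, self.beta_true)),
            "matern_sigma": self.matern_sigma,
            "matern_range": self.matern_range,
            "matern_nu": self.matern_nu,
            "covariate_names": self.covariates.names,
            "grid": self.grid.to_dict(),
        }


def make_truth(
    grid: GridDefinition,
    covariates: CovariateStack,
    beta: np.ndarray,
    sigma: float,
    range_: float,
    nu: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> SyntheticTruth:
    """Assemble the true prevalence surface from covariates plus a latent field."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (covariates.n_layers + 1,):
        raise ValueError("beta must have one intercept plus one slope per layer")
    fieldv = simulate_matern_field(grid, sigma, range_, nu, seed=seed)
    linpred = beta[0] + beta[1:] @ covariates.values
    prev = expit(linpred + fieldv)
    return SyntheticTruth(grid, covariates, beta, sigma, range_, nu, fieldv, prev)


def simulate_survey(
    truth: SyntheticTruth,
    n_clusters: int,
    children_per_cluster: int | tuple[int, int] = 12,
    seed: int | np.random.Generator = 0,
    clumped: bool = False,
    n_clumps: int = 6,
) -> pd.DataFrame:
    """Simulate a cluster survey: PSU centroids plus binomial SAM counts.

    Cluster locations are uniform over the grid extent, or, with
    ``clumped=True``, scattered around ``n_clumps`` district-like centers to
    mimic a multi-stage design. ``children_per_cluster`` may be a fixed count
    or an inclusive (low, high) range. Counts are Binomial(n_examined,
    prevalence at the cluster's cell).
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be at least 1")
    prev = np.asarray(truth.prevalence_surface, dtype=float)
    if np.any(~np.isfinite(prev)) or np.any(prev < 0) or np.any(prev > 1):
        raise ValueError("prevalence surface must lie in [0, 1]")
    rng = _rng(seed)
    grid = truth.grid
    xmin, ymin, xmax, ymax = grid.extent
    if clumped:
        centers = np.column_stack([
            rng.uniform(xmin, xmax, n_clumps),
            rng.uniform(ymin, ymax, n_clumps),
        ])
        which = rng.integers(0, n_clumps, n_clusters)
        spread = 0.12 * grid.diameter
        xy = centers[which] + rng.normal(0.0, spread, (n_clusters, 2))
        eps = 1e-9 * grid.cell_size
        xy[:, 0] = np.clip(xy[:, 0], xmin, xmax - eps)
        xy[:, 1] = np.clip(xy[:, 1], ymin, ymax - eps)
    else:
        xy = np.column_stack([
            rng.uniform(xmin, xmax, n_clusters),
            rng.uniform(ymin, ymax, n_clusters),
        ])
    if isinstance(children_per_cluster, tuple):
        lo, hi = children_per_cluster
        n_exam = rng.integers(lo, hi + 1, n_clusters)
    else:
        n_exam = np.full(n_clusters, int(children_per_cluster))
    if np.any(n_exam < 1):
        raise ValueError("each cluster must examine at least one child")
    p = prev[grid.cell_index(xy[:, 0], xy[:, 1])]
    n_sam = rng.binomial(n_exam, p)
    return pd.DataFrame({
        "cluster_id": [f"psu{i + 1:04d}" for i in range(n_clusters)],
        "x": xy[:, 0],
        "y": xy[:, 1],
        "n_examined": n_exam.astype(int),
        "n_sam": n_sam.astype(int),
    })


def generate_population_raster(
    grid: GridDefinition,
    total_under2: float,
    seed: int | np.random.Generator = 0,
    equal: bool = False,
) -> PopulationRaster:
    """Nonnegative under-2 population surface summing to ``total_under2``.

    The default surface is log-Gaussian (spatially heterogeneous); with
    ``equal=True`` every cell gets the same share.
    """
    if total_under2 <= 0:
        raise ValueError("total_under2 must be positive")
    if equal:
        vals = np.full(grid.n_cells, total_under2 / grid.n_cells)
    else:
        f = simulate_matern_field(grid, sigma=1.0, range_=0.3 * grid.diameter,
                                  nu=1.5, seed=seed)
        w = np.exp(f)
        vals = total_under2 * w / w.sum()
    return PopulationRaster(grid, vals)


@dataclass
class AdminUnits:
    """Administrative-unit polygons partitioning the study region."""

    unit_ids: list[str]
    polygons: list  # shapely geometries

    def __len__(self) -> int:
        return len(self.unit_ids)

    def to_geojson(self) -> dict:
        feats = [
            {"type": "Feature", "properties": {"unit_id": uid}, "geometry": mapping(poly)}
            for uid, poly in zip(self.unit_ids, self.polygons)
        ]
        return {"type": "FeatureCollection", "features": feats}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson()))

    @classmethod
    def load(cls, path: str | Path) -> "AdminUnits":
        gj = json.loads(Path(path).read_text())
        ids, polys = [], []
        for i, feat in enumerate(gj["features"]):
            ids.append(str(feat.get("properties", {}).get("unit_id", f"unit{i + 1:02d}")))
            polys.append(shape(feat["geometry"]))
        return cls(ids, polys)


def generate_admin_polygons(grid: GridDefinition, n_units: int) -> AdminUnits:
    """Partition the grid extent into ``n_units`` rectangular units.

    Uses the most square factorization r x c of n_units; rectangles tile the
    extent exactly (no overlap, full cover), so every cell center falls in
    exactly one unit.
    """
    if n_units < 1:
        raise ValueError("n_units must be at least 1")
    r = int(np.floor(np.sqrt(n_units)))
    while n_units % r != 0:
        r -= 1
    c = n_units // r
    xmin, ymin, xmax, ymax = grid.extent
    xs = np.linspace(xmin, xmax, c + 1)
    ys = np.linspace(ymin, ymax, r + 1)
    ids, polys = [], []
    k = 0
    for i in range(r):
        for j in range(c):
            k += 1
            ids.append(f"unit{k:02d}")
            polys.append(box(xs[j], ys[i], xs[j + 1], ys[i + 1]))
    return AdminUnits(ids, polys)


# Default study conditions for the self-contained demo scenario.
SCENARIO_DEFAULTS = dict(
    n_rows=40,
    n_cols=40,
    cell_size=1.0,
    n_covariates=6,
    beta=(-3.2, 0.8, -0.5, 0.3, 0.0, 0.0, 0.0),
    sigma=1.0,
    range_=10.0,
    nu=1.0,
    n_clusters=123,
    children_per_cluster=(12, 15),
    total_under2=240_000.0,
    n_units=8,
)


@dataclass
class Scenario:
    """A fully materialized synthetic study region."""

    truth: SyntheticTruth
    survey: pd.DataFrame
    population: PopulationRaster
    admin: AdminUnits


def make_scenario(seed: int = 0, **overrides) -> Scenario:
    """Generate the default demo scenario (overridable field by field).

    Defaults produce a 40 x 40 km region with 6 covariates (three with real
    effects), a Matérn(nu=1) field with sd 1 and 10 km range, 123 clumped
    clusters of 12-15 children, and ~7% overall prevalence.
    """
    cfg = {**SCENARIO_DEFAULTS, **overrides}
    rng = np.random.default_rng(seed)
    grid = GridDefinition(n_rows=cfg["n_rows"], n_cols=cfg["n_cols"],
                          cell_size=cfg["cell_size"])
    stack = generate_covariate_surfaces(grid, cfg["n_covariates"], seed=rng)
    beta = np.asarray(cfg["beta"], dtype=float)[: cfg["n_covariates"] + 1]
    truth = make_truth(grid, stack, beta, cfg["sigma"], cfg["range_"],
                       cfg["nu"], seed=rng)
    children = cfg["children_per_cluster"]
    if isinstance(children, list):
        children = tuple(children)
    survey = simulate_survey(truth, cfg["n_clusters"], children,
                             seed=rng, clumped=True)
    pop = generate_population_raster(grid, cfg["total_under2"], seed=rng)
    admin = generate_admin_polygons(grid, cfg["n_units"])
    return Scenario(truth, survey, pop, admin)


def save_scenario(scenario: Scenario, out_dir: str | Path) -> None:
    """Write survey CSV, covariate/population rasters, admin GeoJSON and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.survey.to_csv(out / "survey.csv", index=False)
    scenario.truth.covariates.save(out / "covariates")
    scenario.population.save(out / "population.asc")
    scenario.admin.save(out / "admin.geojson")
    (out / "truth.json").write_text(json.dumps(scenario.truth.params_dict(), indent=2))
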