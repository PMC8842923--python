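"""Gridded posterior prevalence surfaces and exceedance-probability maps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit

from .grids import GridDefinition, CovariateStack, write_ascii_grid
from .kernels import GridKernel, correlation_matrix, cross_correlation, \
    chol_with_jitter, JITTER
from .model import FittedModel

DEFAULT_THRESHOLDS = (0.02, 0.05, 0.10, 0.15)


@dataclass
class PredictionGrid:
    """Per-cell posterior samples of prevalence plus derived summary surfaces.

    ``sample_matrix`` has shape (n_cells, n_draws). Summary surfaces are exact
    functions of the samples: the mean and the equal-tailed 2.5/97.5
    percentiles (linear interpolation between order statistics). Cells with
    masked covariates are NaN throughout, never silent zeros.
    """

    grid: GridDefinition
    sample_matrix: np.ndarray
    mean_surface: np.ndarray
    lower95_surface: np.ndarray
    upper95_surface: np.ndarray

    @classmethod
    def from_samples(cls, grid: GridDefinition, samples: np.ndarray) -> "PredictionGrid":
        samples = np.asarray(samples, dtype=float)
        if samples.shape[0] != grid.n_cells:
            raise ValueError("sample matrix must have one row per cell")
        valid = np.all(np.isfinite(samples), axis=1)
        mean = np.full(grid.n_cells, np.nan)
        lo = np.full(grid.n_cells, np.nan)
        hi = np.full(grid.n_cells, np.nan)
        if valid.any():
            sub = samples[valid]
            mean[valid] = sub.mean(axis=1)
            lo[valid] = np.percentile(sub, 2.5, axis=1)
            hi[valid] = np.percentile(sub, 97.5, axis=1)
        return cls(grid, samples, mean, lo, hi)

    @property
    def n_draws(self) -> int:
        return self.sample_matrix.shape[1]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(out / "mean.asc", self.grid, self.mean_surface)
        write_ascii_grid(out / "lower95.asc", self.grid, self.lower95_surface)
        write_ascii_grid(out / "upper95.asc", self.grid, self.upper95_surface)


@dataclass
class ExceedanceSurface:
    """Per-cell posterior probability that prevalence exceeds a threshold."""

    grid: GridDefinition
    threshold: float
    probability: np.ndarray

    def save(self, path: str | Path) -> None:
        write_ascii_grid(path, self.grid, self.probability)


def predict_grid(model: FittedModel, stack: CovariateStack,
                 n_samples: int = 1000,
                 seed: int | np.random.Generator = 0) -> PredictionGrid:
    """Posterior prevalence samples on every grid cell.

    For each retained posterior draw the latent field is extended to the cell
    centers by a conditional Gaussian-process draw (kriging mean plus
    conditional-covariance noise, jointly across cells), added to the
    covariate fixed effects, and inverse-logit transformed. Exploits the
    regular grid so each draw costs one Cholesky factorization.
    """
    missing = [n for n in model.names if n not in stack.names]
    if missing:
        raise KeyError(f"covariate stack is missing model layer(s): {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_samples > model.n_draws:
        raise ValueError(
            f"requested {n_samples} samples but the model holds {model.n_draws} draws")
    draw_idx = np.unique(np.linspace(0, model.n_draws - 1, n_samples).round().astype(int))

    grid = stack.grid
    Xg = np.column_stack([stack.layer(n) for n in model.names]) \
        if model.names else np.zeros((grid.n_cells, 0))
    cell_mask = np.all(np.isfinite(Xg), axis=1)
    centers = grid.cell_centers()
    gk = GridKernel(grid)
    nu = model.spec.nu

    samples = np.full((grid.n_cells, len(draw_idx)), np.nan)
    for k, i in enumerate(draw_idx):
        sig, rho = model.sigma[i], model.range_[i]
        R_oo = correlation_matrix(model.coords, rho, nu)
        L_oo = chol_with_jitter(R_oo)
        w = solve_triangular(L_oo, model.latent[i] / max(sig, 1e-300), lower=True)
        alpha = solve_triangular(L_oo.T, w, lower=False)
        R_po = cross_correlation(centers, model.coords, rho, nu)
        mean = sig * (R_po @ alpha)
        half = solve_triangular(L_oo, R_po.T, lower=True)
        R_cond = gk.correlation(rho, nu, jitter=JITTER) - half.T @ half
        R_cond[np.diag_indices_from(R_cond)] += JITTER
        L_c = chol_with_jitter(R_cond)
        s_cells = mean + sig * (L_c @ rng.standard_normal(grid.n_cells))
        eta = model.beta[i, 0] + Xg @ model.beta[i, 1:] + s_cells
        p = expit(eta)
        p[~cell_mask] = np.nan
        samples[:, k] = p
    return PredictionGrid.from_samples(grid, samples)


def exceedance_probability(
    pg: PredictionGrid,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> list[ExceedanceSurface]:
    """Fraction of posterior draws strictly above each threshold, per cell.

    Pointwise non-increasing in the threshold; masked cells stay NaN.
    """
    out = []
    valid = np.all(np.isfinite(pg.sample_matrix), axis=1)
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
        prob = np.full(pg.grid.n_cells, np.nan)
        if valid.any():
            prob[valid] = (pg.sample_matrix[valid] > t).mean(axis=1)
        out.append(ExceedanceSurface(pg.grid, float(t), prob))
    return out
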