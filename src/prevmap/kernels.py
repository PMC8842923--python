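"""Matérn covariance kernel and dense covariance-matrix builders.

Range parameterization
----------------------
The spatial ``range`` r follows the SPDE-literature convention

    corr(d) = 2^(1-nu) / Gamma(nu) * (kappa d)^nu * K_nu(kappa d),
    kappa   = sqrt(8 nu) / r,

so r is the distance at which the correlation has dropped to roughly 0.1.
At nu = 1/2 this collapses to the exponential kernel exp(-2 d / r).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor
from scipy.spatial.distance import cdist
from scipy.special import gammaln, k1, kv

from .grids import GridDefinition

# relative diagonal jitter applied before Cholesky factorization
JITTER = 1e-8


def _check_params(sigma: float | None, range_: float, nu: float) -> None:
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be positive")
    if range_ <= 0:
        raise ValueError("range must be positive")
    if nu <= 0:
        raise ValueError("nu must be positive")


def matern_correlation(d: np.ndarray | float, range_: float, nu: float = 1.0) -> np.ndarray:
    """Matérn correlation at distance(s) ``d`` under the sqrt(8 nu)/range scaling.

    Continuous, equal to 1 at d = 0 and strictly decreasing; at 10x the range
    the correlation is well below 0.01.
    """
    _check_params(None, range_, nu)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    x = np.sqrt(8.0 * nu) * d / range_
    # half-integer smoothness has closed forms (and nu=1 a dedicated Bessel)
    # that avoid the slow general-order kv on the sampler's hot path
    if nu == 0.5:
        return np.exp(-x)
    if nu == 1.5:
        return (1.0 + x) * np.exp(-x)
    if nu == 2.5:
        return (x * x + 3.0 * x + 3.0) / 3.0 * np.exp(-x)
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    with np.errstate(over="ignore", invalid="ignore"):
        if nu == 1.0:
            val = xp * k1(xp)
        else:
            log_c = (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(xp)
            val = np.exp(log_c) * kv(nu, xp)
    # Bessel underflow at large argument: correlation -> 0, which is correct
    out[pos] = np.where(np.isfinite(val), val, 0.0)
    return np.clip(out, 0.0, 1.0)


def matern_covariance(
    d: np.ndarray | float, sigma: float, range_: float, nu: float = 1.0
) -> np.ndarray:
    """Matérn covariance sigma^2 * corr(d); sigma^2 exactly at d = 0."""
    _check_params(sigma, range_, nu)
    return sigma**2 * matern_correlation(d, range_, nu)


def correlation_matrix(
    coords: np.ndarray, range_: float, nu: float = 1.0, jitter: float = JITTER
) -> np.ndarray:
    """Dense Matérn correlation matrix between coordinate rows, plus jitter."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = cdist(coords, coords)
    r = matern_correlation(d, range_, nu)
    r[np.diag_indices_from(r)] += jitter
    return r


def cross_correlation(
    a: np.ndarray, b: np.ndarray, range_: float, nu: float = 1.0
) -> np.ndarray:
    """Matérn correlation between two coordinate sets (no jitter)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    return matern_correlation(cdist(a, b), range_, nu)


class GridKernel:
    """Fast Matérn correlation matrices over a regular grid.

    On a regular grid the pairwise distances take only O(n_cells) distinct
    values (one per absolute row/column offset pair), so each new range value
    costs one Bessel evaluation per unique offset instead of per cell pair.
    The O(n^2) integer offset index is built once and reused.
    """

    def __init__(self, grid: GridDefinition):
        self.grid = grid
        n = grid.n_cells
        rows, cols = np.divmod(np.arange(n), grid.n_cols)
        di = np.abs(rows[:, None] - rows[None, :]).astype(np.int32)
        dj = np.abs(cols[:, None] - cols[None, :]).astype(np.int32)
        self._offset_index = di * grid.n_cols + dj
        ui, uj = np.divmod(np.arange(grid.n_rows * grid.n_cols), grid.n_cols)
        self._unique_dist = grid.cell_size * np.hypot(ui, uj)

    def correlation(self, range_: float, nu: float = 1.0, jitter: float = JITTER) -> np.ndarray:
        vals = matern_correlation(self._unique_dist, range_, nu)
        r = vals[self._offset_index]
        r[np.diag_indices_from(r)] += jitter
        return r


def chol_with_jitter(cov: np.ndarray, max_tries: int = 4) -> np.ndarray:
    """Lower Cholesky factor, escalating the diagonal jitter on failure."""
    scale = float(np.mean(np.diag(cov)))
    bump = 0.0
    for attempt in range(max_tries):
        try:
            c, _ = cho_factor(cov + bump * np.eye(cov.shape[0]), lower=True)
            return np.tril(c)
        except np.linalg.LinAlgError:
            bump = scale * JITTER * 10.0 ** (attempt + 1)
    raise np.linalg.LinAlgError(
        "covariance matrix not positive-definite even after jitter escalation"
    )
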