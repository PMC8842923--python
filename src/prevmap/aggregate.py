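"""Population-weighted aggregation of gridded posterior samples to admin units.

Aggregation is draw-wise: for draw s and unit u,

    prevalence_us = sum_{c in u} p_cs * pop_c / sum_{c in u} pop_c
    count_us      = sum_{c in u} p_cs * pop_c

and posterior summaries are taken over the aggregated draws — never the other
way round, so credible intervals reflect the joint spatial uncertainty.
Cell membership is by cell center in polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grids import PopulationRaster
from .mapping import PredictionGrid
from .synthetic import AdminUnits


@dataclass
class AdminEstimate:
    """Posterior summary of prevalence and affected-child count for one unit."""

    unit_id: str
    prev_mean: float
    prev_lo: float
    prev_hi: float
    count_mean: float
    count_lo: float
    count_hi: float
    population: float
    prevalence_draws: np.ndarray
    count_draws: np.ndarray


def assign_cells(pg_grid, units: AdminUnits) -> np.ndarray:
    """Unit index per cell (-1 when no unit contains the cell center).

    Centers exactly on a shared boundary go to the lowest-index unit that
    covers them, keeping the assignment a partition.
    """
    centers = pg_grid.cell_centers()
    x, y = centers[:, 0], centers[:, 1]
    assign = np.full(pg_grid.n_cells, -1, dtype=int)
    for k, poly in enumerate(units.polygons):
        inside = shapely.contains_xy(poly, x, y) & (assign == -1)
        assign[inside] = k
    unresolved = np.nonzero(assign == -1)[0]
    if unresolved.size:
        pts = shapely.points(x[unresolved], y[unresolved])
        for k, poly in enumerate(units.polygons):
            hit = shapely.covers(poly, pts) & (assign[unresolved] == -1)
            assign[unresolved[hit]] = k
    return assign


def population_weighted_aggregate(
    pg: PredictionGrid, pop: PopulationRaster, units: AdminUnits
) -> list[AdminEstimate]:
    """Aggregate posterior prevalence samples to each administrative unit.

    Units with zero total population report prevalence as missing (NaN) and
    count 0. Masked prediction cells contribute nothing (their population is
    excluded from the denominator).
    """
    g1, g2 = pg.grid, pop.grid
    if (g1.n_rows, g1.n_cols, g1.origin_x, g1.origin_y, g1.cell_size) != \
       (g2.n_rows, g2.n_cols, g2.origin_x, g2.origin_y, g2.cell_size):
        raise ValueError("prediction grid and population raster are misaligned")
    assign = assign_cells(pg.grid, units)
    valid = np.all(np.isfinite(pg.sample_matrix), axis=1)
    estimates = []
    for k, uid in enumerate(units.unit_ids):
        cells = np.nonzero((assign == k) & valid)[0]
        w = pop.under2_count[cells]
        total = float(w.sum())
        counts = w @ pg.sample_matrix[cells] if cells.size else \
            np.zeros(pg.sample_matrix.shape[1])
        if total > 0:
            prev = counts / total
            est = AdminEstimate(
                unit_id=uid,
                prev_mean=float(prev.mean()),
                prev_lo=float(np.percentile(prev, 2.5)),
                prev_hi=float(np.percentile(prev, 97.5)),
                count_mean=float(counts.mean()),
                count_lo=float(np.percentile(counts, 2.5)),
                count_hi=float(np.percentile(counts, 97.5)),
                population=total,
                prevalence_draws=prev,
                count_draws=counts,
            )
        else:
            est = AdminEstimate(uid, np.nan, np.nan, np.nan, 0.0, 0.0, 0.0, 0.0,
                                np.full(pg.sample_matrix.shape[1], np.nan),
                                np.zeros(pg.sample_matrix.shape[1]))
        estimates.append(est)
    return estimates


def estimates_table(estimates: list[AdminEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit": e.unit_id,
        "prev_mean": e.prev_mean, "prev_lo": e.prev_lo, "prev_hi": e.prev_hi,
        "count_mean": e.count_mean, "count_lo": e.count_lo, "count_hi": e.count_hi,
        "population": e.population,
    } for e in estimates])


def _pct(x: float) -> str:
    return "" if not np.isfinite(x) else f"{100 * x:.1f}%"


def _children(x: float) -> str:
    return f"{round(x):,}"


def format_headline(estimates: list[AdminEstimate]) -> pd.DataFrame:
    """Human-readable summary: prevalence to 1 decimal percent, counts to the child.

    Mirrors the usual reporting style, e.g. "6.3% (95% CI 4.2-10.9%)" and
    "15,213 children (95% CI 10,209-26,252)".
    """
    rows = []
    for e in estimates:
        rows.append({
            "unit": e.unit_id,
            "prevalence": _pct(e.prev_mean),
            "prevalence_95ci": f"{_pct(e.prev_lo)}-{_pct(e.prev_hi)}"
                               if np.isfinite(e.prev_mean) else "",
            "children": _children(e.count_mean),
            "children_95ci": f"{_children(e.count_lo)}-{_children(e.count_hi)}",
            "population": _children(e.population),
        })
    return pd.DataFrame(rows)
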