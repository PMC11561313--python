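"""Occurrence thinning and predictor pruning.

Two standard pre-modelling reductions: spatial thinning of occurrence
records to a minimum pairwise great-circle distance (reducing sampling-bias
driven spatial autocorrelation), and greedy removal of predictors from
highly correlated pairs (|r| above a threshold) to limit multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvGrid, OccurrenceSet

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "thin_occurrences",
    "pearson_matrix",
    "select_predictors",
    "CorrelationReport",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between WGS84 points (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _pairwise_km(points: np.ndarray) -> np.ndarray:
    lon = points[:, 0]
    lat = points[:, 1]
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def thin_occurrences(
    occ: OccurrenceSet,
    min_dist_km: float = 10.0,
    reps: int = 100,
    seed: int = 0,
) -> OccurrenceSet:
    """Thin occurrences so no retained pair is closer than ``min_dist_km``.

    Uses the iterative-elimination heuristic popularised by spThin: while
    any pair of remaining points conflicts, delete a point with the largest
    number of conflicting neighbours (random tie-break).  The heuristic is
    randomised, so it is repeated ``reps`` times and a run retaining the
    maximum number of points is returned (ties: first found).  Deterministic
    for a fixed seed.  Retained count is heuristic-optimal, but the
    minimum-distance guarantee holds on every run.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pts = occ.points
    if not np.all(np.isfinite(pts)):
        raise ValueError("occurrence coordinates contain non-finite values")
    n = len(pts)
    if n <= 1:
        return OccurrenceSet(occ.species_id, pts.copy())

    conflict = _pairwise_km(pts) < min_dist_km
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return OccurrenceSet(occ.species_id, pts.copy())

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(reps):
        keep = np.ones(n, dtype=bool)
        counts = conflict.sum(axis=1).astype(int)
        while counts[keep].max(initial=0) > 0:
            worst = counts.max()
            candidates = np.flatnonzero(keep & (counts == worst))
            drop = rng.choice(candidates)
            keep[drop] = False
            counts[conflict[drop]] -= 1
            counts[drop] = 0
        if best is None or keep.sum() > best.sum():
            best = keep
    return OccurrenceSet(occ.species_id, pts[best].copy())


def pearson_matrix(grid_or_table) -> pd.DataFrame:
    """Pairwise Pearson correlation of predictors.

    Accepts an :class:`EnvGrid` (correlations over non-nodata cells) or any
    DataFrame of numeric predictor columns (correlations over rows).
    Zero-variance predictors get NaN correlations (flagged by the caller's
    downstream pruning as undefined) rather than raising.
    """
    if isinstance(grid_or_table, EnvGrid):
        data = pd.DataFrame(grid_or_table.table(), columns=grid_or_table.layer_names)
    else:
        data = pd.DataFrame(grid_or_table)
    if data.shape[1] < 2:
        raise ValueError("need at least two predictors for a correlation matrix")
    if data.dropna().shape[0] < 3:
        raise ValueError("need at least three complete observations")
    corr = data.corr(method="pearson")
    # pandas reports 1.0 on the diagonal even for constant columns; mark
    # zero-variance predictors as undefined throughout
    degenerate = data.std(ddof=1) == 0
    for name in data.columns[degenerate]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    return corr


@dataclass
class CorrelationReport:
    """Outcome of correlation-based predictor pruning."""

    matrix: pd.DataFrame
    threshold: float
    dropped: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "dropped": list(self.dropped),
            "kept": list(self.kept),
            "degenerate": list(self.degenerate),
            "matrix": {c: self.matrix[c].round(6).to_dict() for c in self.matrix.columns},
        }


def select_predictors(
    matrix: pd.DataFrame,
    layer_names: list[str] | None = None,
    threshold: float = 0.8,
) -> CorrelationReport:
    """Greedy pruning of correlated predictors.

    While any kept pair has |r| > threshold, drop the member with the
    largest mean absolute correlation to the other kept predictors
    (ties broken alphabetically).  Predictors with undefined (NaN)
    correlations are flagged as degenerate and excluded from the kept set.
    """
    matrix = pd.DataFrame(matrix)
    if layer_names is not None:
        matrix = matrix.loc[layer_names, layer_names]
    names = list(matrix.columns)
    if not np.allclose(matrix.values, matrix.values.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")

    degenerate = [n for n in names if matrix.loc[n].drop(n).isna().all()]
    kept = [n for n in names if n not in degenerate]
    dropped: list[str] = []
    while len(kept) > 1:
        sub = matrix.loc[kept, kept].abs()
        off = sub.values.copy()
        np.fill_diagonal(off, 0.0)
        if np.nanmax(off) <= threshold:
            break
        mean_abs = (np.nansum(off, axis=1)) / (len(kept) - 1)
        order = sorted(range(len(kept)), key=lambda i: (-mean_abs[i], kept[i]))
        victim = kept[order[0]]
        kept.remove(victim)
        dropped.append(victim)
    return CorrelationReport(matrix=matrix, threshold=threshold,
                             dropped=dropped, kept=kept, degenerate=degenerate)
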