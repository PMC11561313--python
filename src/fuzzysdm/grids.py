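"""Gridded data containers shared by every stage of the pipeline.

An :class:`EnvGrid` is a stack of co-registered environmental predictor
layers on a regular lon/lat lattice with a shared nodata mask.  A
:class:`MembershipSurface` is a single layer of values in [0, 1] over the
same footprint -- used for probability of presence, environmental
favourability, relative habitat suitability, and fuzzy intersections.
Nodata cells are represented as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["EnvGrid", "MembershipSurface", "OccurrenceSet", "FootprintError"]

#: membership-surface kinds understood by downstream fuzzy operations
SURFACE_KINDS = ("probability", "favourability", "relative_suitability", "intersection")


class FootprintError(ValueError):
    """Two gridded objects do not share shape, georeference, or nodata mask."""


def _check_footprint(a, b) -> None:
    if a.shape != b.shape:
        raise FootprintError(f"shape mismatch: {a.shape} vs {b.shape}")
    for attr in ("origin_lon", "origin_lat", "cell_size"):
        if not np.isclose(getattr(a, attr), getattr(b, attr)):
            raise FootprintError(f"georeference mismatch on {attr}")
    if not np.array_equal(a.nodata_mask, b.nodata_mask):
        raise FootprintError("nodata masks differ")


@dataclass
class EnvGrid:
    """Co-registered stack of named predictor layers.

    Row 0 is the northern edge; ``origin_lon``/``origin_lat`` give the
    lon/lat of the grid's north-west *corner* in WGS84 decimal degrees.
    """

    layers: dict[str, np.ndarray]
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvGrid needs at least one layer")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"layers have differing shapes: {shapes}")
        shape = shapes.pop()
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape differs from layers")
        for name, arr in self.layers.items():
            self.layers[name] = np.asarray(arr, dtype=float)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def locate(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell (row, col) containing a point; half-open [west, east) x (south, north]."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.ceil((self.origin_lat - lat) / self.cell_size)) - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col

    def valid_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of non-nodata cells, row-major order."""
        rows, cols = np.nonzero(~self.nodata_mask)
        return np.column_stack([rows, cols])

    def table(self) -> "np.ndarray":
        """Predictor matrix over valid cells (n_valid x n_layers), layer order."""
        mask = ~self.nodata_mask
        return np.column_stack([self.layers[n][mask] for n in self.layer_names])


@dataclass
class MembershipSurface:
    """Per-cell membership degrees in [0, 1] over an EnvGrid footprint.

    ``kind`` distinguishes probability of presence, favourability,
    Maxent-style relative suitability, and fuzzy intersections; several
    operations are only defined for specific kinds.  ``provenance`` carries
    the model/species identity and, for favourability, the training
    presence/background counts (n1, n0).
    """

    values: np.ndarray
    kind: str = "probability"
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SURFACE_KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}; expected one of {SURFACE_KINDS}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("membership values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        """Flat array of non-nodata membership values."""
        return self.values[np.isfinite(self.values)]

    def like(self, values: np.ndarray, kind: str, **prov) -> "MembershipSurface":
        """New surface on this footprint with the given values and kind."""
        return MembershipSurface(
            values=values, kind=kind,
            origin_lon=self.origin_lon, origin_lat=self.origin_lat,
            cell_size=self.cell_size, provenance=dict(prov),
        )

    @classmethod
    def from_grid(cls, grid: EnvGrid, values: np.ndarray, kind: str, **prov) -> "MembershipSurface":
        vals = np.asarray(values, dtype=float).copy()
        vals[grid.nodata_mask] = np.nan
        return cls(values=vals, kind=kind, origin_lon=grid.origin_lon,
                   origin_lat=grid.origin_lat, cell_size=grid.cell_size,
                   provenance=dict(prov))

    def check_footprint(self, other: "MembershipSurface") -> None:
        _check_footprint(self, other)


@dataclass
class OccurrenceSet:
    """One species' presence (or background) points in WGS84 degrees."""

    species_id: str
    points: np.ndarray  # (n, 2) array of (lon, lat)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lons(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lats(self) -> np.ndarray:
        return self.points[:, 1]
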