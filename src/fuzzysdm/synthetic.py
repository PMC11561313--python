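"""Virtual landscapes and virtual species.

Every downstream stage of the pipeline (thinning, predictor pruning, SDM
fitting, favourability, fuzzy comparison, evaluation) is exercised on data
from this module, so no external occurrence databases or climate downloads
are needed.  The generator emulates the statistical structure those data
have: a stack of spatially smooth, mutually correlated bioclim-like
predictor layers; species whose probability of presence follows a logistic
response to a few of the layers (optionally with quadratic, i.e. unimodal,
terms); presence records sampled in proportion to that probability; and
uniformly placed random background (pseudo-absence) points.

Random fields are built as white noise convolved with an isotropic Gaussian
kernel whose scale sets spatial smoothness, then linearly mixed (after
empirical orthogonalisation) to hit a requested inter-layer correlation
matrix.  All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import EnvGrid, MembershipSurface, OccurrenceSet

__all__ = [
    "TrueSpecies",
    "make_env_grid",
    "true_probability_surface",
    "sample_occurrences",
    "sample_background",
    "default_study",
]

#: background points used as pseudo-absences, following common SDM practice
DEFAULT_N_BACKGROUND = 10_000


@dataclass
class TrueSpecies:
    """Generating parameters of a virtual species' logistic niche.

    ``intercept`` is the constant of the linear predictor, ``coefficients``
    the linear terms per layer, and ``quadratic`` optional per-layer
    quadratic terms (negative values give unimodal, bell-shaped niches).
    """

    species_id: str
    intercept: float
    coefficients: dict[str, float]
    quadratic: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, grid: EnvGrid) -> np.ndarray:
        for name in list(self.coefficients) + list(self.quadratic):
            if name not in grid.layers:
                raise KeyError(f"species {self.species_id!r} references missing layer {name!r}")
        eta = np.full(grid.shape, float(self.intercept))
        for name, beta in self.coefficients.items():
            eta = eta + beta * grid.layers[name]
        for name, gamma in self.quadratic.items():
            eta = eta + gamma * grid.layers[name] ** 2
        return eta


def make_env_grid(
    seed: int,
    n_rows: int,
    n_cols: int,
    n_layers: int,
    smoothness: float = 5.0,
    target_corr: np.ndarray | None = None,
    origin_lon: float = 110.0,
    origin_lat: float = -10.0,
    cell_size: float = 0.1,
    nodata_fraction: float = 0.0,
) -> EnvGrid:
    """Generate a stack of smooth, mutually correlated random predictor layers.

    Each layer is a standardized Gaussian random field (white noise smoothed
    with an isotropic Gaussian kernel of scale ``smoothness`` cells).  If
    ``target_corr`` is given it must be a symmetric positive-definite matrix
    with unit diagonal; the layers are orthogonalised and re-mixed through
    its Cholesky factor so the achieved pairwise Pearson correlations match
    it closely.  ``nodata_fraction`` punches that share of random nodata
    holes (shared by all layers), emulating ocean/masked cells.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)

    fields = np.empty((n_layers, n_rows, n_cols))
    for k in range(n_layers):
        noise = rng.standard_normal((n_rows, n_cols))
        fields[k] = gaussian_filter(noise, sigma=smoothness, mode="reflect")

    flat = fields.reshape(n_layers, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)

    if target_corr is not None:
        target_corr = np.asarray(target_corr, dtype=float)
        if target_corr.shape != (n_layers, n_layers):
            raise ValueError(f"target_corr must be {n_layers}x{n_layers}")
        if not np.allclose(target_corr, target_corr.T):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(target_corr), 1.0):
            raise ValueError("target_corr must have unit diagonal")
        try:
            chol = np.linalg.cholesky(target_corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "target_corr is not positive definite; supply a valid correlation matrix"
            ) from exc
        # empirical orthogonalisation so the Cholesky mix hits the target
        # correlations almost exactly, not just in expectation
        q, _ = np.linalg.qr(flat.T)
        basis = q.T * np.sqrt(flat.shape[1])
        flat = chol @ basis

    layers = {f"env{k + 1}": flat[k].reshape(n_rows, n_cols) for k in range(n_layers)}

    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if nodata_fraction > 0:
        n_holes = int(round(nodata_fraction * n_rows * n_cols))
        idx = rng.choice(n_rows * n_cols, size=n_holes, replace=False)
        mask.flat[idx] = True

    return EnvGrid(layers=layers, origin_lon=origin_lon, origin_lat=origin_lat,
                   cell_size=cell_size, nodata_mask=mask)


def true_probability_surface(grid: EnvGrid, sp: TrueSpecies) -> MembershipSurface:
    """Per-cell true probability of presence: logistic of the species' linear predictor."""
    p = expit(sp.linear_predictor(grid))
    return MembershipSurface.from_grid(grid, p, kind="probability",
                                       species_id=sp.species_id, source="true")


def sample_occurrences(p_surface: MembershipSurface, n_presences: int, seed: int) -> OccurrenceSet:
    """Draw presence cells without replacement with probability proportional to P.

    Points are placed at cell centers so later raster extraction is exact.
    """
    vals = p_surface.values
    rows, cols = np.nonzero(np.isfinite(vals))
    weights = vals[rows, cols]
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot sample occurrences: probability surface is all zero")
    n_support = int((weights > 0).sum())
    if n_presences > n_support:
        raise ValueError(
            f"n_presences={n_presences} exceeds the {n_support} cells with positive probability"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(weights), size=n_presences, replace=False, p=weights / total)
    pts = [_cell_center(p_surface, rows[i], cols[i]) for i in chosen]
    sp_id = p_surface.provenance.get("species_id", "virtual")
    return OccurrenceSet(species_id=sp_id, points=np.array(pts).reshape(-1, 2))


def sample_background(
    grid: EnvGrid,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
    replace: bool = False,
) -> OccurrenceSet:
    """Uniform random background (pseudo-absence) points over valid cells."""
    cells = grid.valid_cells()
    if len(cells) == 0:
        raise ValueError("grid has no valid cells to sample background from")
    if not replace and n_background > len(cells):
        raise ValueError(
            f"n_background={n_background} exceeds {len(cells)} valid cells; "
            "pass replace=True to sample with replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n_background, replace=replace)
    pts = [grid.cell_center(r, c) for r, c in cells[idx]]
    return OccurrenceSet(species_id="background", points=np.array(pts).reshape(-1, 2))


def _cell_center(surface: MembershipSurface, row: int, col: int) -> tuple[float, float]:
    lon = surface.origin_lon + (col + 0.5) * surface.cell_size
    lat = surface.origin_lat - (row + 0.5) * surface.cell_size
    return lon, lat


def default_study(
    seed: int = 0,
    n_rows: int = 100,
    n_cols: int = 100,
    n_background: int = DEFAULT_N_BACKGROUND,
    prevalence_a: float = 0.10,
    prevalence_b: float = 0.02,
    smoothness: float = 6.0,
):
    """The default two-species virtual study.

    Three correlated predictor layers; two species sharing two niche axes,
    a widespread species A (prevalence ~0.10 against the background sample)
    and a restricted species B (~0.02), mirroring the restricted-versus-
    widespread contrast that motivates prevalence-free favourability.

    Returns ``(grid, species_a, species_b, occ_a, occ_b, background)``.
    """
    corr = np.array([[1.0, 0.6, 0.2],
                     [0.6, 1.0, 0.3],
                     [0.2, 0.3, 1.0]])
    grid = make_env_grid(seed, n_rows, n_cols, 3, smoothness=smoothness, target_corr=corr)
    sp_a = TrueSpecies("species_a", intercept=-0.5,
                       coefficients={"env1": 2.0, "env2": 1.2},
                       quadratic={"env1": -0.8})
    sp_b = TrueSpecies("species_b", intercept=-2.0,
                       coefficients={"env1": 1.6, "env3": 1.5},
                       quadratic={"env1": -0.8})
    p_a = true_probability_surface(grid, sp_a)
    p_b = true_probability_surface(grid, sp_b)
    n1_a = int(round(prevalence_a / (1 - prevalence_a) * n_background))
    n1_b = int(round(prevalence_b / (1 - prevalence_b) * n_background))
    occ_a = sample_occurrences(p_a, n1_a, seed=seed + 1)
    occ_b = sample_occurrences(p_b, n1_b, seed=seed + 2)
    background = sample_background(grid, n_background, seed=seed + 3, replace=True)
    return grid, sp_a, sp_b, occ_a, occ_b, background
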