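"""Environmental favourability and fuzzy comparison of membership surfaces.

The favourability function turns a model's probability of presence P into a
prevalence-free fuzzy membership degree F in the set "areas favourable to
the species".  With n1 training presences and n0 background/absence sites,

    F = (P / (1 - P)) / (n1/n0 + P / (1 - P))

so F = 0.5 exactly where P equals the training prevalence n1/(n1+n0),
and F = P when n1 = n0.  For a logistic model this is algebraically the
logistic of (alpha - ln(n1/n0)) + sum(beta_i * x_i): the same model with
its intercept shifted to remove the prevalence term, which is what makes
favourability comparable across species with different prevalences.

On favourability surfaces the module provides the classic fuzzy-set
operations (cellwise min / max), the fuzzy overlap index
FOvI = sum(min) / sum(max), fuzzy and binary Jaccard similarity matrices,
a ten-bin shared-favourability profile with confidence intervals, and
Kosko's fuzzy entropy sum(min(mu, 1-mu)) / sum(max(mu, 1-mu)) as an
uncertainty indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import MembershipSurface

__all__ = [
    "favourability",
    "favourability_surface",
    "fuzzy_intersection",
    "fuzzy_union",
    "fuzzy_overlap_index",
    "similarity_matrix",
    "shared_favourability_profile",
    "fuzzy_entropy",
    "SharedFavProfile",
]


def favourability(p, n1: int, n0: int):
    """Prevalence-free favourability of probability ``p`` (scalar or array).

    ``n1`` and ``n0`` are the presence and background/absence counts of the
    model that produced ``p``; the limits F(0) = 0 and F(1) = 1 are taken.
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("favourability needs n1 >= 1 and n0 >= 1 (prevalence undefined)")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    ratio = n1 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p / (1.0 - p)
        f = odds / (ratio + odds)
    f = np.where(p == 1.0, 1.0, f)
    f = np.where(p == 0.0, 0.0, f)
    return float(f) if f.ndim == 0 else f


def favourability_surface(p_surface: MembershipSurface, n1: int, n0: int) -> MembershipSurface:
    """Elementwise favourability transform of a probability surface.

    Relative-suitability surfaces (Maxent-style cumulative output) are
    rejected: they are not probabilities of presence, so the prevalence
    correction is undefined for them.
    """
    if p_surface.kind != "probability":
        raise ValueError(
            f"favourability is defined for probability surfaces, not {p_surface.kind!r}; "
            "relative-suitability output is compared as-is, never converted"
        )
    vals = favourability(p_surface.values, n1, n0)
    prov = dict(p_surface.provenance)
    prov.update(n1=int(n1), n0=int(n0))
    out = p_surface.like(vals, kind="favourability")
    out.provenance = prov
    return out


def _paired_valid(a: MembershipSurface, b: MembershipSurface):
    a.check_footprint(b)
    mask = np.isfinite(a.values)
    return a.values[mask], b.values[mask]


def fuzzy_intersection(f_a: MembershipSurface, f_b: MembershipSurface) -> MembershipSurface:
    """Cellwise minimum: simultaneous membership in both species' favourable sets."""
    f_a.check_footprint(f_b)
    return f_a.like(np.minimum(f_a.values, f_b.values), kind="intersection",
                    operands=[f_a.provenance, f_b.provenance])


def fuzzy_union(f_a: MembershipSurface, f_b: MembershipSurface) -> MembershipSurface:
    """Cellwise maximum of two membership surfaces."""
    f_a.check_footprint(f_b)
    return f_a.like(np.maximum(f_a.values, f_b.values), kind="intersection",
                    operands=[f_a.provenance, f_b.provenance])


def fuzzy_overlap_index(f_a: MembershipSurface, f_b: MembershipSurface) -> float:
    """FOvI = sum(min) / sum(max) over valid cells.

    0 means no distributional overlap, 1 identical distributions.
    """
    va, vb = _paired_valid(f_a, f_b)
    denom = np.maximum(va, vb).sum()
    if denom == 0:
        raise ValueError("fuzzy overlap undefined: both surfaces are identically zero")
    return float(np.minimum(va, vb).sum() / denom)


def _crisp(values: np.ndarray, threshold: float) -> np.ndarray:
    return (values >= threshold).astype(float)


def similarity_matrix(
    surfaces: list[MembershipSurface],
    mode: str = "fuzzy",
    labels: list[str] | None = None,
    binary_threshold: float = 0.5,
) -> pd.DataFrame:
    """Pairwise Jaccard similarity between membership surfaces.

    ``fuzzy`` mode uses the fuzzy Jaccard sum(min)/sum(max) (identical to
    FOvI); ``binary`` mode first crisps each surface at ``binary_threshold``
    and computes the ordinary Jaccard index of the resulting cell sets.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces")
    if mode not in ("fuzzy", "binary"):
        raise ValueError("mode must be 'fuzzy' or 'binary'")
    if labels is None:
        labels = [s.provenance.get("species_id", f"s{i}") for i, s in enumerate(surfaces)]
    n = len(surfaces)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            va, vb = _paired_valid(surfaces[i], surfaces[j])
            if mode == "binary":
                va, vb = _crisp(va, binary_threshold), _crisp(vb, binary_threshold)
            denom = np.maximum(va, vb).sum()
            out[i, j] = out[j, i] = (np.minimum(va, vb).sum() / denom) if denom > 0 else 0.0
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class SharedFavProfile:
    """Per-bin summary of two species' favourability along their fuzzy overlap.

    Cells are binned by their cellwise overlap o = min(F_A, F_B) into
    ``n_bins`` equal-width intervals of [0, 1] (last bin right-closed);
    each bin reports the mean favourability of both species with symmetric
    t-based confidence intervals.  Bins holding fewer than two cells are
    flagged and get no interval.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame  # columns: n_cells, mean_F_A, mean_F_B, ci_*_low/high, flagged
    fovi: float
    confidence: float

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def shared_favourability_profile(
    f_a: MembershipSurface,
    f_b: MembershipSurface,
    n_bins: int = 10,
    confidence: float = 0.95,
) -> SharedFavProfile:
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    va, vb = _paired_valid(f_a, f_b)
    overlap = np.minimum(va, vb)
    # exact b/n_bins edges so decimal boundary values land in the upper bin
    edges = np.arange(n_bins + 1) / n_bins
    idx = np.digitize(overlap, edges[1:-1], right=False)

    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        row = {"bin": b, "lo": edges[b], "hi": edges[b + 1], "n_cells": n,
               "mean_F_A": np.nan, "mean_F_B": np.nan,
               "ci_A_low": np.nan, "ci_A_high": np.nan,
               "ci_B_low": np.nan, "ci_B_high": np.nan,
               "flagged": n < 2}
        if n >= 1:
            row["mean_F_A"] = float(va[sel].mean())
            row["mean_F_B"] = float(vb[sel].mean())
        if n >= 2:
            tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
            for key, vals in (("A", va[sel]), ("B", vb[sel])):
                half = tcrit * vals.std(ddof=1) / np.sqrt(n)
                row[f"ci_{key}_low"] = float(vals.mean() - half)
                row[f"ci_{key}_high"] = float(vals.mean() + half)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("bin")
    return SharedFavProfile(bin_edges=edges, table=table,
                            fovi=fuzzy_overlap_index(f_a, f_b), confidence=confidence)


def fuzzy_entropy(surface: MembershipSurface) -> float:
    """Kosko fuzzy entropy: 0 for a crisp surface, 1 when all memberships are 0.5."""
    mu = surface.valid_values
    if mu.size == 0:
        raise ValueError("fuzzy entropy undefined on an empty surface")
    denom = np.maximum(mu, 1.0 - mu).sum()
    return float(np.minimum(mu, 1.0 - mu).sum() / denom)


def plot_shared_favourability(profile: SharedFavProfile, ax=None, labels=("species A", "species B")):
    """Shared-favourability plot: solid line species A, dashed species B, ten-bin x-axis."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = profile.table
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    ok = t["n_cells"] > 0
    ax.plot(centers[ok], t.loc[ok, "mean_F_A"], "-", marker="o", label=labels[0])
    ax.plot(centers[ok], t.loc[ok, "mean_F_B"], "--", marker="s", label=labels[1])
    ci = t["n_cells"] >= 2
    ax.fill_between(centers[ci], t.loc[ci, "ci_A_low"], t.loc[ci, "ci_A_high"], alpha=0.2)
    ax.fill_between(centers[ci], t.loc[ci, "ci_B_low"], t.loc[ci, "ci_B_high"], alpha=0.2)
    ax.axvspan(0.2, 0.8, color="grey", alpha=0.15)
    ax.set_xlabel("fuzzy overlap (min favourability) bin")
    ax.set_ylabel("mean favourability")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
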