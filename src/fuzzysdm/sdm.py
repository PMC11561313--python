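"""Presence/background species distribution models.

Four model families, all trained on a site-by-predictor table with a
binary response (1 = presence record, 0 = random background point treated
as a pseudo-absence):

* ``glm``   -- maximum-likelihood logistic regression (linear logit).
* ``gam``   -- logistic regression on per-predictor cubic B-spline bases
               with a ridge penalty chosen by internal cross-validation; a
               penalized-basis stand-in for backfitting smoothers that
               keeps the logistic algebra (and hence the favourability
               intercept identity) intact.
* ``brt``   -- stochastic gradient boosting with Bernoulli deviance; the
               number of trees is picked at the held-out deviance minimum.
* ``maxent_like`` -- an L1-regularized logistic / point-process surrogate
               on linear + quadratic features whose raw intensity is
               converted to the familiar cumulative (0-100) representation;
               its output is *relative* habitat suitability, never a
               probability of presence.

Model skill is summarized by stratified k-fold cross-validation repeated
several times, with AUC, TSS, CCR, sensitivity, and specificity per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

from . import evaluation
from .grids import EnvGrid, MembershipSurface, OccurrenceSet

__all__ = ["ModelTable", "FittedSDM", "build_table", "fit_glm", "fit_gam",
           "fit_brt", "fit_maxent_like", "fit", "crossvalidate", "predict_surface"]

ALGORITHMS = ("glm", "gam", "brt", "maxent_like")


@dataclass
class ModelTable:
    """Site x predictor table with a binary response."""

    predictors: pd.DataFrame
    response: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=int)
        if len(self.predictors) != len(self.response):
            raise ValueError("predictors and response length mismatch")
        if self.predictors.isna().any().any():
            raise ValueError("predictor table contains missing values")

    @property
    def n1(self) -> int:
        return int(self.response.sum())

    @property
    def n0(self) -> int:
        return int(len(self.response) - self.n1)

    @property
    def prevalence(self) -> float:
        return self.n1 / (self.n1 + self.n0)

    def subset(self, idx) -> "ModelTable":
        return ModelTable(self.predictors.iloc[idx].reset_index(drop=True),
                          self.response[idx])


@dataclass
class FittedSDM:
    """A fitted model exposing ``predict(X) -> values in [0, 1]``.

    ``output_kind`` is ``probability`` for glm/gam/brt and
    ``relative_suitability`` for the Maxent-like model (cumulative values
    rescaled to [0, 1]).
    """

    algorithm: str
    predict_fn: Callable[[pd.DataFrame], np.ndarray]
    feature_names: list[str]
    n1: int
    n0: int
    output_kind: str = "probability"
    parameters: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"prediction input is missing predictors: {missing}")
        out = np.asarray(self.predict_fn(X[self.feature_names]), dtype=float)
        return np.clip(out, 0.0, 1.0)


def build_table(grid: EnvGrid, presences: OccurrenceSet,
                background: OccurrenceSet,
                layer_names: list[str] | None = None) -> ModelTable:
    """Extract predictor values at presence and background points.

    Every point must fall inside the grid on a non-nodata cell; offending
    points are listed in the error.
    """
    names = layer_names if layer_names is not None else grid.layer_names
    rows, bad = [], []
    for label, occ in (("presence", presences), ("background", background)):
        for lon, lat in occ.points:
            try:
                r, c = grid.locate(lon, lat)
            except ValueError:
                bad.append((label, lon, lat, "outside grid"))
                continue
            if grid.nodata_mask[r, c]:
                bad.append((label, lon, lat, "nodata cell"))
                continue
            rows.append([grid.layers[n][r, c] for n in names] + [1 if label == "presence" else 0])
    if bad:
        detail = "; ".join(f"{l} ({x:.5f}, {y:.5f}): {why}" for l, x, y, why in bad[:10])
        raise ValueError(f"{len(bad)} point(s) could not be extracted: {detail}")
    arr = np.asarray(rows)
    return ModelTable(pd.DataFrame(arr[:, :-1], columns=names), arr[:, -1])


def _check_fittable(table: ModelTable) -> None:
    if table.n1 < 1 or table.n0 < 1:
        raise ValueError("model table must contain both presences and background sites")


# ---------------------------------------------------------------------------
# GLM

def fit_glm(table: ModelTable) -> FittedSDM:
    """Maximum-likelihood logistic regression (linear logit)."""
    _check_fittable(table)
    X = sm.add_constant(table.predictors.to_numpy(), has_constant="add")
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(table.response, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            params = res.params
            bse = res.bse
        except Exception:
            # complete/quasi-separation: small-ridge fallback, flagged
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0, maxiter=500)
            params = np.asarray(res.params)
            bse = np.full_like(params, np.nan)
            flags.append("separation: penalized fallback fit")
    names = list(table.predictors.columns)
    alpha = float(params[0])
    betas = {n: float(b) for n, b in zip(names, params[1:])}

    def predict_fn(X: pd.DataFrame) -> np.ndarray:
        eta = alpha + X.to_numpy() @ np.array([betas[n] for n in names])
        return expit(eta)

    return FittedSDM(algorithm="glm", predict_fn=predict_fn, feature_names=names,
                     n1=table.n1, n0=table.n0,
                     parameters={"alpha": alpha, "betas": betas,
                                 "se": {n: float(s) for n, s in zip(["const"] + names, bse)}},
                     flags=flags)


# ---------------------------------------------------------------------------
# GAM

def fit_gam(table: ModelTable, basis_df: int = 4, cv: int = 5, seed: int = 0) -> FittedSDM:
    """Penalized spline logistic regression (GAM-style smooth responses).

    Each predictor is expanded into ``basis_df`` cubic B-spline functions
    (quantile knots); the ridge penalty is selected by internal
    cross-validation over a small grid.
    """
    _check_fittable(table)
    names = list(table.predictors.columns)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("spline", SplineTransformer(n_knots=max(basis_df - 1, 2), degree=3,
                                     include_bias=False)),
        ("logit", LogisticRegressionCV(Cs=np.logspace(-3, 3, 7), cv=cv,
                                       l1_ratios=(0.0,), scoring="neg_log_loss",
                                       max_iter=2000,
                                       random_state=seed)),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(table.predictors.to_numpy(), table.response)

    def predict_fn(X: pd.DataFrame) -> np.ndarray:
        return pipe.predict_proba(X.to_numpy())[:, 1]

    logit = pipe.named_steps["logit"]
    return FittedSDM(algorithm="gam", predict_fn=predict_fn, feature_names=names,
                     n1=table.n1, n0=table.n0,
                     parameters={"basis_df": basis_df, "C": float(logit.C_[0]),
                                 "alpha": float(logit.intercept_[0]),
                                 "coefficients": logit.coef_[0].tolist()})


# ---------------------------------------------------------------------------
# BRT

def fit_brt(table: ModelTable, learning_rate: float = 0.01, tree_depth: int = 3,
            max_trees: int = 1000, seed: int = 0) -> FittedSDM:
    """Boosted regression trees with Bernoulli deviance.

    The number of trees is chosen at the minimum held-out deviance on a
    stratified 20% validation split, then the model is refit on all rows.
    """
    _check_fittable(table)
    names = list(table.predictors.columns)
    X = table.predictors.to_numpy()
    y = table.response
    X_tr, X_va, y_tr, y_va = train_test_split(X, y, test_size=0.2, stratify=y,
                                              random_state=seed)
    probe = GradientBoostingClassifier(learning_rate=learning_rate,
                                       max_depth=tree_depth,
                                       n_estimators=max_trees,
                                       subsample=0.75, random_state=seed)
    probe.fit(X_tr, y_tr)
    dev = []
    eps = 1e-12
    for p in probe.staged_predict_proba(X_va):
        q = np.clip(p[:, 1], eps, 1 - eps)
        dev.append(-2 * np.mean(y_va * np.log(q) + (1 - y_va) * np.log(1 - q)))
    n_trees = int(np.argmin(dev)) + 1
    model = GradientBoostingClassifier(learning_rate=learning_rate,
                                       max_depth=tree_depth,
                                       n_estimators=n_trees,
                                       subsample=0.75, random_state=seed)
    model.fit(X, y)

    def predict_fn(Xq: pd.DataFrame) -> np.ndarray:
        return model.predict_proba(Xq.to_numpy())[:, 1]

    return FittedSDM(algorithm="brt", predict_fn=predict_fn, feature_names=names,
                     n1=table.n1, n0=table.n0,
                     parameters={"learning_rate": learning_rate,
                                 "tree_depth": tree_depth, "n_trees": n_trees})


# ---------------------------------------------------------------------------
# Maxent-like

def _cumulative(raw: np.ndarray) -> np.ndarray:
    """Cumulative representation: 100 x summed normalized weight of cells
    with raw value <= this cell's (ties share one value)."""
    raw = np.asarray(raw, dtype=float)
    w = raw / raw.sum()
    order = np.argsort(raw, kind="stable")
    csum = np.cumsum(w[order])
    # assign every tied value the cumulative weight through the last tie
    sorted_raw = raw[order]
    out = np.empty_like(raw)
    last_of_value = np.searchsorted(sorted_raw, sorted_raw, side="right") - 1
    out[order] = csum[last_of_value]
    return 100.0 * out


def fit_maxent_like(presences: ModelTable | pd.DataFrame,
                    background: ModelTable | pd.DataFrame | None = None,
                    regularization: float = 1.0, seed: int = 0) -> FittedSDM:
    """L1-regularized logistic/PPM surrogate with cumulative output.

    Accepts either one combined :class:`ModelTable` or separate presence
    and background predictor frames.  Features are standardized linear and
    quadratic terms of every predictor.  ``predict`` returns the cumulative
    representation of the raw exp-linear intensity, computed *within the
    queried cell set* and rescaled to [0, 1]; this is relative habitat
    suitability, not probability of presence.
    """
    if isinstance(presences, ModelTable) and background is None:
        table = presences
    else:
        pres = presences.predictors if isinstance(presences, ModelTable) else pd.DataFrame(presences)
        back = background.predictors if isinstance(background, ModelTable) else pd.DataFrame(background)
        table = ModelTable(pd.concat([pres, back], ignore_index=True),
                           np.concatenate([np.ones(len(pres), int), np.zeros(len(back), int)]))
    _check_fittable(table)
    if table.n0 < 2 * table.n1:
        warnings.warn("background sample is not much larger than the presence sample; "
                      "the point-process approximation may be poor", stacklevel=2)
    if (table.predictors.nunique() <= 1).all():
        raise ValueError("all predictors are constant; Maxent-like fit undefined")
    names = list(table.predictors.columns)

    def expand(X: pd.DataFrame) -> np.ndarray:
        A = X.to_numpy()
        return np.hstack([A, A ** 2])

    scaler = StandardScaler().fit(expand(table.predictors))
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / regularization,
                             solver="liblinear", max_iter=2000, random_state=seed)
    clf.fit(scaler.transform(expand(table.predictors)), table.response)

    def predict_fn(X: pd.DataFrame) -> np.ndarray:
        eta = (scaler.transform(expand(X)) @ clf.coef_[0]) + clf.intercept_[0]
        raw = np.exp(eta - eta.max())  # relative intensity, overflow-safe
        return _cumulative(raw) / 100.0

    return FittedSDM(algorithm="maxent_like", predict_fn=predict_fn,
                     feature_names=names, n1=table.n1, n0=table.n0,
                     output_kind="relative_suitability",
                     parameters={"regularization": regularization,
                                 "weights": clf.coef_[0].tolist(),
                                 "intercept": float(clf.intercept_[0])})


_FITTERS = {"glm": fit_glm, "gam": fit_gam, "brt": fit_brt, "maxent_like": fit_maxent_like}


def fit(table: ModelTable, algorithm: str, **kwargs) -> FittedSDM:
    """Fit a table with one of the supported algorithms."""
    if algorithm not in _FITTERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    return _FITTERS[algorithm](table, **kwargs)


# ---------------------------------------------------------------------------
# Cross-validation

def crossvalidate(table: ModelTable, algorithm: str, k: int = 5, reps: int = 10,
                  seed: int = 0, threshold_rule="prevalence", **fit_kwargs) -> pd.DataFrame:
    """Stratified k-fold cross-validation repeated ``reps`` times.

    Returns a tidy frame with one row per (replicate, fold) carrying AUC,
    TSS, CCR, sensitivity, specificity, and the threshold used.
    """
    if table.n1 < k:
        raise ValueError(f"k={k} folds require at least {k} presences (have {table.n1})")
    records = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(skf.split(table.predictors, table.response)):
            train = table.subset(tr)
            model = fit(train, algorithm, **fit_kwargs)
            test = table.subset(te)
            pred = model.predict(test.predictors)
            # thresholds come from the training fold only
            if threshold_rule == "maxTSS":
                thr = evaluation.resolve_threshold(
                    "maxTSS", train.response, model.predict(train.predictors))
            else:
                thr = evaluation.resolve_threshold(threshold_rule, train.response, pred)
            rpt = evaluation.classification_metrics(test.response, pred, thr)
            records.append({"replicate": rep, "fold": fold, "AUC": rpt.auc,
                            "TSS": rpt.tss, "CCR": rpt.ccr,
                            "Sensitivity": rpt.sensitivity,
                            "Specificity": rpt.specificity, "threshold": thr})
    return pd.DataFrame(records)


def predict_surface(model: FittedSDM, grid: EnvGrid) -> MembershipSurface:
    """Predict over every valid grid cell; nodata propagates as NaN."""
    missing = [n for n in model.feature_names if n not in grid.layers]
    if missing:
        raise KeyError(f"grid is missing predictor layer(s): {missing}")
    mask = ~grid.nodata_mask
    X = pd.DataFrame({n: grid.layers[n][mask] for n in model.feature_names})
    vals = np.full(grid.shape, np.nan)
    vals[mask] = model.predict(X)
    kind = "probability" if model.output_kind == "probability" else "relative_suitability"
    return MembershipSurface.from_grid(grid, vals, kind=kind,
                                      algorithm=model.algorithm,
                                      n1=model.n1, n0=model.n0)
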