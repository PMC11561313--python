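"""Discrimination, classification, and calibration metrics for SDMs.

Discrimination: rank-based AUC (Mann-Whitney with midrank ties, equal to
the trapezoidal ROC area).  Classification at a threshold: sensitivity,
specificity, TSS = Se + Sp - 1, and the correct classification rate.
Calibration: the Hosmer-Lemeshow goodness-of-fit test on equal-frequency
(decile) bins of the predicted probability, reporting the chi-squared
statistic, its upper-tail p-value at n_bins - 2 degrees of freedom, and an
RMSE over the per-bin observed-minus-expected presence counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["auc", "classification_metrics", "hosmer_lemeshow",
           "evaluate_model", "EvalReport", "HLReport"]


def _as_binary(obs) -> np.ndarray:
    obs = np.asarray(obs)
    uniq = np.unique(obs)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("observations must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("observations contain a single class; metrics undefined")
    return obs.astype(int)


def auc(obs, pred) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic."""
    obs = _as_binary(obs)
    pred = np.asarray(pred, dtype=float)
    n1 = int(obs.sum())
    n0 = len(obs) - n1
    ranks = stats.rankdata(pred)  # midranks for ties
    return float((ranks[obs == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class EvalReport:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tss: float
    ccr: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {"AUC": self.auc, "threshold": self.threshold, "TSS": self.tss,
                "CCR": self.ccr, "Sensitivity": self.sensitivity,
                "Specificity": self.specificity,
                "TP": tp, "FP": fp, "TN": tn, "FN": fn}


def classification_metrics(obs, pred, threshold: float) -> EvalReport:
    """Confusion-matrix metrics at ``pred >= threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    obs = _as_binary(obs)
    pred = np.asarray(pred, dtype=float)
    hit = pred >= threshold
    tp = int(np.sum(hit & (obs == 1)))
    fp = int(np.sum(hit & (obs == 0)))
    tn = int(np.sum(~hit & (obs == 0)))
    fn = int(np.sum(~hit & (obs == 1)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return EvalReport(auc=auc(obs, pred), threshold=float(threshold),
                      sensitivity=se, specificity=sp, tss=se + sp - 1.0,
                      ccr=(tp + tn) / len(obs), confusion=(tp, fp, tn, fn))


@dataclass
class HLReport:
    chi_sq: float
    df: int
    p_value: float
    rmse: float
    bin_table: pd.DataFrame  # per bin: n, observed O1, expected E1, mean predicted, flagged

    def to_dict(self) -> dict:
        return {"Chi.sq": self.chi_sq, "df": self.df, "P-value": self.p_value,
                "RMSE": self.rmse}


_GUARD = 0.5  # small-count continuity guard for empty expected cells


def hosmer_lemeshow(obs, pred, n_bins: int = 10) -> HLReport:
    """Hosmer-Lemeshow calibration test on equal-frequency probability bins.

    Ties on a quantile edge go to the lower bin.  The chi-squared statistic
    sums (O - E)^2 / E over presences and absences in every bin, with
    E1 = sum of predictions in the bin; degrees of freedom n_bins - 2.
    RMSE is the root of the mean squared per-bin error in *counts* of
    observed vs expected presences.  Bins with a zero expected count are
    computed with a small guard and flagged.
    """
    obs = _as_binary(obs)
    pred = np.asarray(pred, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    n = len(obs)
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} observations for {n_bins} bins")

    inner = np.quantile(pred, np.arange(1, n_bins) / n_bins)
    idx = np.searchsorted(inner, pred, side="left")

    chi = 0.0
    sq_err = []
    rows = []
    for b in range(n_bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            rows.append({"bin": b, "n": 0, "O1": 0, "E1": 0.0,
                         "mean_pred": np.nan, "flagged": True})
            continue
        o1 = int(obs[sel].sum())
        e1 = float(pred[sel].sum())
        o0, e0 = nb - o1, nb - e1
        flagged = e1 <= 0 or e0 <= 0
        chi += (o1 - e1) ** 2 / (e1 if e1 > 0 else _GUARD)
        chi += (o0 - e0) ** 2 / (e0 if e0 > 0 else _GUARD)
        sq_err.append((o1 - e1) ** 2)
        rows.append({"bin": b, "n": nb, "O1": o1, "E1": e1,
                     "mean_pred": float(pred[sel].mean()), "flagged": flagged})
    df = n_bins - 2
    return HLReport(chi_sq=float(chi), df=df,
                    p_value=float(stats.chi2.sf(chi, df)),
                    rmse=float(np.sqrt(np.mean(sq_err))),
                    bin_table=pd.DataFrame(rows).set_index("bin"))


def resolve_threshold(rule, obs, pred) -> float:
    """Threshold rules: 'prevalence' (default), ('fixed', t), or 'maxTSS'."""
    obs = np.asarray(obs)
    if rule == "prevalence":
        return float(np.mean(obs))
    if isinstance(rule, tuple) and rule[0] == "fixed":
        return float(rule[1])
    if rule == "maxTSS":
        cand = np.unique(np.asarray(pred, dtype=float))
        best_t, best_tss = cand[0], -np.inf
        for t in cand:
            r = classification_metrics(obs, pred, min(max(t, 0.0), 1.0))
            if r.tss > best_tss:
                best_t, best_tss = t, r.tss
        return float(best_t)
    raise ValueError(f"unknown threshold rule {rule!r}")


def evaluate_model(model, table, threshold_rule="prevalence",
                   hl_bins: int = 10) -> tuple[EvalReport, HLReport | None, str | None]:
    """Full evaluation of a fitted SDM on a model table.

    Returns ``(eval_report, hl_report, hl_skip_reason)``.  The calibration
    test is skipped for relative-suitability output (Maxent-style cumulative
    values are not probabilities of presence, so observed-vs-expected
    frequencies are meaningless for them) with the reason recorded.
    """
    obs = table.response
    pred = model.predict(table.predictors)
    threshold = resolve_threshold(threshold_rule, obs, pred)
    report = classification_metrics(obs, pred, threshold)
    if model.output_kind == "relative_suitability":
        return report, None, ("relative-suitability output is not a probability "
                              "of presence; HL calibration test not applicable")
    return report, hosmer_lemeshow(obs, pred, n_bins=hl_bins), None
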