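"""Performance statistics: R^2, confusion matrices, ACC/Sn/Sp/MCC, Cohen's d
effect sizes, and the predicted-time-awake > 24 hr classifier."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "RegressionFit",
    "EffectSize",
    "r_squared",
    "confusion",
    "metrics",
    "cohens_d",
    "effect_size_matrix",
    "classify_gt24",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassificationMetrics:
    """ACC, Sn, Sp in [0,1]; MCC in [-1,1]; undefined ratios are NaN."""

    acc: float
    sn: float
    sp: float
    mcc: float

    def rounded(self) -> dict:
        """Whole-percent ACC/Sn/Sp and 2-decimal MCC, the summary-table style."""
        pct = lambda v: float("nan") if math.isnan(v) else round(100.0 * v)
        return {
            "ACC%": pct(self.acc),
            "Sn%": pct(self.sn),
            "Sp%": pct(self.sp),
            "MCC": float("nan") if math.isnan(self.mcc) else round(self.mcc, 2),
        }


@dataclass(frozen=True)
class RegressionFit:
    observed: np.ndarray
    predicted: np.ndarray
    r2: float


@dataclass(frozen=True)
class EffectSize:
    m1: float
    m2: float
    s_pooled: float
    d: float


def r_squared(y, yhat) -> RegressionFit:
    """R^2 = 1 - SSres/SStot with the mean taken over the evaluated set.
    May be negative on validation data."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return RegressionFit(observed=y, predicted=yhat, r2=1.0 - ss_res / ss_tot)


def confusion(true_class, score, boundary: float = 0.5,
              probability_mode: bool = True) -> ConfusionMatrix:
    """Count TP/FP/FN/TN at a decision boundary.

    Predicted positive iff score > boundary; a score exactly at the boundary
    classifies negative.  In probability mode the scores must lie in [0, 1].
    """
    t = np.asarray(true_class).ravel().astype(int)
    s = np.asarray(score, dtype=float).ravel()
    if len(t) != len(s):
        raise ValueError("length mismatch")
    if set(np.unique(t)) - {0, 1}:
        raise ValueError("true_class must be binary 0/1")
    if probability_mode and ((s < 0) | (s > 1)).any():
        raise ValueError("probability scores must lie in [0, 1]")
    pred = s > boundary
    return ConfusionMatrix(
        tp=int(np.sum(pred & (t == 1))),
        fp=int(np.sum(pred & (t == 0))),
        fn=int(np.sum(~pred & (t == 1))),
        tn=int(np.sum(~pred & (t == 0))),
    )


def metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """ACC = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Zero denominators give NaN, never 0."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    total = cm.total
    acc = (tp + tn) / total if total else float("nan")
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else float("nan")
    return ClassificationMetrics(acc=acc, sn=sn, sp=sp, mcc=mcc)


def cohens_d(group1, group2) -> EffectSize:
    """Standardized mean difference (group1 - group2) in pooled-SD units."""
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = len(g1), len(g2)
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    s_pooled = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    m1, m2 = float(g1.mean()), float(g2.mean())
    return EffectSize(m1=m1, m2=m2, s_pooled=s_pooled, d=(m1 - m2) / s_pooled)


def effect_size_matrix(predicted, observed_levels) -> pd.DataFrame:
    """Antisymmetric matrix of Cohen's d between predictions grouped by the
    observed level (e.g. predicted time awake grouped by true sampling time).
    Levels with fewer than 2 samples give NaN rows/columns."""
    pred = np.asarray(predicted, dtype=float).ravel()
    obs = np.asarray(observed_levels).ravel()
    levels = np.unique(obs)
    if len(levels) < 2:
        raise ValueError("need at least 2 observed levels")
    groups = {lv: pred[obs == lv] for lv in levels}
    out = pd.DataFrame(np.zeros((len(levels), len(levels))), index=levels, columns=levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                out.loc[a, b] = out.loc[b, a] = float("nan")
                continue
            try:
                d = cohens_d(groups[a], groups[b]).d
            except ValueError:
                d = float("nan")
            out.loc[a, b] = d
            out.loc[b, a] = -d
    return out


def classify_gt24(predicted_time_awake) -> np.ndarray:
    """Positive ('awake > 24 hr') iff the predicted value exceeds 24;
    exactly 24 classifies negative."""
    pred = np.asarray(predicted_time_awake, dtype=float)
    return (pred > 24.0).astype(int)


def plot_observed_vs_predicted(fit: RegressionFit, ax=None, boundary: float | None = None):
    """Scatter of predicted against observed values with the line of unity;
    an optional horizontal decision boundary (e.g. 24 h) is drawn dashed.
    Requires matplotlib (the ``plot`` extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(fit.observed, fit.predicted, s=12, alpha=0.7)
    lo = min(fit.observed.min(), fit.predicted.min())
    hi = max(fit.observed.max(), fit.predicted.max())
    ax.plot([lo, hi], [lo, hi], color="grey", lw=1)
    if boundary is not None:
        ax.axhline(boundary, ls="--", color="black", lw=1)
    ax.set_xlabel("observed")
    ax.set_ylabel("predicted")
    ax.set_title(f"$R^2$ = {fit.r2:.2f}")
    return ax
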