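"""A-priori feature screening: linear time-awake trend, circadian (cosinor)
modulation, and sleep-history condition differences.

Each test removes the dominant trait-like subject variance before asking its
question:

* ``trend_test`` — per sleep-history condition, OLS of abundance on hours
  awake after subject-mean centering; two-sided t test on the slope.
* ``circadian_test`` — cosinor regression on cos/sin of clock time (24 h
  period) with a linear hours-awake term, after subject-mean centering; joint
  F test on the two rhythm coefficients; amplitude = sqrt(bc^2 + bs^2).
* ``condition_test`` — paired two-sided t test of subject-level condition
  means (insufficient minus sufficient).

``select_a_priori`` combines the three decisions into the two panels used for
downstream modelling:

* hours_awake set — trend in both conditions with concordant sign, no
  circadian modulation, no condition difference;
* sleep_sufficiency set — condition difference, no circadian modulation, no
  trend in either condition.

All tests are vectorized across features (the design matrix is shared), so a
20k-feature screen is a handful of matrix products.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "trend_test",
    "circadian_test",
    "condition_test",
    "screen_features",
    "select_a_priori",
]


def _within_subject_center(Y: np.ndarray, subj_idx: np.ndarray, n_groups: int):
    """Subtract subject means from each row-block of Y (samples x features)."""
    sums = np.zeros((n_groups, Y.shape[1]))
    np.add.at(sums, subj_idx, Y)
    counts = np.bincount(subj_idx, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return Y - means[subj_idx]


def _multi_ols(X: np.ndarray, Y: np.ndarray, df_resid: int):
    """OLS of every column of Y on shared design X; returns (coef, cov_scale,
    rss) where coef is k x p and cov_scale = (X'X)^-1."""
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise ValueError("collinear or degenerate regressors") from exc
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return coef, XtX_inv, rss


def trend_test(values, metadata: SampleMetadata):
    """Per-condition hours-awake slope with subject-mean centering.

    ``values`` may be a single feature (1d, aligned to metadata samples) or a
    features x samples frame.  Returns a DataFrame with columns
    slope_sufficient, p_sufficient, slope_insufficient, p_insufficient.
    """
    V = _as_matrix(values, metadata)
    df = metadata.df
    out = {}
    for cond in ("sufficient", "insufficient"):
        mask = (df["condition"] == cond).to_numpy()
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 samples in condition {cond!r}")
        sub = df.loc[mask]
        t = sub["hours_awake"].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            raise ValueError("degenerate design: hours_awake constant within condition")
        subj, subj_idx = np.unique(sub["subject_id"].to_numpy(), return_inverse=True)
        Y = _within_subject_center(V[:, mask].T, subj_idx, len(subj))
        tc = _within_subject_center(t[:, None], subj_idx, len(subj))[:, 0]
        sxx = float(tc @ tc)
        if sxx == 0:
            raise ValueError("degenerate design: hours_awake constant within subjects")
        slope = (tc @ Y) / sxx
        resid = Y - np.outer(tc, slope)
        dfree = mask.sum() - len(subj) - 1
        if dfree < 1:
            raise ValueError("not enough residual degrees of freedom for trend test")
        s2 = np.einsum("ij,ij->j", resid, resid) / dfree
        se = np.sqrt(s2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, slope / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(tstat), dfree)
        # zero residual variance: significant unless the slope is exactly 0
        p = np.where(se > 0, p, np.where(slope == 0.0, 1.0, 0.0))
        out[f"slope_{cond}"] = slope
        out[f"p_{cond}"] = p
    return pd.DataFrame(out, index=_feature_index(values))


def circadian_test(values, metadata: SampleMetadata):
    """Cosinor fit with a linear hours-awake nuisance term; F test on the
    joint cos/sin coefficients; amplitude on the log2 scale."""
    V = _as_matrix(values, metadata)
    df = metadata.df
    clock = df["clock_time"].to_numpy(dtype=float)
    if np.ptp(clock) < 12.0:
        raise ValueError("clock times must span at least half a 24 h cycle")
    hours = df["hours_awake"].to_numpy(dtype=float)
    subj, subj_idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
    n = len(df)
    X = np.column_stack(
        [hours, np.cos(2 * np.pi * clock / 24.0), np.sin(2 * np.pi * clock / 24.0)]
    )
    Xc = _within_subject_center(X, subj_idx, len(subj))
    Y = _within_subject_center(V.T, subj_idx, len(subj))
    dfree = n - len(subj) - X.shape[1]
    if dfree < 1:
        raise ValueError("not enough residual degrees of freedom for cosinor test")
    coef, XtX_inv, rss = _multi_ols(Xc, Y, dfree)
    # reduced model: hours awake only
    Xr = Xc[:, :1]
    _, _, rss0 = _multi_ols(Xr, Y, dfree + 2)
    q = 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss) / q) / (rss / dfree)
    # zero residual: significant iff the rhythm terms explain anything at all
    p = np.where(rss > 0, stats.f.sf(F, q, dfree), np.where(rss0 > rss, 0.0, 1.0))
    amplitude = np.hypot(coef[1], coef[2])
    return pd.DataFrame({"amplitude": amplitude, "p_circ": p}, index=_feature_index(values))


def condition_test(values, metadata: SampleMetadata):
    """Paired t test of subject condition means (insufficient - sufficient)."""
    V = _as_matrix(values, metadata)
    df = metadata.df
    means = {}
    for cond in ("sufficient", "insufficient"):
        mask = (df["condition"] == cond).to_numpy()
        sub = df.loc[mask]
        subj, subj_idx = np.unique(sub["subject_id"].to_numpy(), return_inverse=True)
        sums = np.zeros((len(subj), V.shape[0]))
        np.add.at(sums, subj_idx, V[:, mask].T)
        counts = np.bincount(subj_idx).astype(float)
        means[cond] = pd.DataFrame(sums / counts[:, None], index=subj)
    common = means["sufficient"].index.intersection(means["insufficient"].index)
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects with both conditions")
    D = means["insufficient"].loc[common].to_numpy() - means["sufficient"].loc[common].to_numpy()
    nsub = len(common)
    shift = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    se = sd / np.sqrt(nsub)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, shift / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(tstat), nsub - 1), np.where(shift == 0.0, 1.0, 0.0))
    return pd.DataFrame({"shift": shift, "p_cond": p}, index=_feature_index(values))


def screen_features(
    matrix: ExpressionMatrix, metadata: SampleMetadata, alpha_screen: float = 0.05
) -> pd.DataFrame:
    """Run all three tests and record the screen decisions at alpha_screen."""
    tr = trend_test(matrix.values, metadata)
    ci = circadian_test(matrix.values, metadata)
    co = condition_test(matrix.values, metadata)
    screen = pd.concat([tr, ci, co], axis=1)
    concordant = np.sign(screen["slope_sufficient"]) == np.sign(screen["slope_insufficient"])
    screen["has_trend"] = (
        (screen["p_sufficient"] < alpha_screen)
        & (screen["p_insufficient"] < alpha_screen)
        & concordant
    )
    screen["has_trend_any"] = (screen["p_sufficient"] < alpha_screen) | (
        screen["p_insufficient"] < alpha_screen
    )
    screen["has_circadian"] = screen["p_circ"] < alpha_screen
    screen["has_condition_diff"] = screen["p_cond"] < alpha_screen
    screen.attrs["alpha_screen"] = alpha_screen
    return screen


def select_a_priori(screen: pd.DataFrame, set_name: str, alpha_screen: float | None = None) -> list[str]:
    """Combine screen decisions into one of the two a-priori panels.

    The two sets are disjoint by construction (a feature with both a trend and
    a condition difference qualifies for neither).
    """
    if alpha_screen is not None and alpha_screen != screen.attrs.get("alpha_screen"):
        concordant = np.sign(screen["slope_sufficient"]) == np.sign(screen["slope_insufficient"])
        has_trend = (
            (screen["p_sufficient"] < alpha_screen)
            & (screen["p_insufficient"] < alpha_screen)
            & concordant
        )
        has_trend_any = (screen["p_sufficient"] < alpha_screen) | (
            screen["p_insufficient"] < alpha_screen
        )
        has_circ = screen["p_circ"] < alpha_screen
        has_cond = screen["p_cond"] < alpha_screen
    else:
        has_trend = screen["has_trend"]
        has_trend_any = screen["has_trend_any"]
        has_circ = screen["has_circadian"]
        has_cond = screen["has_condition_diff"]
    if set_name == "hours_awake":
        keep = has_trend & ~has_circ & ~has_cond
    elif set_name == "sleep_sufficiency":
        keep = has_cond & ~has_circ & ~has_trend_any
    else:
        raise ValueError(f"unknown a-priori set {set_name!r}")
    return screen.index[keep].tolist()


def _as_matrix(values, metadata: SampleMetadata) -> np.ndarray:
    if isinstance(values, pd.DataFrame):
        missing = metadata.sample_ids.difference(values.columns)
        if len(missing):
            raise ValueError(f"values missing sample column(s): {missing.tolist()[:5]}")
        return values[metadata.sample_ids].to_numpy(dtype=float)
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(metadata):
        raise ValueError("feature values not aligned to metadata samples")
    return arr


def _feature_index(values):
    if isinstance(values, pd.DataFrame):
        return values.index
    arr = np.asarray(values)
    n = 1 if arr.ndim == 1 else arr.shape[0]
    return pd.RangeIndex(n)
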