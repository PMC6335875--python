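"""Lambda tuning by repeated stratified k-fold cross-validation.

The tuning rule: assign samples to k random folds (stratified on the class
label for logistic targets, or on an optional binary covariate for linear
targets), compute the mean held-out error per lambda on a shared grid, take
the per-repeat argmin (ties resolve to the larger lambda, i.e. the sparser
model), repeat, and define the operating lambda as the arithmetic mean of the
per-repeat selections.  The final model is then refit once on the full
training set at that mean lambda.

Held-out error is squared error for the linear family and binomial deviance
for logistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solver import enet_path_binomial, enet_path_gaussian
from .penalized import _PROB_CLIP, PenalizedModel, PenalizedRegression

__all__ = ["CVResult", "repeated_cv_lambda", "finalize_model"]

_DEV_CLIP = 1e-10


@dataclass
class CVResult:
    lambdas: np.ndarray  # shared decreasing grid
    selected: np.ndarray  # per-repeat argmin lambda
    cv_error: np.ndarray  # repeats x n_lambda mean held-out error
    mean_lambda: float
    k: int
    repeats: int
    seed: int | None
    family: str
    alpha: float

    @property
    def lambda_sd(self) -> float:
        return float(np.std(self.selected, ddof=1)) if len(self.selected) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"repeat": np.arange(len(self.selected)), "selected_lambda": self.selected}
        )


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin assignment of shuffled indices to k folds within each
    stratum; returns fold index per sample."""
    fold = np.empty(len(labels), dtype=np.int64)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def repeated_cv_lambda(
    X,
    y,
    family: str = "linear",
    alpha: float = 0.5,
    k: int = 10,
    repeats: int = 500,
    seed: int | None = None,
    n_lambda: int = 100,
    ratio: float = 1e-3,
    strata=None,
    tol: float = 1e-4,
) -> CVResult:
    """Repeated stratified k-fold search for the operating lambda.

    ``strata`` (optional, linear family only) is a label array used to balance
    fold assignment; logistic targets are always stratified on the class.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = None
    ya = np.asarray(y, dtype=float).ravel()
    n = len(ya)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")

    if family == "logistic":
        classes = np.unique(ya)
        labels = ya
        min_class = min((ya == c).sum() for c in classes)
        if min_class < k:
            warnings.warn(
                f"smallest class has {min_class} samples; reducing k from {k}",
                stacklevel=2,
            )
            k = max(2, int(min_class))
    elif strata is not None:
        labels = np.asarray(strata).ravel()
    else:
        labels = np.zeros(n)

    full = PenalizedRegression(ya, Xa, family=family, alpha=alpha, feature_names=feature_names)
    grid = full.lambda_grid(n_lambda=n_lambda, ratio=ratio)
    L = len(grid)

    rng = np.random.default_rng(seed)
    cv_error = np.zeros((repeats, L))
    selected = np.zeros(repeats)
    for rep in range(repeats):
        fold = _stratified_folds(labels, k, rng)
        err_sum = np.zeros(L)
        for f in range(k):
            test = fold == f
            train = ~test
            if family == "logistic" and len(np.unique(ya[train])) < 2:
                raise ValueError("a training fold lost one class; reduce k")
            Xtr = Xa[train]
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd == 0.0, 1.0, sd)
            Xs = np.ascontiguousarray((Xtr - mean) / sd)
            Xts = (Xa[test] - mean) / sd
            yt = ya[test]
            if family == "linear":
                ybar = ya[train].mean()
                B, _ = enet_path_gaussian(Xs, ya[train] - ybar, grid, alpha, tol, 100_000)
                pred = ybar + Xts @ B  # n_test x L
                err_sum += np.sum((yt[:, None] - pred) ** 2, axis=0)
            else:
                B, b0s, _ = enet_path_binomial(
                    Xs, ya[train], grid, alpha, tol, 100_000, 25, _PROB_CLIP
                )
                eta = b0s[None, :] + Xts @ B
                p = 1.0 / (1.0 + np.exp(-eta))
                p = np.clip(p, _DEV_CLIP, 1.0 - _DEV_CLIP)
                err_sum += -2.0 * np.sum(
                    yt[:, None] * np.log(p) + (1.0 - yt[:, None]) * np.log(1.0 - p),
                    axis=0,
                )
        err = err_sum / n
        cv_error[rep] = err
        # grid is decreasing, so the first argmin is the largest lambda at ties
        selected[rep] = grid[int(np.argmin(err))]
    mean_lambda = float(np.mean(selected))
    return CVResult(
        lambdas=grid,
        selected=selected,
        cv_error=cv_error,
        mean_lambda=mean_lambda,
        k=k,
        repeats=repeats,
        seed=seed,
        family=family,
        alpha=alpha,
    )


def finalize_model(X, y, family: str, alpha: float, cv: CVResult,
                   tol: float = 1e-7) -> PenalizedModel:
    """One fit on the full training set at the CV mean lambda (honoured
    exactly, never re-selected)."""
    if isinstance(X, pd.DataFrame):
        model = PenalizedRegression(np.asarray(y, dtype=float), X, family=family, alpha=alpha)
    else:
        model = PenalizedRegression(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                                    family=family, alpha=alpha)
    return model.fit(cv.mean_lambda, tol=tol)
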