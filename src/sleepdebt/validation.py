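"""Subject-aware model validation: leave-one-subject-out cross-validation and
independent validation.

LOSO-CV removes *all* of a subject's units per fold and reruns the
training-side computation — flag filtering (when per-unit flags are
available), lambda tuning at a reduced repeat count, and the final fit —
before predicting the held-out units, so no information from the held-out
subject leaks into its own predictions.  Pooled held-out predictions are then
summarized with the same metrics as independent validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import ClassificationMetrics, RegressionFit, confusion, metrics, r_squared
from .partition import LabeledSet
from .penalized import PenalizedModel
from .tuning import CVResult, finalize_model, repeated_cv_lambda

logger = logging.getLogger(__name__)

__all__ = ["ValidationResult", "LosoResult", "independent_validate", "loso_cv"]


@dataclass
class ValidationResult:
    predictions: pd.DataFrame  # unit_id, truth, score, predicted_class
    regression: RegressionFit | None
    classification: ClassificationMetrics | None
    n: int


@dataclass
class LosoResult:
    predictions: pd.DataFrame
    regression: RegressionFit | None
    classification: ClassificationMetrics | None
    n_folds: int
    skipped_subjects: list


def _summarize(truth: np.ndarray, score: np.ndarray, family: str,
               boundary: float = 0.5, unit_ids=None) -> tuple:
    if family == "linear":
        fitres = r_squared(truth, score)
        cls = None
        pred_class = np.full(len(score), np.nan)
    else:
        fitres = None
        cm = confusion(truth, score, boundary=boundary)
        cls = metrics(cm)
        pred_class = (score > boundary).astype(int)
    df = pd.DataFrame(
        {
            "unit_id": unit_ids if unit_ids is not None else np.arange(len(score)),
            "truth": truth,
            "score": score,
            "predicted_class": pred_class,
        }
    )
    return df, fitres, cls


def independent_validate(model: PenalizedModel, labeled_val: LabeledSet,
                         boundary: float = 0.5) -> ValidationResult:
    """Apply a finalized training-set model to an untouched validation set."""
    score = model.predict(labeled_val.X)
    truth = labeled_val.target.to_numpy(dtype=float)
    df, fitres, cls = _summarize(truth, score, model.family, boundary, labeled_val.unit_ids)
    return ValidationResult(predictions=df, regression=fitres, classification=cls,
                           n=len(truth))


def loso_cv(
    labeled_train: LabeledSet,
    family: str,
    alpha: float = 0.5,
    k: int = 10,
    repeats: int = 20,
    seed: int | None = None,
    n_lambda: int = 100,
    ratio: float = 1e-3,
    refit_lambda: bool = True,
    lam: float | None = None,
    flag_threshold: float | None = None,
    boundary: float = 0.5,
    tol: float = 1e-4,
) -> LosoResult:
    """Leave-one-subject-out cross-validation of the full training pipeline.

    With ``refit_lambda`` (default) the repeated-CV lambda search is rerun
    inside every fold at ``repeats`` repeats; otherwise the supplied ``lam``
    is reused.  When the labelled set carries per-unit flags and
    ``flag_threshold`` is given, the >threshold flag filter is recomputed on
    each fold's remaining training units.
    """
    X = labeled_train.X
    y = labeled_train.target.to_numpy(dtype=float)
    subjects = labeled_train.subject.to_numpy()
    uniq = np.unique(subjects)
    if len(uniq) < 3:
        raise ValueError("LOSO-CV needs at least 3 subjects")
    if not refit_lambda and lam is None:
        raise ValueError("lam is required when refit_lambda is off")

    rng = np.random.default_rng(seed)
    rows = []
    skipped = []
    for subject in uniq:
        held = subjects == subject
        ytr = y[~held]
        if family == "logistic" and len(np.unique(ytr)) < 2:
            logger.warning("loso_cv: removing subject %s empties a class; fold skipped", subject)
            skipped.append(subject)
            continue
        Xtr = X.loc[~held]
        Xte = X.loc[held]
        if flag_threshold is not None and labeled_train.flags is not None:
            frac = labeled_train.flags.loc[~held].to_numpy().mean(axis=0)
            keep = X.columns[frac <= flag_threshold]
            Xtr = Xtr[keep]
            Xte = Xte[keep]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if refit_lambda:
            cv = repeated_cv_lambda(
                Xtr, ytr, family=family, alpha=alpha, k=min(k, len(ytr)),
                repeats=repeats, seed=fold_seed, n_lambda=n_lambda, ratio=ratio,
                tol=tol,
            )
            fold_lam = cv.mean_lambda
        else:
            fold_lam = lam
        cv_stub = CVResult(
            lambdas=np.array([fold_lam * 2, fold_lam]), selected=np.array([fold_lam]),
            cv_error=np.zeros((1, 2)), mean_lambda=fold_lam, k=k, repeats=0,
            seed=fold_seed, family=family, alpha=alpha,
        )
        model = finalize_model(Xtr, ytr, family, alpha, cv_stub, tol=min(tol, 1e-6))
        score = model.predict(Xte)
        for uid, t, s in zip(X.index[held], y[held], score):
            rows.append((uid, t, s))

    if not rows:
        raise ValueError("all LOSO folds were skipped")
    pooled = pd.DataFrame(rows, columns=["unit_id", "truth", "score"])
    df, fitres, cls = _summarize(
        pooled["truth"].to_numpy(), pooled["score"].to_numpy(), family, boundary,
        pooled["unit_id"].to_numpy(),
    )
    return LosoResult(
        predictions=df,
        regression=fitres,
        classification=cls,
        n_folds=len(uniq) - len(skipped),
        skipped_subjects=skipped,
    )
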