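"""LOSO-CV and independent validation: fold structure, leakage probes, null
calibration, and the trivial-model contract."""

import numpy as np
import pandas as pd
import pytest

from sleepdebt.metrics import confusion, metrics
from sleepdebt.partition import LabeledSet
from sleepdebt.penalized import PenalizedModel
from sleepdebt.validation import independent_validate, loso_cv


def _labeled_classification(rng, n_subjects=8, per_subject=4, p=15, signal=2.0):
    rows, targets, subjects = [], [], []
    for s in range(n_subjects):
        for i in range(per_subject):
            y = (s * per_subject + i) % 2
            x = rng.normal(size=p)
            x[0] += signal * (2 * y - 1)
            rows.append(x)
            targets.append(y)
            subjects.append(f"S{s:02d}")
    X = pd.DataFrame(np.array(rows), index=[f"u{i}" for i in range(len(rows))],
                     columns=[f"f{j}" for j in range(p)])
    return LabeledSet(
        "acute_loss", "between", X,
        pd.Series(targets, index=X.index, name="target"),
        pd.Series(subjects, index=X.index, name="subject_id"),
        "positive", None, None, [],
    )


def test_fold_count_equals_subjects(rng):
    ls = _labeled_classification(rng)
    res = loso_cv(ls, family="logistic", alpha=0.5, repeats=2, seed=0, n_lambda=15)
    assert res.n_folds == 8
    assert len(res.predictions) == len(ls.target)


def test_held_out_subject_never_influences_its_predictions(rng):
    """Poisoning probe: corrupting a subject's training copy must not change
    that subject's held-out predictions."""
    ls = _labeled_classification(rng)
    res = loso_cv(ls, family="logistic", alpha=0.5, repeats=2, seed=1, n_lambda=15)

    poisoned = ls.X.copy()
    mask = ls.subject == "S03"
    poisoned.loc[mask] = poisoned.loc[mask] + 1e6  # absurd values
    # rebuild with poisoned matrix, then check S03's predictions: they come
    # from a model trained without S03, but the poisoned features enter the
    # prediction step, so instead we poison *another* subject's rows and
    # check S03 is unaffected only through training.
    poisoned2 = ls.X.copy()
    other = ls.subject == "S05"
    # S05's rows perturbed slightly -> only folds that train on S05 change;
    # the S05 fold itself trains without S05, so S05's own predictions depend
    # purely on the unperturbed remainder. Verify by comparing S05 rows after
    # perturbing S05's training influence via label flip instead:
    ls_flipped = LabeledSet(
        ls.variable, ls.mode, ls.X,
        ls.target.where(~other, 1 - ls.target), ls.subject,
        ls.positive_class, None, None, [],
    )
    res_flipped = loso_cv(ls_flipped, family="logistic", alpha=0.5, repeats=2,
                          seed=1, n_lambda=15)
    a = res.predictions.set_index("unit_id").loc[ls.X.index[other], "score"]
    b = res_flipped.predictions.set_index("unit_id").loc[ls.X.index[other], "score"]
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_subjectwise_label_permutation_gives_chance_mcc(rng):
    """Permuting labels subject-wise destroys the signal; pooled MCC stays
    within +/-0.25 of zero (or is undefined when the fit is exactly null)."""
    ls = _labeled_classification(rng, n_subjects=10, per_subject=4, signal=2.0)
    mccs = []
    for rep in range(10):
        perm_rng = np.random.default_rng(rep)
        # shuffle labels within each subject's block of units
        new_target = ls.target.copy()
        for s in ls.subject.unique():
            mask = (ls.subject == s).to_numpy()
            vals = new_target[mask].to_numpy()
            new_target.loc[mask] = perm_rng.permutation(vals)
        ls_perm = LabeledSet(ls.variable, ls.mode, ls.X, new_target, ls.subject,
                             ls.positive_class, None, None, [])
        res = loso_cv(ls_perm, family="logistic", alpha=0.5, repeats=1,
                      seed=rep, n_lambda=10)
        if not np.isnan(res.classification.mcc):
            mccs.append(res.classification.mcc)
    assert mccs, "all permutation fits degenerate"
    assert abs(np.mean(mccs)) < 0.25


def test_fold_skipped_when_class_emptied(rng):
    """A subject holding an entire class cannot be held out."""
    p = 10
    rows = rng.normal(size=(6, p))
    X = pd.DataFrame(rows, index=[f"u{i}" for i in range(6)],
                     columns=[f"f{j}" for j in range(p)])
    ls = LabeledSet(
        "acute_loss", "between", X,
        pd.Series([1, 1, 0, 0, 0, 0], index=X.index),
        pd.Series(["A", "A", "B", "B", "C", "C"], index=X.index),
        "positive", None, None, [],
    )
    res = loso_cv(ls, family="logistic", alpha=0.5, repeats=1, seed=0, n_lambda=10)
    assert res.skipped_subjects == ["A"]
    assert res.n_folds == 2


def test_trivial_model_validation_contract(rng):
    """All-zero logistic model: every score 0.5 -> all-negative assignment,
    Sn = 0, Sp = 100%."""
    p = 4
    model = PenalizedModel(intercept=0.0, coef=np.zeros(p),
                           feature_names=[f"f{j}" for j in range(p)],
                           family="logistic", alpha=0.5, lam=1.0,
                           means=np.zeros(p), sds=np.ones(p), converged=True,
                           n_sweeps=0, n_obs=8, coef_std=np.zeros(p))
    X = pd.DataFrame(rng.normal(size=(10, p)), columns=model.feature_names,
                     index=[f"u{i}" for i in range(10)])
    ls = LabeledSet("chronic_insufficiency", "between", X,
                    pd.Series([1] * 5 + [0] * 5, index=X.index),
                    pd.Series(["s"] * 10, index=X.index), "positive", None, None, [])
    res = independent_validate(model, ls)
    assert np.allclose(res.predictions["score"], 0.5)
    assert res.classification.sn == 0.0
    assert res.classification.sp == 1.0


def test_random_scores_near_half_accuracy(rng):
    """Random uniform scores on balanced classes: expected accuracy 50%."""
    n = 2000
    truth = np.array([1, 0] * (n // 2))
    acc = metrics(confusion(truth, rng.random(n))).acc
    assert abs(acc - 0.5) < 0.05


def test_loso_needs_three_subjects(rng):
    ls = _labeled_classification(rng, n_subjects=2)
    with pytest.raises(ValueError, match="3 subjects"):
        loso_cv(ls, family="logistic", repeats=1, seed=0)
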