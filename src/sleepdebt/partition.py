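"""Training/validation partitioning and sleep-debt variable assembly.

Two partitioning schemes are supported:

* UPUS ("unique participants, unique samples") — subjects are assigned
  wholesale to either side, stratified so that balance covariates (sex by
  default) are split evenly; training and validation share no subject.
* OPUS ("overlapping participants, unique samples") — every subject
  contributes one sleep-history condition's visit to training and the other
  to validation, with the condition-to-side assignment randomized under the
  constraint that each side holds near-equal numbers of sufficient and
  insufficient blocks.

``assemble_variable`` builds the labelled sample sets for the five sleep-debt
variables (time awake; wakefulness > 24 hr; acute sleep loss; chronic sleep
insufficiency; sleep increase/decrease), in between-subject (single-sample)
or within-subject (differenced) mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata, baseline_correct

logger = logging.getLogger(__name__)

__all__ = ["SplitPair", "LabeledSet", "split_upus", "split_opus", "assemble_variable", "VARIABLES"]

VARIABLES = ("time_awake", "gt24", "acute_loss", "chronic_insufficiency", "sleep_change")


@dataclass
class SplitPair:
    train_sample_ids: list[str]
    validation_sample_ids: list[str]
    scheme: str
    balanced_on: list[str]
    seed: int | None

    def __post_init__(self):
        overlap = set(self.train_sample_ids) & set(self.validation_sample_ids)
        if overlap:
            raise ValueError(f"train/validation sample overlap: {sorted(overlap)[:5]}")

    def manifest(self) -> pd.DataFrame:
        rows = [(s, "train") for s in self.train_sample_ids] + [
            (s, "validation") for s in self.validation_sample_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "side"])


@dataclass
class LabeledSet:
    """Units ready for modelling: X is units x features."""

    variable: str
    mode: str  # between | within
    X: pd.DataFrame
    target: pd.Series  # numeric (hours awake) or 0/1 class
    subject: pd.Series
    positive_class: str | None = None
    hours: pd.Series | None = None  # hours awake per unit, kept for gt24
    flags: pd.DataFrame | None = None  # units x features, for per-fold refiltering
    notes: list[str] = field(default_factory=list)

    @property
    def unit_ids(self) -> pd.Index:
        return self.X.index

    def class_counts(self) -> dict | None:
        if self.positive_class is None:
            return None
        t = self.target.astype(int)
        return {"positive": int((t == 1).sum()), "negative": int((t == 0).sum())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "target": self.target.values})


def split_upus(
    metadata: SampleMetadata,
    fraction: float = 0.5,
    balance: tuple[str, ...] = ("sex",),
    seed: int | None = None,
) -> SplitPair:
    """Subject-disjoint split, stratified on subject-level balance fields."""
    df = metadata.df
    rng = np.random.default_rng(seed)
    subj = df.groupby("subject_id", sort=True).first()
    strata = subj.groupby(list(balance), sort=True) if balance else [((), subj)]
    train_subjects: list[str] = []
    val_subjects: list[str] = []
    for _, stratum in strata:
        ids = np.array(sorted(stratum.index))
        if len(ids) < 2:
            logger.warning("split_upus: stratum with a single subject %s assigned to train", ids)
            train_subjects.extend(ids)
            continue
        rng.shuffle(ids)
        n_train = int(round(len(ids) * fraction))
        train_subjects.extend(ids[:n_train])
        val_subjects.extend(ids[n_train:])
    in_train = df["subject_id"].isin(train_subjects)
    return SplitPair(
        train_sample_ids=df.index[in_train].tolist(),
        validation_sample_ids=df.index[~in_train].tolist(),
        scheme="UPUS",
        balanced_on=list(balance),
        seed=seed,
    )


def split_opus(metadata: SampleMetadata, seed: int | None = None) -> SplitPair:
    """Per subject, one condition's samples go to training and the other to
    validation; condition-to-side assignment is randomized subject-wise while
    keeping sufficient/insufficient block counts on each side within one."""
    df = metadata.df
    rng = np.random.default_rng(seed)
    usable = []
    for subject, block in df.groupby("subject_id", sort=True):
        conds = set(block["condition"])
        if conds != {"sufficient", "insufficient"}:
            logger.warning("split_opus: subject %s lacks both conditions; excluded", subject)
            continue
        usable.append(subject)
    usable = np.array(usable)
    rng.shuffle(usable)
    half = len(usable) // 2
    suff_to_train = set(usable[:half])  # these subjects send 'sufficient' to train
    train_ids, val_ids = [], []
    for subject in usable:
        block = df[df["subject_id"] == subject]
        train_cond = "sufficient" if subject in suff_to_train else "insufficient"
        for sid, row in block.iterrows():
            (train_ids if row["condition"] == train_cond else val_ids).append(sid)
    return SplitPair(train_ids, val_ids, scheme="OPUS", balanced_on=["condition"], seed=seed)


def _select_index(block: pd.DataFrame, index: int, fallback_index: int | None):
    hit = block.index[block["sample_index"] == index]
    if len(hit):
        return hit[0], index
    if fallback_index is not None:
        hit = block.index[block["sample_index"] == fallback_index]
        if len(hit):
            return hit[0], fallback_index
    return None, None


def assemble_variable(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    variable: str,
    mode: str,
    fallback: bool = True,
    sample_index: int | None = None,
) -> LabeledSet:
    """Build the labelled unit set for one sleep-debt variable.

    ``sample_index`` selects the variant for chronic_insufficiency (1, with
    fallback 2; or 9, with fallback 10) and sleep_change (2, with fallback 3;
    or 9, with fallback 10).
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    df = metadata.df
    notes: list[str] = []

    if variable in ("time_awake", "gt24"):
        if mode == "between":
            X = matrix.values.T
            hours = df["hours_awake"].astype(float)
            subject = df["subject_id"]
            fl = matrix.flags.T
        elif mode == "within":
            corrected, meta2 = baseline_correct(
                matrix, metadata, reference_index=1, reference_fallback=fallback
            )
            X = corrected.values.T
            hours = meta2.df["hours_awake"].astype(float)
            subject = meta2.df["subject_id"]
            fl = corrected.flags.T
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if variable == "time_awake":
            return LabeledSet(variable, mode, X, hours.rename("target"), subject, None, hours, fl, notes)
        target = (hours > 24.0).astype(int).rename("target")
        return LabeledSet(variable, mode, X, target, subject, "awake > 24 hr", hours, fl, notes)

    if variable == "acute_loss":
        if mode == "between":
            sel = df[df["sample_index"].isin([1, 9])]
            if sel.empty:
                raise ValueError("no eligible samples (#1/#9) for acute_loss/between")
            X = matrix.values[sel.index].T
            fl = matrix.flags[sel.index].T
            target = (sel["sample_index"] == 9).astype(int).rename("target")
            return LabeledSet(
                variable, mode, X, target, sel["subject_id"], "acute sleep loss (#9)",
                sel["hours_awake"].astype(float), fl, notes,
            )
        if mode == "within":
            corrected, meta2 = baseline_correct(
                matrix, metadata, reference_index=1, reference_fallback=fallback
            )
            sel = meta2.df[meta2.df["sample_index"].isin([2, 10])]
            if sel.empty:
                raise ValueError("no eligible differenced samples (#2-#1/#10-#1) for acute_loss/within")
            X = corrected.values[sel.index].T
            fl = corrected.flags[sel.index].T
            target = (sel["sample_index"] == 10).astype(int).rename("target")
            return LabeledSet(
                variable, mode, X, target, sel["subject_id"], "acute sleep loss (#10-#1)",
                sel["hours_awake"].astype(float), fl, notes,
            )
        raise ValueError(f"unknown mode {mode!r}")

    if variable == "chronic_insufficiency":
        if mode != "between":
            raise ValueError("chronic_insufficiency is a between-subject (single-sample) variable")
        idx = 1 if sample_index is None else sample_index
        fb = {1: 2, 9: 10}.get(idx, idx + 1) if fallback else None
        unit_ids, targets, subjects, hours = [], [], [], []
        for (subject, cond), block in df.groupby(["subject_id", "condition"], sort=True):
            sid, used = _select_index(block, idx, fb)
            if sid is None:
                notes.append(f"chronic: no sample #{idx} (or fallback) for ({subject}, {cond})")
                logger.warning(notes[-1])
                continue
            if used != idx:
                notes.append(f"chronic: ({subject}, {cond}) used fallback sample #{used}")
            unit_ids.append(sid)
            targets.append(1 if cond == "insufficient" else 0)
            subjects.append(subject)
            hours.append(float(block.loc[sid, "hours_awake"]))
        if not unit_ids:
            raise ValueError("no eligible samples for chronic_insufficiency")
        X = matrix.values[unit_ids].T
        fl = matrix.flags[unit_ids].T
        return LabeledSet(
            variable, mode, X,
            pd.Series(targets, index=X.index, name="target"),
            pd.Series(subjects, index=X.index, name="subject_id"),
            "chronic sleep insufficiency",
            pd.Series(hours, index=X.index, name="hours_awake"),
            fl, notes,
        )

    # sleep_change: per subject, visit-1 sample minus visit-2 sample at one index
    if mode != "within":
        raise ValueError("sleep_change is a within-subject (two-sample) variable")
    idx = 2 if sample_index is None else sample_index
    fb = {2: 3, 9: 10}.get(idx, idx + 1) if fallback else None
    rows, targets, subjects = [], [], []
    unit_ids = []
    for subject, block in df.groupby("subject_id", sort=True):
        b1 = block[block["visit"] == 1]
        b2 = block[block["visit"] == 2]
        s1, u1 = _select_index(b1, idx, fb)
        s2, u2 = _select_index(b2, idx, fb)
        if s1 is None or s2 is None:
            notes.append(f"sleep_change: subject {subject} lacks sample #{idx} in a visit; excluded")
            logger.warning(notes[-1])
            continue
        if (u1, u2) != (idx, idx):
            notes.append(f"sleep_change: subject {subject} used fallback sample(s) #{u1}/#{u2}")
        diff = matrix.values[s1] - matrix.values[s2]
        rows.append(diff.to_numpy())
        unit_ids.append(f"{subject}_d{idx:02d}")
        # positive class = sleep decrease: sufficient at visit 1, insufficient at visit 2
        targets.append(1 if b1["condition"].iloc[0] == "sufficient" else 0)
        subjects.append(subject)
    if not rows:
        raise ValueError("no eligible subject pairs for sleep_change")
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(unit_ids, name="unit_id"), columns=matrix.feature_ids)
    return LabeledSet(
        variable, mode, X,
        pd.Series(targets, index=X.index, name="target"),
        pd.Series(subjects, index=X.index, name="subject_id"),
        "sleep decrease",
        None, None, notes,
    )
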