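"""Tabular IO and preprocessing for log2 expression matrices.

Implements the preprocessing chain applied before any modelling: per-sample
75th-percentile normalization (a shift on the log2 scale), technical-replicate
averaging, removal of features quality-flagged in more than 10% of *training*
samples, and within-block baseline correction (test sample minus the block's
reference sample) for within-subject analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_expression",
    "read_metadata",
    "percentile_normalize",
    "average_replicates",
    "filter_flagged",
    "baseline_correct",
]

REQUIRED_METADATA_COLUMNS = (
    "subject_id",
    "sex",
    "condition",
    "visit",
    "sample_index",
    "hours_awake",
    "clock_time",
)


@dataclass
class ExpressionMatrix:
    """Log2 abundance values (features x samples) plus 0/1 quality flags."""

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self):
        if self.flags is None:
            self.flags = pd.DataFrame(
                np.zeros(self.values.shape, dtype=np.int8),
                index=self.values.index,
                columns=self.values.columns,
            )
        self.validate()

    def validate(self) -> None:
        v, f = self.values, self.flags
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if v.shape != f.shape or not v.index.equals(f.index) or not v.columns.equals(f.columns):
            raise ValueError("values and flags must share shape, feature ids and sample ids")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            bad = v.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in sample column(s): {bad[:5]}")
        farr = f.to_numpy()
        if not np.isin(farr, (0, 1)).all():
            raise ValueError("flags must be 0 or 1")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)].copy(), self.flags[list(sample_ids)].copy())

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)].copy(), self.flags.loc[list(feature_ids)].copy()
        )


class SampleMetadata:
    """Per-sample design labels, indexed by sample_id."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups[:5]}")
        key = df[["subject_id", "condition", "sample_index"]].apply(tuple, axis=1)
        if key.duplicated().any():
            bad = key[key.duplicated()].iloc[0]
            raise ValueError(f"(subject_id, condition, sample_index) not unique: {bad}")
        bad_cond = set(df["condition"]) - {"sufficient", "insufficient"}
        if bad_cond:
            raise ValueError(f"unknown condition label(s): {sorted(bad_cond)}")
        ha = df["hours_awake"].to_numpy(dtype=float)
        if ((ha < 7.0) | (ha > 35.0)).any():
            bad = df.index[(ha < 7.0) | (ha > 35.0)].tolist()
            raise ValueError(f"hours_awake outside [7, 35] for sample(s): {bad[:5]}")
        self.df = df

    def __len__(self):
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())

    def subjects(self) -> np.ndarray:
        return self.df["subject_id"].unique()


def _read_tsv(path) -> pd.DataFrame:
    # readers tolerate CRLF and quoted headers (pandas C engine handles both)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression(path, flags_path=None) -> ExpressionMatrix:
    """Read an expression TSV (first column feature_id, then sample columns).

    A flags TSV of identical shape may accompany it; without one all
    measurements are taken as passing.
    """
    values = _read_tsv(path)
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric values in sample column(s): {non_numeric[:5]}")
    values = values.astype(float)
    flags = None
    if flags_path is not None:
        flags = _read_tsv(flags_path)
        if not flags.index.equals(values.index) or not flags.columns.equals(values.columns):
            raise ValueError("flags file does not align with expression file")
        flags = flags.astype(np.int8)
    return ExpressionMatrix(values=values, flags=flags)


def read_metadata(path, expression: ExpressionMatrix | None = None) -> SampleMetadata:
    """Read sample metadata; when an expression matrix is supplied the sample
    sets must match exactly (errors name the offending samples)."""
    meta = SampleMetadata(_read_tsv(path))
    if expression is not None:
        m = set(meta.sample_ids)
        e = set(expression.sample_ids)
        if m != e:
            only_e = sorted(e - m)
            only_m = sorted(m - e)
            parts = []
            if only_e:
                parts.append(f"samples only in expression: {only_e[:5]}")
            if only_m:
                parts.append(f"samples only in metadata: {only_m[:5]}")
            raise ValueError("sample sets differ; " + "; ".join(parts))
    return meta


def percentile_normalize(matrix: ExpressionMatrix, p: float = 75.0) -> ExpressionMatrix:
    """Subtract each sample's p-th percentile (linear-interpolation
    convention) from that sample's values.  Idempotent; preserves all
    within-sample differences exactly."""
    arr = matrix.values.to_numpy()
    if arr.shape[0] < 1:
        raise ValueError("empty expression matrix")
    q = np.percentile(arr, p, axis=0, method="linear")
    out = matrix.values - q
    return ExpressionMatrix(values=out, flags=matrix.flags.copy())


def average_replicates(matrix: ExpressionMatrix, replicate_map) -> ExpressionMatrix:
    """Average technically replicated features.

    ``replicate_map`` maps every feature_id to a group id; the output has one
    row per group with the arithmetic mean of members' values and, as a
    conservative choice, a flag of 1 whenever any member is flagged.
    """
    rm = pd.Series(replicate_map)
    missing = matrix.feature_ids.difference(rm.index)
    if len(missing):
        raise ValueError(f"replicate_map missing feature(s): {missing.tolist()[:5]}")
    groups = rm.loc[matrix.feature_ids]
    values = matrix.values.groupby(groups.values).mean()
    flags = matrix.flags.groupby(groups.values).max().astype(np.int8)
    values.index.name = matrix.values.index.name
    flags.index.name = matrix.flags.index.name
    return ExpressionMatrix(values=values, flags=flags)


def filter_flagged(
    train: ExpressionMatrix,
    apply_to: list[ExpressionMatrix] | None = None,
    threshold: float = 0.10,
):
    """Remove features flagged in strictly more than ``threshold`` of the
    *training* samples; the removal is applied identically to every matrix in
    ``apply_to`` (validation flags never influence the decision)."""
    apply_to = apply_to or []
    for m in apply_to:
        if not m.feature_ids.equals(train.feature_ids):
            raise ValueError("feature sets differ between train and apply_to matrices")
    frac = train.flags.to_numpy().mean(axis=1)
    keep = train.feature_ids[frac <= threshold]
    out_train = train.subset_features(keep)
    out_rest = [m.subset_features(keep) for m in apply_to]
    return (out_train, out_rest) if apply_to else (out_train, [])


def baseline_correct(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    reference_index: int = 1,
    reference_fallback: bool = False,
):
    """Transform each (subject, condition) block to test-minus-reference
    differences.

    The reference sample (default sample #1; sample #2 when missing and
    ``reference_fallback`` is on) is subtracted from every other sample in its
    block and then dropped.  Blocks lacking a usable reference are excluded
    with a logged warning.
    """
    df = metadata.df
    keep_cols = []
    new_values = {}
    new_flags = {}
    for (subject, cond), block in df.groupby(["subject_id", "condition"], sort=False):
        ref_rows = block.index[block["sample_index"] == reference_index]
        if len(ref_rows) == 0 and reference_fallback:
            ref_rows = block.index[block["sample_index"] == reference_index + 1]
        if len(ref_rows) == 0:
            logger.warning(
                "baseline_correct: block (%s, %s) lacks reference sample #%d; excluded",
                subject,
                cond,
                reference_index,
            )
            continue
        ref = ref_rows[0]
        for sid in block.index:
            if sid == ref:
                continue
            new_values[sid] = matrix.values[sid] - matrix.values[ref]
            new_flags[sid] = np.maximum(matrix.flags[sid], matrix.flags[ref]).astype(np.int8)
            keep_cols.append(sid)
    if not keep_cols:
        raise ValueError("baseline_correct produced no samples (no block had a reference)")
    values = pd.DataFrame(new_values, index=matrix.feature_ids)[keep_cols]
    flags = pd.DataFrame(new_flags, index=matrix.feature_ids)[keep_cols]
    out_meta = SampleMetadata(df.loc[keep_cols].copy())
    return ExpressionMatrix(values=values, flags=flags), out_meta
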