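"""UPUS/OPUS splits and labelled-set assembly for the sleep-debt variables."""

import numpy as np
import pytest

from sleepdebt.cohort import SyntheticConfig, generate_cohort
from sleepdebt.partition import assemble_variable, split_opus, split_upus


@pytest.fixture(scope="module")
def cohort36():
    cfg = SyntheticConfig(n_subjects=36, n_features=50, n_trend=5, n_circadian=5,
                          n_condition=5, n_mixed=0, seed=5)
    return generate_cohort(cfg)


class TestUpus:
    def test_half_split_balanced_on_sex(self, cohort36):
        _, meta, _ = cohort36
        split = split_upus(meta, seed=1)
        df = meta.df
        tr_subj = df.loc[split.train_sample_ids, "subject_id"].unique()
        va_subj = df.loc[split.validation_sample_ids, "subject_id"].unique()
        assert len(tr_subj) == 18 and len(va_subj) == 18
        sex = df.groupby("subject_id")["sex"].first()
        assert (sex.loc[tr_subj] == "M").sum() == 9
        assert (sex.loc[va_subj] == "M").sum() == 9

    def test_subject_disjoint(self, cohort36):
        _, meta, _ = cohort36
        split = split_upus(meta, seed=2)
        df = meta.df
        tr = set(df.loc[split.train_sample_ids, "subject_id"])
        va = set(df.loc[split.validation_sample_ids, "subject_id"])
        assert tr.isdisjoint(va)
        # all of a subject's samples follow the subject
        for subject in tr:
            ids = df.index[df["subject_id"] == subject]
            assert set(ids) <= set(split.train_sample_ids)

    def test_seed_reproducible(self, cohort36):
        _, meta, _ = cohort36
        a = split_upus(meta, seed=9)
        b = split_upus(meta, seed=9)
        c = split_upus(meta, seed=10)
        assert a.train_sample_ids == b.train_sample_ids
        assert a.train_sample_ids != c.train_sample_ids


class TestOpus:
    def test_condition_blocks_balanced(self, cohort36):
        _, meta, _ = cohort36
        split = split_opus(meta, seed=3)
        df = meta.df
        tr = df.loc[split.train_sample_ids]
        blocks = tr.groupby("subject_id")["condition"].first()
        n_suff = (blocks == "sufficient").sum()
        assert n_suff in (17, 18, 19)
        assert abs(n_suff - (36 - n_suff)) <= 1 or n_suff in (17, 19)

    def test_every_subject_on_both_sides_samples_disjoint(self, cohort36):
        _, meta, _ = cohort36
        split = split_opus(meta, seed=4)
        df = meta.df
        tr = set(df.loc[split.train_sample_ids, "subject_id"])
        va = set(df.loc[split.validation_sample_ids, "subject_id"])
        assert tr == va == set(df["subject_id"])
        assert set(split.train_sample_ids).isdisjoint(split.validation_sample_ids)

    def test_subject_with_one_condition_excluded(self, cohort36):
        _, meta, _ = cohort36
        df = meta.df
        keep = df.index[~((df["subject_id"] == "S01") & (df["condition"] == "sufficient"))]
        split = split_opus(meta.subset(keep), seed=5)
        all_ids = split.train_sample_ids + split.validation_sample_ids
        assert not any(df.loc[i, "subject_id"] == "S01" for i in all_ids)


class TestAssembleVariable:
    def test_acute_between_counts(self, cohort36):
        matrix, meta, _ = cohort36
        split = split_upus(meta, seed=1)
        ls = assemble_variable(matrix.subset_samples(split.train_sample_ids),
                               meta.subset(split.train_sample_ids),
                               "acute_loss", "between")
        # 18 subjects x 2 conditions at samples #1 and #9 -> 72 units, 36/class
        assert len(ls.target) == 72
        assert ls.class_counts() == {"positive": 36, "negative": 36}

    def test_gt24_threshold_labels(self, cohort36):
        matrix, meta, _ = cohort36
        ls = assemble_variable(matrix, meta, "gt24", "between")
        hours = ls.hours
        assert (ls.target[hours == 22.5] == 0).all()
        assert (ls.target[hours == 25.5] == 1).all()

    def test_time_awake_within_targets_follow_test_sample(self, cohort36):
        matrix, meta, _ = cohort36
        ls = assemble_variable(matrix, meta, "time_awake", "within")
        # 9 differenced samples per block
        assert len(ls.target) == 36 * 2 * 9
        assert ls.target.min() >= 10.5  # first test sample is #2

    def test_chronic_fallback_to_sample2(self, cohort36):
        matrix, meta, _ = cohort36
        df = meta.df
        drop = df[(df["subject_id"] == "S03") & (df["condition"] == "sufficient")
                  & (df["sample_index"] == 1)].index
        keep = [s for s in meta.sample_ids if s not in set(drop)]
        ls = assemble_variable(matrix.subset_samples(keep), meta.subset(keep),
                               "chronic_insufficiency", "between")
        assert len(ls.target) == 72
        used = [u for u in ls.unit_ids if u.startswith("S03_suf")]
        assert used and df.loc[used[0], "sample_index"] == 2

    def test_sleep_change_positive_is_decrease(self, cohort36):
        matrix, meta, _ = cohort36
        ls = assemble_variable(matrix, meta, "sleep_change", "within")
        df = meta.df
        assert len(ls.target) == 36
        first_cond = df[df["visit"] == 1].groupby("subject_id")["condition"].first()
        for uid, subject in ls.subject.items():
            expected = 1 if first_cond[subject] == "sufficient" else 0
            assert ls.target[uid] == expected

    def test_unknown_variable_rejected(self, cohort36):
        matrix, meta, _ = cohort36
        with pytest.raises(ValueError, match="unknown variable"):
            assemble_variable(matrix, meta, "melatonin", "between")

    def test_train_val_unit_disjointness(self, cohort36):
        matrix, meta, _ = cohort36
        for scheme_split in (split_upus(meta, seed=7), split_opus(meta, seed=7)):
            tr = assemble_variable(matrix.subset_samples(scheme_split.train_sample_ids),
                                   meta.subset(scheme_split.train_sample_ids),
                                   "acute_loss", "between")
            va = assemble_variable(matrix.subset_samples(scheme_split.validation_sample_ids),
                                   meta.subset(scheme_split.validation_sample_ids),
                                   "acute_loss", "between")
            assert set(tr.unit_ids).isdisjoint(va.unit_ids)
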