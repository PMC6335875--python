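"""End-to-end experiment orchestration.

``run_experiment`` mirrors the biomarker-discovery workflow: simulate or load
a cohort, normalize, filter quality-flagged features on the training side
only, build UPUS/OPUS splits, assemble each sleep-debt variable, optionally
restrict to an a-priori screened feature set, tune lambda by repeated k-fold
CV, finalize the model on the full training side, then evaluate by LOSO-CV
and independent validation.  Every random step draws its seed from a single
master seed through a documented counter scheme, so a rerun with the same
config reproduces all numbers exactly.

Seed counters (spawn keys of ``numpy.random.SeedSequence(master_seed)``):
0 = cohort simulation; 1 = UPUS split; 2 = OPUS split; for combination i (in
stable enumeration order) 10 + 2*i = lambda tuning and 11 + 2*i = LOSO-CV.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SyntheticConfig, generate_cohort
from .io import (
    ExpressionMatrix,
    SampleMetadata,
    filter_flagged,
    percentile_normalize,
    read_expression,
    read_metadata,
)
from .metrics import classify_gt24, confusion, effect_size_matrix, metrics
from .partition import LabeledSet, assemble_variable, split_opus, split_upus
from .screen import screen_features, select_a_priori
from .tuning import finalize_model, repeated_cv_lambda
from .validation import independent_validate, loso_cv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AuditLog", "run_experiment", "apply_model", "summarize_metrics"]

# which modes make sense for each variable
VARIABLE_MODES = {
    "time_awake": ("between", "within"),
    "gt24": ("between",),
    "acute_loss": ("between", "within"),
    "chronic_insufficiency": ("between",),
    "sleep_change": ("within",),
}
VARIABLE_FAMILY = {
    "time_awake": "linear",
    "gt24": "linear",  # linear prediction thresholded at 24 hr
    "acute_loss": "logistic",
    "chronic_insufficiency": "logistic",
    "sleep_change": "logistic",
}
VARIABLE_APRIORI_SET = {
    "time_awake": "hours_awake",
    "gt24": "hours_awake",
    "acute_loss": "hours_awake",
    "chronic_insufficiency": "sleep_sufficiency",
    "sleep_change": "sleep_sufficiency",
}
METHOD_ALPHA = {"elastic_net": 0.5, "ridge": 0.0}


@dataclass
class RunConfig:
    cohort: dict = field(default_factory=lambda: {"synthetic": {"n_subjects": 12, "n_features": 2000}})
    variables: list = field(default_factory=lambda: list(VARIABLE_MODES))
    schemes: list = field(default_factory=lambda: ["UPUS", "OPUS"])
    modes: list = field(default_factory=lambda: ["between", "within"])
    feature_inputs: list = field(default_factory=lambda: ["all_features", "a_priori"])
    methods: list = field(default_factory=lambda: ["elastic_net", "ridge"])
    chronic_indexes: list = field(default_factory=lambda: [1])
    sleep_change_indexes: list = field(default_factory=lambda: [2])
    k: int = 10
    repeats: int = 20
    loso_repeats: int = 5
    refit_lambda: bool = True
    n_lambda: int = 50
    ratio: float = 1e-3
    alpha_screen: float = 0.05
    percentile: float = 75.0
    flag_threshold: float = 0.10
    reference_fallback: bool = True
    ridge_all_features: bool = False  # ridge keeps every feature; pair it with a-priori input
    seed: int = 0
    output_dir: str = "sleepdebt_run"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def validate(self) -> None:
        bad = set(self.variables) - set(VARIABLE_MODES)
        if bad:
            raise ValueError(f"unknown variable(s): {sorted(bad)}")
        bad = set(self.schemes) - {"UPUS", "OPUS"}
        if bad:
            raise ValueError(f"unknown scheme(s): {sorted(bad)}")
        bad = set(self.methods) - set(METHOD_ALPHA)
        if bad:
            raise ValueError(f"unknown method(s): {sorted(bad)}")
        bad = set(self.feature_inputs) - {"all_features", "a_priori"}
        if bad:
            raise ValueError(f"unknown feature input(s): {sorted(bad)}")


class AuditLog:
    """Records which data side each pipeline stage touched; tests assert that
    no training-side stage ever reads validation values."""

    def __init__(self):
        self.records: list[tuple[str, str, str]] = []

    def record(self, stage: str, side: str, combo: str = "") -> None:
        self.records.append((stage, side, combo))

    def training_stages_clean(self) -> bool:
        train_only = {"flag_filter", "screen", "tune", "fit", "loso"}
        return all(side == "train" for stage, side, _ in self.records if stage in train_only)


def _child_seed(master: int, counter: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(counter,)).generate_state(1)[0] % (2**31))


def _load_cohort(cfg: RunConfig, seed: int):
    if "synthetic" in cfg.cohort:
        kw = dict(cfg.cohort["synthetic"])
        kw.setdefault("seed", seed)
        sc = SyntheticConfig(**kw)
        matrix, meta, truth = generate_cohort(sc)
        return matrix, meta, truth
    files = cfg.cohort["files"]
    matrix = read_expression(files["expression"], files.get("flags"))
    meta = read_metadata(files["samples"], matrix)
    return matrix, meta, None


def _assemblies(variable: str, cfg: RunConfig):
    """(mode, sample_index) pairs requested for one variable."""
    out = []
    for mode in VARIABLE_MODES[variable]:
        if mode not in cfg.modes:
            continue
        if variable == "chronic_insufficiency":
            out.extend((mode, ix) for ix in cfg.chronic_indexes)
        elif variable == "sleep_change":
            out.extend((mode, ix) for ix in cfg.sleep_change_indexes)
        else:
            out.append((mode, None))
    return out


def _combo_tag(scheme, variable, mode, sample_index, feature_input, method) -> str:
    ix = "" if sample_index is None else f"_i{sample_index}"
    return f"{scheme}_{variable}{ix}_{mode}_{feature_input}_{method}"


def _cls_row(prefix: str, cls) -> dict:
    if cls is None:
        return {f"{prefix}_{m}": float("nan") for m in ("ACC", "Sn", "Sp", "MCC")}
    return {
        f"{prefix}_ACC": cls.acc,
        f"{prefix}_Sn": cls.sn,
        f"{prefix}_Sp": cls.sp,
        f"{prefix}_MCC": cls.mcc,
    }


def run_experiment(config: RunConfig, audit: AuditLog | None = None) -> str:
    config.validate()
    audit = audit if audit is not None else AuditLog()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "panels"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "predictions"), exist_ok=True)
    t_start = time.time()

    matrix, meta, _truth = _load_cohort(config, _child_seed(config.seed, 0))
    matrix = percentile_normalize(matrix, config.percentile)

    splits = {}
    if "UPUS" in config.schemes:
        splits["UPUS"] = split_upus(meta, seed=_child_seed(config.seed, 1))
    if "OPUS" in config.schemes:
        splits["OPUS"] = split_opus(meta, seed=_child_seed(config.seed, 2))

    rows = []
    failures = []
    notes = []
    timings = {}
    combo_counter = 0

    for scheme, split in splits.items():
        train_m = matrix.subset_samples(split.train_sample_ids)
        val_m = matrix.subset_samples(split.validation_sample_ids)
        train_meta = meta.subset(split.train_sample_ids)
        val_meta = meta.subset(split.validation_sample_ids)

        # flag filter computed on the training side only
        audit.record("flag_filter", "train", scheme)
        train_m, (val_m,) = filter_flagged(train_m, [val_m], config.flag_threshold)

        screen = None
        apriori_sets = {}
        scheme_inputs = list(config.feature_inputs)
        if "a_priori" in config.feature_inputs:
            audit.record("screen", "train", scheme)
            try:
                screen = screen_features(train_m, train_meta, config.alpha_screen)
                apriori_sets = {
                    name: select_a_priori(screen, name)
                    for name in ("hours_awake", "sleep_sufficiency")
                }
                screen.to_csv(os.path.join(outdir, f"screen_{scheme}.tsv"), sep="\t")
            except ValueError as exc:
                # e.g. OPUS training sides hold one condition per subject, so
                # the paired condition test is undefined there
                failures.append(("screen", scheme, "", str(exc)))
                scheme_inputs = [fi for fi in scheme_inputs if fi != "a_priori"]

        for variable in config.variables:
            for mode, sample_index in _assemblies(variable, config):
                try:
                    ls_train = assemble_variable(
                        train_m, train_meta, variable if variable != "gt24" else "time_awake",
                        mode, fallback=config.reference_fallback, sample_index=sample_index,
                    )
                    ls_val = assemble_variable(
                        val_m, val_meta, variable if variable != "gt24" else "time_awake",
                        mode, fallback=config.reference_fallback, sample_index=sample_index,
                    )
                except ValueError as exc:
                    failures.append((variable, mode, scheme, str(exc)))
                    continue
                notes.extend(ls_train.notes + ls_val.notes)
                family = VARIABLE_FAMILY[variable]
                # stratify linear fold assignment on the condition label
                strata = None
                if family == "linear":
                    strata = (
                        train_meta.df.loc[ls_train.unit_ids, "condition"].to_numpy()
                        if set(ls_train.unit_ids) <= set(train_meta.sample_ids)
                        else None
                    )
                for feature_input in scheme_inputs:
                    for method in config.methods:
                        if method == "ridge" and feature_input == "all_features" and not config.ridge_all_features:
                            continue
                        tag = _combo_tag(scheme, variable, mode, sample_index, feature_input, method)
                        t0 = time.time()
                        try:
                            row = _run_combo(
                                config, audit, outdir, tag, scheme, variable, mode,
                                sample_index, feature_input, method, family,
                                ls_train, ls_val, apriori_sets, strata, combo_counter,
                            )
                            rows.append(row)
                        except Exception as exc:  # per-combination isolation
                            logger.exception("combination %s failed", tag)
                            failures.append((tag, "", "", str(exc)))
                        timings[tag] = round(time.time() - t0, 3)
                        combo_counter += 1

    metrics_df = pd.DataFrame(rows)
    metrics_path = os.path.join(outdir, "metrics.tsv")
    if len(metrics_df):
        metrics_df.to_csv(metrics_path, sep="\t", index=False, float_format="%.10g",
                          lineterminator="\n")
    else:
        with open(metrics_path, "w") as fh:
            fh.write("")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "master_seed": config.seed,
        "seed_scheme": "SeedSequence(master, spawn_key=(counter,)): 0 simulate, 1 UPUS, 2 OPUS, 10+2i tune, 11+2i LOSO",
        "failures": [list(f) for f in failures],
        "notes": notes,
        "timings_s": timings,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir


def _run_combo(config, audit, outdir, tag, scheme, variable, mode, sample_index,
               feature_input, method, family, ls_train: LabeledSet, ls_val: LabeledSet,
               apriori_sets, strata, combo_counter) -> dict:
    alpha = METHOD_ALPHA[method]
    Xtr, ytr = ls_train.X, ls_train.target
    Xval = ls_val.X
    if feature_input == "a_priori":
        wanted = apriori_sets.get(VARIABLE_APRIORI_SET[variable], [])
        keep = [f for f in wanted if f in Xtr.columns]
        if not keep:
            raise ValueError(f"a-priori set {VARIABLE_APRIORI_SET[variable]} empty for {tag}")
        Xtr = Xtr[keep]
        Xval = Xval[keep]

    # lambda tuning and final fit use training data only
    audit.record("tune", "train", tag)
    tune_seed = _child_seed(config.seed, 10 + 2 * combo_counter)
    target_tr = ytr.to_numpy(dtype=float) if variable != "gt24" else ls_train.hours.to_numpy()
    target_val = ls_val.target.to_numpy(dtype=float) if variable != "gt24" else ls_val.hours.to_numpy()
    cv = repeated_cv_lambda(
        Xtr, target_tr, family=family, alpha=alpha, k=min(config.k, len(target_tr)),
        repeats=config.repeats, seed=tune_seed, n_lambda=config.n_lambda,
        ratio=config.ratio, strata=strata,
    )
    audit.record("fit", "train", tag)
    final = finalize_model(Xtr, target_tr, family, alpha, cv)
    panel = final.nonzero_panel()
    with open(os.path.join(outdir, "panels", f"{tag}.txt"), "w") as fh:
        fh.write("\n".join(map(str, panel)) + ("\n" if panel else ""))

    # LOSO-CV on the training side
    audit.record("loso", "train", tag)
    loso_seed = _child_seed(config.seed, 11 + 2 * combo_counter)
    fold_flags = ls_train.flags[Xtr.columns] if ls_train.flags is not None else None
    ls_for_loso = LabeledSet(
        variable, mode, Xtr,
        pd.Series(target_tr, index=Xtr.index, name="target"),
        ls_train.subject, ls_train.positive_class, ls_train.hours, fold_flags, [],
    )
    loso = loso_cv(
        ls_for_loso, family=family, alpha=alpha, k=config.k,
        repeats=config.loso_repeats, seed=loso_seed, n_lambda=config.n_lambda,
        ratio=config.ratio, refit_lambda=config.refit_lambda,
        lam=cv.mean_lambda,
        flag_threshold=config.flag_threshold if fold_flags is not None else None,
    )

    # independent validation
    audit.record("predict_validation", "validation", tag)
    ls_val_use = LabeledSet(
        variable, mode, Xval,
        pd.Series(target_val, index=Xval.index, name="target"),
        ls_val.subject, ls_val.positive_class, ls_val.hours, None, [],
    )
    iv = independent_validate(final, ls_val_use)

    row = {
        "variable": variable,
        "sample_index": "" if sample_index is None else sample_index,
        "scheme": scheme,
        "mode": mode,
        "feature_input": feature_input,
        "method": method,
        "family": family,
        "n_train": len(target_tr),
        "n_val": len(target_val),
        "n_features_in": Xtr.shape[1],
        "panel_size": len(panel),
        "lambda": cv.mean_lambda,
    }
    if variable == "gt24":
        # classify by thresholding the predicted time awake at 24 hr
        loso_truth = (loso.predictions["truth"].to_numpy() > 24.0).astype(int)
        loso_cls = metrics(confusion(loso_truth, classify_gt24(loso.predictions["score"]),
                                     boundary=0.5, probability_mode=False))
        iv_truth = (iv.predictions["truth"].to_numpy() > 24.0).astype(int)
        iv_cls = metrics(confusion(iv_truth, classify_gt24(iv.predictions["score"]),
                                   boundary=0.5, probability_mode=False))
        row.update(_cls_row("loso", loso_cls))
        row["loso_R2"] = float("nan")
        row.update(_cls_row("iv", iv_cls))
        row["iv_R2"] = float("nan")
    elif family == "linear":
        row.update(_cls_row("loso", None))
        row["loso_R2"] = loso.regression.r2
        row.update(_cls_row("iv", None))
        row["iv_R2"] = iv.regression.r2
        if mode == "between":
            es = effect_size_matrix(iv.predictions["score"], iv.predictions["truth"])
            es.to_csv(os.path.join(outdir, "predictions", f"{tag}_effectsizes.tsv"),
                      sep="\t", float_format="%.10g", lineterminator="\n")
    else:
        row.update(_cls_row("loso", loso.classification))
        row["loso_R2"] = float("nan")
        row.update(_cls_row("iv", iv.classification))
        row["iv_R2"] = float("nan")

    preds = pd.concat(
        [loso.predictions.assign(approach="LOSO-CV"), iv.predictions.assign(approach="IV")],
        ignore_index=True,
    )
    preds.to_csv(os.path.join(outdir, "predictions", f"{tag}.tsv"), sep="\t",
                 index=False, float_format="%.10g", lineterminator="\n")
    return row


def apply_model(model_path, expression_path, flags_path=None) -> pd.DataFrame:
    """Apply a serialized model to a new expression matrix (samples scored
    column-wise); used by the CLI ``validate`` command."""
    from .penalized import PenalizedModel

    model = PenalizedModel.from_tsv(model_path)
    matrix = read_expression(expression_path, flags_path)
    scores = model.predict(matrix.values.T)
    return pd.DataFrame({"sample_id": matrix.sample_ids, "score": scores})


def summarize_metrics(metrics_path) -> str:
    """Human-readable summary of a metrics.tsv: whole-percent classification
    metrics (matching the usual reporting style) and 2-decimal R^2/MCC."""
    df = pd.read_csv(metrics_path, sep="\t")
    lines = []
    for _, r in df.iterrows():
        head = (f"{r['variable']}{'' if pd.isna(r['sample_index']) or r['sample_index'] == '' else '#' + str(r['sample_index'])}"
                f" [{r['scheme']}/{r['mode']}] {r['feature_input']}+{r['method']}"
                f" (n_train={r['n_train']}, n_val={r['n_val']}, panel={r['panel_size']})")
        lines.append(head)
        for prefix, label in (("loso", "LOSO-CV"), ("iv", "IV")):
            if not pd.isna(r.get(f"{prefix}_ACC", float("nan"))):
                lines.append(
                    f"  {label}: ACC = {round(100 * r[f'{prefix}_ACC'])}%"
                    f" Sn = {round(100 * r[f'{prefix}_Sn'])}%"
                    f" Sp = {round(100 * r[f'{prefix}_Sp'])}%"
                    f" MCC = {round(r[f'{prefix}_MCC'], 2)}"
                )
            elif not pd.isna(r.get(f"{prefix}_R2", float("nan"))):
                lines.append(f"  {label}: R^2 = {round(r[f'{prefix}_R2'], 2)}")
    return "\n".join(lines)
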