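"""Synthetic crossover sleep-debt transcriptome cohorts with known ground truth.

The generator emulates the design of a balanced crossover sleep study: each
subject completes two laboratory visits, one after a week of sufficient sleep
and one after a week of insufficient sleep, and during each visit donates ten
3-hourly blood samples spanning roughly 7 to 35 hours of continuous
wakefulness.  Log2 expression for feature g in subject s at a timepoint is

    value = mu_g + u_{g,s} + a_g * hours_awake
            + b_g * cos(2*pi*(clock_time - phi_g)/24)
            + delta_g * 1[condition == insufficient] + noise

with a subject "trait" effect u_{g,s} ~ N(0, tau_g^2) drawn once per
(feature, subject) and shared across the subject's two visits — the property
that makes between-subject prediction hard and within-subject differencing
effective.  Ground-truth feature classes (trend / circadian / condition /
mixed / null) are returned alongside the data so that screening and panel
selection can be scored against the truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "default_timepoints",
    "generate_cohort",
    "cohort_to_files",
]

SUFFICIENT = "sufficient"
INSUFFICIENT = "insufficient"


def default_timepoints() -> list[tuple[int, float, float]]:
    """Ten 3-hourly samples: hours awake 7.5..34.5, first draw at ~15:30.

    Returns (sample_index, hours_awake, clock_time) triples; clock time wraps
    modulo 24.
    """
    return [(k + 1, 7.5 + 3.0 * k, (15.5 + 3.0 * k) % 24.0) for k in range(10)]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Effect magnitudes are in log2 units; ``trend_slope`` is log2 units per
    hour awake.  Defaults mirror the real study's scale: 36 subjects
    (18 male), ~20k features, large trait-like between-subject variance
    relative to state effects.
    """

    n_subjects: int = 36
    n_features: int = 20_000
    n_trend: int = 500
    n_circadian: int = 2_000
    n_condition: int = 300
    n_mixed: int = 100
    trend_slope: float = 0.02
    circadian_amplitude: float = 0.3
    condition_effect: float = 0.3
    trait_sd: float = 1.0
    noise_sd: float = 0.4
    flag_rate: float = 0.01
    timepoints: list[tuple[int, float, float]] = field(default_factory=default_timepoints)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
            "n_trend": self.n_trend,
            "n_circadian": self.n_circadian,
            "n_condition": self.n_condition,
            "n_mixed": self.n_mixed,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        labelled = self.n_trend + self.n_circadian + self.n_condition + self.n_mixed
        if labelled > self.n_features:
            raise ValueError(
                "n_trend + n_circadian + n_condition + n_mixed "
                f"({labelled}) exceeds n_features ({self.n_features})"
            )
        for name in ("trait_sd", "noise_sd", "circadian_amplitude"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("trend_slope", "condition_effect"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not (0.0 <= self.flag_rate <= 1.0):
            raise ValueError(f"flag_rate must lie in [0, 1], got {self.flag_rate!r}")
        if len(self.timepoints) < 1:
            raise ValueError("timepoints must be non-empty")
        idx = [t[0] for t in self.timepoints]
        if len(set(idx)) != len(idx):
            raise ValueError("timepoints sample_index values must be unique")


def _feature_truth(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    p = cfg.n_features
    classes = np.array(["null"] * p, dtype=object)
    lo = 0
    for name, n in (
        ("trend", cfg.n_trend),
        ("circadian", cfg.n_circadian),
        ("condition", cfg.n_condition),
        ("mixed", cfg.n_mixed),
    ):
        classes[lo : lo + n] = name
        lo += n

    a = np.zeros(p)
    b = np.zeros(p)
    phi = np.zeros(p)
    delta = np.zeros(p)
    mu = rng.normal(7.0, 2.0, size=p)
    tau = np.full(p, float(cfg.trait_sd))

    sign = rng.choice([-1.0, 1.0], size=p)
    is_trend = (classes == "trend") | (classes == "mixed")
    is_circ = classes == "circadian"
    is_cond = (classes == "condition") | (classes == "mixed")
    a[is_trend] = sign[is_trend] * cfg.trend_slope
    b[is_circ] = cfg.circadian_amplitude
    phi[is_circ] = rng.uniform(0.0, 24.0, size=int(is_circ.sum()))
    # mixed features get an independent sign for the condition shift
    sign2 = rng.choice([-1.0, 1.0], size=p)
    delta[is_cond] = np.where(classes[is_cond] == "mixed", sign2[is_cond], sign[is_cond])
    delta[is_cond] *= cfg.condition_effect

    feature_ids = [f"F{i + 1:05d}" for i in range(p)]
    return pd.DataFrame(
        {
            "class": classes,
            "a_g": a,
            "b_g": b,
            "phi_g": phi,
            "delta_g": delta,
            "mu_g": mu,
            "tau_g": tau,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def _design(cfg: SyntheticConfig) -> pd.DataFrame:
    """Sample metadata for the full crossover: sexes alternate across
    subjects; the first floor(n/2) subjects have visit order
    sufficient -> insufficient, the rest the reverse."""
    rows = []
    half = cfg.n_subjects // 2
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        sex = "M" if s % 2 == 0 else "F"
        order = (SUFFICIENT, INSUFFICIENT) if s < half else (INSUFFICIENT, SUFFICIENT)
        for visit, cond in enumerate(order, start=1):
            for sample_index, hours_awake, clock_time in cfg.timepoints:
                rows.append(
                    {
                        "sample_id": f"{subject}_{cond[:3]}_{sample_index:02d}",
                        "subject_id": subject,
                        "sex": sex,
                        "condition": cond,
                        "visit": visit,
                        "sample_index": sample_index,
                        "hours_awake": float(hours_awake),
                        "clock_time": float(clock_time),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(cfg: SyntheticConfig):
    """Generate (ExpressionMatrix, SampleMetadata, truth DataFrame).

    Deterministic given ``cfg.seed``: identical seeds give bit-identical
    output.
    """
    from .io import ExpressionMatrix, SampleMetadata

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = _feature_truth(cfg, rng)
    meta = _design(cfg)

    p = cfg.n_features
    n = len(meta)
    subjects = meta["subject_id"].to_numpy()
    subj_codes, subj_idx = np.unique(subjects, return_inverse=True)

    # trait effect: one draw per (feature, subject), shared across visits
    u = rng.normal(0.0, 1.0, size=(p, len(subj_codes))) * truth["tau_g"].to_numpy()[:, None]

    hours = meta["hours_awake"].to_numpy()
    clock = meta["clock_time"].to_numpy()
    insuff = (meta["condition"] == INSUFFICIENT).to_numpy().astype(float)

    a = truth["a_g"].to_numpy()[:, None]
    b = truth["b_g"].to_numpy()[:, None]
    phi = truth["phi_g"].to_numpy()[:, None]
    delta = truth["delta_g"].to_numpy()[:, None]
    mu = truth["mu_g"].to_numpy()[:, None]

    values = (
        mu
        + u[:, subj_idx]
        + a * hours[None, :]
        + b * np.cos(2.0 * np.pi * (clock[None, :] - phi) / 24.0)
        + delta * insuff[None, :]
    )
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=(p, n))
    flags = (rng.random(size=(p, n)) < cfg.flag_rate).astype(np.int8)

    vdf = pd.DataFrame(values, index=truth.index.copy(), columns=meta.index.copy())
    fdf = pd.DataFrame(flags, index=truth.index.copy(), columns=meta.index.copy())
    matrix = ExpressionMatrix(values=vdf, flags=fdf)
    metadata = SampleMetadata(meta)
    return matrix, metadata, truth


def cohort_to_files(matrix, metadata, truth: pd.DataFrame, directory) -> dict[str, str]:
    """Write expression.tsv / flags.tsv / samples.tsv / truth.tsv.

    Values round-trip losslessly through :func:`sleepdebt.io.read_expression`
    (pandas writes shortest-exact float representations).
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "flags": os.path.join(directory, "flags.tsv"),
        "samples": os.path.join(directory, "samples.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    matrix.values.to_csv(paths["expression"], sep="\t", lineterminator="\n")
    matrix.flags.astype(int).to_csv(paths["flags"], sep="\t", lineterminator="\n")
    metadata.df.to_csv(paths["samples"], sep="\t", lineterminator="\n")
    truth.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    return paths
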