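# Methods

## Study design emulated by the generator

The synthetic cohort reproduces the statistical structure of a balanced
crossover sleep-restriction protocol. Each of `n_subjects` (default 36,
alternating sex) completes two laboratory visits; after one week of
*sufficient* sleep or one week of *insufficient* sleep (order
counterbalanced: the first ⌊n/2⌋ subjects are sufficient-first), the subject
stays awake for ~40 h under constant conditions while ten blood samples are
drawn 3-hourly. Sample #1 is taken at 15:30 clock time, 7.5 h after waking;
sample #10 at 34.5 h awake. Clock time wraps modulo 24, so within a visit
circadian phase and time awake advance together — the confound the real
protocol has, reproduced deliberately.

Log2 expression of feature *g* in subject *s* at a timepoint is

    y = μ_g + u_{g,s} + a_g·t_awake + b_g·cos(2π(t_clock − φ_g)/24)
        + δ_g·1[condition = insufficient] + ε,

with the subject trait effect `u_{g,s} ~ N(0, τ_g²)` drawn once per
(feature, subject) and shared across the subject's two visits, and
`ε ~ N(0, noise_sd²)` independent per measurement. Features are labelled
trend / circadian / condition / mixed (trend + condition) / null, with signs
of `a_g` and `δ_g` random, circadian acrophase uniform on [0, 24), and
baselines `μ_g ~ N(7, 2²)`. Every measurement is independently quality-flagged
with probability `flag_rate`. Identical seeds give bit-identical cohorts.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 36 | size of the emulated cohort (18 male, 18 female) |
| `n_features` | 20 000 | microarray scale |
| `trend_slope` | 0.02 log2/h | ~0.5 log2 units across 27 h awake, a moderate time-awake response |
| `circadian_amplitude` | 0.3 log2 | typical rhythmic amplitude for rhythmic blood transcripts |
| `condition_effect` | 0.3 log2 | chronic state effects are small — far below trait variance |
| `trait_sd` | 1.0 log2 | trait-like variance dominating the state effects; the within/between ratio is not published, so this is a package choice |
| `noise_sd` | 0.4 log2 | residual measurement noise; package choice, same caveat |
| `flag_rate` | 0.01 | sparse quality failures |

What the generator does **not** emulate: probe-level artifacts, batch and
spatial effects, heteroskedastic or multiplicative noise, correlated feature
blocks beyond the shared trend/clock/condition terms, dropout patterns of the
real cohort, and melatonin or any physiological channel. Effects are additive
on the log2 scale. Passing tests therefore demonstrate that the *pipeline*
behaves correctly under the design's statistical structure — subject-trait
dominance, circadian/time-awake confounding, crossover labelling — not that
any particular gene panel in real data is correct.

## Preprocessing

* **75th-percentile normalization** subtracts each sample's 75th percentile
  (linear-interpolation convention) from that sample's log2 values. A shift —
  not a division — because the data are already log-scale; this makes the
  operation idempotent and preserves within-sample contrasts exactly.
* **Replicate averaging** takes the arithmetic mean per replicate group; a
  group is flagged if any member is flagged (conservative OR).
* **Flag filtering** removes features flagged in strictly more than 10% of
  *training* samples; the removal is applied identically to the validation
  matrix, whose flags never influence the decision.
* **Baseline correction** turns each (subject, condition) block into
  test-minus-reference differences against sample #1 (optionally sample #2
  when #1 is missing), dropping the reference. This removes the trait term
  `u_{g,s}` exactly, which is why within-subject analyses survive trait
  dominance.

## Partitions and variables

UPUS assigns whole subjects to train/validation, stratified on sex; OPUS
sends one sleep-history condition per subject to each side, randomized under
the constraint that each side's sufficient/insufficient block counts differ
by at most one. Five sleep-debt variables are assembled: time awake
(regression, between- or within-subject), wakefulness > 24 h (classification
by thresholding the predicted time awake at 24 h; a prediction of exactly 24
classifies negative), acute sleep loss (samples #1 vs #9, or differenced
#2−#1 vs #10−#1), chronic sleep insufficiency (sample #1 per condition,
fallback #2; variant at #9/#10), and sleep increase/decrease (visit-1 minus
visit-2 difference at sample #2, fallback #3; variant at #9/#10; *decrease*
is the positive class — a convention, surfaced in reports).

## The a-priori screen

Three desk-scale tests with shared, vectorized designs substitute for the
original mixed-model time-course machinery while keeping the same selection
semantics:

* **trend**: per condition, OLS of abundance on hours awake after
  subject-mean centering (t test, df = n − #subjects − 1);
* **circadian**: cosinor regression on cos/sin of clock time with an
  hours-awake nuisance term, subject-centered; joint F test on the two
  rhythm coefficients; amplitude = √(β_cos² + β_sin²);
* **condition**: paired t test of subject-level condition means.

The *hours awake* set requires a trend significant in both conditions with
concordant sign, no circadian modulation and no condition difference; the
*sleep sufficiency* set requires a condition difference, no circadian
modulation and no trend in either condition. No multiple-testing correction
is applied at the screen stage; `alpha_screen` (default 0.05) is a knob. Note
the sets are conjunctions of positive criteria with *negated* exclusions, so
tightening `alpha_screen` shrinks the qualifying pools but simultaneously
relaxes the exclusions — the net set size is not strictly monotone in alpha.

## Penalized regression

The solver minimizes the glmnet-convention objective (1/2n normalization, so
lambda is sample-size stable) over features standardized internally to zero
mean and unit population variance, with an unpenalized intercept;
coefficients are reported back on the original scale. Linear fits use cyclic
coordinate descent with an active-set strategy (full sweep, then iterate the
nonzero set to convergence, then a full verification sweep); logistic fits
wrap that in penalized IRLS with probabilities clipped at 1e-5. Convergence
is a maximum absolute coefficient change below `tol` (1e-7 for final fits,
1e-4 inside cross-validation, where the selected lambda is insensitive to the
last decimals). The objective is non-increasing across sweeps (asserted in
tests), warm-started path fits match cold starts, and subgradient optimality
holds at 1e-5 on random problems.

Numerical choices: λ_max = max_j |⟨x_j, w⟩| / (n·max(α, 0.001)) with *w* the
null-model working response (the 0.001 floor gives ridge a finite grid),
nudged up by a factor (1 + 1e-9) so the boundary feature is exactly zero at
λ_max; grids are log-spaced over `ratio` = 1e-3 by default. Binomial path
fits stop refining once >99% of the null deviance is explained
(near-separation, routine when n ≪ p at small lambda): beyond that point the
fit cannot meaningfully improve and unbounded coefficient growth only
destabilizes the IRLS weights. Zero-variance features are retained with a
unit standardization divisor and necessarily receive zero coefficients.

## Lambda tuning and validation

The operating lambda is the arithmetic mean (raw scale — no transform) of the
per-repeat argmins of mean held-out error over stratified 10-fold CV
(squared error for linear, binomial deviance for logistic; folds stratified
on the class, or on the condition label for linear targets). Ties at the
argmin resolve to the larger lambda (the sparser model). 500 repeats is the
reference setting; tests and scenarios use 10–20, which moves the mean lambda
by less than its repeat-wise standard error (asserted). The final model is
one fit on the full training set at exactly the mean lambda.

LOSO-CV removes all of a subject's units per fold and reruns flag filtering,
lambda tuning (at a reduced repeat count, `loso_repeats`) and the final fit
before predicting the held-out units; a flag also allows reusing a fixed
lambda per fold. Undefined metrics (zero confusion-matrix denominators, e.g.
when an exactly-null model assigns every sample to one class at the 0.5
boundary, ties classifying negative) are reported as NA, never 0. Percentage
metrics are rounded to whole percent in human-readable summaries and kept at
full precision in machine-readable output.

## Validation scenarios (`sleepdebt.benchmarks`)

* **Panel recovery**: 10 co-regulated informative features (shared latent,
  marginal standardized effect 3) among 2,000, n = 60 — the scale of the
  acute-loss training sets. The tuned panel recovers the true features
  essentially always. The panel also carries null features (typically
  30–80% of the panel, though under 2% of the 1,990 nulls): the argmin-CV
  tuning rule necessarily selects a lambda below the noise-entry point,
  because the shrinkage bias of the true coefficients falls first-order in
  lambda while the first noise entrants cost only second-order. A sparser
  rule (e.g. one-standard-error) would avoid this but is deliberately out of
  scope; the benchmark reports the purity honestly.
* **Acute scenario**: 30 trend features at 0.05 log2/h make samples #1 vs #9
  nearly separable (per-feature d ≈ 1.1, multivariate Bayes error ≪ 5%);
  independent validation accuracy and the LOSO−IV gap verify end-to-end
  correctness of the between-subject path.
* **Chronic scenario**: condition effect 0.2 vs trait sd 2.0 with 40
  condition features. Between-subject classification from one sample is near
  chance by design (multivariate Bayes accuracy ≈ 65%); within-subject
  differencing (sleep increase/decrease at sample #2) removes the trait term
  and classifies accurately. Both arms use the sleep-sufficiency screen
  computed on the training side.
* **OPUS pathology**: no condition effect; the OPUS condition-to-side
  assignment is a deterministic function of a per-subject latent (mean of a
  5-feature trait block). The model learns the latent; every subject's
  validation sample carries the opposite label; IV MCC goes strongly
  negative. The UPUS LOSO control on the same cohort has labels balanced
  within subject, so the pipeline's tuned model is at or near the null model
  and the pooled MCC is near zero or NA — never below-chance.

## Pipeline reproducibility

`run_experiment` derives every random operation's seed from one master seed
via `numpy.random.SeedSequence(master, spawn_key=(counter,))` with a fixed
counter registry (0 simulation, 1 UPUS, 2 OPUS, 10+2i tuning and 11+2i
LOSO-CV for the i-th combination in stable enumeration order), so rerunning a
config reproduces `metrics.tsv` byte for byte. An audit log records which
data side each stage touched; tests assert that no training-side stage
(filtering, screening, tuning, fitting, LOSO) ever reads validation values.
Desk-scale defaults (12 subjects, 2,000 features, 20 tuning repeats, 5 LOSO
repeats, 50-point grids) keep a full grid under a quarter hour on one core.

## Known limitations

* The a-priori screen is a declared substitute for the original time-course
  machinery; its feature counts are not comparable to published counts.
* The OPUS scheme cannot support the paired condition test on its training
  side (one condition per subject), so a-priori combinations are skipped
  there with a recorded note.
* Effect magnitudes in the generator are constant per class (random signs and
  phases only); real effect-size distributions are long-tailed.
* The solver covers linear and logistic families only; no Cox/multinomial,
  no sparse-matrix storage, no adaptive or group penalties.
* `repeats=500` tuning at 20k features is hours of compute; the desk-scale
  settings are the tested configuration.
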