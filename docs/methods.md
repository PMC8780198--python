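# Methods

## Cohort model

The synthetic cohort emulates a neurological-ICU drift-test study: 36
patients × 4 limbs = 144 observations, each rated in three sessions (expert
GS, non-experts TS1 and TS2) within a short interval, so the true grade is
constant across sessions. True grades are drawn i.i.d. from the skewed
composition P(9, 8, 7, 5) = (0.542, 0.271, 0.152, 0.035); ages are
N(65.4, 16.02²) years clipped to [18, 100]; gender is Bernoulli(0.5)
(no composition data exists to calibrate it against).

### Forward kinematics

Each session's 20 s, 50 Hz trace is the gravity projection of a limb whose
tilt angle follows

    drift(t) = rate·t + amp·sin(2π f t)   [degrees],

with per-grade parameters

| grade | rate (deg/s) | amp (deg) | f (Hz) |
|------:|-------------:|----------:|-------:|
| 9     | 0.05         | 0.5       | 1.0    |
| 8     | 0.30         | 0.7       | 1.0    |
| 7     | 0.80         | 1.0       | 1.2    |
| 5     | 2.50         | 1.5       | 1.5    |

plus isotropic Gaussian sensor noise (default s.d. 1e-4 g — a lightly
filtered MEMS accelerometer; much larger values would let noise dominate the
total-variation feature SumOsc). This form was chosen because it is
physically plausible (steady drift plus tremor-like oscillation), has
monotone severity (weaker limb → lower grade → larger drift and
oscillation), and is exactly invertible by the feature extractor, giving
closed-form oracles. The parameters were set once so the cohort-level
feature magnitudes sit where real drift tests put them (MeanDrift a few
degrees, MaxDrift ≈ 5–10°, SumOsc tens of degrees over 20 s); the default
seed-7 cohort gives GS means of 2.95° / 6.5° / 57.0°.

Sessions differ through (a) a lognormal jitter `exp(N(0, σ_jitter²))` on
rate and amplitude (the patient never performs twice identically; σ 0.12
for the expert session, 0.18 for non-experts) and (b) a session noise
multiplier (1.0 expert, 1.5 non-expert). Closed-form recovery tests use
profiles with jitter 0 and noise 0.

### Manual-rating noise

A rater's manual grade is drawn from a confusion kernel
`P(rated | true) ∝ exp(−|Δindex|/spread)` over class indices of the
observed-grade scale, row-normalized; spread 0 is perfect rating and
spread → ∞ the uniform limit. Defaults — expert 0.35, non-experts 0.9 and
1.0 — were calibrated once by simulation so the manual three-rater
Krippendorff alpha lands in the "fair" reliability band (0.21–0.40), which
is where non-expert MRC scaling sits in practice, and were then frozen.

Random streams are split per (observation, rater) with
`SeedSequence([seed, tag, obs, crc32(rater_id)])`, so adding or removing a
rater never perturbs other raters' draws, and the whole cohort is bitwise
reproducible from one seed.

## Feature extraction

The tilt angle is computed per sample as the angle between the normalized
acceleration and a reference orientation — by default the normalized mean
of the first 0.5 s ("the limb starts still"); this auto reference degrades
if the patient moves immediately, a documented limitation, and an explicit
reference vector can be passed instead. Samples with ‖a‖ < 0.1 g cannot
indicate the gravity direction and are flagged as free-fall artifacts and
interpolated; more than 10% flagged samples is an error. An optional
4th-order zero-phase Butterworth low-pass (off by default, so the synthetic
forward model inverts exactly) can precede the angle computation.

SumOsc is defined as the total variation of the raw drift angle over the
window. Whether "accumulated oscillation" should instead be computed on a
detrended or band-passed angle is genuinely open; total variation of the
raw angle is the simplest reading and is what the generator's calibration
anchors assume.

## Balancing and costs

`N` must be divisible by `M`; then `n(SB_i) = N/M − n(T_i)` is exact and no
rounding policy is needed. Classes already at or above quota get their
boosting factor clamped to 0 (no undersampling). SMOTE neighbors are found
on z-scored features (k = 5, silently reduced to `n_class − 1`; a singleton
class falls back to 1%-scale jitter duplication with a warning); the
interpolation `x + u(x_nn − x)` is affine-equivariant, so synthetics are
materialized in the original feature space.

The imbalance-weighted cost matrix implements the per-class factor
`(Σ_{k≠i} n_k)/n_i` times the linear ordinal distance; as printed elsewhere
the normalization is ambiguous (the fraction cancels to 1), and this is the
one reading that yields a meaningful per-class imbalance factor — it is
isolated in `imbalance_cost_matrix` should a different convention be
wanted. Costs act on class indices of the observed scale by default, so
grades 5 and 7 are adjacent; `distance="grade"` switches to raw grade
distances.

## Classifier and selection

Base learners are CART trees. AdaBoost follows the multiclass SAMME weight
update with learning-rate-scaled vote weights; cost sensitivity multiplies
each misclassified instance's weight update by the committed cost
`c[pred, true]`, and RUSBoost additionally fits each round on a
weight-proportional random undersample capped at the minority-class size.
Cost sensitivity enters at two points — the boosting update and the
minimum-expected-cost prediction rule — each independently switchable for
ablation. Ties in expected cost break toward the lower class index, i.e.
the more severe grade (clinically conservative).

The cross-validated objective is the mean held-out realized cost
`c[pred, true]` over stratified folds of the *original* instances only;
synthetics join every training fold but are never validated on, preventing
SMOTE leakage. Model selection minimizes this objective over
family × n_learners [10, 300] × depth [1, 8] × learning rate [0.01, 1]
(log-scaled) with a GP surrogate (Matern 5/2 + white noise, one-hot family
encoding) and expected-improvement acquisition; a seeded random-search
engine is available as fallback. The config default is 50 iterations.

The end-to-end experiment and ablation default to a fixed AdaBoost spec
(60 trees, depth 3, learning rate 0.5, `selection_iterations=0`): on the
144-observation cohort the selection adds minutes per run for little change
in the reliability comparison, and the multi-seed analyses run 20 cohorts.
Full selection is one config switch (`selection_iterations=50`).

## Agreement statistics

All statistics are implemented from first principles:

- **ICC(2,k)** from the two-way ANOVA decomposition,
  `(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)`, with the F-based
  confidence interval (single-measures bound, Satterthwaite df, stepped up
  by Spearman–Brown) and p-value from `MS_R/MS_E` — the average-measures
  two-way-random conventions of McGraw & Wong. Note this is *absolute
  agreement*: systematic rater offsets keep it below 1 even with zero
  residual noise. Zero between-subject variance returns 0 with a warning.
- **Krippendorff's alpha** from the coincidence matrix (each ordered rater
  pair within a subject contributes `1/(m_u − 1)`), subjects with fewer
  than two ratings dropped, `alpha = 1 − D_o/D_e`; nominal (default),
  ordinal (cumulative-frequency metric) and interval distances. The
  nominal default matches how near-identical alpha and Fleiss-kappa values
  arise for ordinal MRC tables.
- **Fleiss' kappa** by category proportions; applied verbatim to two-rater
  tables as well (this differs from Cohen's kappa).
- **Bland–Altman** with sample (n−1) SD and a configurable LoA multiplier
  (default 1.96).

Tests cross-check alpha against an independently written pair-enumeration
oracle, ICC against an explicit ANOVA recomputation and against pingouin,
and Fleiss' kappa against statsmodels.

## Experiment protocol

The model trains on the GS session's features labeled by the GS *manual*
grades (the expert is the operational ground truth; `train_on_truth=True`
switches to simulated true grades for oracle studies), pooled across limbs
(limb id is not a feature). It then grades the TS1/TS2 sessions from their
sensor features alone — their manual ratings are never shown to the model.
The report compares (GS, TS1, TS2) with (GS, AI_TS1, AI_TS2) cell by cell:
pairwise and three-rater alpha and kappa, percent agreements and confusion
matrices vs GS, plus per-feature ICC and Bland–Altman between sessions.
Reports serialize to canonical sorted-keys JSON, so one seed gives a
byte-identical report.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* the analysis assumes — skewed
ordinal composition, grade-monotone kinematics, rater-dependent confusion,
session-to-session variability — but not the messiness of real ICU data:
non-stationary tremor spectra, partial test compliance, free-fall-like
artifacts, demographic correlations with severity, or inter-limb
correlation within a patient. Passing tests therefore demonstrate the
pipeline's correctness and the direction of the manual-to-machine
reliability improvement under these assumptions, not clinical performance.
Between-session feature ICCs in the synthetic cohort (≈ 0.97) are higher
than in real drift tests (≈ 0.74–0.85), because the jitter model leaves
between-subject variance dominant.

## Problem sizes

Default analyses use the 144-observation cohort (1000-sample traces per
session), balancing to N = 600, and 20 cohort seeds for the multi-seed
reliability comparison; each end-to-end run takes well under a second with
the fixed spec.
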