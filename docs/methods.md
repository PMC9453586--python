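# Methods

## Problem and scope

`labwatch` predicts, for each of 25 laboratory analytes, whether the value
at the next 4-hour grid step of an ICU stay will be outside its reference
interval. Stays last 12–72 hours (3–18 grid steps). Inputs are the lab
history on the grid plus three static demographics (age, sex, weight);
the output is a 25-bit abnormality vector. All models are trained on binary
cross-entropy, classified at probability threshold `TH = 0.5`, and compared
with window length `W = 6` unless configured otherwise. Real cohort
extracts are consumed through a plain CSV schema (`measurements.csv`:
stay_id, channel, time_h, value; `demographics.csv`: stay_id, age, sex,
weight, duration_steps); all experiments in this repository run on the
synthetic generator described below.

## Synthetic cohort generator

Each channel of each stay follows a latent mean-reverting AR(1) process on
the 4-hour grid,

    x_t = μ + φ (x_{t−1} − μ) + σ √(1−φ²) ε_t ,   ε_t ~ N(0,1),

(stationary mean μ = channel baseline, stationary SD σ, lag-1
autocorrelation φ, default 0.85) overlaid with *abnormal episodes* driven by
a two-state Markov chain: a normal step enters an episode with probability
`episode_rate` (default 0.03) and an episode persists with probability
`episode_persistence` (default 0.9). The chain is initialized at its
stationary law, so the per-step abnormality marginal is flat across the
stay. During an episode the latent value is

    v_t = boundary + dir · (margin · width + 0.3 · |x_t − μ|),

i.e. just past the violated range boundary (`margin` = 0.15 range-widths by
default), with the AR deviation damped by 0.3. Two properties follow by
construction: every episode step is abnormal, and episode values remain
clinically plausible — they stay inside the cohort-wide Tukey fences that
the preprocessing computes, while injected gross outliers (placed at
±10 range-widths by `inject_outliers`) do not. Episodes are what makes
next-step abnormality predictable from history; AR boundary flickers add a
small irreducible label noise.

Recorded measurements sample the latent grid at each channel's cadence
(4 h for most channels; 8 h and 24 h for slower assays such as the liver
panel and coagulation) with uniform jitter inside the grid bin, plus
Gaussian observation noise (default range_width/20). Missingness drops each
measurement independently with a per-channel probability (default 0.15).
Demographics are truncated normals for age (65 ± 15 years, bounded to
18–95) and weight (85 ± 20 kg, bounded to 35–200) and Bernoulli(0.4) for
female sex. Stay durations are uniform over 3–18 steps.

The default 25-channel panel uses standard adult reference intervals
(CBC, electrolytes, renal and liver panels, blood gas, coagulation);
baselines sit at the interval midpoint with σ = width/4. The panel is a
synthetic stand-in: it does not claim to match any real cohort's
channel-by-channel distributions, only the structural signature (sparsity,
cadence mixture, outliers, predictable abnormality).

A second hospital is emulated by `shifted_cohort_config`: baselines shifted
by +1 σ and missingness raised by +0.10 on every channel. This produces the
covariate shift used by the cross-cohort generalization experiment.

**What the generator does not emulate:** cross-channel physiological
coupling (channels are independent given demographics), treatment feedback
(interventions that pull values back into range), informative missingness
(sicker patients are sampled *more* often in reality), non-stationary
admission dynamics, and real reference-range demographics adjustments.
Passing tests therefore demonstrate that the pipeline and learners behave
correctly on data with this structure — not that any accuracy number
transfers to real EHR data.

## Preprocessing

Order of operations: discretize → sample-and-hold → Tukey outlier deletion
→ stay filtering → imputation. Outlier deletion runs *before* imputation so
a single imputation pass closes every hole.

- **Discretization.** Grid bin *m* covers `[4m, 4m+4)` hours, 0-based from
  admission; the latest measurement in a bin wins (the most recent value is
  the clinically operative one).
- **Hold times.** Per channel, all consecutive inter-measurement gaps are
  pooled across stays; the hold time is the smallest distinct gap whose
  cumulative count fraction strictly exceeds the coverage threshold
  (default 0.9), rounded up to a grid multiple. A value observed at step
  *t* is held for `hold/4` further steps unless a newer observation
  arrives; cells beyond every horizon stay missing. Channels with fewer
  than two measurements cohort-wide fall back to one step and are flagged.
- **Tukey range test.** Quartiles by linear interpolation between order
  statistics, per channel over all observed and held cells cohort-wide;
  the closed fences `[Q1 − k·IQR, Q3 + k·IQR]` (k = 1.5) keep constant
  channels intact (IQR = 0 deletes nothing). Channels with fewer than four
  finite cells are skipped and flagged.
- **Stay filtering.** Stays whose missing fraction strictly exceeds 0.5
  after holding are discarded (a stay at exactly 50% is kept).
- **Imputation.** Each incomplete stay-time row finds its k = 5 nearest
  fully observed rows (Euclidean distance over the row's observed channels,
  z-scored cohort-wide) and takes their mean; an iterative rank-r SVD pass
  (hard-impute, r = min(5, C−1), ≤100 iterations, relative tolerance 1e−9)
  then replaces just the filled cells with their low-rank reconstruction —
  this recovers exactly low-rank matrices and otherwise smooths the fill
  using cross-channel correlation; anything still unfillable takes the
  cohort channel mean. Observed cells are never modified.

`PreprocessingPipeline` carries fit/transform semantics: hold times and
Tukey fences are estimated on the training cohort only and reused on any
other cohort, which keeps the cross-cohort experiment free of leakage.
Imputation always operates within the cohort being transformed.

## Windowing and splits

For stays of L ≥ W+1 steps: one sample per target `m = W … L−1`. Shorter
stays (2 ≤ L ≤ W) contribute one sample, inputs left-padded with zero rows,
target the last step. Boundary values equal to a range endpoint count as
normal (closed interval). All windows are pooled, shuffled and partitioned
68/12/20 (largest-remainder rounding) — windows of one stay may land in
different partitions, which mirrors the original experimental design;
a grouped stay-level split exists behind `group_by_stay=True` but is off by
default. Per-channel z-scoring statistics come from the training partition
only, with padding rows excluded and kept at exactly zero after scaling;
demographics (sex encoded 0/1) are z-scored the same way. Label
binarization always uses raw channel units.

## Models

All six families map (window, demographics) to 25 abnormality
probabilities; the sequence encoder's output is concatenated with the
demographic vector before a ReLU dense stack and a sigmoid head
(late concatenation). Defaults, all overridable:

| family       | encoder                                            | ~params |
|--------------|----------------------------------------------------|---------|
| lstm         | 64-unit LSTM (tanh), batch-norm on final state     | 32k     |
| cnn          | Conv1D 64 filters, kernel 3, LeakyReLU             | 31k     |
| mcnn         | two parallel Conv1D streams, kernels 2 & 4, 32 filters each | 31k |
| transformer  | time2vec width 8 → width-32 projection, 2-head self-attention + FFN block, layer norm | 23k |
| tcn          | residual dilated causal conv blocks, dilations 1/2/4, 32 filters, kernel 3 | 21k |
| gbm          | 25 one-vs-rest LightGBM boosters on the flattened window (200 rounds, depth 6) | — |

The time encoding follows the learned linear-plus-periodic construction:
component 0 is affine in the step index, the remaining components are
sinusoids of learned affine arguments; the embedding is concatenated
feature-wise with the window before attention and trains jointly with the
network.

Training: Adam (lr 5e−3 default), batch 64, max 40 epochs, early stopping
when the validation loss fails to improve on the running best by at least
0.01 for 10 consecutive epochs ("min-delta" semantics; the first epoch
counts as non-improving, so a perfectly flat loss stops at epoch 10).
History records every epoch's train/validation loss and validation
micro-accuracy/F1. A NaN loss aborts with the offending epoch and batch.
LightGBM runs with `deterministic=True`, one thread and a fixed seed; a
label that is constant in training degenerates to a flagged constant-prior
predictor rather than an error.

The neural stack runs on `labwatch.nn`, a small reverse-mode autodiff
engine over numpy arrays (broadcast-aware arithmetic, batched matmul,
dilated causal conv1d, stable BCE-with-logits). Gradients of every layer
are verified against central finite differences in the test suite. All
computation is float64, single-threaded, and bitwise reproducible for a
fixed seed: two runs with the same configuration produce identical
prediction matrices.

## Evaluation

Confusion counts are pooled over every (sample, label) cell
(micro-averaging); accuracy, precision, recall and F1 derive from the
pooled counts, with empty denominators reported as 0 and flagged. "Binary
accuracy" is the per-cell accuracy, not exact-match subset accuracy.
`run_comparison` trains every architecture on each cohort in turn
(early-stopping on that cohort's validation split) and reports within-cohort
test metrics plus metrics on the *entire* other cohort, preprocessed with
the training cohort's hold times, fences and normalization — one row per
(direction, architecture, test set). A failing architecture loses only its
own rows.

## Benchmark conditions and problem sizes

The learnability benchmark ("noiseless persistence cohort") uses
episode_rate 0.12, episode_persistence 1 (abnormality absorbing), zero
observation noise, no missingness, and latent AR SD = range_width/6. The
latent dispersion is kept non-zero deliberately: with a point-mass value
distribution the IQR degenerates to zero and the Tukey fences would delete
every genuinely abnormal value, destroying the task through the very
preprocessing under test. On this cohort the naive persistence predictor
scores micro-F1 ≈ 0.96, bounding what any learner can achieve; the
residual errors are episodes that begin exactly at the target step and AR
boundary flickers.

Test-suite and acceptance-script problem sizes are desk-scale by design:
500 stays for the learnability benchmark, 200 stays for outlier-recall
measurement, 60-stay cohorts and five seeds for the generalization-gap
direction, small cohorts for contract tests. These sizes give stable
pass/fail behaviour for the properties asserted (directions, floors,
exact identities) without attempting to reproduce absolute accuracies from
any external dataset.

## Known limitations

- Channel independence in the generator means multi-channel architectures
  cannot demonstrate any advantage from cross-channel signal here.
- The Tukey step deletes genuinely extreme abnormal values on distributions
  with very heavy point masses; the fences are only as good as the
  cohort-wide quartiles.
- Hold-time estimation assumes the gap distribution is stationary across a
  cohort; per-stay cadence drift is not modelled.
- The transformer uses a single attention block and flattened outputs; it
  is sized for small synthetic cohorts, not for large-scale training.
- The numpy training loop is CPU-bound and intended for cohorts of
  hundreds, not tens of thousands, of stays.
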