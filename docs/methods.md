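# Methods

`avbci` implements an end-to-end analysis of neuronal-avalanche dynamics in
motor-imagery (MI) brain-computer-interface (BCI) training: avalanche
detection on source-level EEG ROI time series, feature screening against BCI
performance, group-level ROI selection, and longitudinal support-vector
models that predict next-session performance. Because no public dataset with
this structure exists, the package ships a first-class synthetic-cohort
generator that reproduces the statistical structure the analysis assumes;
every pipeline property is validated against the generator's ground truth.

## Avalanche model

Source-reconstructed EEG, band-limited and mapped to 68 cortical ROIs
(Desikan-Killiany atlas), is z-scored per trial and per ROI (population SD).
A (ROI, time) cell is *active* when |z| exceeds a threshold θ = μ + k·σ —
numerically just `k` after standardization. The two-sided rule follows the
neuronal-avalanche literature (an excursion is an excursion regardless of
sign); a one-sided mode is available behind a flag.

An *avalanche* is a maximal run of consecutive frames with ≥ 1 active ROI;
it is retained when its duration reaches the minimum duration λ_min (ms →
samples by ceiling, so 5 ms at 250 Hz is 2 samples and never undershoots the
stated minimum). Avalanches touching epoch edges are kept truncated: 7-s
epochs are long relative to avalanche durations and exclusion would bias the
duration distribution of long events.

Per trial, two features summarize the detected cascades:

* λ_av — mean avalanche duration (ms);
* α_av — duration-weighted mean activation count,
  α_av = Σ_av(α·λ) / Σ_av λ, with λ in samples and α the number of active
  (ROI, time) cells in the cascade. The same weighting applied to per-ROI
  counts yields a per-ROI activation vector that sums exactly to α_av.

Trials with zero avalanches are excluded from subject-level means by default
(a zero-length avalanche is undefined, not an observation of 0 ms); a flag
includes them as zeros. The candidate parameter grid is k ∈ {1..5} ×
λ_min ∈ {5, 50, 80} ms; a pair is *physiologically valid* when every
(subject, session, condition) cell yields ≥ 1 avalanche and the grand-mean
duration exceeds 5 ms. Screening is strict per cell rather than on average:
a pair that starves any cell cannot feed the longitudinal models.

z-scoring is per trial (not per session): it keeps trials exchangeable
within a cell and matches trial-wise feature extraction. The alternative is
exposed by composing `zscore_epoch` manually.

## Statistics

* **Δ features**: Δx(i, s) = x_MI(i, s) − x_Rest(i, s) per subject and
  session. The MI − Rest orientation is the default (positive when MI
  exceeds Rest, so learning moves Δ upward); `convention="rest_minus_mi"`
  flips it. Both orientations are deliberately kept; output tables record
  which was used.
* **Repeated-measures correlation**: the common within-subject association
  between a Δ feature and the BCI score, from the ANCOVA fit of the score on
  the feature with subject-specific intercepts and a shared slope;
  r = sign(slope)·√(SS_x / (SS_x + SS_err)), df = N − n_subjects − 1, p from
  the t distribution. Implemented directly on the within-subject-centered
  normal equations; `pingouin.rm_corr` is the independent oracle in tests.
* **Permutation two-way ANOVA**: observed F statistics from the balanced
  fixed-effects condition × session decomposition with subjects as
  within-cell replicates; the null distribution shuffles the full response
  vector across all rows (no exchangeability blocks) and recomputes all
  three effects from the same permuted vector, 10,000 iterations by default.
  Empirical p uses the add-one estimator, p = (1 + #{F* ≥ F}) / (1 + n),
  so p > 0 always. Degenerate 0/0 F ratios are defined as 0.
* **Friedman** (per condition, across sessions) and **Wilcoxon signed-rank**
  (per session, MI vs Rest, zeros dropped, exact for small tie-free n) give
  the localized learning/condition effects; both via scipy. The fully tied
  Friedman layout returns (0, 1) by definition.
* **Parameter screening**: pairs whose rmcorr is significant (p < α,
  uncorrected — each pair is reported on its own) for either Δλ_av or Δα_av,
  ordered by |r|. Prediction runs screen on the training sessions only
  (sessions 1–3) to keep session 4 untouched.
* **Hit/Miss**: trial-level rank-sum (Mann-Whitney) contrasts — the trials
  are unpaired — for MI-Hit vs MI-Miss, Rest-Hit vs Rest-Miss, MI-Hit vs
  Rest-Hit.

## ROI selection

Per-trial, per-ROI duration-weighted activations are converted to *shares*
of the trial's total activation by default. The raw per-ROI activation is
approximately (ROI's supra-threshold rate) × (duration-weighted mean
avalanche length), so any global change in cascade duration — exactly what
MI learning produces — moves *every* ROI's raw contrast coherently and a
per-ROI screen on raw activations flags most of the cortex. The share
cancels global duration scaling exactly and keeps the contrast spatially
selective; the raw mode remains available (`share=False`). Shares (or raw
activations) are then normalized within subject to a percentage of the
maximum that ROI reached across the subject's first Rest session (Rest-1 is
the task-free baseline; a per-(subject, ROI) reference preserves spatial
patterns and removes between-subject amplitude offsets). Per (subject, session, ROI), a paired t
statistic contrasts MI and Rest trial values. Trials carry no natural
pairing, so pairs are matched by sorted index after truncation to the common
trial count; this quantile matching shrinks the difference variance and
inflates |t|, which is harmless here because all inference happens at the
group level across subjects (under the null the t signs stay symmetric). A
Welch two-sample mode is available for calibrated per-cell inference.

The group screen treats each ROI's (subject × session) t-matrix as a
randomized block design (session fixed, subject blocking, no interaction —
one observation per cell): the *condition effect* asks whether the mean t
exceeds zero (one-sample t across subject means, one-sided MI > Rest by
default — with shares, the ROIs competing with a task-recruited region
necessarily lose share, and a two-sided rule would flag that dilution as an
effect; `tail="two-sided"` is exposed), the *session effect* is the
block-design F test. The default rule selects on the condition effect and
records the session effect; `and`/`or`/`session` rules are exposed. An empty selection is a legitimate outcome and is serialized as
such. Masking restricts epochs to the selected ROI rows and re-runs
detection — avalanche boundaries change on the reduced raster, so features
are recomputed, never subset.

## Longitudinal models

Each subject contributes X_i ∈ R^(s×f): one row of f = 2 features (Δλ_av,
Δα_av) per training session (s = 3). A temporal trend β = (1, β₁, …, β_{s−1})
collapses the rows, x̃_i = X_iᵀβ, and G_ij = βᵀX_iX_jᵀβ is the Gram matrix
of a standard dual SVM (ε-SVR for score regression, soft-margin SVC for the
control/no-control classification at the 57 % chance threshold, strict
inequality at the boundary).

β and the dual solution are estimated by alternating optimization:

1. solve the dual QP on G(β) (scikit-learn's libsvm backend, precomputed
   kernel);
2. hold the collapsed weight profile u = Σ_j a_j X_jᵀβ fixed, making the
   model prediction linear in β (f_i = (X_i u)ᵀβ + b), and minimize the
   *primal loss itself* — C·Σ hinge (classification) or C·Σ ε-insensitive
   loss (regression) plus ½ρ‖β_free‖² — over the free components, with β₀=1
   eliminated by substitution.

Step 2 makes the loop a block coordinate descent on one objective, so the
objective decreases monotonically and ‖Δβ‖ reaches the 1e-6 tolerance
within a handful of iterations on synthetic cohorts. A simpler alternative —
a ridge least-squares regression of the decision values onto the targets —
is kept as `update_beta(..., loss="squared")`; used inside the loop it
destroys confident solutions (squared loss punishes margins beyond ±1) and
limit-cycles, which is why the primal-loss step is the default for the
estimators. If the loop hits `max_iter` the best iterate (smallest ‖Δβ‖) is
returned and flagged via `converged_ = False`.

With s = 1 the model degenerates exactly (prediction-for-prediction) to the
standard linear SVR/SVC — a unit-tested contract.

Defaults: β⁰ = (1, …, 1), ρ = 1e-3, tol = 1e-6, max_iter = 100, C = 10,
ε = 1 (score units, %). Features are standardized per feature on the
training fold. Baselines are standard linear SVR/SVC on the concatenated
(s·f)-vector with the same C and ε (a session-mean variant sits behind a
flag). Evaluation is leave-one-subject-out: train on the remaining subjects'
sessions 1–3 features and session-4 targets, predict the held-out subject's
session 4. The *random sessions* control permutes each subject's session
rows (row multiset preserved) before training and prediction. β stability is
summarized by pairwise cosine similarity over fold β's and by ‖β_fold −
mean β‖.

## Synthetic cohorts

Defaults (the study conditions): 20 subjects × 4 sessions × 2 conditions
(Rest, MI) × 32 trials, 68 ROIs, 7-s epochs at 250 Hz.

* Background: per-ROI unit-variance AR(1), φ = 0.95. White noise would make
  avalanche durations trivially geometric; the AR(1) autocorrelation
  produces realistic threshold-crossing runs.
* Bursts: Poisson arrivals at 1.5 events/s; each burst picks ~5 ROIs
  uniformly, a log-normal duration (median 60 ms, σ_log = 0.5), and adds a
  Tukey envelope of 4 z-units (smooth on/offsets avoid single-sample
  threshold chatter).
* Task structure: in MI, each burst additionally recruits each of 5 planted
  ROIs with probability 0.4 — additive recruitment keeps every non-planted
  ROI condition-null, which is what the ROI screen assumes. 60 % of subjects
  are *learners*: their MI burst-duration median scales by
  1 + 0.25·(session − 1). All subjects' MI scale also carries session-level
  jitter (SD 0.15): day-to-day fluctuation of task engagement. This jitter
  is what makes single-session Δ features noisy and next-session prediction
  a genuine extrapolation problem; without it the learning ramp is clean
  enough that session order carries no information and any static model
  matches the longitudinal ones.
* Scores: score(i, s) = 50 + 25·gap(i, s) + N(0, 5), clipped to [0, 100],
  where gap is the *generative* MI−Rest duration-scale difference (including
  the session jitter), not a detected feature — the feature→score
  correlation stays an emergent, testable property. Non-learners hover just
  below the 57 % chance level; learners reach ≈ 66–72 % by session 4.

Every epoch's RNG is keyed by (seed, subject, session, condition, trial), so
any cohort subset reproduces the exact epochs of a full generation, and all
outputs are bit-reproducible under a fixed seed.

What the generator does *not* emulate: volume conduction and source
leakage, artifacts, oscillatory (band-limited) structure, within-session
fatigue or drift, heavy-tailed avalanche-size criticality. Passing
parameter-recovery tests therefore shows the pipeline recovers the planted
structure under idealized source dynamics, not that real EEG carries such
structure.

## Numerical choices and degenerate inputs

* Strict inequalities at both thresholds (|z| > k; score > 57).
* ms → samples by ceiling everywhere.
* Constant ROI rows are an error at z-scoring (named row), not silently
  dropped.
* Empty trials, empty cells and empty ROI selections are flagged, not
  fabricated; downstream stages that cannot proceed raise with the stage
  name.
* All randomness in a pipeline run derives from one root seed with fixed
  per-stage offsets; re-running a stage with the same config reproduces its
  outputs byte-wise.
* The inner libsvm QPs run at tol = 1e-8 with a 200,000-iteration guard —
  an unbounded solver can stall on the degenerate Gram matrices a diverging
  β would produce (the divergence guard aborts the loop at ‖β‖ > 1e8).

## Problem sizes

Tests and the acceptance script run the full pipeline at the study scale
above (5,120 epochs of 68 × 1750 samples per cohort). Multi-seed checks
(model orderings, ROI recovery, Wilcoxon power) regenerate only the cohort
slices they need — the keyed per-epoch RNG makes subsets exact — and
permutation-test calibration uses 2,000 permutations per replicate dataset,
500 replicates. A full cohort generates in ≈ 20 s and screens the 15-pair
grid in ≈ 2–3 minutes on one core.

## Known limitations

* The alternation optimizes a non-convex joint objective; block descent
  finds a local optimum dependent on β⁰ = (1, …, 1). No restarts are
  performed.
* The regression variant predicts the scalar session-4 score directly; a
  formulation that also projects the outcome vector through β exists in the
  longitudinal-SVM literature, but the scalar target matches the evaluation
  protocol here and keeps the β update well-posed.
* rmcorr assumes a common slope across subjects; heterogeneous slopes are
  averaged, not modeled.
* The screening step reports uncorrected per-pair significance by design;
  with 15 pairs, occasional false-positive pairs are expected and surface in
  the selection list's tail.
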