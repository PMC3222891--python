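# Methods

`patternsep` implements an MVPA pipeline for asking whether highly
overlapping episodic-like memories are stored as distinct ("pattern
separated") representations in medial-temporal-lobe voxel patterns, and
whether latent factors shared between memories (spatial context, event
content) have their own generalizing codes. This note documents the models,
the synthetic-data generator, the numerical choices, and the limits of what
the tests show.

## Experimental design model

Four memory conditions A–D arise from a 2×2 crossing of two action events
with two spatial contexts: A=(event 1, context 1), B=(1, 2), C=(2, 1),
D=(2, 2). Every condition therefore has exactly one *spatial* partner (same
context), one *content* partner (same event) and one *orthogonal* partner
(neither). The default design is 15 participants × 20 trials per condition
(80 trials), presented in a pseudo-random order with no immediate
condition repeats.

Orders are built by count-weighted sequential sampling: each position draws
among the remaining labels excluding the previous one, with probability
proportional to remaining counts, restarting on a dead end (bounded at
10,000 restarts). Whole-sequence rejection sampling is not viable here —
for a balanced 4×20 multiset the probability that a uniform shuffle has no
adjacent repeat is ≈ exp(−Σc nc(nc−1)/N) = e^−19 ≈ 6·10⁻⁹. The sequential
construction is exchangeable over condition labels, so each condition is
equally likely at every serial position (verified by χ² over 10,000
orders); it is not exactly uniform over the set of valid orders, a
difference immaterial to every analysis downstream.

Default timing — 12 s recall periods, 4 s inter-trial gap, TR 2 s — is a
configurable placeholder for a slow event-related recall design; only the
regressor geometry, not the exact values, matters to the synthetic
analyses.

## Synthetic signal model

Per participant, eight unit-norm voxel templates are drawn independently
(standard normal, normalized): one bound trace per memory u_A..u_D, one per
context v₁, v₂, one per event w₁, w₂. A trial of memory m produces

    x = amp_bound·u_m + amp_context·v_c(m) + amp_event·w_e(m) + ε,
    ε ~ N(0, noise_sd²·I)

Recall-accuracy flags are Bernoulli(1 − p_inaccurate); inaccurate trials
are dropped before decoding, mirroring the restriction of the analyses to
accurately recalled trials. Templates are near-orthogonal at realistic
voxel counts; `orthogonalize=True` Gram–Schmidts them exactly for analytic
checks. Participants share no group topography, matching the
within-participant decoding design.

Defaults: 300 voxels, noise_sd 1, p_inaccurate 0.05, amp_bound = 1.5,
amp_context = 1.5, amp_event = 0. The true amplitude ratios in real data
are unknowable; these were fixed once by an amplitude sweep against the
decoding stage so that the qualitative empirical pattern — bound traces and
a shared context code clearly detectable at n = 15, an event-content code
not — is reproduced with margin but far from saturation (four-way accuracy
≈ 0.34 against chance 0.25; context transfer ≈ 0.6 against 0.5). At
amplitude 0.5 all analyses are statistically indistinguishable from chance
at these sizes, and at ≥ 3 they saturate; neither regime exercises the
inference machinery meaningfully.

The generator does **not** emulate spatial voxel correlations, temporal
drifts beyond polynomials, motion or physiological artifacts, subject-level
amplitude heterogeneity, or informative inaccurate-trial patterns. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* under the assumed signal structure, not decodability of any real
dataset.

## Single-trial GLM

Every recall period is a separate boxcar regressor convolved with a
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
dispersions 1, ratio 1:6, 32 s kernel, peak-normalized to 1), all trials in
one simultaneous model with Legendre drift terms (default order 1) and a
constant. Convolution is at TR resolution. OLS gives per-trial betas;
conversion to t uses the full-model residual variance:
t_i = β_i / √(σ̂²·[(XᵀX)⁻¹]_ii). The t-maps of accurately recalled trials
are the decoding features. Rank deficiency is detected by pivoted QR and
reported with the offending column names. No prewhitening is applied;
exact-recovery tests use white noise (AR(1) generation is available for
robustness exercises). The synthetic time series is constructed as
B·Xᵀ_trial + E with B the noise-free pattern amplitudes, so in the
noiseless limit the GLM recovers B to machine precision.

## Decoding

Four-way classification is a one-vs-one linear soft-margin SVM (cost
default 1.0, unstated in the original analysis): one binary max-margin
classifier per unordered pair, majority vote, ties broken by summed signed
decision values and then lexicographic condition order. Cross-validation is
leave-one-trial-out: no value of the held-out trial, including its
contribution to any normalization statistic, enters training (verified by
an explicit held-out-refit oracle test). Chance is 1/4.

Cross-classification trains A vs B and tests C vs D (context transfer;
scored correct when the predicted training condition shares the test
trial's context, A↔C/B↔D) or trains A vs C and tests B vs D (event
transfer, A↔B/C↔D); chance 1/2. Misclassifications in the four-way
analysis are decomposed by the factor shared between the true and predicted
condition (spatial / content / orthogonal).

Features are used raw by default: t-maps are already noise-normalized per
voxel by the β→t conversion, and the generator produces voxels on a common
scale, so per-fold z-scoring changes nothing statistically (verified
empirically) while a fold-independent Gram makes permutation inference an
order of magnitude cheaper. `normalize="zscore"` (training-fold statistics
only) remains available and equally leakage-free.

The binary SVM is solved in the dual by an SMO solver (maximal-violating-
pair selection, the libsvm formulation, tolerance 1e−4) on precomputed Gram
matrices, numba-compiled. Leave-one-out sweeps reuse solutions: folds
outside a class pair share one classifier; folds inside it refit with the
held-out trial's dual weight frozen at zero after an in-place equality-
constraint repair, with the gradient maintained incrementally. The solver
is cross-checked against scikit-learn's SVC (decision values to 1e−3,
identical predictions away from the margin) and against explicit per-fold
retraining.

Class imbalance after accuracy filtering is tolerated without rebalancing.
A known consequence, inherent to leave-one-out CV, is a null accuracy
slightly *below* nominal chance (Monte Carlo: 0.226 rather than 0.25 at 80
trials): holding out one trial of class k leaves k under-represented in
training. The permutation test's null distribution is centred at the same
biased value, so inference is unaffected; tests of the null level assert
against the Monte-Carlo value, not 1/4.

## Group inference

Per-participant accuracies are compared to chance with a one-sample Student
t, df = n − 1, one-tailed (upper tail) — the convention under which every
reported (t, P) pair of the original analysis is self-consistent. Paired
one-tailed t-tests compare misclassification proportions (direction:
spatial greater); participants without errors are excluded with a warning.
When all differences are exactly zero the t statistic is defined as 0
(p = 0.5); zero variance around a nonzero mean raises an error.

The permutation test permutes the condition-label vector over trials
independently within each participant (preserving the balanced counts),
reruns the full analysis, and compares the observed group mean against the
null group means with the add-one rule p = (1 + #{null ≥ obs})/(1 + R), so
p ≥ 1/(R+1). Default R = 500. The scheme is recorded in the run manifest.

## Reproducibility

All randomness flows from a single master seed through SHA-256-derived
per-stage, per-participant child seeds (`util.derive_seed`), so adding
participants or stages never shifts existing streams and identical configs
give byte-identical result tables. Voxel scan order is ascending C-order
flat index, hashed into the manifest.

## Problem sizes used in the validation suite

Unit tests run scaled-down designs (1–4 participants, 4–8 trials per
condition, 25–120 voxels) chosen as the smallest sizes at which each
property is non-trivial. The acceptance checks use the full study geometry
(15 × 20 × 4 × 300 voxels, 500 permutations) for the headline recovery
claims, and a reduced all-null configuration (6 participants, 10 trials
per condition, 100 voxels, 200 permutations, 200 datasets) for type-I
calibration — sizes at which the binomial uncertainty of the estimated
rejection rate is comfortably inside the asserted band.

## Known limitations

* The SVM cost, normalization and software of the original analysis are
  unknown; defaults are declared, not inferred, and cost-insensitivity on
  separable data is tested.
* Polynomial drift replaces SPM's cosine basis; no SPM bit-compatibility.
* No hyperparameter search, searchlights, nonlinear kernels, smoothing
  control, or hippocampal-subfield analyses.
* Group tests are uncorrected per-ROI/analysis, matching the original
  reporting.
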