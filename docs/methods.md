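# Methods

This note documents the models, procedures, defaults, and design choices
behind `svdecode`, in the order the pipeline runs them.

## Task design

The generator reproduces the risky decision-making task's structure: 21
lottery amounts ($4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 23, 26, 30,
34, 39, 44, 50, 57, 66), three stated probabilities (25/50/75%) and three
ambiguity levels (24/50/74% occlusion, objective p = 50%). The 20
non-catch amounts × 6 uncertainty levels give 120 unique trials, dealt 30
per run in a seeded random order over four runs; a dominated $4 catch
lottery (p = 50%, no ambiguity) opens each run, for 124 trials. The task
is usually summarized as four 30-trial runs; we read that as 30 *unique*
trials per run — a 124-trial total requires the catch trial to sit on top
of the 30, so each run holds 31 trials.

Timing: 4 s lottery display, 2 s response window, 0.5 s confirmation, and
a 5 ± 0.75 s fixation plus a (2 s − RT) compensation. Because the
compensation cancels the response time, per-trial duration is
response-independent; onsets therefore accumulate 6.5 s + jitter, with
jitter uniform on [4.25, 5.75] s. Runs are 364 s (6 min 4 s).

For run counts other than four, each run still receives 30 unique pairs
drawn from the shuffled 120-pair pool (the pool is re-shuffled per block
of four runs), so `n_runs = 1` yields 31 trials.

## Choice model and estimation

SV = [p − β·(A/2)]·v^α; the safe option is evaluated at p = 1, A = 0.
Pr(lottery) = 1/(1 + exp(γ·(SV_lottery − SV_safe))), implemented exactly
in this sign convention (value-consistent behavior means γ < 0); γ is
left unbounded and its sign free. Probabilities are clipped to
[1e−12, 1 − 1e−12] before the log so deterministic simulators keep the
likelihood finite. Missing responses are censored, never imputed; catch
trials enter the likelihood like any other non-missing trial.

Estimation is bound-constrained maximum likelihood (L-BFGS-B; 0 ≤ α ≤ 10,
−5 ≤ β ≤ 5) from 20 seeded starts by default: 4 fixed canonical starts
(neutral and mildly averse choosers, both noise signs) plus uniform draws
over the box. The canonical starts matter — with purely random starts the
optimizer occasionally stalls on likelihood plateaus at extreme α/γ,
where the clipped likelihood is locally flat. Pseudo-R² is McFadden's
1 − LL/LL₀ with LL₀ the chance model (log ½ per trial); this definition
is a package choice, made because it is the standard for binary choice.
Ties SV_lottery = SV_safe need no special casing (the logistic gives ½).

Identifiability caveat: for nearly deterministic choosers (|γ| large) α
is only set-identified, and for nearly random choosers (|γ|·SV-range
small) nothing is identified; recovery statements below assume moderate
noise.

## Synthetic cohorts

`CohortSpec` draws each agent's (α, β, γ) from per-group distributions,
truncated to the estimation bounds. Defaults center α on the observed
group medians (0.599 controls, 0.628 patients) with SD 0.40, and β on
0.524 / 0.352 with SDs 0.70 / 0.80, on the order of the reported
interquartile ranges. γ is −lognormal(median 1.5, σ = 0.5); the median
was calibrated so simulated cohorts reproduce the reported
moderate-to-good fit quality (mean pseudo-R² ≈ 0.52 over 50 agents at 124
trials). Missingness is uniform at 2% by default (capped at 20%).

Beta patterns: each ROI carries a unit-norm encoding direction w (seeded
at the cohort level); trial t's pattern is
amplitude·z(SV_lottery,t)·w(context_t) + N(0, noise_sd²), with z the
within-participant standardization over included trials. The SV signal is
*graded*, not binarized, so the median-split decoder faces a realistic
continuous signal. `shared_across_contexts` m ∈ [0, 1] mixes a common
direction with context-specific ones (w_ctx ∝ √m·w_shared +
√(1−m)·w_own), giving within-context decodability at any m but
cross-context generalization only as m → 1. Group differences are
expressed through per-ROI amplitude maps (e.g. zero amplitude in selected
networks), which propagate monotonically to decoding accuracy and
widespreadness.

Simulated BOLD runs (TR 1 s) are built from the same convolved
regressors the GLM uses (decision epochs + SV modulator) so that, with
zero noise and drift, the GLM recovers the generating betas to machine
precision; options add slow cosine drift, white noise, and leakage of the
13 emitted confound series (an FD-like series, 6 motion-like random
walks, 6 component-like white series). The noise model is deliberately
simple — white noise plus drift, no autocorrelation, no physiological or
motion artifacts — so passing tests demonstrate correctness of the
estimators, not robustness to realistic fMRI noise.

## First-level GLM

The canonical HRF is the double-gamma difference (response gamma shape 6,
undershoot shape 16 scaled by 1/6) evaluated over 32 s. Kernels are
normalized to the *continuous-time* unit peak (located once on a dense
grid), so kernels at different TRs sample the same function exactly.

Designs contain: a 4 s decision-epoch boxcar over non-missing trials; the
selected modulator (lottery SV, chosen-option SV, or |SV_safe −
SV_lottery| difficulty), floored at 0, scaled by the run maximum to
[0, 1], mean-centered within run, applied as boxcar heights and
HRF-convolved; a missing-trial regressor when needed; the 13 confounds;
and a constant. The negative-SV floor is a package choice: extreme
ambiguity aversion can push p − βA/2 below zero, and the stated [0, 1]
normalization presumes non-negative values. Mean-centering within run
follows the common convention that lets the epoch regressor carry the
mean response. The beta-series design replaces the modulator with one
regressor per non-missing trial. Only single-modulator models are built,
so no orthogonalization question arises.

Fitting residualizes data and design against a discrete-cosine basis
(cutoff 128 s; K = ⌊2T/128⌋ components, zero-mean so the constant column
is untouched) and solves OLS per voxel; rank-deficient designs raise an
error naming the offending columns via pivoted QR. No prewhitening is
applied (the synthetic noise is white; documented limitation). Sphere
extraction averages voxels whose centers fall within 5 mm of the four
meta-analytic valuation-system coordinates (vmPFC −1/46/−7, ventral
striatum ±10/10/−4, PCC −4/−30/36); group tests are one-sample and
pooled two-sample t tests, two-tailed.

## Decoding

Trials are labeled low/high by a median split of run-max-normalized
lottery SVs computed with individual-specific parameters ("normalized"
is read as the same run-max scaling used for the univariate modulator —
it is not separately defined). Median-tied trials are assigned one by
one, in seeded order, to the currently smaller class; exact ties between
class counts break at random. The within-context variant takes separate
medians for risk and ambiguity trials. Catch trials participate unless
configured out.

Per ROI, trials whose spatial-mean beta lies more than 3 SDs from the
across-trial mean of those means are dropped (under Gaussian noise
~0.27% of trials, matching the small per-participant counts reported).
The classifier is a linear-kernel SVC with C = 1 (linear being the usual
default for beta-pattern decoding), on betas as-is — no feature scaling
by default. Leave-one-run-out CV holds
out each run once; every training fold is balanced by randomly removing
majority-class samples (subsampled globally across the three training
runs, not stratified by run), repeated `n_boot` times with the fold
accuracy averaged over bootstraps. With exactly balanced labels and
n_boot = 1 the bootstrap path reduces to plain CV. Cross-context decoding
trains on one context's trials in the retained runs and tests on the
other context's trials in the held-out run, both directions averaged.

## Permutation inference

Per-ROI significance: for each participant, each null iteration draws one
shuffle of the trial labels and substitutes it for the training labels in
every fold (test labels untouched); CV accuracies are averaged over folds,
then over participants, giving a group null against which the observed
group accuracy is compared. Two numerical choices here differ from the
most literal reading of the usual verbal recipe, and both were forced by
calibration measurements:

* the shuffle is drawn *once per iteration* and applied consistently
  across folds, not independently per fold. Independent per-fold shuffles
  destroy the cross-fold covariance that the observed statistic has
  (folds share training trials), making the null under-dispersed; in a
  200-simulation null calibration this inflated the 5%-level rejection
  rate to ~10%. The consistent shuffle restores exchangeability.
* permuted p-values count ties as exceedances, p = #{null ≥ observed}/n.
  Counting only strict exceedances is anticonservative whenever the
  statistic is discrete (accuracies on a 1/n_trials grid, proportions on
  a 1/n_ROIs grid): measured type-I error reached 36% for the
  widespreadness group test under the null. The tie-inclusive count is
  the standard valid rule (P(p ≤ a) ≤ a under exchangeability); p = 0
  remains possible, but only when the observed statistic strictly
  exceeds every null value.

Group contrasts on decoding scores permute group membership; the
reported p is one-sided (first group minus second), so swapping the
groups complements it. The widespreadness index is the proportion of a
network's ROIs significant at each threshold (0.05, 0.01, 0.001); its
group test recomputes per-pseudo-group ROI p-values from *cached*
per-participant observed and null accuracies under each group-label
permutation, rather than re-decoding — the statistics are identical and
the cost drops by the number of permutations. The p floor is 1/n_perm;
analysis-scale runs should use ≥1000 permutations (the desk-scale
defaults use 200 with correspondingly coarse p grids).

Because proportions are coarse at desk scale, the widespreadness group
test is conservative when many diffs tie (measured rejection 1–2.5% at
the 5% level under identical-process groups); with heterogeneous signal
and larger networks it approaches the nominal level from below.

## Synthetic atlas

The default registry has 216 parcels in 8 networks: 200 "cortical"
parcels split as visual 31, somatomotor 37, dorsal-attention 23,
salience/ventral-attention 22, limbic 12, control 30, default 45, plus 16
"subcortical" parcels as their own network. The limbic and
salience/ventral-attention counts (12 and 22) were chosen so the group
differences reported at those granularities (5/12 = 41.7%, 5/22 = 22.7%,
8/22 = 36.4%) are representable exactly. Parcels are abstract voxel-index
sets of 20–60 voxels; no spatial embedding is needed for decoding.

## Problem sizes used by the shipped checks

The test suite and acceptance script run at desk scale, chosen so every
stochastic check has adequate Monte-Carlo resolution: chance-level
decoding uses 20 participants × 3 ROIs with 10–20 bootstraps; null-
calibration uses 200 simulated datasets at 39 permutations each (39 makes
"p < 0.05" an exact 5%-level rule: at most one null value at or above the
observed); parameter recovery uses 50 agents at 124 trials; the
widespreadness sensitivity check uses 5 participants per group, 2 ROIs
per network, 50 decoding permutations and 500 group-label permutations.

## Known limitations

* White-noise fMRI model; no autocorrelation, physiological noise, or
  motion simulation — GLM t statistics on synthetic BOLD are not meant to
  emulate real-data error rates.
* The atlas is topological only; sphere ROIs and volumetric export use a
  trivial affine, not template geometry.
* Preference recovery degrades outside the moderate-noise regime, as it
  must; the generator's defaults stay inside it.
* Alternative utility specifications (probability weighting, prospect
  theory) and support-vector regression on continuous SV are out of
  scope.
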