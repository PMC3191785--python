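# Methods

## Model

Each of the C simultaneously recorded cells is modelled as a discrete-time
point process with conditional intensity

    log λ_c(t | H_t) = α₀ᶜ + Σ_{i=1..C} Σ_{k=1..K} α_{i,k}ᶜ · x_{i,t−k}

where x_{i,t−k} is the spike count of cell i in the k-th lagged history
window (an inclusive millisecond range such as 1–3 or 31–40 ms, strictly
before the current bin), exp(α₀ᶜ) is the baseline rate in spikes/s, and
exp(α_{i,k}ᶜ) is a dimensionless gain. At bin width Δ = 1 ms, λΔ is the
per-bin spike probability and spike indicators are 0/1. The network
log-likelihood is a sum of per-target-cell terms

    L(αᶜ) = Σ_t [ y_t log(λ_t Δ) − λ_t Δ ],

the direct discretization of the continuous-time point-process likelihood.
Because the target index decouples, every cell's coefficient vector is
estimated independently; −L is convex, so Newton iteration with
backtracking finds the global optimum. Iteration stops when the penalized
log-likelihood changes by less than `tol` (default 1e-4, config-exposed).

Assumptions: trials are independent and statistics are stationary across
trials within a condition; history at each trial start is empty; the only
covariates are ensemble spiking history (no kinematic, LFP or stimulus
terms).

## Regularization and model selection

The penalty −ρ·αᵀQα is applied to the coupling coefficients only. The
intercept (baseline log-rate) is not penalized: shrinking it would bias
every cell toward 1 spike per second·Δ, and standard ridge practice leaves
it free. Q defaults to the identity (ridge); `Q_kind="first_difference"`
penalizes differences between adjacent windows of the same source cell,
encouraging smooth coefficient traces.

ρ is selected by leave-one-trial-out cross-validation on held-out
log-likelihood over a default grid of 8 log-spaced values in [1e-4, 1e2];
trials are the exchangeable blocks, and a k-fold-over-trials option exists
for large trial counts. The number of history windows is selected by
minimizing BIC = −2L + dim(α)·log l, where l is the number of 0/1 samples
in the fit. All candidate schemes are scored on a common set of bins (the
mask of the longest candidate history); comparing likelihoods computed on
different bin sets mixes samples and systematically favours longer-lag
schemes. Ties break toward fewer windows, then toward the earlier
candidate — a compact model is preferred.

Coefficient covariance is the inverse observed information
Σ = (Σ_t λ_tΔ · x(t)x(t)ᵀ)⁻¹; for the log-linear intensity the
second-derivative term of λ cancels in expectation. A singular information
matrix falls back to the pseudo-inverse with a warning flagging
unidentifiable coefficients.

## Design matrices

Column order is fixed: intercept, then source cell 0's K windows, then
cell 1's, and so on. "1~3 ms" means lags of 1, 2, 3 whole bins before the
current bin — the current bin never contributes, keeping the model causal.
Bins whose full history precedes the epoch start are masked out of the
likelihood rather than zero-padded, avoiding biased low counts at trial
starts. Multi-spike bins saturate the 0/1 indicator; the collision count
is reported so users can shrink Δ.

## Goodness of fit

Under a correct model the rescaled inter-spike intervals
τ_j = ∫ λ dt between spikes are unit-exponential, and u = 1 − exp(−τ) is
uniform; the KS statistic is compared with the asymptotic simultaneous
band c/√n (c = 1.36 at 95%, 1.22 at 90%; the 90% band is the stricter
criterion, so passing it implies passing at 95%). Two numerical choices
matter here and were validated against a true-parameter oracle:

* **Exact discrete rescaling (default).** The data are Bernoulli bins, so
  the per-bin survival is 1 − p, not exp(−p). The default interval is the
  sum of hazards −log(1 − p_t) over bins strictly between spikes plus a
  seeded truncated-exponential draw for the spike bin itself, which makes
  τ exactly Exp(1) under the model. The naive sum of λΔ
  (`discrete_correction=False`) deflates KS pass rates to ~80% already at
  10 spikes/s once a few thousand intervals are pooled.
* **Trial concatenation.** After rescaling, each trial is a segment of a
  unit-rate Poisson process; segments are laid end to end, intervals may
  bridge trial boundaries, and only the global leading/trailing partials
  are discarded. Ending every interval at its trial boundary instead
  censors long intervals (trials hold only tens of spikes) and fails
  calibration even at the true parameters.

With both choices, true-parameter rescaling of simulated data is exact
(KS p = 0.16 at n ≈ 12,000 pooled intervals). In-sample rescaling of
*fitted* models is conservative (~99% pass at a 95% band) because the fit
absorbs sample fluctuations — the usual estimated-parameter KS effect —
so the calibration suite measures coverage out-of-sample: fit on 200
trials, rescale 40 held-out trials, which is nominal (≈95%).

## Connection detection and summaries

A coefficient whose 95% Wald interval α̂ ± 1.96√Σᵢᵢ excludes zero is a
directed functional connection at that lag, excitatory if positive,
inhibitory if negative. No multiplicity correction is applied by default;
`bonferroni_lags=True` divides the level across the K windows for
conservative use. Two normalizations coexist deliberately:

* the mean (E+I) connectivity ratio averages per-lag counts of significant
  off-diagonal coefficients over the C(C−1) directed pairs, excluding
  self-connections, and the E:I balance likewise counts only
  between-cell edges;
* the cell-group interaction fractions (RS-RS, RS-FS, FS-FS) count a
  directed pair once if significant at ≥1 lag and divide by n_RS²,
  2·n_RS·n_FS and n_FS² respectively, *including* self-pairs.

Condition comparisons use the Wilcoxon signed-rank test for paired
per-dataset statistics (Mann-Whitney otherwise) and a three-factor
type-II ANOVA (cell group × task outcome × period) via statsmodels.

## Monte-Carlo controls

The split-half check refits each outcome condition on random halves of
its trials (20 runs by default) and reports mean ± SEM traces; absence of
overfitting shows as positive correlation between half-sample means and
full-sample traces. The shuffle check permutes trial IDs so each
pseudo-group contains equal numbers of truly successful and unsuccessful
trials (nearest balanced split, with a warning, for odd group sizes; 100
runs by default); "no difference under the null" is operationalized as
the across-run mean ± 1.96·SEM covering zero per window. Since the
network likelihood factorizes over targets, each control refit estimates
only the focal pair's target cell against the full covariate set — this
is algebraically identical to a full-ensemble refit for the reported
trace. There is deliberately no scalar "trace difference" statistic; the
per-window confidence intervals are the output.

## Synthetic ensembles

The generator samples the same model family forward in time: independent
per-bin Bernoulli draws per cell with probability λΔ computed from the
ensemble's own sampled history (exact as Δ→0; simultaneous spikes across
cells are well-defined under the conditional-independence factorization).
λΔ is clipped at 1 − 1e-6 and clipping events are counted and logged.
Defaults emulate the recordings the pipeline targets: 3-second trials with
a trigger at 1.5 s separating background from reaching epochs;
regular-spiking baseline rates 8.5 ± 3.6 spikes/s and fast-spiking
22.7 ± 9.6 spikes/s (spike durations 0.9 and 0.45 ms regime centroids);
coupled pairs drawn with a configurable density, signed excitatory with
odds `ei_balance` (default 1.11), the same magnitude at every window.

Magnitude defaults put λΔ in a stable regime (`coupling_scale` = 0.4,
0.5–0.6 in strong-coupling tests): reciprocal excitation at 0.8 across
all windows produces runaway rates and heavy clipping, which no realistic
inhibition-stabilized cortical network shows. What the generator does
*not* emulate: common-input correlations from unrecorded sources,
nonstationary task modulation within a trial, bursting/adaptation beyond
what the planted self-history induces, and electrode artifacts. Passing
recovery tests therefore demonstrates correctness of the inference
machinery on data from the assumed model class, not robustness to the
confounds of real recordings.

## Problem sizes in the validation suites

The calibration suites use small ensembles chosen so the statistics, not
the compute, dominate: Wald coverage on 200 two-cell ensembles of 200
trials; false-edge rate on 100 three-cell null ensembles of 100 trials;
KS coverage on 200 single-cell runs (200 fit + 40 held-out trials); BIC
selection over 20 runs; controls on a 24+24-trial two-cell ensemble. The
acceptance script re-runs the same designs at reduced run counts
(documented in its output `n` fields).

## Known limitations

* The Wald criterion is per-coefficient; with K windows the per-pair
  false-positive rate is ≈ 1 − 0.95ᴷ under the null (the optional
  Bonferroni flag addresses this at the cost of power).
* Ridge-penalized fits (ρ > 0) bias coefficients toward zero; Wald
  intervals are computed from the unpenalized information and are exact
  only at ρ = 0.
* The asymptotic KS band constants are used; exact small-n bands are out
  of scope (fits with fewer than ~50 intervals should be read with care).
* RS/FS classification is a 2-means partition of standardized
  (duration, rate); with overlapping clusters the boundary is data-driven,
  not a fixed published criterion.
* The simulator and the fitted model share the same family, so model
  mis-specification is only probed through the deliberate
  misspecification tests, not emulated realistically.
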