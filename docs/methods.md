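# Methods

## The score

The MAPK Pathway Activity Score (MPAS) summarizes the transcriptional output
of the RAS→RAF→MEK→ERK cascade in one number per sample:

    MPAS_s = ( Σ_{i=1..n} z_{i,s} ) / √n

where `z_{i,s}` is the z-score of gene *i*'s expression in sample *s* across
the cohort, and *n* = 10 for the fixed signature (PHLDA1, SPRY2, SPRY4,
DUSP4, DUSP6, CCND1, EPHA2, EPHA4, ETV4, ETV5).  The CTRL score is the same
aggregate over four housekeeping genes (MLH1, SMARCA4, U2AF, CLTC); since
housekeeping expression carries no pathway signal, CTRL behaves as a
built-in negative control whose downstream "predictions" should sit at
chance.

Because the z-scores are cohort-relative, so is the score: MPAS values are
comparable between samples scored together but carry no absolute calibration
across platforms or cohorts.  `recenter_scores` shifts a score table so that
0 is the mean of a chosen reference cohort, which is a presentation choice,
not a calibration.

Numerical choices:

- z-scores use the population (divisor-N) standard deviation.  This makes
  the two-sample case exact (z = ±1 per gene, scores ±√n) and is the
  convention the analytic tests pin down.
- When a measurement panel covers only part of the signature (the package
  supports panels with 5–6 of the 10 genes), `missing="subset"` scores with
  the genes present and divides by √n_used, warning about the omission.
  Re-normalizing keeps the score scale comparable; whether to keep √10
  instead is genuinely open, and the n actually used is recorded in the
  output so either convention can be reconstructed.

## Normalization chains

Panel-style counts (Nanostring-like): raw counts → background filter →
housekeeping normalization → log2(x+1) → z-score.  The background level per
sample is max(10, geometric mean of the negative-control probes); counts
below it are floored to it rather than dropped, so the matrix shape is
stable for scoring (dropping samples is left to the caller).  Housekeeping
normalization rescales each sample by (global housekeeping geometric mean) /
(sample housekeeping geometric mean), the standard geometric-mean-ratio
panel practice.

Sequencing-style matrices arrive already library-normalized and skip the
panel steps: raw → log2(x+1) → z-score.  log2(x+1) stands in for a variance
stabilizing transformation; it preserves the per-gene sample ranking, which
is all the rank-based downstream analyses consume.

Each matrix carries an explicit processing state and every operation rejects
out-of-order input, so z-scoring raw counts (or double-normalizing) is an
error rather than a silent mistake.

## Drug sensitivity

Viability is day-0 corrected and vehicle-relative:
`v = (raw − mean(day0)) / (mean(vehicle) − mean(day0))`, so 1 is vehicle
growth, 0 is stasis, and negative values are net cell death (kept, not
clipped).  Summaries:

- **IC50** from a four-parameter logistic fit
  `v(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)` by least squares over
  a deterministic multi-start grid (hill ∈ {0.5, 1, 2} × IC50 at each tested
  dose, plus a flat start), so the fit is reproducible without random
  restarts.  Fits whose inhibition depth (top − bottom) is below 0.05 —
  including flat and monotone-increasing series — are flagged
  `no_inhibition` with IC50 = +∞; IC50s more than 100× outside the tested
  dose range are flagged `extrapolated`.
- **Mean viability (MV)**: unweighted mean of per-dose replicate-mean
  viabilities over the tested positive doses (the dose grid is recorded with
  the output, since MV is grid-dependent by construction).  Sensitivity is
  reported as 1 − MV.
- **Sensitivity label**: sensitive iff IC50 < 1 µM (the upper end of the
  clinical serum-concentration range); exactly 1 µM and +∞ are resistant.

The dose-profile analysis tracks the score in one line across its own dose
series: expression per dose is reduced to that line, log-transformed if
needed, and z-scored **across doses** (not across a cohort), then the
profile is min–max rescaled and fitted with the same 4PL machinery.
Because rescaling stretches pure noise across [0, 1], a curve fit is
attempted only when the profile shows a clear decreasing dose trend
(Spearman ρ ≤ −0.6 vs dose); otherwise the profile is reported as
no-inhibition.  Note that score inhibition is only expected to mirror
viability inhibition in MAPK-active (score-high) lines: a line with negative
baseline score moves *toward* the cohort mean under pathway inhibition.

## Predictor evaluation

Continuous predictors become binary sensitive/resistant calls by a median
split: strictly above the cohort median is positive, ties at the median are
negative (deterministic, documented; the evaluation cohort's own median is
used).  For the elastic net, lower predicted viability means sensitive, so
the split is on −prediction.  Calls are scored against the IC50 labels with
TPR = TP/(TP+FN), FPR = FP/(FP+TN), ACC = (TP+TN)/N; rates with a zero
denominator are reported as null.  Continuous agreement uses Spearman rank
correlation (average ranks on ties, asymptotic p).

The elastic-net comparator uses mixing weight α = 0.5 and a penalty chosen
by 5-fold cross-validation (shuffled fold assignment, deterministic given
the seed) over 100 log-spaced penalties spanning [λ_max·1e-4, λ_max], where
λ_max is the smallest penalty that zeroes every coefficient.  Genes are
standardized to mean 0 / sd 1 before fitting to remove absolute-expression
bias, which also makes predictions invariant to per-gene affine rescaling of
the input.  `cv_r` is the Pearson correlation between out-of-fold
predictions (at the selected penalty, same folds) and the response.

`percentile_in_reference` places a correlation inside a reference
distribution of competing predictors using a top-oriented strict-inequality
convention (0th percentile = beats everything).  Published percentile
figures from prediction competitions cannot be reproduced exactly without
the competition's raw values and interpolation rule, so the convention here
is a declared choice.

## Survival analysis

Cox proportional-hazards fits maximize the partial likelihood with the
**Breslow** convention for tied event times, by Newton–Raphson on the
analytic gradient and Hessian (step-halving, convergence at max|grad| <
1e-9).  Breslow was chosen because it is the simplest exactly-specifiable
convention and makes the coefficient invariant under record duplication,
which keeps scan output stable on replicated inputs.  (The established
survival library in this stack implements the Efron correction instead; it
is used as an independent cross-check on tie-free data, where the two
coincide, and supplies the Kaplan–Meier estimator and the log-rank test.)
Inference is Wald-type: CI = exp(β ± 1.96·se), per-term p from the normal
approximation; a log-rank p is additionally reported for dichotomous terms.
Monotone likelihoods (perfect separation) are detected as a scale-free
effect size |β|·sd(x) exceeding 20 and flagged non-converged rather than
reported with meaningless standard errors.  Constant covariates and
collinear pairs are hard errors naming the offending terms.

Two scans summarize hazard as a function of where a score is cut:

- **Threshold scan**: dichotomize at each percentile from the 10th to the
  90th (inclusive, default step 5) and fit the indicator.  The 50th-
  percentile position reproduces median dichotomization exactly.  Positions
  where either side has fewer than 2 events are emitted as nulls, keeping
  the grid rectangular.
- **Sliding-window scan**: windows [q, q+30] advancing by 2 percentile
  points, reported at their centers (15, 17, …, 85).  A window width of 15
  is available via `window_pct` (two widths appear in the source material;
  the wider one is the default and the discrepancy is surfaced here rather
  than resolved).  Fitting a membership indicator compares window vs
  remainder; the default `comparator="population"` re-references the HR to
  the cohort-average hazard via h_pop = h/(f·h + 1 − f) (f = window
  fraction), applied to the HR and its CI endpoints — a monotone transform,
  so orderings across positions are preserved.

The binomial death test asks whether deaths concentrate in the score-high
group: k deaths among high-group members out of K total deaths, tested
two-sided and exactly against p₀ = (high-group size)/(cohort size).

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular dataset.  A latent per-sample activity a ~ Normal(μ, σ²)
(default standard normal) drives everything:

| quantity | model | defaults and rationale |
|---|---|---|
| signature expression | counts = round(exp(c0 + β·a + ε)), ε ~ N(0, σ_g) | c0 = 5 (~150 counts, panel scale), β = 1, σ_g = 0.5 (≈65% CV, generous panel noise) |
| housekeeping expression | same, no activity term | CTRL genes stay uninformative |
| negative controls | exp(1.8 + ε) ≈ 6 counts | sit below the background floor by design |
| mean viability | sigmoid(−k(a − a₀)) + N(0, 0.1), clipped to (−0.5, 1.5) | k = 1: activity halves viability over ~2 sd |
| IC50 | log10 IC50 = c − d·a + N(0, 0.25) | c = 0, d = 0.5: median 1 µM, balanced labels |
| mutation flag | Bernoulli, logit shifted by ρ_mut·a | ρ_mut = 0 by default — mutation status deliberately carries ~no activity information, mirroring the observed disconnect between mutation and pathway activity; raise it to give the mutation predictor a non-trivial regime |
| survival | T ~ Exp(λ₀·exp(β_surv·score)), C ~ U(0, c_max) | λ₀ = 0.1, β_surv = log 1.5, c_max = 32 → ≈30% censoring (`expected_censoring_fraction` gives the analytic value) |
| dose response | E(d) = d^h/(d^h + IC50^h); viability = 1 − E(d) + noise; treated activity = a·(1 − E(d)) | 9 log-spaced doses 0.0015–10 µM plus vehicle; score and viability decay together by construction |

All randomness flows through one `numpy.random.Generator` passed explicitly,
so a (config, seed) pair reproduces a cohort bit-identically.

What the generator does **not** emulate: whole-transcriptome covariance
(only the 20 panel genes exist), batch effects, tissue-specific expression
structure, mutation co-occurrence, or non-proportional hazards.  Passing
tests therefore demonstrate that the machinery recovers the structure it
assumes — scores tracking a latent factor, hazards loglinear in the score —
not that real cohorts satisfy those assumptions.

## Problem sizes used in the test suite

The bundled checks run cohorts of 40–500 samples and 20–50 replicate seeds
per property (e.g. HR recovery at n = 500 over 50 seeds; scan calibration at
n = 400; classification at n = 40, the validation-panel scale).  These sizes
give stable averages for the properties tested while keeping the whole
suite runnable in minutes on one CPU.

## Known limitations

- The score has no cross-cohort calibration; comparing absolute MPAS values
  between platforms is undefined behavior by design.
- The MV definition is grid-dependent; two labs with different dose grids
  get different MVs.  The grid is recorded with every output.
- The 4PL fitter assumes a monotone non-increasing response; biphasic
  dose-response curves will fit poorly (high rss) rather than erroring.
- Wald CIs undercover slightly in small cohorts with few events; the scans
  null out positions with <2 events per side rather than reporting unstable
  fits.
- The window-scan "population" reference is an algebraic re-referencing of
  the indicator fit, not a separate estimation; its CI is transformed
  through the same map and inherits the indicator fit's coverage.
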