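# Methods

## Sleep scoring

Sleep is scored from per-minute beam-break counts as maximal runs of
consecutive zero-activity minutes of length ≥ `min_bout` (default 5 min,
the standard behavioral definition for activity-monitor data; the
threshold is a parameter). Total sleep is the percentage of window
minutes inside such runs; bout number and mean bout length decompose it;
mean awake movement is beam breaks per non-bout minute (undefined, and
reported as NA, for a fly that never woke). Runs are clipped to the
analysis window before the length test, so a bout truncated to < 5 min by
a window edge does not count.

**Day/night boundary.** ZT intervals are half-open ([0, 12) day,
[12, 24) night), so no minute is double-counted. Bouts spanning the
boundary contribute their minutes to each phase separately (preserving
the conservation law: day + night sleep minutes = whole-window sleep
minutes, exactly) but are counted once, in the phase of their first
minute, for phase-level bout numbers.

**Percent change in sleep** is computed within fly as
100·(starved% − fed%)/fed% and then averaged to line level; a fly with
zero fed sleep has no defined value and is excluded from that average
with a logged reason. Negative values mean starvation suppressed sleep.

**Protocol annotation.** The first lights-on at or before the first
reading anchors ZT 0. Acclimation (2 d) and baseline (2 d) run from that
anchor; the starvation window is the configured clock time on the day
baseline ends (13:00 → ZH3 when lights-on is 10:00) plus 24 h. Minutes
between baseline end and starvation start (the transfer gap) are labelled
`excluded`. Baseline summaries pool both baseline days per fly rather
than averaging per-day summaries; for complete days the two differ only
for bouts crossing midnight-of-baseline, and pooling keeps the
conservation identities exact.

**Trace QC.** The study does not state how dead-in-tube flies were
handled; we flag a fly whose trace ends in ≥ 12 h (configurable) of
continuous zero activity and exclude it from fed summaries. The start of
that terminal quiet run is retained as a death-time estimate for
cross-checks only — LD50 always comes from vial censuses.

## LD50

A vial's LD50 is the earliest time the survival curve, interpolated
linearly between censuses, equals half the initial count; an exact-half
count at a census time yields that census time. A step-function variant
(first census at or below half) is available for sensitivity analysis
(`method="step"`); which the original analysis used is not stated, and
linear interpolation is the minimal-assumption default. Vials never
reaching half by the last census are right-censored and excluded from
line means, with the count logged; a line cell needs ≥ 2 uncensored
vials. Both mean and median line LD50 are reported; downstream models
consume the mean.

## Metabolite normalization and plate QC

Analyte quantities are divided by well protein (mg/mg). A second value
divides each well's per-protein ratio by the plate's mean Canton-S
per-protein ratio for the same analyte; any multiplicative plate effect
cancels exactly in this ratio, which is why it is the yardstick for
plate-effect diagnostics, while models consume the per-protein values.

The QC contract is the Akhr-mutant phenotype: TGA well above Canton-S,
glucose similar. Operationally (Welch t-tests on control wells,
α = 0.05, configurable): FAIL if the one-sided test of Akhr TGA >
Canton-S is non-significant, or the two-sided Akhr-vs-Canton-S glucose
test is significant; plates with < 2 replicate wells of either control
are "indeterminate" (kept, flagged). Note the one-sided rule means a
plate with truly equivalent controls fails ≈ 95% of the time — the rule
is deliberately conservative in favor of discarding uninformative plates.

## Statistical models

- **Pairwise families**: Welch two-tailed t-tests; Bonferroni
  significance at raw p < α/m where m is the number of tests actually
  performed in the family (degenerate comparisons are skipped and do not
  count). Family membership is whatever list the caller passes — one
  family per summary-table block in the pipeline.
- **ANOVA**: sequential (Type I) sums of squares, line nested within
  population via within-population recoding of line labels
  (`C(population):C(line_code)`), giving population 1 df and
  line-within-population 2(k−1) df for k lines per population. Type II
  is available through the `typ` argument.
- **MANOVA**: Pillai's trace per term over the four sleep/movement
  responses, with univariate sequential-ANOVA follow-ups; a singular
  response covariance raises with advice to drop collinear responses.
- **OLS models of LD50**: treatment coding with references Female, 21 °C,
  ME, so effects are Sex (M), Temperature (25), Population (PC);
  continuous predictors enter on their measured scales. On the full
  design (80 line means) the metabolism model has F df (5, 74) and the
  behavior model (6, 73).
- **Bayesian models**: the same design matrix is QR-reparameterized
  (X = QR with the thin factorization, scaled so Q*ᵀQ* = (n−1)I — which
  also certifies the model has enough degrees of freedom) and the
  posterior sampled with 4 independent chains. Because the model is
  Gaussian-linear, the conditional posteriors under a Normal prior on
  the rotated coefficients (sd = 100 × sd(y), weakly informative) and an
  InvGamma(0.001, 0.001) prior on σ² are exact, so a Gibbs sweep replaces
  Hamiltonian Monte Carlo without changing the target distribution; this
  choice was forced by the runtime environment (no HMC engine available)
  and is noted as a design decision. Chains start overdispersed; 2000
  iterations with the first half discarded; rHat (rank-normalized, via
  arviz) must be ≤ 1.05 for every parameter or the fit raises and
  withholds summaries. Reported per term: posterior mean (Estimate), sd
  (Est.Error), central 95% credible interval, rHat and Monte-Carlo SE;
  100 posterior-predictive replicate response vectors support the
  density-overlay check. An optional line-level varying intercept is
  deliberately **not** included: the published model terms are fixed
  effects, and the residual df (74/73) identify the rows as line × sex ×
  temperature means.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* and the *reported qualitative
structure*, not any real fly's physiology:

- Two-state semi-Markov sleep/wake per fly: phase-specific wake→sleep
  hazards, shifted-geometric bout lengths (floor 5 min) with
  population-specific means (PC night bouts ~45 min vs ME ~25 min →
  PC sleeps more at night through bout length, the reported pattern),
  zero-truncated-Poisson beam breaks on awake minutes (ME rate 2.5/min
  vs PC 1.5/min → ME moves more when awake).
- Starvation multiplies bout-length means by 0.6 and awake activity by
  1.3, leaving the initiation hazard alone — so bout number is unchanged
  by starvation, as reported.
- Line effects are log-normal multipliers (sd 0.15 on bout means, 0.10 on
  hazards) shared across conditions.
- Death times: line means are drawn jointly with line starved-sleep
  scores from a bivariate normal with per-population correlation ρ
  (defaults ρ_PC = 0.9, ρ_ME = 0), plus population (+15 h for ME), sex
  (+10 h female), temperature (+8 h at 21 °C) offsets and vial (sd 1.5 h)
  and fly (sd 3 h) noise; negative draws are resampled and counted.
  Baseline 25 h puts PC males at 25 °C near 1 day of resistance and ME
  females at 21 °C near 2.4 days — the order of magnitude reported for
  such assays.
- Plates carry both analytes, 4 Canton-S and 4 Akhr wells, log-normal
  multiplicative plate effects (sd 0.25) on the analyte channel, 15% well
  CV, and an optional rate of "inverted-control" plates for QC power
  studies.

**Simplifications to keep in mind.** Wake minutes always emit ≥ 1 beam
break, so quiet wakefulness — real in flies — never masquerades as sleep;
this is what makes the generator's sleep ledger agree *exactly* with the
pipeline's scoring, and it means green recovery tests certify the
pipeline's bookkeeping, not its robustness to quiet-wake ambiguity.
There is no circadian anticipation, no activity ramp before death, no
temperature dependence of the sleep parameters, and monitor files are
written noise-free (no status-code errors or gaps). Bout lengths are
memoryless beyond the 5-min floor.

Determinism: all randomness flows from a single integer seed through
`numpy` SeedSequence spawning; identical seed + config give byte-identical
output files.

## Numerical choices

- Exact-half survivor counts at a census time: LD50 = that census time
  (earliest-crossing convention).
- Line LD50 SE uses the sample sd (ddof = 1) over uncensored vials, as do
  all reported standard errors (including hourly sleep profiles).
- The Gibbs sampler clamps the residual sum of squares at 1e-12 to keep
  the InvGamma draw proper on degenerate (σ → 0) synthetic data.
- Regressions with fewer than 3 points per group are skipped, not fit.
- Scaled-down defaults are used in tests and the acceptance script
  (fewer flies/replicates than the 24-per-cell study design) purely for
  runtime; effect sizes, rates and thresholds are never tuned to test
  outcomes.

## Known limitations

- Real published coefficients are not reproducible here: they depend on
  the deposited raw data, which this package deliberately does not ship.
  Structural quantities (degrees of freedom, estimator identities,
  convergence behavior, power under the stated coupling) are what the
  test suite pins down.
- Only the 42-column DAM2-style monitor dialect is parsed; multi-beam
  monitors and acquisition-time QC are out of scope.
- Kaplan–Meier/Cox survival modelling is intentionally absent: the
  statistic of interest is the interpolated half-death time.
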