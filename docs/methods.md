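# Methods

## Estimands and identification

The exposure is the SEN provision category recorded in the January census
of Year 1 — `None`, `Support`, or `EHCP` — analysed as an intention-to-treat
contrast between two levels at a time, with the cohort restricted to pupils
observed in one of the two arms. Two estimands are targeted per outcome:
the ATE (average over the whole two-arm population) and the ATT (average
over pupils actually assigned the exposed level). Identification assumes no
interference, consistency of the recorded category, no unmeasured
confounding given the covariate set, and positivity; the last is the one
assumption checked empirically, via the propensity-overlap gate described
below.

Reporting scales follow the field's conventions: rate ratios for count
outcomes (events per person-time or per possible session), risk ratios for
persistent absence (the crude row is an odds ratio, as such tables are
conventionally laid out), and mean differences for year-standardised test
scores.

## Synthetic cohort generator

The generator emulates the analysis-ready rectangle of a national linked
education/health cohort of children with an isolated cleft; it does not
emulate raw hospital episodes or termly census files.

**Covariates.** Categorical margins (gender, gestational-age, birthweight
and maternal-age bands, ethnic and language group, deprivation quintile,
free-school-meal eligibility, academic cohort, cleft type, chronic-condition
flags, month-of-birth) are drawn to match the published descriptive table
of the cohort; the joint dependence structure is not published, so only a
few dependencies judged clinically plausible are built in (FSM by
deprivation quintile, chronic conditions by cleft type, school-readiness
score depressed by chronic illness, deprivation and prematurity).
Continuous covariates (school-readiness z-score, prior hospital-contact
rate, school-level SEN/FSM proportions) use normal/gamma/beta laws chosen
to roughly match published medians and interquartile ranges.

**Assignment.** A single multinomial logit over the three levels (not three
separate binary models) keeps the generating law coherent; the pairwise
binary PS models of the analysis are fitted on arm-restricted subsets at
estimation time. Intercepts are calibrated so arm shares are ≈65.9/30.4/3.7
per cent; slope coefficients reproduce the published gradients (more
Support among boys, preterm or low-birthweight births, deprived areas,
FSM-eligible pupils, severe cleft types, chronic conditions, and low
school-readiness scores). The EHCP level is driven hard by severity
markers, so that contrasts involving it genuinely lack overlap — the
positivity-failure path is a study condition, not an edge case.

**Follow-up.** Entry at the January census leaves 0.58 of a year in Year 1;
Years 2–6 are whole years. A pupil's window closes at loss to follow-up
(2.5 %/year, independent of covariates and treatment), at the study end for
their academic cohort, or at the end of Year 6. KS1 requires enrolment in
Year 2, KS2 in Year 6 — late cohorts therefore never contribute KS2, which
reproduces the published pattern of ~88 % KS1 and ~47 % KS2 availability.
Possible half-day sessions are 220 in the partial Year 1 and 380 per full
year. A 0.08 % sliver of pupils carries no absence data at all (their
absence outcomes are undefined, mirroring the published N = 6,596 vs 6,601).

**Outcomes.** Counts (A&E days, admitted days, medical / unauthorised /
other absence sessions) are Poisson draws per observed year around a
pupil-level gamma frailty shared across years, so each pupil's total is
marginally NB2 with the configured dispersion and years are positively
correlated within pupil. The analysed hospital outcome is
`AE + APC − same-day overlap` (overlap binomial with probability 0.55 given
the smaller component), capped at follow-up days; the accounting identity
is preserved exactly for the disaggregation sensitivity analysis.
Persistent absence is the deterministic ≥10 % functional of all simulated
absence sessions (a direct-logistic mode exists for power experiments).
Raw test scores add a deterministic year-specific marking shift and scale
on top of a latent z-scale linear predictor; per-year standardisation in
the prep module removes it. Cluster-level normal intercepts (default SD
0.15–0.2 on the link scale) on all outcomes make local-authority clustering
consequential for inference. Offsets (follow-up, sessions) are generated
independently of covariates and treatment, so the exposure-weighted and
pupil-averaged marginal rate ratios share a single truth.

**Default treatment effects** are set to the magnitudes the study reports
as its causal findings: null on hospital days, +9 % on medical absences,
−10 % on unauthorised absences, −0.21/−0.27 SD on KS1/KS2 (EHCP effects are
larger but never analysed, being refused at the gate). Intercepts and
dispersions were calibrated once against the published aggregate rates
(385 hospital days per 1000 years; 35.3 and 9.8 absences per 1000
sessions; ~10 % persistent absence) and then frozen.

**Missingness** is MAR on fully observed covariates: log-odds coefficients
on cohort year, FSM and ethnicity, with the intercept solved per draw so
marginal masking rates match the published `Unknown` fractions
(gestational age 22.7 %, birthweight 16.6 %, maternal age 4 %, deprivation
0.2 %, school readiness 0.9 %).

**Oracle.** `true_marginal_effects` simulates both potential outcomes for
every Monte-Carlo pupil on shared noise (frailties, cluster intercepts,
score residuals) and averages on the reporting scale; the ATT restricts the
average to pupils whose realised assignment draw is the exposed level.
Monte-Carlo standard errors come from 20 batch means. Score truths are
evaluated on the latent z-scale, the scale the analysis targets after
per-year standardisation.

## Analysis variables

Rates are `numerator/denominator × 1000`; follow-up is measured in days
and reported in years of 365.25 days. Persistent absence counts all
absence types in the numerator (the definition does not restrict type);
the threshold is boundary-inclusive. Scores are standardised within
academic year using the population SD over the generated cohort — the
original study standardised against the full national pupil database,
which has no analogue here; this is a documented divergence. Progress
scores are the difference between the Key Stage z-score and the
school-readiness z-score.

MCIM expansion zero-fills masked continuous covariates and pairs them with
an indicator column; masked categorical covariates become an explicit
`Unknown` level. Both value and indicator enter every model: propensity,
conditional, g-computation and AIPW.

## Models and estimators

The design matrix is shared by all models (`design.py`): full dummy sets
for categorical covariates, linear terms for binary and continuous ones,
quadratic terms for continuous covariates in the propensity model only.
The skewed prior-contact rate enters on the log1p scale. Exactly collinear
columns are dropped greedily (Gram-matrix residual test, earlier columns
win).

*Propensity.* Binary logistic GLM per contrast. Rare dummy levels present
in only one arm (fewer than max(20, 0.5 %) pupils) have no finite log-odds
and are dropped with a warning; any remaining coefficient that moves the
linear predictor by more than 15 logits per covariate SD raises a
separation error naming the column. No trimming or winsorisation is applied
by default; a percentile winsorisation option exists.

*Positivity gate.* The overlap table counts pupils per fixed-width PS
decile and arm. A decile is unsupported for an arm when the other arm
holds less than 0.2 % of its own pupils there (an empty cross-arm cell is
the extreme case); the gate fails when more than 5 % of either arm's mass
sits in unsupported deciles, and warns between 2 and 5 %. The share-based
form is deliberately sample-size-stable: a raw zero-cell rule flips
verdicts at realistic cohort sizes because the expected cross-arm count in
an extreme decile is of order one, so observing zero is routine. Under
default conditions Support-vs-None passes (occasionally warns) and
EHCP-vs-None fails, across seeds.

*Outcome families.* Negative binomial (NB2) with log-exposure offset for
counts, dispersion profiled by maximum likelihood on the log scale
(bounded search, tolerance 1e-8) with a Poisson fallback when the profile
optimum is at ~0 overdispersion; logistic for persistent absence; linear
for scores. Weighted fits use the same families with case weights.

*IPW.* Weighted treatment-only model; ratio estimates default to the
exponentiated coefficient (for Poisson this equals the weighted aggregate
rate ratio; an explicit aggregate mode is provided). Binary outcomes
report the ratio of weighted means (risk ratio), scores the weighted mean
difference. Weights above 50 are flagged in diagnostics but not truncated.

*G-computation.* Outcome model on confounders + treatment (no
interactions by default; `treat_x_*` columns support fully interacted,
saturated models), predictions under both arms averaged over the estimand
population. Count outcomes use the exposure-weighted (aggregate) marginal
mean by default — the convention that reproduces the published crude rate
ratio from aggregate totals — with a pupil-averaged alternative.

*AIPW.* The standard augmented estimating equation on the rate /
probability / raw scale, Poisson working model for counts (NB available
behind a flag). Propensity scores outside (ε, 1−ε), ε = 1e-3, are an
error. The ATT variant weights reference-arm residuals by `p/(1−p)`,
normalised, and is flagged as an extension in diagnostics because the
source layout leaves AIPW ATT blank. Post-lasso selection of both nuisance
models (10-fold CV over a log-spaced penalty grid, minimum out-of-fold
deviance, treatment and intercept unpenalised, unpenalised refit on the
selected set) is implemented and tested; the estimator API defaults to the
full-covariate nuisances, with lasso behind a `use_lasso` flag. The L1
path is warm-started down the penalty grid; even so, cross-validated
selection multiplies the cost of an AIPW fit by two orders of magnitude,
which is why it is opt-in rather than the default.

## Inference

All causal CIs come from the cluster bootstrap: local authorities are
resampled with replacement (same number of clusters), repeated clusters
are relabelled as distinct, and the full chain — propensity fit included,
so nuisance uncertainty propagates — is re-run per replicate. Intervals
are percentile order statistics without interpolation, so log-scale and
ratio-scale intervals agree exactly. Failed replicates are dropped; more
than 5 % failures is a hard error. Inside bootstrap replicates the NB
dispersion is held at its full-sample ML value (coefficients are refit);
the dispersion search dominates NB fitting cost and its sampling
variability contributes negligibly to interval width. Crude and
conditional regression rows use cluster-robust sandwich SEs (score
contributions aggregated by cluster, G/(G−1) correction) instead. B
defaults to 1000 in the pipeline; tests and examples use smaller B chosen
for runtime, stated per test.

## Problem sizes used in the test suite

Parameter-recovery acceptance runs on a 20,000-pupil cohort with a
200,000-pupil oracle and a 48-replicate bootstrap SE; double-robustness on
a 12,000-pupil reduced-confounder configuration (assignment and outcomes
depend only on FSM, chronic condition and school readiness, all exactly
representable in the analysis design, so "correct model" is literal);
coverage on 50 repetitions of a 1,800-pupil, 60-cluster cohort with
B = 199. These sizes are the package's choices for routine verification;
all tolerances are 3 × (Monte-Carlo SE + bootstrap SE), never constants
tuned to a particular draw.

## What passing tests do and do not show

The generator reproduces the published margins, the confounding-by-
indication structure, the censoring pattern and the missingness pattern —
under it, the estimators provably recover known truths, AIPW is doubly
robust, and cluster-bootstrap intervals attain near-nominal coverage. Real
linked administrative data differ in ways the generator does not emulate:
covariate measurement error, misclassified SEN recording, informative loss
to follow-up, unmeasured confounders (parental education, home learning
environment), and within-authority policy correlation beyond a shared
random intercept. Passing tests therefore validate the estimation
machinery, not the substantive conclusions one would draw from restricted
data.

## Known limitations

* The ≥10 % persistent-absence functional makes its risk ratio a
  non-analytic functional of the count laws; its truth exists only by
  simulation, and logistic outcome models for it are approximations even
  in the generator's world (the count construction, not a logistic law,
  generates the flag).
* MCIM is known to leave residual confounding in general; under the
  generator's MAR-on-observables masking the induced bias is well inside
  one bootstrap SE at the tested sizes, consistent with published
  simulation evidence, but it is not zero.
* The positivity gate automates a judgement the original analysts made by
  eye; its two thresholds (5 pupils per cell, 5 % unsupported mass) are
  package defaults, not estimated quantities.
* Cluster effects are exchangeable random intercepts; spatial or policy
  structure between authorities is out of scope.
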