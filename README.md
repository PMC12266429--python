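# emultrial

Target-trial emulation of early special-educational-needs (SEN) provision
for children with an isolated orofacial cleft, built as a reusable Python
library: a clustered synthetic-cohort generator with exact potential-outcome
truths, propensity-score diagnostics with a positivity gate, and
triangulated causal estimation (IPW, g-computation, AIPW) of the ATE and
ATT with cluster-bootstrap inference.

## The scientific problem

In England every pupil can receive SEN provision — None, SEN Support, or an
Education and Health Care Plan (EHCP) — so the effect of early provision on
later health and schooling cannot be randomised. Observational school/
hospital linkage cohorts answer the question instead, but assignment is
heavily confounded by indication: children who receive support are sicker,
poorer and further behind at school entry. The target-trial framework makes
the estimand explicit — the intention-to-treat effect of the provision
category recorded in Year 1 on outcomes accumulated to the end of primary
school (Year 6):

* unplanned hospital days (same-day A&E/admission deduplicated), as a rate
  per person-time — effect reported as a **rate ratio (RaR)**;
* medical and unauthorised school absences per possible half-day session
  (**RaR**), and **persistent absence** (≥10 % of sessions missed,
  **risk ratio, RiR**; odds ratio for the crude row);
* Key Stage 1/2 maths z-scores, standardised within academic year
  (**mean difference, Δ**).

For a pairwise contrast (exposed level *e* vs reference *r*) the package
estimates, with propensity score `p(X) = P(A=e | X)` fitted by logistic
regression on the arm-restricted cohort:

* **IPW** — weights `1/p(X)` and `1/(1−p(X))` (ATE), or `1` and
  `p(X)/(1−p(X))` (ATT), in a weighted treatment-only outcome model;
* **g-computation** — an outcome regression (negative binomial with
  log-exposure offset, logistic, or linear) predicts both potential
  outcomes per pupil; standardised means are compared;
* **AIPW** — the doubly robust combination
  `ψ_a = E[ 1{A=a}/p_a(X) (Y − m_a(X)) + m_a(X) ]`, consistent when either
  nuisance model is correct (Poisson outcome working model for counts);
  optional post-lasso selection of both nuisance specifications.

Missing confounders are handled by the missing-covariate-indicator method
(zero-fill plus indicator; explicit `Unknown` category for categorical
covariates). Confidence intervals resample whole local-authority clusters
and re-run the entire chain, propensity fit included. A contrast whose
propensity distributions barely overlap — in this cohort, anything
involving EHCP — is refused at the positivity gate rather than estimated.

The real linked cohort is access-restricted, so the package ships a
generator that emulates its structure (≈6,600 pupils in ≈150 local
authorities, arm shares ≈66/30/4 %, overdispersed counts with person-time
and session offsets, MAR-masked birth covariates, academic-cohort censoring
of KS2) and computes the **true** marginal ATE/ATT per outcome by
simulating both potential outcomes — which is what the tests recover.

## Worked example

`examples/03_effect_estimates.py` generates a 6,601-pupil confounded
cohort, computes the oracle truth, and triangulates the ATE with 50
cluster-bootstrap replicates:

```
hospital (RaR); oracle truth = 0.989
  crude regression :  1.316   (confounded by indication)
  IPW             :  0.943   95% CI (0.864, 1.039)
  gcomp           :  0.936   95% CI (0.875, 0.989)
  AIPW            :  0.952   95% CI (0.876, 1.051)

ks1 (Delta); oracle truth = -0.210
  crude regression : -0.633   (confounded by indication)
  IPW             : -0.201   95% CI (-0.260, -0.130)
  gcomp           : -0.189   95% CI (-0.234, -0.138)
  AIPW            : -0.209   95% CI (-0.261, -0.152)
```

The crude hospitalisation rate ratio of 1.32 is almost entirely confounding
by indication: the causal estimators bracket the true null (0.99). For KS1
maths the true disadvantage of −0.21 SD remains after adjustment — a third
of the crude gap. The other examples cover cohort generation and margins
(`01`), propensity overlap and the positivity refusal of EHCP contrasts
(`02`), and Year-2-censoring / complete-records sensitivity analyses
(`04`).

A thin CLI wraps the same library:

```bash
emultrial simulate --seed 1 --out cohort.csv
emultrial run --cohort cohort.csv --seed 1 -B 200 --out results/
emultrial report --results results/
```

Exit code 3 flags a run in which every requested contrast was refused at
the positivity gate.

## Layout

```
src/emultrial/
  config.py       generator configuration and study-condition defaults
  simulate.py     clustered cohort simulator, potential-outcome bookkeeping
  oracle.py       Monte-Carlo marginal truths (ATE/ATT per outcome)
  prep.py         rates, persistent flag, score standardisation, filters
  design.py       MCIM design matrices shared by all models
  propensity.py   pairwise PS models, overlap deciles, positivity gate, lasso
  estimators.py   crude/conditional/IPW/g-computation/AIPW estimation
  uncertainty.py  cluster bootstrap and cluster-robust sandwich SEs
  pipeline.py     end-to-end orchestration and report tables
  cli.py          thin click front end
examples/         narrative scripts, one per capability
docs/methods.md   model, assumptions, numerical choices, limitations
```
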