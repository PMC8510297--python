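# Methods

## Signature discovery by multi-cohort meta-analysis

Each cohort contributes, per gene, a two-class standardized mean difference:
Hedges' adjusted g with the small-sample correction J = 1 − 3/(4·df − 1) on
df = n₁ + n₂ − 2 pooled-SD degrees of freedom, and sampling variance
v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Per-study effects are pooled by
inverse-variance weighting. Two pooling models are exposed:

* `fixed` — weights 1/vᵢ;
* `random_dl` (default) — DerSimonian–Laird: Cochran's Q on the
  fixed-effect weights, τ² = max(0, (Q − (k−1))/C) with
  C = Σw − Σw²/Σw, then re-pooling with weights 1/(vᵢ + τ²).

Random effects is the default because the whole design premise is that the
cohorts are biologically, clinically and technically heterogeneous; the
power analysis below reasons over exactly that heterogeneity. The pooled
z = ES/SE gives the two-sided p that is Benjamini–Hochberg corrected across
genes and drives all selection. Fisher sum-of-log combinations of one-sided
per-study p-values (from the pooled-variance t statistic, per direction) are
computed and reported but intentionally not used for selection: they answer
a different question (consistency of direction) and have no natural effect
floor. Genes with zero pooled SD in some study are pooled over the remaining
studies (recorded in `n_studies`); genes usable in fewer than two studies
are dropped. The gene universe defaults to the intersection of all cohorts'
panels (`min_fraction = 1.0`); pooling over partial panels is opt-in since
missing-gene policies change the multiplicity burden.

The leave-one-dataset-out (LODO) filter reruns the full meta-analysis k
times, dropping one cohort each time, on the same gene universe. A gene
passes only if it stays below the FDR threshold with an unchanged
effect-size sign in the full run and in all k reruns. This deliberately
removes genes driven by a single cohort — the targeted simulation in the
test suite (a gene differentially expressed in 1 of 5 cohorts) confirms the
filter catches exactly that case.

Signature selection thresholds: FDR < 0.01 and |summary ES| ≥ 0 by default,
both configurable (the sensitivity grid sweeps FDR 1–20% and |ES| 0.6–1.2).
Ordering within the signature is |summary ES| descending with lexicographic
tie-break, so output is fully deterministic.

Signature scoring of an individual sample is the geometric mean of the
up-genes minus the geometric mean of the down-genes, computed after shifting
the dataset so its minimum value is ≥ 1 (log-safe), then z-scored across the
samples of the dataset; a zero-variance score vector is defined as all
zeros with a warning. AUROC uses the Mann–Whitney formulation with ties
counting one half.

## Power of a multi-cohort design

Power follows the standard meta-analytic formulation: per-study variances
vᵢ at the target summary effect, between-study variance τ² added to each,
summary variance V = 1/Σ 1/(vᵢ+τ²), noncentrality λ = ES/√V, and two-sided
power 1 − Φ(z₁₋α/₂ − λ) + Φ(−z₁₋α/₂ − λ). Heterogeneity levels none / low /
moderate / high are encoded as τ² = c·v̄ with c = 0, 1/3, 2/3, 1 (the usual
convention; an explicit τ² overrides the level, since conventions vary).
With the packaged 11-cohort sizes this gives 99.15% power at ES 0.66 with no
heterogeneity and >99.99% at ES 1.41 at the highest level (α = 0.01,
two-sided). A Monte-Carlo companion (`monte_carlo_power`) simulates the same
generative model and is used to cross-check the analytic value to ±0.01.

## Pathway overrepresentation

One-sided hypergeometric upper tail P(X ≥ k) over the measured gene
universe (not the whole genome — using the genome inflates enrichment of
anything well-measured), after intersecting each set with the universe and
dropping sets below `min_size = 5`. BH correction runs over exactly the
tested sets. The odds ratio uses a Haldane 0.5 correction when a 2×2 cell
is zero. Up- and down-genes are tested jointly by default; a directional
mode exists because the choice is genuinely open.

## Drug ranking by signature reversal

Pearson correlation between the signature's summary effect sizes and each
drug's perturbation effect sizes over shared genes (≥ 3 required), p from
the t transform on n−2 df, BH across drugs, rank 1 = most negative r, ties
broken by q then drug id. The reliable-gene ("gold") mask restricts the
shared genes by default. Multiple cell-context profiles of one drug are
averaged per gene before correlation (per-context values remain available).
Zero-variance profiles get r = NaN and are excluded from ranking rather than
erroring, so one degenerate drug cannot abort a compendium run. The
sensitivity grid reports the per-cell top-10 sets and their mean pairwise
Jaccard similarity ("stability", 1.0 by convention when fewer than two cells
are non-empty; empty-signature cells are excluded).

## Survival emulation

Cohort assembly implements a new-user, active-comparator design: subjects
need a qualifying diagnosis, no exclusion diagnosis (prefix-matched ICD
codes; trailing `.x` marks a hierarchy prefix), and a study-drug
prescription strictly after first diagnosis. Index date is the first
qualifying prescription; subjects on both drug classes are assigned to the
treatment arm with index at the first exposure-drug date
(intention-to-treat at initiation) and counted in the attrition report.
Follow-up runs to the first outcome code, else censoring at the last
recorded event; time must be positive. Covariate flags count any occurrence
on or before index; age is computed at index.

The Cox model is fitted by Newton–Raphson on the partial likelihood with
analytic score and observed information, Efron tie handling by default
(claims data carry heavy date ties) and Breslow as an alternative;
convergence at max |score| < 1e-9, capped at 25 iterations with
step-halving; covariates are centered internally (invariant for the
coefficients, stabilizes the exponentials). Standard errors come from the
inverse observed information; CIs and p-values are Wald. Collinear
covariates raise a singular-information error; coefficients drifting past
|β| > 50 are treated as a monotone likelihood (perfect separation) and
raise an error suggesting a penalized fit, which is not implemented. The
implementation matches lifelines (Efron), scikit-survival (Breslow) and
direct grid maximization of the written-out partial likelihood in the test
suite.

The proportional-hazards test is the Grambsch–Therneau score test on
scaled Schoenfeld residuals against a transform of event time (default:
one minus the left-continuous Kaplan–Meier estimate; rank and identity
transforms available), per covariate plus a global test. Schoenfeld
residuals use the full-risk-set expectation; with heavily tied data this is
an approximation to the Efron-weighted version. The test is calibrated
(uniform p under proportional hazards by construction) and matches the
reference implementation on untied data in the tests.

Kaplan–Meier estimation is the plain product-limit estimator with Greenwood
variance; censored-only times shrink the risk set without adding a step.

Propensity scores are an L1-penalized logistic regression of exposure on
standardized covariates with the penalty chosen by 5-fold cross-validated
deviance (stratified folds, seeded). Matching is 1:1 nearest-neighbor
without replacement on the logit of the propensity, greedy in descending
treated propensity; a caliper of 0 is read as "no caliper" (the matching
convention), a positive caliper is honored. The balance report gives
standardized mean differences before and after matching.

Duration sensitivity refits the model while restricting the treated arm to
increasing minimum on-therapy durations (comparators untouched); grid
points with fewer than 5 treated subjects are flagged unstable. Stability
across the grid is assessed as no significant pairwise difference between
log hazard ratios (Wald test with independence-based standard errors, which
is conservative because the restricted cohorts are nested). The long- vs
short-term contrast subsets treated subjects followed at least 720 days and
compares ≥ 6 months on therapy against less. The negative-control analysis
refits the model on an outcome that shares the confounding structure but
carries no true treatment effect; a confidence interval excluding 1 flags
residual (healthy-user-type) bias.

## What the synthetic generators emulate — and what they do not

* `gen_multicohort` defaults are the discovery-study conditions: 11 cohorts
  with the published per-group sizes (5–30 per group, 272 samples, 171
  cases), 10 000 genes, 500 differentially expressed at mean |g| = 1.0,
  true per-study effects drawn N(±1.0, τ²) with τ² = 0.05 (low
  heterogeneity, matching where the discovery study located its signature
  genes), unit within-group SD so planted effects are directly on the g
  scale, and fully shared gene panels (`platform_dropout = 0`; the dropout
  knob emulates partially overlapping platforms when needed). Values are
  exchangeable Gaussians — no probe-level noise, batch structure,
  normalization artifacts or gene–gene correlation — so recovery results
  bound what the statistics can do under their own assumptions, not
  microarray reality.
* `gen_drug_compendium` plants one perfect reverser (−disease ES + noise)
  and one mimic among i.i.d. N(0,1) null profiles, 781 drugs and a 60%
  gold mask by default; `extra_reverser_strengths` plants additional graded
  partial reversers for experiments about rank stability among genuinely
  correlated drugs. Null drugs are uncorrelated with each other, unlike
  real perturbation panels.
* `gen_survival_cohort` draws age ~ N(58, 15²) truncated at 18, sex and
  binary comorbidities; exposure by a logistic model with the intercept
  bisection-calibrated to the target marginal rate; exponential event times
  (proportional hazards hold exactly) with baseline hazard 1/1500 per day
  (median time-to-event about 2.8 years for an unexposed average subject);
  independent exponential censoring bisection-calibrated to the target
  censoring fraction; and an optional negative-control outcome sharing the
  covariate hazards with exposure HR 1. Healthy-user confounding is a named
  spec: comorbidities and age lower exposure probability and raise hazard.
  Real claims data add informative censoring, time-varying exposure and
  coding error, none of which are modeled.

All generators are bit-reproducible given (config, seed); one run seed fans
out to per-component child streams via fixed offsets, so regenerating one
component never perturbs another.

## Problem sizes in the test suite

The recovery tests run the full 11-cohort, 10 000-gene configuration over
10 seeds (meta-analysis plus LODO is about 1.5 s per seed), the 781-drug
reverser ranking over 100 seeds, FDR calibration on 50 null replicates of
1 000 genes, proportional-hazards calibration on 200 replicates of n = 150,
CI coverage on 200 replicates of n = 400, and single survival cohorts of
n = 5 000–6 000 — sizes chosen so each property is measured with sensible
Monte-Carlo error while the whole suite stays in the minutes range.

## Known limitations

* No moderated (limma-style) within-study statistics, meta-regression or
  covariate adjustment at the gene level.
* The p-value-combination branch assumes a pooled-variance t statistic per
  study; the discovery study did not print its within-study statistic.
* No Firth-style remedy for separated Cox fits; the error message points
  at the option.
* Propensity matching is greedy nearest-neighbor; optimal matching is out
  of scope.
* ICD matching is prefix-based; no hierarchy expansion, competing risks or
  inverse-probability weighting.
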