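# reposign

Computational drug repositioning for inflammatory disease, built as three
reusable, individually testable stages:

1. **Multi-cohort disease signature discovery.** Case/control expression
   cohorts (genes × samples, log2 scale) are combined by a per-gene
   random-effects meta-analysis: within each cohort the effect of disease on
   a gene is Hedges' adjusted g,

   g = J · (x̄₁ − x̄₀) / s_pooled,  J = 1 − 3/(4·df − 1),
   var(g) = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)),

   pooled across cohorts by inverse-variance weighting (DerSimonian–Laird
   τ² by default), with Benjamini–Hochberg FDR correction and Fisher
   combination of one-sided per-study p-values per direction. A
   leave-one-dataset-out (LODO) filter keeps only genes that stay
   significant, with a consistent sign, when every cohort is dropped in
   turn — so no single study can drive the signature. The analytic power of
   a given multi-cohort design is available via the Hedges–Pigott formula
   (`reposign.power_analysis`), and signatures can be checked by
   overrepresentation analysis against GMT gene-set collections
   (`reposign.pathway_enrichment`).

2. **Signature-reversal drug ranking.** Each drug in a perturbation
   compendium (genes × drugs effect sizes, optionally restricted to the
   "gold" reliable-gene mask, as in LINCS L1000 Level-5 data) is scored by
   the Pearson correlation between its profile and the signature's summary
   effect sizes over shared genes. Rank 1 is the most negative correlation:
   the drug that most strongly opposes the disease state. A sensitivity grid
   re-selects the signature over FDR × effect-size thresholds and reports
   the stability of the top-10 drug set.

3. **Target-trial-style survival validation.** A new-user, active-comparator
   cohort is assembled from a subject-level event stream (first qualifying
   prescription after diagnosis sets the index date; exclusion diagnoses and
   on-index outcomes drop subjects, with an attrition report). Hazard ratios
   come from a Cox proportional-hazards model fitted by Newton–Raphson on
   the partial likelihood (Efron or Breslow ties), with Kaplan–Meier curves,
   a Grambsch–Therneau proportional-hazards test, L1-propensity-score
   matching, treatment-duration sensitivity analyses and a negative-control
   outcome to surface healthy-user bias.

Every stage has a synthetic-data generator with known ground truth
(`reposign.synthetic_data`): planted differentially expressed genes with
between-study heterogeneity, a planted signature-reversing drug, a planted
enriched gene set, and survival cohorts with a known hazard ratio and a
healthy-user confounding knob. The test suite uses these to verify that the
pipeline recovers what was planted.

## Worked example

```python
import numpy as np
from reposign import (run_meta, lodo_filter, select_signature, rank_drugs,
                      cox_fit, ph_test, table1_size_pairs, meta_power, PowerSpec)
from reposign.drug_repositioning import profiles_from_table
from reposign.synthetic_data import (SimConfig, gen_multicohort,
                                     gen_drug_compendium, gen_survival_cohort,
                                     healthy_user_confounding)

# 1. discovery: 11 cohorts with the published group sizes, 500 planted DE genes
cfg = SimConfig(seed=0)
datasets, truth = gen_multicohort(cfg)
meta = run_meta(datasets, model="random_dl")
lodo = lodo_filter(datasets, fdr_threshold=0.01, full=meta)
sig = select_signature(meta, lodo, fdr=0.01)
planted = set(truth.de_genes)
print(f"signature: {len(sig.up)} up / {len(sig.down)} down "
      f"({len(set(sig.genes) & planted)}/{len(planted)} planted genes recovered)")

# 2. power of that design
spec = PowerSpec(table1_size_pairs(), target_es=0.66, alpha=0.01)
print(f"analytic power at summary ES 0.66: {meta_power(spec):.4f}")

# 3. drug ranking against a synthetic compendium with a planted reverser
eff, gold = gen_drug_compendium(truth, sig.effects().to_dict(),
                                n_drugs=781, noise_sd=1.0, seed=1)
hits = rank_drugs(sig, profiles_from_table(eff, gold))
top = hits.iloc[0]
print(f"top-ranked drug: {top.drug_id} (r={top.r:.3f}, FDR={top.q:.2e})")

# 4. survival validation on a confounded synthetic cohort
cohort, _ = gen_survival_cohort(6000, true_hr=0.6,
                                confounders=healthy_user_confounding(1.0), seed=2)
covs = ["exposure", "age", "sex", "comorbidity_1", "comorbidity_2", "comorbidity_3"]
fit = cox_fit(cohort, covs)
lo, hi = fit.ci95["exposure"]
print(f"adjusted exposure HR: {fit.hr['exposure']:.2f} ({lo:.2f}-{hi:.2f}), "
      f"p={fit.p['exposure']:.1e}; PH test p={ph_test(fit)['exposure']:.2f}")
```

Output:

```
signature: 221 up / 271 down (492/500 planted genes recovered)
analytic power at summary ES 0.66: 0.9915
top-ranked drug: reverser (r=-0.704, FDR=6.03e-43)
adjusted exposure HR: 0.58 (0.54-0.62), p=5.3e-46; PH test p=0.80
```

Reading the numbers: the meta-analysis with LODO recovers 98% of the planted
disease genes at FDR < 0.01 with very few extras; the 11-cohort design has
99.15% power to detect a summary effect of 0.66 at α = 0.01; the planted
reversal drug ranks first out of 781 with a strongly negative correlation;
and the Cox model, after covariate adjustment, estimates a hazard ratio of
0.58 against a simulated truth of 0.6, with no evidence against proportional
hazards.

A thin CLI mirrors the first two stages — `reposign meta`, `reposign power`,
`reposign enrich`, `reposign reposition`; see `--help` on each.

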