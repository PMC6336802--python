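# fepstrat

Symptom-based stratification and remission prediction for first-episode
psychosis (FEP) cohorts.

Early response to a first antipsychotic strongly predicts long-term outcome
in psychosis, yet one-size-fits-all predictors of remission have not held
up — plausibly because FEP patients are heterogeneous in both symptom
expression and underlying biology.  `fepstrat` implements a three-stage
analysis for cohorts with baseline PANSS symptom ratings, a serum
immune-analyte panel and standard clinical covariates:

1. **Sparse two-level clustering** of the 30 PANSS items.  The estimator
   minimizes the Frobenius reconstruction objective
   `‖Z − Y·Wᵀ‖²_F` by alternating over a one-hot label matrix `Y`
   (m patients × k clusters) and a weight matrix `W` (d items × k) with at
   most `s` nonzero rows, so each split is driven by a small, interpretable
   item subset.  Applied with k = 2 to the whole cohort and again within
   each branch, it yields four subtypes C1A/C1B/C2A/C2B ordered by symptom
   severity (with `s = d` the method reduces exactly to k-means).
2. **Serum-analyte screening**: analytes below their lower limit of
   detection (LLOD) in more than 10% of samples are excluded; the rest are
   log10-transformed (censored values at LLOD/2) and compared between a
   subtype and all other patients with two-sided Mann–Whitney tests,
   Benjamini–Hochberg FDR and pooled-SD Cohen's *d*; a 10,000-drawing
   random-subset test quantifies how surprising the subtype's count of
   elevated analytes is.
3. **Subtype-specific remission prediction** with a repeated-partition
   elastic-net ensemble.  Remission follows the RSWG consensus rule (PANSS
   P1, P2, P3, N1, N4, N6, G5, G9 all ≤ 3 after treatment).  Five-fold
   cross-validation is repeated over many random partitions; per partition
   the elastic-net hyper-parameters (α, λ) are tuned among 10 candidates by
   cross-validated AUC, and each fold fit is one "drawing".  Per variable
   the ensemble reports the selection proportion, a frequency-weighted odds
   ratio of non-remission, and a permutation p-value at the mean (α, λ);
   held-out AUC, sensitivity and specificity are averaged across drawings.

Because patient-level data of this kind are rarely shareable, the package
ships a **synthetic-cohort generator** (`fepstrat.simulate`) that draws
cohorts with the full assumed structure — latent subtypes with sparse
PANSS-item signatures, block-correlated log-normal analytes with LLOD
censoring and subtype effect sizes, realistic covariates, and a logistic
non-remission process within the high-severity subtype — so the entire
pipeline is testable end to end with known ground truth.

## Worked example

```python
from fepstrat import (SyntheticCohortConfig, generate_cohort,
                      HierarchicalKSparse, llod_filter, log_transform,
                      univariate_compare, build_features,
                      RemissionEnsemble, EnsembleConfig)
from sklearn.metrics import adjusted_rand_score

cohort = generate_cohort(SyntheticCohortConfig(seed=1))      # n = 325
hier = HierarchicalKSparse(cohort.panss, s_level1=9,
                           s_within={"C1": 8, "C2": 7}).fit(seed=0)
print(hier.summary())
print("ARI vs truth:",
      round(adjusted_rand_score(cohort.true_subtype, hier.final_labels), 3))

retained = llod_filter(cohort.analytes)                      # 35 of 43
log_table = log_transform(cohort.analytes, retained)
screen = univariate_compare(log_table, (hier.final_labels == "C1A").to_numpy())
print("elevated in C1A:", list(screen.significant_higher()))
```

prints (abridged):

```
Two-level sparse clustering
  level 1: s=9, items N1, N2, N4, N6, N7, G5, G7, G13, G16
  C1 split: s=8, items P1, P2, P3, P5, G1, G2, G6, G9
  C2 split: s=7, items P1, P3, P6, G3, G4, G11, G14
  C1A: n=92
  C1B: n=77
  C2A: n=92
  C2B: n=64
ARI vs truth: 0.914
elevated in C1A: ['IL-7', 'IL-15', 'IL-17', 'IFN-g', 'TNF-a', 'sICAM-1']
```

The level-1 split selects nine negative/general-psychopathology items, the
within-branch splits select eight and seven positive/general items, and the
pro-inflammatory signature of the most severe subtype (C1A) is largely
recovered at FDR < 0.1.  Fitting the five-variable remission ensemble
inside C1A:

```python
feats = build_features(log_table, cohort.covariates)
c1a = feats.X.index[(hier.final_labels == "C1A").to_numpy()]
y = ~cohort.remission.loc[c1a]                               # 1 = non-remitter
ens = RemissionEnsemble(feats.X.loc[c1a, ["IL-15", "CXCL12", "cmv_igg",
                                          "drug_use", "age"]],
                        y, EnsembleConfig(n_partitions=20)).fit(seed=0)
print(ens.summary())
```

reports, across 100 drawings, a held-out AUC of 0.68 ± 0.12 with IL-15
selected in 100% of drawings and a weighted odds ratio of 0.78 — lower
serum IL-15 raises the odds of non-remission in this subtype, with the
remaining four variables contributing more weakly at this sample size
(n = 92 recovered C1A patients).

There is also a CLI:

```bash
fepstrat simulate --seed 1 --out cohort/ --n-patients 325
fepstrat run-all  --seed 1 --out run/
```

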