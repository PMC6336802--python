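# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Sparse two-level clustering

Patients are clustered on their 30 baseline PANSS item scores.  Items are
z-scored first (`standardize_items`): unstandardized 1–7 scores would bias
both the Frobenius objective and the item selection toward high-variance
items.  Constant items map to zero columns; the stored center/scale is
reused verbatim when assigning new patients.

The estimator solves

    min ‖Z − Y·Wᵀ‖²_F   s.t.  Y one-hot (m × k),  ≤ s nonzero rows of W,

by alternating two exact half-steps:

* **Weight step** — given labels, the unconstrained minimizer of column j
  of W is the mean of Z over cluster j.  The objective decrease from
  retaining item i is Δᵢ = Σⱼ nⱼ·w̄ᵢⱼ², so keeping the s items with the
  largest Δᵢ (ties to the lower item index) and zeroing the rest is the
  exact minimizer over (W, S) given Y.  The hard L0 row-sparsity
  formalization was chosen because the procedure is expected to report
  exact selected-item counts per split (9 / 8 / 7 by default).
* **Label step** — each patient moves to the nearest weight column in the
  selected-item subspace (squared Euclidean distance; ties to the lowest
  cluster index), which is exact because the discarded items contribute a
  Y-independent constant.

Both half-steps are exact minimizations, so the objective is non-increasing;
this is asserted on every iteration of every fit.  Restarts use
k-means++-style seeding on the full standardized space (default 20 starts,
best objective kept, ties to the earliest start).  An emptied cluster is
repaired by moving the worst-reconstructed point into it, which cannot
increase the objective.  With s = d the procedure is standard k-means; the
test suite checks objective equality with scikit-learn's KMeans on a
separable fixture.

The two-level stratification fits k = 2 on the whole cohort and again
inside each branch, re-standardizing and re-selecting items per split.
Branch and subtype names are tied to severity so labels are reproducible
across runs: the branch with the higher mean negative-subscale score is C1,
and within each branch the cluster with the higher mean PANSS total is the
"A" subtype.  A branch with fewer than 2 patients cannot be split again and
is flagged instead.  The sparsity per split can be pinned or chosen by
`choose_sparsity`, which fits every s in a grid (default 2–15) and keeps
the one maximizing the mean silhouette computed in the **full** standardized
space — there the candidates differ only in s, so a common space is the
right yardstick — with ties resolved toward the smallest s.

New patients are assigned hierarchically: level-1 nearest centroid on the
level-1 selected items (after applying the level-1 training
standardization), then the matching level-2 solution.

## Validation

Silhouettes use Euclidean distance and are computed in the space a method
actually clusters in: the standardized selected items for the sparse
solution and the retained principal components for the PCA+k-means
comparator.  A common full-space yardstick was considered and rejected:
PCA+k-means (approximately) minimizes full-space within-cluster scatter, so
whenever the two partitions differ the full-space silhouette favors
PCA+k-means *by construction*, regardless of which partition better
recovers the generating structure — on sparse-signal fixtures it loses on
recovery (ARI) in every replicate yet wins the full-space silhouette in
most.  Singleton clusters score 0 by the usual convention.

The PCA comparator z-scores, projects onto the smallest number of leading
components explaining ≥ 80% of variance (the fraction is configurable, or a
fixed count can be given), and runs k-means with matched restarts.

Assignment stability repeats, over independent random splits (default 50
drawings, 80/20; the split fraction is a package choice, as only the number
of drawings is prescribed by the procedure being reimplemented), a
train-side hierarchical fit followed by nearest-centroid assignment of the
held-out patients.  Train-derived cluster names are mapped onto the
full-data solution's names by maximal-agreement bipartite matching
(Hungarian algorithm) computed on the *training* patients, so the held-out
agreement is measured without peeking; per-cluster accuracies are averaged
across drawings.

## Analyte screening

Analytes censored (below LLOD) in strictly more than 10% of samples are
excluded; a censored fraction of exactly 10% is retained.  Retained
analytes are analysed as log10 concentrations with censored entries imputed
at LLOD/2 (a conventional substitution; the choice only affects the ≤ 10%
censored tail of retained analytes).  Log base 10 matches the magnitude of
typical pg/mL serum panels (CRP ≈ 10⁶ pg/mL → 6.0).

Group comparisons are two-sided Mann–Whitney U tests (exact method for
small tieless samples, normal approximation with tie correction otherwise)
with Benjamini–Hochberg step-up FDR across the retained analytes and
pooled-SD Cohen's d; "elevated in the subtype" means FDR q < 0.1 with a
higher subtype mean.

The enrichment test asks how often a uniformly random patient subset of the
same size would show at least as many elevated analytes.  Because the
combined-sample ranks never change across drawings, the null is computed by
a rank-sum matrix product per batch of random subsets, with the asymptotic
(continuity-corrected, tie-corrected) p-value and a vectorized BH
adjustment per drawing; the observed count uses the same asymptotic path so
observed and null are exactly comparable.  Two tail estimates are reported:
the empirical probability with the +1 pseudocount, which is floored at
1/(n_drawings+1), and a Poisson tail fitted to the null counts, which can
resolve far smaller probabilities when the observed count lies beyond every
drawing.

## Remission prediction

Remission is the RSWG consensus rule: PANSS items P1, P2, P3, N1, N4, N6,
G5, G9 all ≤ 3 at follow-up.  The modelled outcome is **non-remission**, so
odds ratios above 1 indicate non-remitter risk.

The feature table concatenates the retained log analytes with age, sex
(male = 1), BMI, waist circumference, recreational drug use and three IgG
serostatus flags; continuous columns are z-scored (stored center/scale),
binaries are 0/1, and patients with any missing value are dropped
(complete-case).  Inside each penalised fit every column is additionally
standardized for the penalty (glmnet's internal standardization) and the
coefficients back-transformed — otherwise 0/1 binaries would be penalized
at roughly half the scale of the z-scored continuous columns.  Reported
odds ratios are therefore per SD for continuous variables and per category
for binaries.

The ensemble repeats outcome-stratified five-fold cross-validation over
independent random partitions (stratification prevents single-class folds
at subtype sample sizes near 100).  Per partition, 10 candidate (α, λ)
pairs are evaluated — α from a fixed 10-point grid on [0.05, 1], λ drawn
from a per-α log-spaced path from λ_max (the smallest penalty zeroing all
coefficients) down three decades — and the pair maximizing the mean
cross-validated AUC is kept; the winning pair's five fold fits are the
partition's drawings.  The glmnet parameterisation maps to scikit-learn's
saga solver via C = 1/(n·λ), l1_ratio = α, with the solver's internal
shuffling seeded for reproducibility.  The default is 400 partitions
(2000 drawings); analyses in this repository use 20 partitions
(100 drawings), which the tests show is enough for stable selection
proportions and AUC summaries at these sample sizes.

Summaries per variable: the selection proportion (fraction of drawings with
a nonzero coefficient); the weighted odds ratio — the mean of
exp(coefficient) over the drawings where the variable was selected, with
its SD, the selection proportion reported alongside (an alternative reading
that exponentiates proportion × mean log-OR is available behind a flag);
and a permutation p-value from a single elastic net refit at the mean
(α, λ) compared against B outcome-permuted refits with the +1 pseudocount.
Held-out performance is the per-drawing AUC and, at the probability
threshold (default 0.5; unstated in the procedure being reimplemented), the
sensitivity and specificity for predicting non-remission; a Youden-optimal
threshold is reported alongside because shrunken risk predictions rarely
cross 0.5 when the non-remission prevalence is below it.  Drawings whose
held-out fold lacks a class have the undefined quantity excluded and
counted.

## Synthetic cohorts

The generator draws, deterministically given one seed (sub-generators use
spawned sub-seeds):

* **Subtypes** — multinomial with proportions 97/62/95/71 out of 325.
* **PANSS items** — item = clip(round(subtype item mean + shared severity
  factor + item noise), 1, 7).  The per-subtype item-mean profiles are
  built additively so each clustering split's separation loads on that
  split's own informative items (9 negative/general items for C1-vs-C2,
  8 and 7 positive/general items within branches), with diffuse remainders
  keeping every subtype's subscale totals at their configured values
  (e.g. C1A positive total 24.6, negative 25.7, general 47.8).  The shared
  severity factor (SD 0.4) induces the positive inter-item correlation real
  ratings show; item noise SD is 0.8.  Only subscale summaries are
  available for calibration, so the informative-item identities are a
  modelling choice.  Clipping at the 1–7 bounds inflates the lowest
  configured means slightly (visible for the mildest subtype); the most
  severe subtype's totals are reproduced within sampling error.
* **Analytes** — log10 concentrations from block-correlated normals (one
  cytokine, one chemokine, one vascular/acute-phase block; single ρ = 0.3,
  chosen once as a realistic within-panel correlation), per-analyte means
  from the observed panel medians and SD 0.30; a subtype effect of size d
  adds d·SD to that subtype's members (nine configured effects, e.g.
  IL-15 d = 0.50 in C1A, IL-8 d = 0.58 and CXCL12 d = −0.36 in C2B).
  Eight designated low-abundance cytokines get their LLOD at their own 20th
  percentile, so they exceed the 10% censoring threshold by construction;
  all other LLODs sit 6 SD below the mean.
* **Covariates** — per-subtype normals/Bernoullis (age, BMI, waist; sex,
  drug use, three serostatus flags).  Age is untruncated even though the
  emulated trial enrolled 18–40-year-olds: truncation would shift the mean
  ~0.9 years above the configured value, and the tails are harmless here.
* **Outcomes** — every subtype has a base remission rate (0.577 / 0.548 /
  0.613 / 0.904); within C1A, P(non-remission) is logistic in five
  standardized predictors with odds ratios 0.585 (IL-15), 1.369 (CXCL12),
  1.490 (CMV), 1.393 (drug use), 0.804 (age), and the intercept solved by
  root bracketing so the marginal rate equals the base rate.  Other
  subtypes are biomarker-independent, reflecting the finding that no
  variable was associated with remission outside the most severe subtype.
  Whether such odds ratios are per SD or per raw unit is not stated
  anywhere; per-SD was chosen for compatibility with the standardized
  elastic net and is used consistently in generator and estimator.
* **Follow-up items** — drawn conditionally on a first-drawn remission
  label (remitters from a discretized normal capped at 3; non-remitters
  with at least one item forced above 3), so the remission rule holds
  exactly by construction rather than approximately.

`oracle_bayes_auc` Monte-Carlo-estimates the AUC of the *true* linear
predictor under the outcome model (unit-variance continuous predictors,
binaries at their within-subtype prevalence) — the ceiling any fitted
classifier can reach.  For the default model it is 0.682 (n_mc = 10⁶), and
the ensemble's held-out AUC approaches it within 0.05 at n = 2000.

**What the synthetic cohorts do not show.**  Real PANSS ratings have
rater effects, ordinal floor clumping and item correlations beyond one
severity factor; real analyte panels have heavier tails, plate/batch
effects and a richer correlation structure than three equicorrelated
blocks; covariates are generated independently within subtype.  Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes, at the configured effect sizes and sample sizes — not that it
would perform identically on clinical data.

## Numerical choices and edge cases

* Alternating minimization stops when labels stabilise or the objective
  decrease falls below 1e-8 (max 100 iterations); monotonicity is asserted
  with a 1e-9 slack for floating-point noise.
* All tie-breaks are deterministic (lowest item index, lowest cluster
  index, smallest s, first tuning candidate).
* Degenerate inputs: all-identical rows give a zero objective; a constant
  item standardizes to zero and can never be selected ahead of a varying
  one; an intercept cannot be solved for base rates of exactly 0 or 1 and
  raises.
* Stages derive their seeds from one master seed through a fixed-order
  SeedSequence spawn, so every pipeline artifact is bit-reproducible; the
  run manifest records seeds and SHA-256 digests of all outputs.

## Known limitations

* Elastic-net selection proportions are not a causal ranking: predictors
  strongly correlated with a large true effect can out-rank a weak true
  effect.  With ρ = 0.3 blocks and an amplified IL-15 effect, cytokines
  correlated with IL-15 carry a marginal signal comparable to the weakest
  true predictor, and both this implementation and R's glmnet then select
  them at similar or higher proportions — an inherent property of penalised
  regression under multicollinearity, documented here because the
  biomarker panels this package targets are strongly collinear.
* At subtype sample sizes near 100 the held-out AUC of even the
  correctly-specified five-variable model sits well below the generative
  ceiling, and permutation p-values for all but the strongest predictor
  are unremarkable; larger cohorts (n ≳ 1000) recover the ceiling.
* The LLOD is an input per analyte; assay-level processing (standard
  curves, plates) is out of scope.
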