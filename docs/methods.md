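# Methods

This note documents the statistical procedures implemented in `agemod`,
the modelling assumptions behind them, the synthetic-data generator that
stands in for real cohort data, and the numerical and design choices that
were genuinely open.

## Deconfounding

Confounds enter in two blocks. *Essential* confounds (default 17 columns:
age, sex, age×sex, site, head size, motion, plus generic standardized
covariates in synthetic cohorts) are used as explicit regressors. The
*nuisance* block (default 545 columns, including further age-related terms
such as age² and age×sex) is z-scored with training statistics and
compressed by PCA; the smallest number of components whose cumulative
explained variance **strictly exceeds** the threshold (default 0.85) is
retained. Z-scoring before the decomposition is a choice: the nuisance
columns are heterogeneous in units, and an unscaled PCA would be dominated
by whichever columns happen to have large variance.

Variables (IDPs and traits) are residualised on `[1 | essential | nuisance
PCs]` by per-variable OLS. The intercept is always included so training
residuals are centred. A rank-deficient design falls back to the
minimum-norm least-squares solution with a logged warning; with fewer
subjects than nuisance columns the PCA is rank-truncated, also logged.

Two fitting modes exist because the two analyses need different leakage
contracts: `full` fits the design and regressions once on all subjects
(univariate analysis, which has no train/test split), while in
cross-validated analyses everything is fitted per training fold and
applied frozen to held-out rows. Consequently held-out residuals are *not*
exactly orthogonal to held-out confounds; that is the contract, not a
defect. A control mode drops every design column whose name contains
"age" (age, age×sex, age², …) before fitting, reproducing the
no-age-deconfounding control analysis in which IDP–cognition coefficients
are dominated by shared age dependence.

Mean imputation of missing IDP entries uses training-row column means
(full-cohort means in `full` mode). Subjects with missing cognitive-trait
values are excluded rather than imputed, mirroring how the cognitive
target is defined.

## Composite cognitive target

Traits with coverage below a threshold (default 0.8 observed fraction) are
dropped; survivors can be ranked by out-of-sample elastic-net
predictability from the IDPs (Pearson r over 5 outer folds, with the same
hyperparameter grid as the prediction stage in an inner loop). The top K
(default 30) traits are z-scored (population SD) on training rows and
combined by the first principal component of their covariance. Loadings
have unit norm; the sign is fixed so the composite correlates positively
with the mean standardized trait — PC orientation is otherwise arbitrary
and a sign flip would silently invert every downstream coefficient.
Degenerate leading eigenvalues are resolved deterministically by taking
the eigenvector of the numerically largest eigenvalue of the symmetric
eigendecomposition. Screening is performed once on a designated split by
default (defining one consistent outcome variable); per-fold re-screening
is available for users wanting zero optimism at the cost of a
fold-dependent target.

## Quartile-stratified moderation test

Subjects are stratified at the empirical 25/50/75 age percentiles; ages
exactly at a cut join the lower quartile. For each IDP the model has four
quartile intercepts and four quartile-specific slopes (no global
intercept); because the design is block-diagonal over quartiles, the joint
OLS equals four independent per-quartile simple regressions — the package
keeps the explicit 8-column fit as the reference implementation and a
vectorised per-quartile engine for the permutation loop, with tests
pinning their agreement below 1e-8. IDPs are z-scored within quartile
(population SD) so slope magnitudes are comparable across quartiles;
intercepts then equal quartile means of the outcome.

The moderation statistic per quartile is T_q = b_q − mean(b_others). The
null is generated by permuting quartile labels across subjects: one shared
shuffle per replicate for *all* IDPs, so the replicate archive preserves
cross-IDP dependence (required for a valid permutation Fisher test), and
within-quartile standardisation is recomputed under the permuted labels so
the statistic is the same function of permuted data as of observed data.
P-values are two-sided on |T| with the +1 correction, p = (1 + #{|T_perm|
≥ |T_obs|})/(1 + B), hence p ∈ [1/(B+1), 1]. Two-sidedness is a choice:
sign reversals across quartiles are substantively meaningful, so both
directions count. BH FDR is applied across all IDP×quartile tests.

Ensemble enrichment per quartile: a one-sample two-sided KS test of the
p-values against Uniform(0,1) (permutation p-values live on a 1/(B+1)
grid, so the KS p is approximate; at the default B = 10,000 the
discreteness is negligible, and at B = 1000 it is still far below the KS
critical values used), Storey's π₀ at fixed λ = 0.5 (no spline
smoothing; λ exposed in config), and Fisher's statistic −2Σlog p compared
against the same statistic computed on each replicate's p-vector, with +1
correction. Replicate p-values use the self-inclusive exceedance rank
among all B replicates (p ≥ 1/B), a mildly conservative and standard
construction.

One algebraic property worth knowing: because T_q contrasts one quartile
against the mean of the rest, a slope shift of δ confined to one quartile
also shifts the other three quartiles' contrasts by −δ/3. With many
affected IDPs the ensemble statistics, which are designed to detect weak
distributed effects, can register this spillover in unaffected quartiles
as a mild enrichment. The recovery analyses therefore call a quartile
"unenriched" when π₀ ≥ 0.9 and the Fisher p stays well above the
permutation floor, while the affected quartile shows π₀ clearly below 0.9
with a Fisher p exactly at the floor.

## Cross-age generalization

The cohort is split at the median age (ties go to the young half, logged
convention). The fold plan draws, per repetition, an independent balanced
k-way partition of each half; test folds for a given (repetition, test
group) are identical across all six regimes, so per-repetition accuracies
are paired. Per fold and regime, the training set is the training portion
of the train group; pooled training draws a uniform subsample (without
replacement, seeded per fold) of both groups' training portions,
size-matched to the test group's within-group training set, so every
regime trains and evaluates on equal numbers of subjects. An optional
stratified-by-group subsampling mode is not enabled by default since
plain uniform subsampling matches the stated procedure.

All preprocessing — IDP mean imputation, confound design, deconfounding of
IDPs and traits, composite construction, feature z-scoring — is fitted on
the regime's training rows only and applied frozen to the test fold; a
bitwise leakage-guard test corrupts test-fold data and asserts every
training artifact is unchanged.

The elastic net uses the scikit-learn objective (1/2n)‖y − Xβ‖² +
α[ρ‖β‖₁ + ((1−ρ)/2)‖β‖²]. Hyperparameters are selected by inner
cross-validated MSE over α ∈ logspace(1e-3, 1e2, 13) and ρ ∈ {0, 0.1,
0.25, 0.5, 0.75, 1} with 5 inner folds, then refitted on the full training
rows; the grid and inner-fold count are configurable. Accuracy metrics:
Pearson r per test fold, Fisher-z averaged (atanh–mean–tanh, inputs
clipped at ±(1−1e-12)) to one value per repetition×regime; RMSE; and
%ΔRMSE against RMSE_null, the *population* SD of the test-fold target —
the error a mean predictor cannot reduce (population rather than sample SD
because the mean predictor is evaluated on the same fold that defines it).

Planned regime contrasts (within vs pooled, within vs across, pooled vs
across, and young- vs old-trained within each test group) use two-sided
paired Wilcoxon signed-rank tests across the matched repetitions — exact
null distribution for n ≤ 25 after dropping zero differences (Wilcoxon
convention; all-zero differences report p = 1) — with BH correction across
the planned set, and a normal-approximation 95% CI on the mean Δr.
Per-category feature importance is the mean |β| across IDPs in a category,
averaged over folds and repetitions, with relative reductions reported as
100(1 − mean_old/mean_young).

## Synthetic cohort generator

The generator emulates the *statistical structure* the analyses assume,
not the marginal distributions of real imaging data. Ages are uniform on
the configured range (default 47–83 years) so quartile cut-points are
analytically predictable in tests. A latent cognitive factor g ~ N(0,1),
independent of age, drives both traits and IDPs:

* traits: t_j = λ_j·g + a·age_z + √(1−λ_j²−a²)·ε, so the trait–factor
  correlation equals the configured loading λ_j exactly (default loadings
  spread over 0.7–0.25; age trend a = −0.3 on the z-scored age scale,
  reflecting age-related cognitive decline);
* IDPs: confound effects (a strong negative age loading, N(−0.4, 0.15²),
  plus small loadings on the other essential confounds and on the shared
  nuisance factors) + s_{q(i),j}·g + σ·ε, where s is the per-IDP,
  per-quartile slope matrix (the moderation profile) and σ = 1 by default.

The nuisance block is low-rank Gaussian (5 shared factors) with age² and
age×sex columns, so PCA retention is meaningful and age-related nuisance
terms exist for the control mode. IDP missingness is completely at random
at rate 0.0217 by default; an age-dependent mode (missingness probability
ramping with age rank at the same mean rate) is available behind a flag.
All randomness flows from one seed through named substreams (cohort,
missingness, folds, permutations, subsampling, model fits), so any stage
is reproducible in isolation.

Old-half heterogeneity is modelled by multiplying residual SDs by
`group_noise_ratio` for subjects above the median age. The configuration
accepts three targets: trait residuals, IDP residuals, or both. The
cross-age asymmetry study condition uses **both** at ratio 2: doubling
only the trait residuals lowers the old-half accuracy ceiling but leaves
old-trained coefficient *directions* essentially intact (Pearson r is
scale-invariant), which does not reproduce the empirically observed
failure of old-trained models on young subjects; adding IDP-side residual
variance — structural variance uncorrelated with cognition, the natural
model of differential atrophy and comorbidity in older brains — degrades
old-trained coefficient estimates themselves and robustly yields the full
regime ordering, the generalization asymmetry, and the higher selected
regularization for old-trained models.

### Study conditions and problem sizes

Three frozen desk-scale conditions (factories in `agemod.synthdata`) back
the tests and the acceptance script:

* `null_moderation_config`: n = 2000, 200 IDPs (category-proportional to
  the 1439-IDP composition), constant slopes 0.15, noise ratio 1 — the
  calibration condition; quartile labels are exchangeable by construction.
* `moderated_cohort_config`: n = 8000 (2000 per quartile), 200 IDPs, a
  +0.1 oldest-quartile slope increment on 30 IDPs — the recovery
  condition.
* `asymmetric_generalization_config`: n = 4000, 200 IDPs, 8 traits with
  loadings 0.45–0.2, shared slope 0.05 against unit IDP noise, noise
  ratio 2 on both targets — a deliberately weak-signal regime (within-age
  r ≈ 0.2–0.35) in which, as in real brain-cognition prediction,
  training-set noise materially limits generalization. Evaluated with
  k = 5, 10 repetitions.

The full-scale defaults (n = 25,170 subjects, 1439 IDPs, 545 nuisance
confounds, 30 traits, 10,000 permutations, 10×10-fold CV) remain the
configuration defaults; the desk-scale sizes above are the package's own
choice for routine verification, and the structural-counts check runs at
the full 1439-IDP dimensionality with a small subject count.

## Known limitations

* The generator's IDP noise is independent across IDPs given the latent
  factor and confounds; real IDPs have richer residual covariance
  (spatial, acquisition-related). Passing tests therefore demonstrate
  correctness of the statistical machinery and qualitative recoverability
  of the designed effects, not performance on real imaging data.
* A single latent factor drives all traits; real cognition is
  multi-domain, and domain-specific composites would need a factor model
  the composite stage does not implement (first PC only).
* The KS enrichment test treats permutation p-values as continuous; at
  small permutation counts the discreteness makes it conservative.
* Quartile moderation is piecewise-constant in age by design; continuous
  age-varying coefficient models are out of scope.
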