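# Methods

This note documents the statistical models, the search machinery, the
synthetic-data generator and the numerical choices behind `logicgei`, and
what the validation experiments do and do not establish.

## Exposure definitions

Three environmental exposures are derived from questionnaire-style inputs:

- **Smoking** — subjects with fewer than 100 lifetime cigarettes are
  `never`; otherwise pack-years = (cigarettes/day × years smoked) / 20,
  categorised `lt20py` (< 20) vs `ge20py` (≥ 20).
- **Alcohol** — `heavy` when long-term consumption strictly exceeds
  20 g/week (men) or 10 g/week (women). The long-term value is the mean of
  the consumptions reported 10 and 20 years prior; an aggregation rule is
  needed because two time points are collected, and the mean is the least
  committal choice. Classifying on *either* time point exceeding the
  cut-off is a defensible alternative; it would only enlarge the heavy
  category.
- **Protein** — animal/vegetable protein intake ratio, `high` when
  strictly > 1.5. A zero vegetable denominator is flagged with a warning
  and assigned `high` (the ratio is unbounded above).

Boundary conventions (strict `>` for alcohol and protein, `≥ 20`
pack-years for smoking, matching the "20 or more" phrasing of that
category) are fixed here so that categorisations are reproducible.

## Genotype encoding and missingness

Each SNP contributes a dominant (count ≥ 1) and a recessive (count = 2)
indicator on the configured minor allele; the minor allele is declared in
the pathway config, never re-estimated from the sample, so leaf labels are
stable across datasets. Missing genotypes evaluate both indicators to 0:
tree evaluation stays total during the stochastic search, at the cost of
treating a missing genotype as a non-carrier. Regression stages are
complete-case per fitted model.

## Logic-regression search

A logic model is `link(μ) = β₀ + Σⱼ βⱼ Tⱼ(x)` with `Tⱼ` Boolean trees;
links are Bernoulli-logit (risk) and exponential survival
(`log rate`, cases only). Scores are deviance / −2·log-likelihood at the
MLE. Because tree columns are binary, subjects are aggregated over unique
tree-value patterns before fitting, making the per-move fit cost
independent of cohort size.

- **Move set** (standard for logic regression): alternate-leaf,
  alternate-operator, grow-branch, prune-branch, split-leaf, delete-leaf;
  uniform over legal moves, leaf-count bounds enforced.
- **Annealing defaults**: 25 000 iterations, geometric cooling 0.999 per
  iteration, 10 restarts keeping the best visited model, start temperature
  calibrated so that ~90% of initial uphill moves are accepted (it can also
  be fixed explicitly). At temperature → 0 the sampler reduces to greedy
  hill-climbing. All runs are deterministic given their generator.
- **Size selection**: stratified K-fold cross-validation (default 10
  folds, stratified by outcome class or event indicator) over a grid of
  (number of trees, total leaves); default grid {1, 2} trees × {1..8}
  leaves; plain minimum mean validation deviance, ties toward fewer leaves
  then fewer trees. Fold membership comes from a seeded permutation, never
  contiguous slices.
- **One GST per gene**: if the selected model holds two trees, the tree
  with the larger |coefficient| becomes the GST (logged). Monomorphic
  genes, and trees that evaluate to a constant, are flagged degenerate and
  excluded downstream.
- **MLE solver**: Newton-Raphson with step-halving, convergence
  |Δloglik| < 1e-10, ≤ 100 iterations; |β| > 15 on the log scale flags
  separation/boundary estimates.

The test suite verifies the annealer against exhaustive enumeration of all
trees up to Boolean equivalence on small instances (≤ 6 columns,
≤ 3 leaves), where the global optimum is computable.

## GEI models

Candidate interactions are (gene, exposure, non-reference level) products.
A GST and its complement span the same model once main effects are present
(`comp = 1 − gst`), so each pair is fitted once and reported in the
orientation with OR_INT/HR_INT > 1 — which is why complementary trees can
appear across different exposures in the output tables. Every model keeps
GST and exposure main effects and adjusts for age, sex (2-level), race
(3-level), study center (2-level) and the Step-2 pathway trees; a pathway
tree that is collinear with the main-effect design (e.g. a single-leaf
tree duplicating a GST) is dropped as a redundant adjustment. Risk models
are logistic over all subjects; survival models are Cox regressions over
cases with the baseline hazard stratified by SEER stage (Efron tie
handling, via lifelines), eventless strata dropped. Inference is Wald
throughout; separation is flagged, not silently reported.

**Backward selection** removes exactly one term per step — the largest p,
ties broken by smaller |estimate| then term name — until all remaining
interactions have p ≤ 0.05 (configurable). If a model is unfittable, the
lowest-prevalence interaction column is dropped first (logged). Survivors
from all sub-pathways are jointly refitted in a single full-pathway model;
the significant set and its count come from that joint fit.

**Permutation correction**: each run independently permutes every GST
column and each of the three exposure columns across subjects (marginal
prevalences are preserved exactly; subject-level linkage between exposures
is intentionally destroyed, the exposures being modelled as separate
variables), re-runs all of Step 3, and records the significant-GEI count.
Empirical p = #{runs with count ≥ observed}/B, B = 1000 by default.
Counts are tallied per endpoint. The correction is valid because the
permuted columns are exchangeable with respect to the fixed outcome and
covariates under the null of no GST/exposure association.

## Synthetic cohorts

The generator's defaults are the study conditions the framework targets:
747 cases / 956 controls; the packaged 34-gene, 257-SNP angiogenesis
pathway with per-SNP MAF drawn once from [0.05, 0.5]; exposure prevalences
smoking (48.7 / 23.4 / 27.9%), alcohol (77.4 / 22.6%), protein
(35.6 / 64.4%); SEER-stage multinomial (2.7 / 52.9 / 34.1 / 8.4 / 1.9%).

- **Genotypes**: two independent haplotype draws per SNP from latent
  standard normals thresholded at the MAF quantile — Hardy-Weinberg holds
  marginally per SNP — with an equicorrelation `ld_rho` between latents
  within a gene to induce LD. `ld_rho` defaults to 0.3, a moderate
  tag-SNP-panel value; no empirical LD estimates exist for the original
  panel, so this is a stand-in, and analyses sensitive to LD should vary it.
- **Outcomes**: prospective logistic draws with planted
  `β_INT · T(x) · 1[E = level]` terms (plus optional planted main
  effects), quota-sampled until the case and control targets are met.
  Under case-control quota sampling the interaction and main-effect odds
  ratios remain interpretable; only the intercept is distorted.
- **Survival** (cases only): exponential event times with stage-specific
  baseline hazards (defaults 0.002–0.04 events/month, increasing with
  stage) times exp(planted log-HR terms); administrative censoring at the
  horizon (default 120 months; the design enforces > 60 months of
  potential follow-up, matching the cohort's guaranteed five-plus years).
- Identical seed + design ⇒ byte-identical data. The pipeline derives
  per-stage/per-gene/per-permutation streams from one master seed, so
  e.g. changing the permutation count never changes the GST search.

What the generator does **not** emulate: exposure measurement error and
recall bias, frequency matching of controls on age/sex, population
stratification, haplotype-block LD structure (only equicorrelation), and
informative censoring. Passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed model, not robustness to
those real-data features.

## Validation experiments and problem sizes

The acceptance script and test suite use reduced search budgets chosen so
each experiment answers its question at Monte-Carlo precision:

- Annealing vs enumeration: 4 columns, ≤ 3 leaves, n = 500, 1200
  iterations × 2 restarts, 20 seeded runs.
- CI coverage of a planted OR_INT = 2.0: full pipeline (GST search with a
  single-leaf grid, 200 iterations, then the adjusted interaction model)
  at n = 1703, 200 replicates in the script (60 in the test, with a
  three-binomial-SE acceptance band). The recovered tree is aligned to the
  planted truth (complement orientation flips the coefficient's sign, not
  its information).
- Null calibration: 40–50 fully null cohorts at n = 1703, 6 genes, ~24
  candidate terms each; per-term Wald rejection at p ≤ 0.05 compared with
  the nominal 5% within three binomial standard errors.
- Permutation validity: fully null cohorts; the empirical p must not be
  anti-conservative (checked against uniform bounds, and by comparing the
  permutation-count distribution with observed counts across null
  replicates).

## Known limitations

- The exponential survival score used in Steps 1–2 assumes constant
  hazards; Step 3 relaxes this to the semiparametric stratified Cox model,
  but tree selection under gross non-exponentiality may be suboptimal.
- Backward selection p-values are not adjusted for selection; that is the
  permutation correction's job, and per-term CIs from the joint model
  retain mild selection optimism.
- One GST per gene discards within-gene heterogeneity beyond a single
  Boolean pattern; the cap of 2 trees / 8 leaves bounds expressiveness.
- The annealer is stochastic: on large genes a too-small budget returns a
  locally optimal GST. The enumeration oracle only certifies small
  instances.
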