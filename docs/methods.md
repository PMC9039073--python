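# Methods

## Scope and data model

`lipidrank` implements a hierarchical machine-learning workflow for finding
lipid classes and individual lipid species whose serum concentrations
discriminate cases from controls in a small case-control cohort. The
canonical design it targets is a panel of 530 lipid species in 34 classes
measured on 52 subjects (22 cases, 30 controls), with age and sex as
covariates, but every dimension is a parameter.

Concentrations live in a subjects × features matrix on the linear scale;
missing cells (undetectable peaks) are NaN and are excluded from every
statistic unless explicitly imputed. A species→class taxonomy maps dotted
species names (`PC.38.5` = glycerophosphatidylcholine with 38 carbons and 5
double bonds) to class symbols (`PC`, `TG`, `Cer`, …).

**Class concentrations are sums of member-species concentrations.** Summing
is the standard lipidomics convention and preserves mass: per subject the
class totals equal the species totals, a property the test suite checks.
The alternative (independently integrated class totals) is not supported.

**Missing-data policy.** Features missing in more than `drop_frac` (default
0.2) of subjects are dropped; a feature missing everywhere is always
dropped. Remaining missing cells are imputed as half the feature's observed
minimum — the usual stand-in for below-detection-limit abundances — or left
missing with `impute="none"`. Both knobs are configurable because the
appropriate policy depends on the instrument and panel.

## Synthetic cohorts

Real serum lipidomics data for this design are not publicly deposited, so
the generator is a first-class module: it defines the study conditions
under which every downstream stage is validated.

Species concentrations are log-normal:

    log x_ij = b_class(j) + b_species(j) + case_i · (d_class(j) + d_species(j)) + e_ij,
    e_ij ~ N(0, noise_sd²)

with class baselines ~ N(2, 1), species baselines ~ N(0, 0.5), and additive
case-vs-control effects `d` on the natural-log scale whose sign is the
direction of effect. Defaults: 22 cases vs 30 controls; `noise_sd = 1.0`
(log-scale biological + analytical spread of roughly e^±1, typical for
serum lipid species); ages ~ N(51, 12) truncated to [30, 85] and sex drawn
Bernoulli per group (55% female cases, 67% female controls), matching the
demographics of a mid-life familial-parkinsonism cohort; optional uniform
`missing_rate` emulates sporadic undetectable species.

The default 530-species taxonomy is a fixed fixture: the ten headline
classes (PC 60, TG 40, Cer 20, DG 15, MhCer 12, NAPE 10, NAPS 7, GB3 5,
BMP 4, LPS 3) jointly hold 176 species; the remaining 354 species are spread
over 24 further common lipid classes. Per-class species counts are declared,
not estimated — no public per-class breakdown exists for the real panel.

`simulate_raw_peaks` adds a per-sample latent technical factor ~
N(0, drift_sd) with unit loading to every log-peak and to each internal
standard (IS), plus N(0, 0.05) measurement noise, producing the input
fixture for normalization.

What the generator does *not* emulate: correlated species within a class
beyond the shared class baseline, heavy-tailed or heteroscedastic noise,
batch structure, censoring-at-threshold missingness (missingness is
uniform), and covariate–lipid dependence (age and sex are independent of
concentrations under the null). Passing tests therefore demonstrate
correctness of the machinery and calibration under this model, not
performance on real sera.

## NOMIS normalization

Each centered log-peak is regressed on the centered log-intensities of an
IS subset; the normalized log-value subtracts the fitted IS component, and
output is exponentiated back to the linear scale. The subset is chosen by
exhaustive search over all combinations of the usable (non-constant)
standards up to `max_subset` (default 5), minimizing the mean leave-one-out
squared residual pooled over features. LOO residuals come from the hat
matrix (`e/(1-h)`), so the criterion is an honest out-of-sample estimate
rather than in-sample fit.

The candidate set deliberately includes the **empty subset** (centering
only). Without it, data with no technical drift would still receive a
regression on noise-only standards; with it, normalization reduces to the
identity exactly when the standards carry no shared variance, which the
acceptance suite verifies. Samples lacking an IS measurement have all their
features flagged missing; missing raw entries stay missing.

## Monte-Carlo cross-validation and ranking

Repeated random subsampling without replacement: per repetition,
`round(0.2·n)` subjects (10 of 52) are held out for testing; the training
set is split again 80:20 into inner-train and validation for
hyperparameter tuning. Repetition r uses generator seed `seed + r`, so a
plan is reproducible rep-for-rep. Splits are **stratified by group by
default** (largest-remainder apportionment: 4 cases + 6 controls per test
set at 22/30); unstratified literal random sampling is available but risks
single-class sets at this n. Every one of the four index sets must contain
both groups.

The classifier is a random forest. The default tuning grid is trees
{200, 500} × features-per-split {√p, p/3} × min-leaf {1, 5}; tuning
maximizes validation AUC (ties: accuracy, then grid order), and the chosen
configuration is refit on the full outer-training set. Metrics use the case
group as positive class: accuracy/TPR/TNR at a 0.5 probability threshold,
and AUC by the rank (Mann–Whitney) formulation with ties counted ½ — an
independent brute-force pair-counting oracle backs this in the tests.

Variable importance is mean decrease in impurity, normalized to sum to one
within each repetition and averaged over repetitions; the ranking includes
the covariates, so the class-level table has 36 rows (34 classes + age +
sex). Ties in mean importance break by mean rank, then name.

## Hierarchical selection

*Stage 1 (classes).* All classes plus covariates are ranked; for each
fraction in the scan grid (default 0.1–1.0 in steps of 0.1) the classifier
is re-evaluated on the top `round(fraction·34)` classes (+ covariates), and
the fraction with the best mean AUC wins. Rounding is half-away-from-zero
(30% of 34 → 10). The full scan table is reported so any other criterion
can be applied in post-hoc audit. "Best" = mean AUC, with ties resolved
toward the smaller feature set; AUC is the natural single-number choice for
an imbalanced 22/30 design and is threshold-free.

*Stage 2 (species).* Method 1 ranks all 530 species and scans top-k models
(k default 5–25, each model = k species + age + sex). Method 2 first
restricts candidates to species of the stage-1 winning classes (176 in the
default panel when the ten headline classes win) and then proceeds
identically; its pool is always a subset of method 1's. Stage-2 scans use
fresh split plans with seeds derived from the run seed (`seed+10000`,
`seed+20000`) so the three scans are mutually independent but jointly
reproducible.

## Statistical validation

- **Welch t test** (unequal variances, Satterthwaite df) per selected
  feature, two-tailed, with a symmetric 95% CI for the mean difference.
  All differences and CIs use the **case − control** convention.
- **Bonferroni**: per-family threshold α/m, reported to two significant
  digits (0.05/17 → 0.0029; 0.05/34 → 0.0015); families are the tested
  feature sets, as configured.
- **Univariate logistic** per feature with Wald p; monotone perfect
  separation is detected analytically and flagged instead of reporting a
  divergent estimate.
- **Sequential multivariate logistic** selection: SFS, SBS and SFFS driven
  by likelihood-ratio p-values (enter 0.05 / remove 0.10; LR rather than
  Wald because it is stable at n ≈ 52). SFFS floats after each addition,
  re-testing included features. Ties break by candidate order; every step
  is logged with its log-likelihoods so decisions replay exactly. When a
  fit is separated or singular, a near-unpenalized ridge logistic
  (C = 10⁴) supplies the log-likelihood so steps remain well-defined.
  A feature's "multivariate significant" flag is membership in the union
  of the three methods' selections.
- **Direction of effect**: one joint ridge-penalized logistic fit on the
  standardized (zero-mean, unit-variance) selected features; direction is
  the coefficient sign, with the penalty chosen by 5-fold cross-validated
  deviance when not supplied. An exactly-zero coefficient is reported as
  indeterminate, never silently signed. A linear ridge variant is offered
  behind a flag. Note that a joint-model sign can legitimately disagree
  with the marginal mean difference under collinearity.

## Reporting and determinism

`run_pipeline` executes missing-data policy → aggregation → stage 1 →
both stage-2 methods → validation, and writes metrics JSON, ranked tables
(rank, feature, direction, class/class-direction at species level, 95% CI,
p, significance flags), scan tables and a run log. Every random element is
seeded from the single run seed; reports are byte-identical across
repeated runs of the same configuration (the logged config omits the
output-directory path for that reason). Rendered tables are assembled from
stored intermediates, never recomputed at render time.

## Study sizes used in the shipped test battery

The simulation studies in the test-suite and acceptance script use a single
100-tree forest configuration and moderate repetition counts (25 MCCV reps
for class-level scans, 15 for species-level, 20 seeded cohorts for
calibration/recovery studies, 10 for the summary script): sizes chosen so
the full battery runs on one CPU in minutes while keeping Monte-Carlo
standard errors well inside the asserted margins. The margins quoted with
each check account for the noise at these sizes.

## Known limitations

- Null cohorts at n = 52 carry real finite-sample group differences, so a
  single cohort's mean AUC can sit 0.1 or more from 0.5 even under the
  null; chance-level calibration is a statement about the average over
  cohorts.
- Sequential selection is greedy; SFFS agrees with exhaustive best-subset
  search on the constructed instances tested, but carries no global
  optimality guarantee.
- Impurity-based importances are biased toward high-cardinality/continuous
  features; here all lipid features are continuous, and permutation
  importance is available as an option.
- NOMIS assumes log-linear IS–peak relationships with sample-level factors;
  feature-specific drift loadings are generated with unit loading and the
  model fits per-feature slopes, but nonlinear drift is out of scope.
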