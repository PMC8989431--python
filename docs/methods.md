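# Methods

## The model

Disease risk is modelled per variant with two logistic regressions. The
*marginal* model

    logit P(y_i = 1) = α + β^M_G g_ij + β_E e_i + β_C c_i

gives the classical GWAS per-allele effect `β^M_G` used to weight a
traditional polygenic risk score,

    PRS_i = Σ_j β^M_G(j) · g_ij .

The *interaction* model adds a per-variant gene–environment product term,

    logit P(y_i = 1) = α + β^M_G g_ij + β_E e_i + β^I_{G×E} g_ij e_i + β_C c_i ,

where `β^M_G` is now the main effect at exposure 0 and `β^I_{G×E}` the
per-variant G×E interaction. The interaction PRS carries both:

    iPRS_i = Σ_j β^M_G(j) · g_ij + Σ_j β^I_{G×E}(j) · g_ij e_i .

All weights are expressed on the risk-allele scale before scoring: a variant
with a negative main weight has its counted allele swapped (`g → 2 − g`) and
both weights negated, so main weights are non-negative. The flip set is
defined by the sign of the estimated main weight (a zero weight counts as
already risk-oriented) and is applied identically to every sample that is
ever scored with that weight set.

Risk prediction is two-stage: the scores enter a second logistic regression
refit on the training data,

    prs_model :  logit P(y=1) = b0 + b1·PRS + b2·PRS·E + b3·E
    iprs_model:  logit P(y=1) = b0 + b1·iPRS + b2·E .

The score-level equations are sometimes written without coefficients; we
treat them as regressions with a free intercept and free coefficients,
the standard practice when a score is transported to a prediction model.
The contrast between the two models is the point: `prs_model` can only
modulate the whole score by exposure through one global product term, while
`iprs_model` already carries exposure modulation per variant inside the
score.

## Why the iPRS can win

Marginal weights average each variant's effect over exposure strata. When a
variant's interaction opposes its main effect (*antagonistic*), that average
understates the effect in the unexposed and overstates it in the exposed; a
set of such variants cannot be repaired by one global PRS×E coefficient.
The interaction-model weights separate the two components per variant, so
the iPRS prediction model dominates most clearly under antagonism, less so
when all interactions are synergistic (a roughly proportional amplification
that the global PRS×E term can partly mimic). The simulation studies below
reproduce exactly this ordering.

## Association scans

Per-variant fits are maximum-likelihood logistic regressions with Wald
standard errors and two-sided normal p-values. The genome scan vectorizes
Newton–Raphson across variants: with a binary exposure and no covariates,
every entry of each variant's 3×3 or 4×4 information matrix is a pair of
per-stratum weighted column sums, so one iteration over a block of variants
costs a handful of elementwise passes. Iterations run in float32 to a step
tolerance of 1e-4, followed by one float64 Newton polish step and a float64
Hessian for the standard errors; the result matches per-variant statsmodels
fits to ~1e-7, which the test suite verifies on every run. Scans with
covariates or a non-binary exposure fall back to per-variant statsmodels
fits.

Degenerate variants (monomorphic after imputation, or without variation in
the exposed stratum when an interaction is requested) and separated fits are
flagged non-converged, carry NaN estimates, and are never selected. Missing
dosages are mean-imputed per variant before fitting and scoring. Variant
selection keeps variants with `min(p_main, p_interaction)` (or `p_main`
alone) below a fixed threshold, default 5×10⁻⁶; no further multiplicity
correction is applied.

## Quality control

Samples with call rate below 95% are removed first; then variants failing
MAF < 0.01, the conditional exact Hardy–Weinberg test at p < 10⁻⁶ (computed
on all retained samples), missingness > 5%, or duplication (same id, or same
chromosome/position/allele pair) are removed, each attributed to the first
failing rule in that order. LD-based pruning of related variants is out of
scope and not implemented.

## Synthetic data

Genotypes are independent biallelic dosages `Binomial(2, MAF_j)` with
`MAF_j ~ Uniform` over a configurable range; the exposure is
`Bernoulli(0.5)`. No linkage disequilibrium, population structure or
missingness is generated, so passing simulation tests demonstrates the
statistical machinery, not robustness to the correlation structure of real
genotype panels.

**Sparse design.** Ten SNPs stand in for a GWAS-significant panel: six carry
main effects, four of those interact with the exposure. Scenario
`all_antagonistic` sets every interaction sign opposite its SNP's main
effect, `all_synergistic` the same sign, `half_half` two and two. Magnitudes
default to |β^M| = |β^I| = β_E = log 1.5 — a canonical moderate odds ratio
of 1.5 per allele — with a baseline intercept α = logit(0.1) (a ~10%
population prevalence typical of the screening-cohort setting). Outcomes are
drawn from the logistic model and individuals are quota-sampled until
exactly 1,000 cases and 1,000 controls accumulate (configurable; excess
draws discarded; a draw budget guards against an intercept that makes one
class unreachably rare). A variant design allows interacting SNPs without
main effects; for those, "antagonistic" means a negative interaction
coefficient relative to the nominal positive risk direction.

**Polygenic design.** Of `m` variants (default 40,000), 1% are causal with
effects drawn from `N(0, h²/n_causal)`, `h² = 0.3`, so the genetic linear
predictor carries a variance budget of `h² · E[2p(1−p)] ≈ 0.11`. A fraction
of 10⁻⁴ of variants (4 at the default `m`) additionally interact with the
exposure, 70% antagonistically. Because so few variants interact, each
interaction must be individually substantial to matter at all; the default
magnitude is fixed at |β^I| = log 1.5 with the sign set by the antagonism
rule (drawing interaction magnitudes from the same `N(0, h²/n_causal)` pool
as the main effects would make the interacting set statistically invisible,
defeating the design's purpose). The exposure effect defaults to log 1.5.
Samples are a population draw (no quota).

Every dataset carries a truth record (per-variant effects, MAFs, intercept,
exposure effect) sufficient to recompute each sample's exact outcome
probability, and can be exported as a PLINK 1 triplet plus phenotype table.

## Study evaluation protocol

`run_simulation_study` generates, analyses and evaluates replicate datasets,
then averages the metric battery. Two protocol details are design-dependent:

* **Sparse design: in-sample evaluation.** Each replicate is one simulated
  study: the panel is assumed pre-identified (no p-value selection), weights
  are estimated on the full replicate, and both prediction models are fit
  and evaluated on it. With 10 SNPs (≤ 24 fitted parameters) at n = 2,000
  the optimism is small and identical machinery sees both models.
* **Polygenic design: held-out evaluation, recalibrated second stage.**
  Weights for all variants (no selection, following the polygenic assumption
  that all variants contribute) are estimated on a stratified half of each
  replicate and the scores are evaluated on the other half. With far more
  variants than samples, the training-half score quasi-separates the
  training outcomes, so the 3–4 coefficient second stage is refit on the
  evaluation half; this recalibration leaks no per-variant weight and leaves
  the score's ranking untouched.

The real-data path (`cross_validate`, CLI `fit-evaluate`) instead runs the
full leakage-free pipeline — scan, selection at 5×10⁻⁶, flip, weights,
scores, second stage — inside each training fold of a stratified k-fold
split (default k = 5, seeded), with a `whole_sample_weights` flag
reproducing the alternative protocol in which only the second stage is
cross-validated.

## Evaluation metrics

* **AUC** via the Mann–Whitney identity, ties counting one half, so the
  DeLong machinery and the point estimate agree exactly.
* **DeLong's test** for paired ROC curves from the covariance of per-case
  and per-control placement values; identical predictions are flagged
  degenerate with p = 1. Cross-checked in the tests against R's pROC.
* **Risk stratification** cuts predicted risk at its empirical 5th and 95th
  percentiles (linear-interpolation quantiles; ties fall to the lower
  group): bottom 5% low risk, top 5% high risk. Prevalence per group is
  compared across the two models by a Pearson chi-square on the 2-model ×
  3-group case-count table. The two stratifications come from the same
  samples; the test ignores that pairing, as in common practice — an
  anti-conservative caveat documented here deliberately.
* **Brier score** with a seeded 2,000-replicate percentile bootstrap 95% CI.
* **Calibration curve** over 10 quantile bins (merged when prediction ties
  collapse edges).
* **Spiegelhalter's z** with the convention z = 0 when every prediction is
  exactly one half, and **Cox recalibration** (logistic regression of
  outcomes on the logit of predicted risk; slope 1 / intercept 0 is perfect
  calibration).

## Numerical and reproducibility choices

All randomness flows from one integer seed through `numpy` seed sequences;
each study replicate spawns a child stream and is reproducible in isolation
(the CLI `study` command resumes interrupted runs replicate-by-replicate).
Second-stage fits reject separation rather than report unstable
coefficients. Predicted probabilities are clipped to the open unit interval
at 1e-12 before calibration metrics. CLI runs write a manifest (resolved
configuration, seed, input digests, package version) beside their outputs.

## Problem sizes

The bundled studies run at desk scale, chosen so the full battery completes
on one CPU: the sparse study uses 100 replicates per scenario of 1,000 cases
and 1,000 controls; the polygenic study uses 20 replicates of n = 5,000
individuals × m = 40,000 variants (the acceptance script) and reduced grids
in the test suite. A cohort-scale version of the polygenic design —
~14,000 individuals × ~440,000 real chromosome-1 genotypes, 100
replicates — differs only in runtime, not code paths.

## Known limitations

* Synthetic genotypes are LD-free and unstructured; selection thresholds
  tuned for correlated panels behave differently here.
* Under the stated polygenic generator (h² = 0.3 split over 1% of
  variants), even an oracle scoring with the true effects attains a test
  AUC of only ≈ 0.6: the genetic linear predictor's standard deviation is
  ≈ 0.33, and with estimated weights over 40,000 variants the estimation
  noise dominates the score. The absolute AUC levels this package reports
  for the polygenic design are therefore modest; the design still exercises
  the full pipeline end to end.
* The G×E interaction is a binary-exposure product term; continuous
  exposures are accepted by the scoring and prediction modules but not by
  the generators.
* `prevalence_chisq` ignores the pairing of the two models' stratifications
  (see above).
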