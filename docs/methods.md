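# Methods

## The design

`mrphewas` implements a sex-specific drug-target Mendelian-randomization
(MR) phenome-wide scan over GWAS summary statistics. Genetic variants in or
near a drug-target gene proxy lifelong pharmacological modulation of the
target (e.g. HMGCR inhibition by statins); their associations with an
exposure (LDL-c in SD units) and with each phenotype in each sex stratum
(`both`, `men`, `women`) are combined into causal-effect estimates, scanned
across a filtered phenome, and compared between sexes.

All estimators work on the two-sample summary-statistic model: for variant
j, the observed outcome association is

    beta_out_j = theta * beta_exp_j + alpha_j + eps_j

with `theta` the causal effect per exposure unit, `alpha_j` a pleiotropic
(direct) effect, and `eps_j` sampling noise with known standard error.
Exposure associations `beta_exp_j` are treated as fixed (conditioned-on),
the usual strong-instrument two-sample convention; Wald-ratio standard
errors therefore carry only the outcome uncertainty (first-order delta
method, `se_out / |beta_exp|`).

## Estimators

* **Wald ratio** (J = 1): `beta_out / beta_exp`.
* **IVW** (J >= 2): generalized least squares of outcome betas on exposure
  betas through the origin, with covariance `Omega_ij = se_i se_j rho_ij`
  from the instrument LD correlation matrix (identity when absent). With
  multiplicative random effects (used at J >= 3) the standard error is
  inflated by `sqrt(phi)`, `phi = max(1, Q/(J-1))`, where Q is the residual
  GLS sum of squares. The floor at 1 means heterogeneity can widen but
  never narrow intervals. At J = 2 a fixed-effect fit is reported and
  labelled as such.
* **MR-Egger** (J >= 3): the same weighted regression with an intercept,
  after orienting each pair so the exposure beta is positive. The intercept
  estimates mean directional pleiotropy; its two-sided test is the
  exclusion-restriction diagnostic. `phi = max(1, Q/(J-2))`. When a
  correlation matrix is present the same Omega is used — an extension
  beyond the independent-instrument formulation, visible in the output.
* **Multivariable MR**: outcome betas regressed jointly on E exposure-beta
  columns without intercept, weights `1/se_out^2`; separates direct
  effects. All-zero exposure columns carry no signal and are excluded from
  the fit (reported with effect 0, infinite SE); collinear non-zero columns
  are a hard error naming the offending pair.
* **Odds-ratio conversion**: binary traits analysed by linear regression
  are converted for presentation via `log OR = beta / (k(1-k))` at case
  fraction k, SEs scaled identically. Significance is always assessed on
  the linear scale; the conversion has a known O(beta^2) approximation
  error, negligible at phenome-scan effect sizes.

P-values and confidence intervals use standard-normal quantiles throughout
(one convention, documented here; Student-t would be defensible for Egger
at small J but is not the default).

## Phenome orchestration

Manifest filtering applies, in a fixed order with first-match reason codes:
duplicates (keep first), binary traits with fewer than 100 cases,
quantitative traits with n < 10,000 (both bounds strict "less than"),
ICD-coded traits lacking a main code or coded in the excluded external-cause
range (default Z00–Z99), and excluded subcategories (a configurable list).
The order affects only the recorded reason, not the kept set. Np is the
kept count; the family-wise threshold is `alpha / Np` (0.05/1701 = 2.9e-5
at the published phenome size), reported at full precision and at 2
significant figures.

Effects are reported on the anchor-relative scale: each estimate divided by
the absolute value of the same target's LDL-c effect in the same stratum,
so the anchor row itself is sign(beta_anchor) × 1. Sex differences use the
two-sided z-test `z = (b_m - b_w)/sqrt(se_m^2 + se_w^2)` on *unscaled*
estimates (the scaled columns have no usable SE); the same contract serves
primary-versus-replication comparison. Sex-difference p-values are reported
raw, alongside the Bonferroni-gated main associations.

## Harmonization and pruning

Outcome associations are expressed for the exposure's effect allele: label
swaps negate the beta and flip the allele frequency; strand complements are
resolved before the swap rule. Palindromic variants (A/T, C/G) are kept
only when both allele frequencies fall outside 0.5 ± w (default w = 0.08)
on the same side; otherwise the variant is dropped with a reason code. LD
pruning is greedy in ascending exposure p-value order (lexicographic
variant-id tie-break): a variant is kept iff its r² with every kept variant
is below the threshold (default 0.01). `se_from_beta_p` recovers standard
errors from printed beta/p pairs via the normal quantile, computed in log
space (`ndtri_exp`) so table values down to p ≈ 1e-324 are usable.

## The synthetic phenome

The generator emulates the statistical structure the estimators assume, not
real biology:

* Instrument panels: allele frequencies U(0.1, 0.9); per-allele exposure
  effects with magnitude U(0.6, 1.4) × 0.06 SD and random sign; exposure
  SEs `1/sqrt(2 p (1-p) n_exp)` with n_exp = 300,000. Panels are fixed by
  their seed and shared across strata and replicates.
* Outcome SEs follow the same formula at UK-Biobank-like stratum sizes
  (360k both, 167k men, 194k women); binary traits are scaled by
  `sqrt(k(1-k))` (default case fraction k = 0.1) and emitted on the
  linear-probability scale with `theta_linear = logOR * k(1-k)`.
* Noise is correlated within declared LD blocks (Cholesky of the block
  correlation matrix); the block matrix is emitted as the instrument
  correlation.
* Directional pleiotropy `alpha ~ N(mu_a, sigma_a^2)` is drawn **relative
  to the exposure-increasing allele** (multiplied by sign(beta_exp)). This
  is the convention under which the Egger intercept equals mu_a; pleiotropy
  drawn in raw allele orientation averages out under Egger's positive-
  exposure orientation and is indistinguishable from balanced pleiotropy.
* Three default instrument regimes mirror how a lipid target is proxied:
  J = 1 (a single lead variant), J = 6 within one gene region (rho = 0.5),
  and J = 56 independent score variants.

The phenome fixture plants an LDL-c anchor (theta = -1 in every stratum,
the exposure-lowering convention), signals with |anchor-scaled effect| >=
0.5, one women-only trait (theta_women = -0.25, theta_men = 0) exercising
the sex-difference test, nulls across binary/ordered/continuous types and
several categories, and six manifest rows engineered to trip each exclusion
rule exactly once.

Calibration of the women-only effect was done analytically before any
empirical run: with per-stratum IVW SE `1/sqrt(sum (beta_exp_j/se_out_j)^2)`,
a difference of 0.25 needs combined SE ≲ 0.09 for 80% power at alpha =
0.05; the default panel (J = 56, scale 0.06, stratum sizes above) gives
combined SE ≈ 0.014, so the test is comfortably powered even at J = 1. The
directional-pleiotropy scenario (mu_a = 0.015, sigma_a = 0.005) was chosen
the same way to put the Egger intercept test above 80% power at J = 56.

What the generator does **not** emulate: realistic allele-frequency spectra
and LD beyond equicorrelated blocks, winner's-curse selection of
instruments, sample overlap between exposure and outcome GWAS, non-normal
effect-size distributions, or errors-in-variables in the exposure betas.
Passing tests therefore show the estimators are correct under the stated
model, not that real-data violations of it are handled.

## Numerical choices

* Normal quantile z = 1.959964 for all 95% intervals; p-values via `ndtr`
  and, for the -log10 p column, via `log_ndtr` so underflowed p-values keep
  their tail mass.
* Omega is factorized by Cholesky; condition numbers above 1e8 are a hard
  error naming the most-correlated variant pair (no silent ridging).
* Ties in pruning order break lexicographically on variant id; output
  order is the greedy kept order.
* Serialized tables use tabs, period decimals, "NA", `%.6g` floats and 3
  significant digits for p-values; the -log10 p column preserves precision
  below 1e-300. Re-running with identical inputs, config and seed is
  byte-identical (run hashes exclude timestamps).

## Problem sizes used in the checks

Parameter recovery and Egger calibration use 1000 replicates at J = 56;
Egger power 500 replicates; the global-null family-wise-error suite scans a
100-phenotype single-stratum phenome 1000 times at J = 1; the odds-ratio
check fits logistic regressions to 20 independent replicates of n = 200,000
individuals at k ∈ {0.1, 0.3, 0.5}. The whole suite runs in well under a
minute on one CPU.

## Known limitations

* Wald/IVW standard errors ignore exposure-side uncertainty by design;
  with weak instruments this understates uncertainty (no weak-instrument
  diagnostics such as conditional F are provided).
* No weighted-median, mode-based, MR-PRESSO or Steiger estimators.
* The correlated-Egger path shares IVW's Omega and should be read as an
  extension, not a validated published estimator.
* The phenome category mapping is a plain user-supplied table; no ontology
  resolution or manual curation of subcategories is reproduced.
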