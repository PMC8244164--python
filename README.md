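# mrphewas

Sex-specific drug-target Mendelian randomization (MR), scanned across a
phenome of GWAS summary statistics.

Variants in a drug-target gene (e.g. *HMGCR* for statins, *PCSK9* for PCSK9
inhibitors, *NPC1L1* for ezetimibe) act as lifelong proxies for
pharmacological modulation of the target. Regressing their per-allele
associations with thousands of phenotypes — separately in men and women —
on their associations with the exposure (LDL-c) yields causal-effect
estimates for every trait, and a z-test on the sex-stratified estimates
asks which effects differ between men and women. This package is for
genetic epidemiologists who want that whole pipeline — harmonization,
estimation, phenome filtering, multiplicity control, sex contrasts — as
tested, scriptable components, exercised end-to-end on synthetic summary
statistics with known ground truth.

## The statistics

For harmonized variant j with exposure association β̂_Xj and outcome
association β̂_Yj (SE σ_j):

* Wald ratio (J = 1): θ̂ = β̂_Yj / β̂_Xj, SE σ_j/|β̂_Xj|.
* IVW with correlated instruments: generalized least squares through the
  origin, Ω_ij = σ_i σ_j ρ_ij from the LD correlation matrix,

      θ̂ = (XᵀΩ⁻¹X)⁻¹ XᵀΩ⁻¹Y,   Q = (Y − Xθ̂)ᵀΩ⁻¹(Y − Xθ̂),

  with multiplicative random effects se(θ̂) = √(φ (XᵀΩ⁻¹X)⁻¹),
  φ = max(1, Q/(J−1)), applied when J ≥ 3.
* MR-Egger: the same regression with an intercept α₀ after orienting
  exposure betas positive; α₀ ≠ 0 indicates directional pleiotropy and the
  slope is the pleiotropy-robust estimate (φ = max(1, Q/(J−2))).
* Multivariable MR: Y regressed on several exposures' betas jointly,
  weights 1/σ², separating direct effects.
* Binary traits fitted by linear regression are presented as odds ratios
  via log OR = β/(k(1−k)) at case fraction k.
* Phenome control: Bonferroni at α/Np over the Np phenotypes passing the
  inclusion rules (≥ 100 cases for binary traits, n ≥ 10,000 for
  quantitative ones, main-ICD and external-cause rules, de-duplication).
* Sex differences: z = (β̂_m − β̂_w)/√(se_m² + se_w²), two-sided.

Effects are reported relative to the same instrument's LDL-c effect
(anchor scaling), so the LDL-c row is ±1.00 by construction.

## Worked example

```
$ phewas simulate --out fx --seed 5
wrote fixture: 56 manifest rows, 150 sumstat files, 7 non-null phenotypes

$ phewas run --manifest fx/manifest.tsv --sumstats-dir fx/sumstats \
    --instruments fx/instruments.tsv --target-label HMGCR-statins \
    --config fx/config.yaml --out results.tsv
tested 50 phenotypes at P < 1.0e-03; 8 significant phenotype(s), 21 significant row(s); 0 skipped

$ phewas threshold --np 1701
2.9e-05
```

The simulated phenome has 56 manifest rows of which 6 are engineered to be
excluded (one per filter rule), leaving Np = 50 and a Bonferroni threshold
of 0.05/50 = 1.0e-3. The scan recovers the planted anchor (LDL-c, true
scaled effect −1.00 in every stratum), the five planted signals and the
women-only trait; with 150 tests at this threshold a single null false
positive, as here, appears in a few percent of runs. `phewas threshold`
reproduces the published-phenome threshold 0.05/1701 = 2.9 × 10⁻⁵. The
results TSV carries, per target × phenotype × stratum: method, β, SE, CI,
p, −log₁₀p, dispersion φ, heterogeneity Q, odds ratios for binary traits,
anchor-scaled β, the significance flag, and the sex-difference z and p.

The numbered scripts under `analysis/` run the full narrative on three
instrument regimes (lead SNP, 6 correlated region variants, 56-variant
score): `01_simulate_phenome.py`, `02_run_phewas.py`,
`03_sex_differences.py` (the planted women-only trait is the top
sex-difference hit in every regime), `04_sensitivity.py` (lead-SNP vs
correlated-IVW agreement, MR-Egger intercepts, multivariable MR). Their
tables land in `results/`.

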