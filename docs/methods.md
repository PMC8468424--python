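# Methods

## Score definition and allele orientation

The polygenic risk score is the additive log-odds score
PRS<sub>i</sub> = Σ<sub>k</sub> β<sub>k</sub>x<sub>ik</sub> over the 15-SNP
panel, with β<sub>k</sub> = ln(published per-allele OR) and x<sub>ik</sub> the
count of the published minor allele. Two conventions are enforced at the data
layer rather than left to the analyst:

- **Orientation is publication-anchored.** The panel stores the published
  effect-allele frequency, constrained to (0, 0.5], so "minor allele" always
  means the published minor allele. A cohort in which that allele happens to
  be the *major* allele (this occurs for one panel SNP) still uses the same
  weight on the same allele; genotype readers flip dosages (d → 2 − d) when a
  file counts the opposite allele, and record the flip.
- **Betas are computed, not stored.** The panel fixture stores odds ratios at
  their printed precision; ln() is taken at load time to avoid double
  rounding.

Missing dosages are handled by policy at scoring time (`expected_dosage`
default: fill 2 × control minor-allele frequency, which is the HWE-unbiased
expectation and preserves sample size; `zero` and `drop_individual` as
alternatives). Phenotype missingness is handled by an explicit complete-case
filter that reports removals by field and by status.

## Synthetic cohort

The generator emulates a retrospective case-control study as rejection
sampling from a prospective population model: genotypes are independent
Binomial(2, MAF) draws (Hardy–Weinberg, no linkage disequilibrium — the panel
SNPs sit on distinct loci), risk factors are drawn independently from
configurable marginals, disease is Bernoulli(logistic(η)) with
η = intercept + Σβ<sub>k</sub>x<sub>k</sub> + Σγ<sub>j</sub>z<sub>j</sub>,
and individuals are retained until the case and control quotas (defaults
1109/1177) are filled. The intercept is either fixed or calibrated by root
bracketing so that the population prevalence hits a target (default 0.10,
a configurable design choice: high enough that quota filling is cheap, low
enough that the disease is realistically uncommon).

Covariate defaults (prevalences/means and effect sizes) are a documented
plausible set for a Mediterranean screening-age population — e.g. height 162 ±
6 cm, postmenopausal fraction 0.65, family-history prevalence 0.12 with
γ = ln(1.8). They are synthetic choices, not estimates from any dataset;
every recovery test states its generating values explicitly. Continuous
factors contribute γ(z − mean) so the intercept keeps a baseline-risk
interpretation. Breastfeeding is generated only for parous women; nulliparous
women carry a distinct age-at-first-full-term-pregnancy code that the model
folds into the reference band.

What the generator deliberately does **not** emulate: LD between SNPs,
genotype–covariate correlation (an explicit screening step checks for it in
the analysis, and the generator's independence makes the null case exact),
age-dependent incidence, and selection effects of real screening programmes.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features.

## Logistic fitting

A plain Newton/IRLS maximiser with an explicit contract: convergence when the
relative log-likelihood change falls below 1e-10 (max 100 iterations); hard
error on rank-deficient designs (collinear columns identified via QR);
complete separation detected when any coefficient passes |β| > 15 and
reported as a flagged, non-converged fit rather than silent output. Wald
covariance from the inverse observed information; weights clipped at 1e-12 to
keep the information matrix finite at extreme fitted probabilities. The test
suite cross-checks coefficients and standard errors against an independent
maximum-likelihood implementation to 1e-6, and against the closed-form 2×2
log-OR to 1e-8 on expanded contingency tables.

## Stratification conventions

Two deliberately different quantile rules:

- **PRS quartiles are control-anchored**: cut-points are quantiles of the
  control score distribution (type-7 linear interpolation), so bins have
  epidemiological meaning ("relative to the population distribution"), and
  cases fall where they fall. Reference = 2nd quartile.
- **Integrated-model deciles are pooled**: cut-points come from the whole
  analysis sample's fitted probabilities. Reference = 5th decile.

Both use half-open [lower, upper) intervals with the top bin closed above, so
scores equal to a cut-point go to the upper bin and out-of-range cases land in
the extreme bins. Per-bin odds ratios use the closed-form 2×2 estimate —
identical to the logistic point estimate with bin indicators — with Wald CIs
(se = √Σ 1/count). CIs are Wald throughout; profile-likelihood intervals are
out of scope and would differ visibly only for extreme bins.

## Calibration and discrimination

Hosmer–Lemeshow groups individuals by sorted fitted probability into
near-equal tenths; tied probabilities never straddle a boundary (the boundary
shifts to the next distinct value, merging groups when necessary), and the
statistic is referred to χ² with (groups − 2) df — the convention consistent
with the reported χ²/p pairing at 10 groups. AUC is the Mann–Whitney
statistic with ties counted ½; its variance uses the DeLong case/control
placement values with a Wald CI clipped to [0, 1]. The AUC reported by the
integrated model is apparent (in-sample). Because a freely fitted 14-term
model is optimistic — under an all-null generating model the apparent AUC at
n ≈ 2000 sits near 0.55, not 0.50 — the package also provides a k-fold
out-of-fold AUC (`cross_validated_auc`), and the null-discrimination property
tests assert on that unbiased quantity. Sensitivity/specificity default to a
0.5 probability threshold (positive iff p̂ ≥ threshold).

## Numerical and design choices

- Quantiles: numpy's default linear-interpolation rule (type 7), for
  determinism and ubiquity.
- No multiple-testing correction anywhere; nominal two-sided p < 0.05.
- 2×2 tables with a zero cell are rejected with advice rather than silently
  continuity-corrected.
- Per-SNP association rows for monomorphic SNPs are flagged, not estimated.
- Spearman screening uses mid-rank ties, pairwise-complete observations and
  the t approximation; it is the interaction screen — no product-term test is
  part of the core model.
- Display rounding is half-up at printed precision; machine precision is
  retained in JSON outputs.

## Problem sizes in the test and acceptance suites

Recovery checks run at population n = 50,000 (per-SNP) and at the default
cohort size n = 2,286 (multivariable). Operating characteristics use 500
replicates each: DeLong coverage on 200 + 200 binormal samples (true
AUC = Φ(1/√2) ≈ 0.760), Hosmer–Lemeshow type-I error at n = 2,000 under a
correctly specified 3-term model. Fifteen simultaneous 3·SE recovery checks
are granted one allowed miss (family-wise pass probability under perfect
recovery ≈ 96% otherwise); all betas must still lie within 4·SE.

## Known limitations

- The panel is small (15 SNPs); the score explains little variance by design,
  and all conclusions are about pipeline correctness, not clinical utility.
- Wald intervals can be inaccurate for extreme strata counts.
- The generator's independence assumptions (SNP–SNP, SNP–covariate) make it
  unsuitable for studying confounding or LD-related bias.
- Retrospective sampling identifies covariate effects but not the population
  intercept; absolute-risk projection is explicitly out of scope.
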