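# Methods

This note documents the statistical models, the numerical choices, and
the points where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohort generator

The generator emulates a prospective birth cohort of mother–child pairs
with cord-blood methylation. Its defaults reproduce the marginals of
the motivating cohort: n = 722 pairs, exposure GWG ~ N(15.2, 5.6²) kg,
BMI ~ N(24.5, 4.1²) kg/m², z-birthweight mean −0.42, maternal age
~ N(29.9, 4.1²), and categorical covariates at the cohort frequencies
(education 11/164/516 primary/upper-secondary/university; country of
birth 630/62 Sweden/other; smoking 2/681 yes/no). The published cohort
table prints an SD of 0.04 for the z-birthweight, which is implausible
for a z-score (it is consistent with a standard error, 0.04·√722 ≈ 1);
the generator therefore targets the printed mean and leaves the SD to be
implied by the outcome equation (≈ 1 in the null configuration).

**Beta values.** Methylation is generated on the logit scale and mapped
through the logistic function, clipped to [1e-6, 1−1e-6], which keeps
every value in [0, 1] while the analysis models beta values linearly.
For a planted mediator with baseline level m₀ (default 0.5) the logit
slope is α_a / (m₀(1−m₀)), a local linearization making the beta-scale
slope equal the requested α_a near m₀. Because the logistic squashes
tails, the realized beta-scale slope differs slightly from the nominal
value; `CohortTruth.alpha_a` stores the *realized* covariate-adjusted
OLS slope, and recovery tests compare against that.

**Null probes** are block-correlated logit-normal noise (block size 10,
within-block correlation 0.3 by default) with probe-specific means
spread over the unit interval — a minimal stand-in for locally
correlated methylation without a genome model.

**Outcome.** Y = −0.42 + c·(X − μ_x) + Σ_j β_m,j (M_j − M̄_j) +
covariate terms + N(0, σ_y²), with σ_y = 0.9 by default. The accounting
identity E[slope of Y on X] = c + Σ α_a,j β_m,j holds by construction
and is verified at large n in the tests.

**Strong-signal defaults.** Neither the motivating study nor any
public source states realistic effect sizes for methylation mediation,
so defaults are chosen for testability: three planted mediators with
α_a = 0.002 beta-units/kg (t ≈ 30 for the exposure→mediator path at
n = 722, mediator noise 0.01) and β_m = 30 z-units/beta-unit (Wald
t ≈ 7–8 for the mediator→outcome path). This makes planted mediators
decisively recoverable by all three selection methods while null
configurations stay null. The implied total GWG effect (≈ 0.2 z/kg) is
deliberately larger than the published adjusted estimate (0.031); the
generator is a test harness for the machinery, not a calibrated model
of real methylation data. Features of real data it does not emulate:
array-wide probe placement, probe-specific measurement error models,
genetic (meQTL) structure, batch effects, and cell-type–specific
methylation differences. Passing tests therefore demonstrate
correctness of the algorithms, not field performance on real cohorts.

**Cell proportions** are Dirichlet draws (default six cord-blood
compartments, concentration (2, 12, 6, 30, 4, 2), granulocyte-dominated).
Because proportions sum to one, the pipeline omits the last compartment
from adjustment designs (reference coding); the estimator layers also
drop exactly collinear covariate columns with a logged warning.
**Missingness** is completely at random — the motivating analysis only
states that missing data were excluded, not a mechanism.

## Step 1: association screen

Per exposure, two OLS fits of z-birthweight: exposure only, and
exposure + covariates, with listwise deletion *per model* (the
unadjusted fit only drops rows missing the exposure or outcome). 95%
CIs and p-values come from the t distribution of each fit, so p < 0.05
⟺ the CI excludes zero. Categorical covariates are dummy-coded against
their most frequent level (education = University, country = Sweden,
smoking = No), which affects intercepts only. No multiplicity
correction is applied across exposures, matching the presentation the
pipeline reproduces. BMI subgroup analyses use WHO cuts 18.5/25/30
(configurable; published cohort tables print bands 18–24.9 / ≥ 25, a
discrepancy worth noting); subgroups with n < 3 or zero variance report
an undefined correlation rather than raising.

## Step 2: high-dimensional mediator selection

**Screening.** The SIS statistic for probe j is the absolute t
statistic of the probe in Y ~ probe + exposure + covariates + cell
proportions (partial association; a raw marginal screen is available by
passing no covariates). All probes are screened in one vectorized pass
by residualizing both sides on the adjustment design, which equals
brute-force per-probe regression (tested). Screening size
d = ⌈2n/ln n⌉ — the conventional default in this method family; the
motivating description says only that d is below the sample size.
Constant (or covariate-collinear) probes get statistic 0 and rank last
rather than erroring.

**De-biased LASSO (HDMA, HIMA2).** Exposure and covariates are
unpenalized, handled by Frisch–Waugh partialling: Y and all probes are
residualized on [1, X, C] (SVD-based projection, safe under rank
deficiency) and the LASSO is fit on standardized residualized probes,
penalty by 10-fold cross-validation (minimum-CV rule, fold seed from
the run seed). De-biasing follows the nodewise-regression construction:
for each probe j, a LASSO of M_j on the remaining probes yields a row
of the approximate precision matrix with τ_j² = ‖r_j‖²/n + λ_j‖γ_j‖₁;
the de-biased estimate is b + Θ Mᵀ(y − Mb)/n with Wald standard errors
σ̂ √((Θ Σ̂ Θᵀ)_jj / n), σ̂² = RSS/(n − k − ŝ). The nodewise penalty is a
fixed universal λ = 0.5 √(log p / n) on standardized columns rather
than per-column cross-validation: the fixed rate is the standard
theoretical choice, deterministic, and roughly 50× cheaper across the
replicated calibration studies; per-column CV remains available via
`nodewise_alpha="cv"`. On orthonormal designs the de-biased estimate
provably equals the marginal statistic z = Mᵀy/n (soft-threshold plus
correction), which the tests check; Wald CI coverage is verified by
simulation (90–98% band at n = 300, p = 150).

**MCP (HIMA).** Coordinate descent on the same partialled/standardized
system using Gram-matrix updates with active-set cycling (numba-jit).
γ = 3.0 by default (γ ≤ 1 is rejected); λ by 10-fold CV over a
25-point geometric path down to 0.05·λ_max. The univariate update is
the firm-threshold rule sign(z)(|z|−λ)₊/(1−1/γ) for |z| ≤ γλ, else z —
checked against the closed form on orthonormal designs, against OLS at
λ = 0, and against the LASSO as γ → ∞. Survivors are refit jointly by
OLS with the unpenalized columns to obtain β_m estimates and t-test
p-values, matching the published description of mediator inference
among probes that survived both reduction steps.

**Mediator models.** One OLS of probe ~ exposure + covariates per
screened probe, vectorized over probes (shared design), giving α_a and
its t-test p_α. Null calibration (uniform p-values) is tested by
Kolmogorov–Smirnov.

**Joint significance and FDR.** p_joint = max(p_α, p_β). HDMA and HIMA
adjust p_joint by Benjamini–Hochberg ("joint significance uniform").
HIMA2 uses the composite-null "mixture" correction: Storey-type null
proportions π₀ estimated at λ = 0.5 separately for the α and β p-value
vectors and combined multiplicatively into π₀₀ (both null), π₀₁ and
π₁₀ (one path null); the estimated FDR at threshold t is
[(π₀₁+π₁₀)t + π₀₀t²]·m / R(t), converted to monotone q-values. Since
the bracket never exceeds t, mixture q-values are bounded by BH
q-values, so the mixture procedure never flags fewer tests — the
"less conservative by construction" property, tested directly. This is
an approximation of the cited method's internals chosen from its
published description; the exact estimator internals are not public.

**Accounting.** Each method's global indirect effect is the sum of
contributions α_a·β_m over the post-penalty (pre-FDR) selected set; the
total effect is the covariate-adjusted exposure→outcome OLS slope on
the same complete cases; the direct effect is defined as total − global
indirect, so the identity holds to machine precision by construction.

**Problem sizes.** The replicated calibration suite runs 500
complete-null cohorts at n = 300, p = 1000 (d = 106) and checks that
each method flags any false mediator in at most 5% of replicates plus a
three-sigma Monte-Carlo margin; recovery uses 30 seeds at n = 722,
p = 2000; the single-model bias check uses 200 replicates at p = 50
(the probe count does not enter a single-mediator fit). These sizes
were chosen to make the full suite run in a few minutes on one CPU
while keeping the Monte-Carlo margins meaningful.

## Step 3: classical mediation

**Structural equations.** For mediators in serial order M₁…M_k (k ≤ 3):
M_j ~ X + M₁..M_{j−1} + C, then Y ~ X + all M + C; parallel models drop
the cross-mediator terms; the single model is the two-equation special
case. Every covariate enters every equation. Pathway estimates are
products of chain coefficients; a serial model has 2^k − 1 pathways
ordered singletons-first, then pairs lexicographically, then the full
chain. The total indirect effect is the pathway sum and the total
effect is direct + total indirect (sum convention — the published
tables are additively consistent, and for OLS with shared rows the sum
equals the total-effect regression slope exactly); the total's SE and
p come from a separate Y ~ X + C fit with the same estimator, mirroring
the convention of printing SE/p for direct and total but CIs only for
indirect effects.

**MM-regression.** The robust estimator is a fast-S stage (bisquare ρ,
c₀ = 1.5476 for 50% breakdown; 50 random elemental p-subsets plus the
LS fit, each refined by iterated reweighting with M-scale updates, best
scale kept) followed by an M-step at fixed S-scale with bisquare ψ
tuned to 95% normal efficiency (c₁ = 4.685, solved numerically from
the efficiency integral for other settings). Standard errors use the
usual MM sandwich s²·(E ψ²)/(E ψ′)²·(XᵀX/n)⁻¹/n. Exact-fit data return
scale 0 with the exact coefficients. Non-convergence raises an error
carrying the last iterate.

**Bootstrap.** Whole rows are resampled with replacement (R = 5000 by
default for reported CIs; tests use smaller R); every refit reuses the
model seed so runs are reproducible. Percentile CIs at the requested
level for each pathway and for the total indirect; a pathway is
"significant" when its CI excludes zero. Failed refits are redrawn and
counted; more than 10% failures aborts. Direct- and total-effect
inference comes from the estimator's asymptotics on the original
sample, not the bootstrap.

**Serial mediator choice.** The published analysis selects the three
serial mediators "based on the results from single mediation
assessments" without stating the rule. The package's declared default:
bootstrap-significant single-model indirect effects first, then
decreasing |estimate|, ties broken by probe id. The rule is
configurable and recorded in the output metadata.

**Robustness conditions.** The robustness contract is tested with 10%
gross response outliers (+10 residual SD) concentrated in the upper
exposure tail. Outliers placed there bias the OLS slope systematically,
so the contrast with the MM fit measures resistance to contamination
rather than sampling noise; with uniformly random outlier placement
the OLS slope stays unbiased and the comparison degenerates to a
variance ratio near the contract boundary.

## Degenerate inputs and numerical conventions

- Beta matrices are validated into [0, 1] on read, naming the offending
  probe and sample; duplicate probe ids are rejected.
- All projections onto covariate spans use SVD/least-squares, safe when
  the span is rank-deficient; estimator layers drop exactly collinear
  covariate columns (never the exposure or a mediator) with a warning.
- Percentile CIs need not contain the point estimate in pathological
  resamples; this is logged, not raised.
- File writes are atomic (temp + rename); gzip members carry a fixed
  mtime so reruns with the same config and seed are byte-identical.
- Floating-point text round-trips are documented at 10 significant
  digits.

## Known limitations

- The mixture-FDR null-proportion estimator is a two-threshold
  Storey-type approximation of the cited method, not a port of it;
  results on real data will not be bit-identical to the R packages in
  that family (screening sizes and CV folds of the original runs are
  unreported in any case).
- The de-biased LASSO's fixed nodewise penalty trades a little
  efficiency for determinism and speed.
- Serial models are capped at three mediators, matching the limit of
  the classical-mediation tooling the pipeline mirrors.
- The generator's linearized beta-scale effects are local: very large
  α_a or extreme base levels make the realized slope visibly smaller
  than the nominal one (the realized value is always stored).
- Desk-scale targets: the screening path streams fine up to tens of
  thousands of probes; array-scale (850k) inputs are out of scope.
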