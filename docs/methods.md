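# Methods

This note documents the statistical model behind `expomic`, the
defaults and numerical choices, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The mediation model

For an exposure X, a single continuous mediator M (a gut-microbiome
index) and an outcome Y, the package fits the causal-steps
decomposition with a shared covariate set Z (age and sex by default):

    Y = i1 + c  X + Z γ1 + e1        (total effect)
    M = i2 + a  X + Z γ2 + e2        (exposure → mediator)
    Y = i3 + c' X + b M + Z γ3 + e3  (direct + mediator paths)

The indirect effect is ab; for continuous Y and identical covariate
sets in all three regressions, c = c' + ab holds as an algebraic
identity of least squares, which the test suite asserts to 1e-10.

Continuous exposures are Z-scored on the analysis sample (after
listwise deletion for the triplet), so a, c and c' are per-SD effects;
binary/dummy exposures are left on their 0/1 scale. Binary outcomes
use logistic regressions for the Y-models, putting b, c and c' on the
log-odds scale while a stays linear.

**Indirect-effect CI.** Two engines, chosen by outcome type:

* *Continuous Y*: nonparametric bootstrap — rows resampled with
  replacement, a and b refit per resample, percentile interval of the
  a·b draws. Default 5000 resamples (configurable; the simulation
  studies use 300, where percentile-endpoint noise is already well
  below the effect sizes probed). The resampling stream is governed by
  an explicit seed recorded in the result.
* *Binary Y*: the a·b estimates come from different model families, so
  the bootstrap's exchangeability argument is weaker and the normal
  (Sobel) approximation is poor at moderate effect sizes. Instead the
  CI is taken from the exact distribution of the product of two
  independent normals N(a, se_a²)·N(b, se_b²). The product CDF
  P(UV ≤ z) = E_U[Φ((z/U − b)/se_b) · 1(U>0) + Φ̄(·) · 1(U<0)]
  is evaluated by panelled Gauss–Legendre quadrature (48 nodes per
  panel, 24 panels per sign region geometrically refined towards the
  integrable kink at U = 0, integration clipped at 10σ of U); quantiles
  are found by Brent root-finding. Against high-precision adaptive
  quadrature the CDF agrees to ~1e-12, and CI endpoints match a
  2×10⁶-draw Monte-Carlo oracle to ~3e-4 — the interval is genuinely
  asymmetric whenever either standardized effect is small.

**Proportion mediated** is ab/c, reported signed; values outside [0,1]
are flagged (`out_of_range`) rather than clipped, since inconsistent
mediation legitimately produces them; |c| < 1e-8 flags the ratio
undefined. For binary outcomes ab/c mixes linear and logistic scales
and is non-collapsible; it is reported as a descriptive quantity with a
caveat flag.

**Classification.** ab significant means its CI excludes zero; c'
significant means p < α (0.05). Rules: ab not significant → *none*;
ab significant and c' not → *full*; both significant, same sign →
*partial*; opposite signs → *inconsistent*. The "full" rule is an
interpretive completion of the partial/inconsistent taxonomy and is
surfaced in the result metadata.

## The association screen

Each exposure is regressed on each dependent variable separately (OLS,
HC1 sandwich standard errors, listwise deletion per pair; the HC
variant is configurable). Adjusted R² uses the bivariate formula
1 − (1 − R²)(n−1)/(n−2). P-values are BH-adjusted within a family —
per dependent variable by default, because the downstream reporting is
organized per index/outcome; a global family is available and the
choice is recorded in the output metadata. Significance requires the
dual criterion: FDR < 0.05, the 95% CI for β excluding zero, and
adjusted R² > 0.005 — the effect-size gate keeps very large cohorts
from flagging practically negligible slopes. The exported matrix
stores sign(β)·adjR² for significant pairs and exactly 0 elsewhere.

Triplets passed to mediation are the Cartesian product, per exposure,
of its screen-significant mediators and outcomes.

## Mediator indices

Computed on raw counts (no rarefaction — a deliberate, logged caveat;
sequencing-depth variation therefore leaks into richness metrics):

* Shannon entropy in **bits** (log2 default, natural log available);
* observed features (taxa with count > 0);
* Fisher's α: the unique positive root of S = α ln(1 + N/α), solved by
  Brent's method to |S_model − S| < 1e-9; all-singleton samples
  (S = N) have no finite root and return a flagged NaN;
* PCoA1/PCoA2: Gower double-centering of −D²/2 on the Bray–Curtis
  matrix D(u,v) = 1 − 2Σmin(u,v)/(Σu+Σv), eigendecomposition, axes
  scaled by √eigenvalue. Negative eigenvalues (Bray–Curtis is
  non-Euclidean) are dropped with a warning rather than
  Cailliez-corrected; axis signs are fixed so the lexicographically
  first sample has non-negative coordinates, making runs comparable;
* F/B and Gram+/Gram− ratios from summed counts (scale-invariant, so
  counts vs relative abundances is immaterial); zero denominators give
  flagged NaN, never infinity;
* guild abundances (risk-associated: Eggerthella, Anaerotruncus,
  Klebsiella; 17 butyrate producers; 7 lactate producers) as summed
  relative abundance, absent members contributing zero (logged).

Taxon matching is exact string match; genus→phylum and Gram lookups
ship as configurable defaults covering the synthetic community and
common gut genera.

## Environmental standardization

Cities with >14 samples are eligible; the standardization target is
the median eligible-city size (lower median for even counts, so the
target is an achievable size) or an explicit override. Cities above
the target are reduced by drawing uniform random subsets until one
passes a two-sample KS test (subset vs full city) on the per-sample
alpha-diversity distribution at p > 0.05; Fisher's α is the default
gate metric (Shannon/observed configurable), max 1000 iterations, and
exhaustion raises an error carrying the best subset seen. Cities at or
below the target pass through unchanged. Under iid sampling the
per-draw acceptance probability is ≈ P(p > 0.05) ≈ 0.95, which the
simulation study confirms (≥ 90% first-draw acceptance). Note the KS
gate has essentially no power for very small subsets — a subset of
size 3 passes almost surely — so the gate is meaningful only at
realistic target sizes.

## Group statistics

Mann–Whitney U uses midranks; the p-value is exact (enumeration-based)
when n1·n2 ≤ 400 with no ties, else the tie-corrected normal
approximation. PERMANOVA computes pseudo-F from among/within sums of
squares obtained directly from the distance matrix via the Gower
identity SS = Σ_{i<j} d²_ij / m, with the add-one permutation p-value
(1 + #{F_perm ≥ F_obs})/(1 + n_perm); the permutation stream is
seed-controlled. Quartile prevalence shifts compare presence
fractions between samples strictly above the 75th and strictly below
the 25th exposure percentile (boundary ties excluded, counts logged)
with two-sided Fisher's exact tests and BH adjustment; chi-squared is
available as an alternative.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline
assumes: standard-normal exposures; mediators linear in exposure with
Gaussian noise; outcomes linear (or logistic) in exposure and mediator;
age ~ N(45, 15) truncated to [18, 90] and sex ~ Bernoulli(0.5),
optionally entering the outcome; genus tables drawn
Dirichlet–multinomial from a fixed base community (taxa named after the
real guild lists so every index code path is exercised; default depth
10,000 reads, Dirichlet concentration mass ≈ 50 giving realistic
overdispersion) with planted per-taxon log-concentration shifts
proportional to an exposure; MCAR missingness at configurable rates.

It deliberately does **not** model phylogenetic correlation among
taxa, sequencing error, compositional spurious correlation beyond what
the Dirichlet–multinomial induces, geographic autocorrelation, or
informative missingness. Passing parameter-recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions — not robustness to the violations real cohort data
exhibit (confounding, measurement error, MNAR dropout).

Triplet simulation defaults to the *abstract* mode (M is the abstract
index value), separating statistical correctness from ecological
plumbing; the end-to-end mode (outcomes wired to an index computed
from generated counts) is used in the generator's cohort mode.

## Simulation studies and problem sizes

`expomic.evaluation` packages the validation studies; the acceptance
script and test suite run them at these sizes, chosen to make
Monte-Carlo error small relative to the bands checked:

* mediation recovery: 500 replicates, n = 5000, planted a = 0.5,
  b = 0.4, c' = 0.3 (ab = 0.20); bootstrap engine at 300 resamples;
  checks: mean ab within 5% of 0.20, CI coverage in 92–98%;
* distribution-of-product CI: 5×5 grid of standardized effects
  {0, 0.5, 1, 2, 5}² at se = 0.1, each endpoint against 2×10⁶
  Monte-Carlo products (tolerance 0.005; observed error ~3e-4);
* null screen: 50 exposures × 10 indices at n = 1000, 20 replicates;
* test type-I errors: 500 replicates each (PERMANOVA at 99
  permutations, so the add-one p-floor is 0.01);
* subsampler: 100 seeds, city of 100 samples subsampled to 55.

All studies derive their randomness from a single master seed.

## Known limitations

* Cross-sectional mediation: estimates are associational; no
  sensitivity analysis for unmeasured confounding is provided.
* One mediator per model; exposure–mediator interactions and multiple
  or binary mediators are out of scope (all ten indices are
  continuous).
* The bivariate screen is intentionally unadjusted; covariates enter
  only at the mediation stage.
* Proportion mediated for binary outcomes inherits the
  non-collapsibility of odds ratios; treat it as descriptive.
* BH-FDR assumes independence/PRDS across tests in a family; heavily
  correlated indices make it conservative in unclear directions.
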