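# Methods

This note documents the statistical model, the numerical algorithms, the
synthetic-data generator, and the design decisions behind `methaherd`.

## The phenotype: indirect methane prediction

Enteric methane is expensive to measure at population scale, so the
phenotype analysed here is *predicted* methane, computed deterministically
from routinely recorded lactation milk traits (kg/lactation):

| Equation | Predictor | Form (g CH4/lactation) |
|---|---|---|
| MPE1 | milk yield (MY) | 299 + 2.73 MY |
| MPE2 | energy-corrected milk (ECM) | 259 + 3.86 ECM |
| MPE3 | ECM and protein concentration (CPC) | 150 + 4.31 ECM + 28.3 CPC |

with ECM = 0.327 milk + 12.95 fat + 7.2 protein and CPC = 100 protein/milk
(%). The equations are applied to per-lactation totals; dividing by the
lactation length (310 days on average in the target population) converts to
g/day, reported as integers. The published standard errors of the equation
coefficients are carried as metadata and not propagated — the phenotype is
the point prediction, exactly as it would enter a breeding-value
evaluation. Consequence worth stating: MPE1 is an affine function of milk
yield, so its correlation with milk is identically 1 and its heritability
equals the heritability of milk yield. The generator offers an optional
independent noise term on the methane columns (off by default) for
exploring the sub-unit-correlation regime.

## The model

For records y of one trait:

    y = X b + Z a + W pe + e
    V(a) = A s2a,  V(pe) = I s2pe,  V(e) = I s2e,  Cov(a, pe) = 0

Fixed effects b: parity (1–6), herd, year, season of calving (1–4) as
reference-coded factors and lactation length (days, 200–400) as a single
mean-centered linear covariate. `a` are additive genetic effects with the
pedigree numerator relationship matrix A; `pe` are cow permanent-environment
effects shared across a cow's repeated lactations. Derived parameters:

    h2 = s2a / sP2,   r = (s2a + s2pe) / sP2,   sP2 = s2a + s2pe + s2e
    rg = covG / sqrt(s2gx s2gy),  rp = covP / sqrt(sP2x sP2y)

Repeatability r is an upper bound on h2 by construction. For two traits on
the same records the (co)variances become 2x2 blocks G_a, G_pe, R_0 and
covP = covG + covPE + covR.

## Pedigree machinery

* A is built by the tabular recursion (a_ii = 1 + a_{sd}/2; a_ij = mean of
  parental relationships), dense, for tests and small runs only.
* Inbreeding and the Mendelian-sampling variance fractions d_i come from
  the Meuwissen–Luo ancestor-traversal algorithm (cost n x ancestor-path
  size, no dense matrix).
* A-inverse is assembled directly by Henderson's rules with
  inbreeding-corrected diagonals (alpha = 1/d_i), sparse, so the pipeline
  scales to tens of thousands of animals. log|A| = sum(log d_i) falls out
  for free and feeds the REML likelihood.
* Unknown parents are unrelated, non-inbred base-population members.
  Pruning keeps focal animals and ancestors within g parent-links (default
  g = 6); a parent-link counts one generation. Topological order is
  parents-before-offspring with stable tie-breaking by input order.

## REML

One engine fits k traits (k = 1, 2) recorded on the same records. Per
iteration, at the current (G_a, G_pe, R_0):

1. Henderson's mixed-model equations are formed on the R^-1 scale. The
   permanent-environment block is (block-)diagonal (one kxk block per cow)
   and is absorbed analytically; the remaining fixed+animal core is dense
   and Cholesky-factorized (LAPACK dpotrf/dpotri). All traces of the full
   MME inverse needed later are recovered through the Schur complement:
   per-cow quadratic forms handle every absorbed index.
2. EM updates are conditional expectations: G_a <- (A-quadratic form of
   the BLUP solutions + trace term)/q, similarly for G_pe and R_0 (the
   residual update uses (e'e + tr(M C^-1 M'))/n). These are exact EM steps,
   so the restricted log-likelihood is non-decreasing along them — a
   property the tests assert per iteration.
3. The score vector and average-information (AI) matrix are computed from
   the same cached quantities (the AI matrix needs one extra multi-RHS
   solve against the cached factorization). From the second iteration on,
   the engine proposes theta + AI^-1 score; if the proposal leaves the PSD
   cone it is eigenvalue-clipped, and if its likelihood is lower (or not
   finite) the engine falls back to the EM step for that iteration. Pure
   EM mode (`method="em"`) is available for the monotonicity checks.
4. Convergence: relative parameter change < 1e-8 (components at the floor
   are measured against the phenotypic scale) or |dlogL| < 1e-6, max 500
   iterations. Non-convergence returns `converged=False` with a warning,
   never silently. Variance blocks are floored at 1e-8 of the mean
   phenotypic variance; with exactly collinear traits the likelihood is
   unbounded at the singularity, the floor caps it, and the estimated
   correlations approach 1 to ~1e-6.
5. Standard errors are the square roots of the diagonal of the inverse AI
   matrix at convergence; ratio and correlation SEs use the first-order
   delta method. AIC = -2 logL + 2 m with m the number of (co)variance
   parameters (3 univariate, 9 bivariate); REML AICs are compared only
   across models sharing the fixed structure, which is how the package
   uses them (MPE1 vs MPE2 vs MPE3).

Bivariate starting values are the univariate fits with cross-covariances
seeded at half the phenotypic correlation. The engine was validated against
a dense-covariance implementation of the restricted likelihood (agreement
to ~1e-13) and central finite differences of the scores, and against
closed-form ANOVA on balanced designs of unrelated cows (1e-9 relative).
With A = I the additive/permanent split is unidentifiable by design; only
their sum is compared there.

## Synthetic herds

The generator runs the model forward:

* **Pedigree**: founder sires (optionally founder dams), then generations
  of daughters by random mating; later-generation sires are fresh
  founders, so matings are selfing-free. The focused recovery experiments
  use a paternal half-sib design (dams unknown), the classic layout for
  variance-component estimation.
* **Breeding values** by gene dropping: founders ~ N(0, G); offspring =
  parent average + Mendelian deviation ~ N(0, d_i G) with the same d_i as
  the A-inverse construction, so effect covariances are exactly A (x) G.
* **Records**: four base yield traits (milk, fat, protein, lactose) drawn
  jointly; per-level fixed-effect values drawn once per herd/year/season/
  parity level; lactation length uniform on [200, 400] with a small
  proportional slope. Dry matter = fat + protein + lactose + a positive
  "other solids" margin (mean 82 kg, SD 15), which enforces the
  composition constraint by construction while keeping dry matter a linear
  combination of Gaussian traits. Methane columns are computed from the
  yields by the prediction equations.
* **Calibration**: trait means and SDs default to the published population
  scale (milk 11,221 ± 2,353 kg, fat 428 ± 92, protein 375 ± 74, lactose
  546 ± 114). Milk variance components are the published methane
  components divided by 2.73^2 — so the MPE1 column has exactly the
  published additive/permanent/residual components (6,771,940; 3,371,540;
  12,418,000), with the same component fractions applied to the other
  yields. Cross-trait genetic/environmental correlations are field-typical
  values for Holstein yield traits (0.55–0.96). Records per cow follow a
  truncated geometric on parities 1–6 calibrated to the published 2.18
  records/cow. Fixed-effect level SDs default to 1.5% of the trait mean
  per factor, keeping the fixed-effect share of variance near 4% so the
  generated phenotypic variance stays within 10% of the component sum.

What the generator does *not* emulate: selection and culling (no
truncation of parents on phenotype), genotype-by-environment interaction,
heterogeneous herd variances, seasonality of lactation curves, and any
real excess of phenotypic SD over the component sum (the published milk SD
of 2,353 exceeds the component-implied 1,740, i.e. real fixed effects are
much larger than the generator's default). Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated model, not robustness to violations of it.

## Problem sizes and experiment protocols

All experiments are desk-scale by design and run on one CPU:

* Ratio reproduction and per-day conversions: closed-form, instantaneous.
* Heritability/repeatability recovery: 200 sires x 10 daughters x 2
  records (4,000 records, ~2,200 animals), true components as published,
  intercept-only fixed structure, 10 seeds; the mean estimated h2 and r
  are compared with 0.30 and 0.45 within +/-0.03 (the per-seed sampling SD
  of h2 is ~0.06, so the 10-seed mean has Monte-Carlo SE ~0.018).
* Full simulate->fit loop through the pipeline: the ~2,000-cow preset with
  the complete fixed-effect structure, 20 seeds, mean bias of h2 and r
  below 0.02.
* Bivariate checks: affine-copy correlations at a 200-cow design; null
  (rg = 0) and rg = 0.8 recovery at the 200 x 10 design with 5 and 3 seeds
  respectively — seed counts chosen to keep the default test run within a
  desk-scale budget while leaving the Monte-Carlo error of each mean well
  inside the asserted band.
* The study-scale preset (~17,468 cows / ~38,000 records, 28 herds) is
  available for the analysis drivers; a univariate fit at that scale forms
  a ~18k-dimensional core and is minutes-scale, so the drivers default to
  the small preset.

## Known limitations

* The absolute published variance components, AIC values and
  methane–milk-trait correlation tables depend on the real (undeposited)
  herd data and are not reproducible from simulation; the package
  reproduces every quantity that is a deterministic function of printed
  values, and validates the estimation machinery by parameter recovery.
* The dense-core MME factorization is O((p+q)^3) per iteration per trait
  pair; beyond ~30k animals a sparse factorization would be needed.
* Only single- and two-trait models are implemented (no 3+ trait,
  random-regression, or genomic models).
* The bivariate engine assumes both traits observed on every record, which
  is exact for derived methane traits and milk traits from the same
  lactation.
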