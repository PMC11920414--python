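# Methods

## Model

Let y be the 62 ordinal symptom items, organized into six scale-level
domains (ODD 8, CND 18, HYP 9, INA 9, DEP 13, ANX 5 items), and x the
exogenous regressors (standardized mother/father/child PGS, plus sex
and year of birth as item-level covariates). The second-order MIMIC
model is

    f      = B f + Γ x + ζ,        ζ ~ (0, I)
    y*     = L f + K x + ε,        ε ~ (0, Θ diagonal)

with factor vector f = (P, η_ODD, …, η_ANX). B carries the
second-order loadings (η_d ← P), so (I − B)⁻¹ = I + B exactly; L is
the item loading matrix (one domain per item; in the symmetric
bifactor alternative every item loads on P and one orthogonal specific
factor and B = 0); Γ holds the structural PGS paths (to P, to domains,
or — in symptom-heterogeneity models — moved into K as direct item
paths); K also carries covariate→item paths.

**Identification.** All factor residual variances are fixed at 1
(unit-variance identification); for ordinal items the delta
parameterization fixes the liability variance at 1 so residual
variances are derived, not free. Unstandardized paths are therefore on
a residual-sd scale; the **standardized solution** (computed from the
model-implied factor and item variances) is the scale on which
generating effect sizes are recovered and shrinkage is calculated.

## Estimation

Two estimators share one compiled parametrization and analytic
gradients (verified against numerical differentiation in the tests):

* `ml_continuous` — normal-theory ML on continuous indicators in the
  conditional (fixed-x) formulation: the x-block is saturated, so only
  Π = L(I+B)Γ + K and Ω = L(I+B)(I+B)ᵀLᵀ + Θ are modelled. The
  statistic is T = n·F̂ with df = p(p+1)/2 + pk − q. Standard errors
  come from the observed information. This is the fast path for
  simulation studies (one 62-item fit ≈ 0.1–0.3 s).
* `dwls_ordinal` — two-stage weighted least squares faithful to
  ordinal-SEM practice: (1) per-item thresholds from marginal category
  proportions via the inverse normal, with categories observed fewer
  than 5 times collapsed into the nearest adjacent category; each
  pairwise polychoric (item–item), polyserial (item–continuous) and
  Pearson (continuous–continuous) correlation maximizes its pairwise
  likelihood under pairwise deletion, with the bivariate-normal CDF
  evaluated by 48-point Gauss–Legendre quadrature of its
  single-integral representation; (2) the model-implied correlations
  minimize a discrepancy weighted by the inverse of each moment's
  estimated sampling variance (per-pair observed information).

**Robustness approximation.** The full asymptotic covariance of the
polychoric moment vector (≈2.3k moments at full scale) is approximated
by its diagonal. Under that approximation the DWLS statistic is
already on the χ² scale with df = moments − free parameters, the
mean-and-variance (Satterthwaite) adjustment is the identity, and the
sandwich standard errors reduce to the WLS information. Exact
replication of any particular robust-correction flavour is therefore
not claimed; at the sample sizes of interest the χ² *difference* tests
that drive model selection are insensitive to this choice.

Heywood cases (negative residual variances) are bounded at zero and
flagged; non-convergence triggers up to three random restarts before
the fit is flagged and excluded from selection.

`chisq_diff` verifies nesting structurally before testing: free
parameters must be a subset, except that a freed path one level up the
hierarchy (PGS→P) counts as nested under the full set of freed paths
one level down (PGS→every domain, or PGS→every item of a domain),
because mediation constrains the lower-level paths to be proportional
to the loadings. Negative scaled differences are floored at 0 with a
warning.

## Synthetic-trio generator

The generator is the package's stand-in for restricted cohort data and
defines the study conditions:

* **Transmission.** Parents' standardized PGS have within-trait
  correlation a (assortment stand-in, default 0) and cross-trait
  correlation matrix C (default identity). The raw child score is
  (M + F)/2 + s with segregation variance (1 + a)/2 (scaled with the
  parental covariance so the child's cross-trait correlations
  reproduce C); after standardization cor(child, parent) =
  (1+a)/2·√(2/(2+2a)) — the Mendelian 0.5 under random mating.
* **Effects.** Betas (per trait and family member) are injected on the
  general factor, on specific domains, on single items, or "mixed"
  (parents on P, child on the domains); atomic targets combine with
  `+`. Every latent is rescaled to unit variance after injection, so
  betas are standardized effect sizes (rescaling attenuates them by
  1/√(1+q) with q the injected variance — ≈0.3% at the study's effect
  sizes, far inside every tolerance used).
* **Items.** Liabilities use first-order loadings 0.6 and second-order
  loadings 0.7 uniformly (defaults, overridable — the fitted weights
  of the reference analysis are not public); thresholds default to
  right-skewed category probabilities (0.65/0.20/0.10/0.05) matching
  symptom-scale skew; sex and birth-year effects on liabilities
  default to 0.10 and 0.03; missingness is MCAR at a configurable
  rate, with at least one observed item per retained child (the
  analysis inclusion criterion). A zero-beta trait serves as the
  negative-control PGS.
* **Seeding.** One integer seed drives all draws; replicate r of any
  simulation study uses seed + r, so results are bit-reproducible and
  invariant to parallel worker count.

What the generator does **not** emulate: locus-level genotypes,
assortative-mating dynamics across generations, rater bias,
non-random missingness, and item-specific loading/threshold
heterogeneity. Passing simulation tests therefore demonstrate
estimator and algorithm correctness under the assumed data-generating
process, not robustness to these real-data complications.

## Selection and inference

The decision ladder is executed exactly as specified by the analysis
design: compare null vs P-mediated vs domain-heterogeneity by χ²
difference at α = 0.05/N, where N is the number of nested comparisons
actually performed in the run (2 per trait, plus one per domain for
traits whose domain-heterogeneity model wins). Because the symptom
stage is conditional on the earlier gates, N is resolved by
fixed-point iteration, preferring the larger N (more conservative) on
a cycle; ties at exactly α retain the more restrictive model. No
inference is reported for traits that keep the null. Child and
parental p-values are BH-adjusted in two never-pooled families of
design-defined sizes N_PGS × 7 and N_PGS × 7 × 2. The unconditional
(child-only / parents-only) models used for shrinkage exclude the
other family members' PGS columns from the model entirely — the
"not adjusted" estimand — rather than fixing their paths at zero
inside a joint model, which would distort the fit.

## Power simulations

`power.PowerScenario` fixes the design: betas child 0.04, mother 0.03,
father ∈ {0.03, 0.01, 0.001}; N = 15,000 families; three mechanisms
(general / specific / mixed); estimator ml_continuous by default
(continuous liabilities), dwls_ordinal available for fidelity runs;
default 200 replicates per scenario (a declared desk-scale choice —
Monte-Carlo SE √(p(1−p)/R) ≈ 0.028 at p = 0.8). "Detection" of a
family member's effect is the Wald test of their single path when the
mechanism acts on P, and the joint Wald test across their six domain
paths when it acts on the specific domains (the effect is then a
single hypothesis spread over six parameters).

Measured at these defaults, maternal-path power is ≈0.78 under the
general mechanism and ≈0.85 (joint) under the specific mechanism, so
the pooled fully-mediated detection rate is ≈0.81. With stronger
measurement (higher loadings, as fitted weights in real symptom data
typically are) power rises; the defaults above are deliberately
conservative.

## Numerical choices

* Optimizer: L-BFGS-B with analytic gradients, ftol 1e-12, gtol 1e-7,
  residual variances bounded below at 1e-6; three random restarts.
* Polychoric optimizer: bounded Brent on (−0.999, 0.999), xatol 1e-8;
  correlations at the bound are clipped and logged.
* Asymptotic variances: numeric second derivative of the pairwise
  log-likelihood at the optimum (step 5e-4), Pearson-style fallback
  (1−r²)²/n if curvature is non-positive.
* Degenerate inputs: empty pairwise overlap aborts with the offending
  pair named; items with <2 observed categories are rejected;
  rank-deficient covariate designs drop collinear columns with a
  warning; a PGS fully explained by covariates is set to 0 and
  flagged.

## Known limitations

* Diagonal-Γ robustness approximation (above): exact WLSMV p-values
  from other software will differ slightly; χ² difference verdicts at
  n ≥ a few thousand are stable.
* Thresholds are treated as fixed in stage 2 of DWLS (their sampling
  noise is ignored in the weight matrix).
* The second-order and bifactor base models are non-nested; they are
  compared by RMSEA then SRMR, and the trio ladder is built on the
  second-order base.
* With uniform second-order loadings, equal effects on *all* specific
  domains are empirically indistinguishable from a P-mediated effect
  (the implied moments coincide); domain-heterogeneity selection
  consistency is therefore assessed with effects on a subset of
  domains.
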