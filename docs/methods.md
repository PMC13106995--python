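# Methods

## The liability-threshold model

All analyses treat a binary lifetime syndrome as the visible part of a
latent standard-normal liability: individual *i* is affected iff
*Lᵢ* > *t* = Φ⁻¹(1 − *K*), with *K* the lifetime morbid risk. Twin pairs
share a bivariate-normal liability with correlation *r*; the probandwise
concordance implied by the model is C(*r*) = Φ₂(*t*, *t*; *r*)/*K*, a
strictly increasing function of *r* (checked numerically), so concordance
plus morbid risk identify the tetrachoric correlation. *K* is an input
parameter per syndrome: population morbid risks come from registers or
census extrapolation, which is outside this package's scope. All code
restricts *K* to (0, 0.5); thresholds are then positive and the affected
state is the minority state, which is the regime twin studies of psychosis
occupy.

## Likelihood and ascertainment

The estimation unit is the *proband unit*: an ordered (proband with the
syndrome, co-twin) pair. A pair ascertained through both members
contributes two units; a triplet proband with two co-twins contributes two
units. The likelihood for *k* concordant of *n* units is binomial with
success probability C(*r*): conditioning on the proband's affection is the
ascertainment correction, and it uses exactly the information a
probandwise concordance table carries. Full contingency-table likelihoods
would need the count of unaffected pairs, which proband-ascertained
designs do not observe; they are deliberately not implemented.

The ACE decomposition maximises ℓMZ(*a*² + *c*²) + ℓDZ(½ *a*² + *c*²)
over the simplex {*a*², *c*² ≥ 0, *a*² + *c*² ≤ 1}. Boundary solutions are
genuine maximum-likelihood answers (no concordant MZ pairs ⇒ *a*² = 0
exactly) and are flagged rather than smoothed. Dominance (ADE), sex
limitation and between-sample heterogeneity submodels are out of scope.

## Numerical choices

- **Bivariate-normal upper tail**: the single-integral identity with the
  ρ = sin θ substitution, integrated by a fixed 96-point Gauss–Legendre
  rule. The transformed integrand is analytic on the closed interval, so
  the rule is accurate to ~1e-15 (verified against independent 2-D
  quadrature and scipy's MVN CDF); endpoints r = ±1 use closed forms.
- **Tetrachoric search**: bounded scalar minimisation on r ∈ [−0.99, 0.999]
  (open at ±1 to keep the likelihood finite when 0 < k < n), xatol 1e-10;
  boundary-adjacent optima are snapped and flagged. k = n is reported as
  r = 1 (C(1) = 1).
- **ACE optimisation**: Nelder–Mead from five fixed starts on the simplex;
  estimates below 1e-7 whose boundary value is at least as likely are
  snapped to 0. Agreement with a dense independent grid search (step
  0.005) is part of the test suite.
- **Profile CIs**: the set {θ : 2[ℓmax − ℓ(θ)] ≤ 3.841} found by bisection,
  profiling the other variance share where applicable. When k = 0 the
  profile set reaches the lower search edge and the lower limit is
  reported as *not applicable* — the convention degenerate tables are
  printed with. Wald intervals around raw concordances are likewise
  degenerate (zero-width, flagged) at k ∈ {0, n}; an exact binomial option
  is not substituted because the normal-approximation interval is the
  stated method.
- **Mixed logistic models**: random-intercept marginal likelihoods are
  integrated by adaptive Gauss–Hermite quadrature (default 21 nodes; 1
  node = Laplace). Each group's integrand is re-centred at its posterior
  mode (vectorised Newton — the integrand is log-concave so this is
  globally convergent) and scaled by local curvature. Two grouping factors
  are treated as nested (pair within sample; pairs never span samples),
  with an adaptive outer integral. Variance components are optimised on
  the standard-deviation scale with a zero lower bound; when the variance
  estimate hits zero the model collapses to plain logistic and those exact
  estimates are returned. Fixed-effect SEs come from a finite-difference
  Hessian, dropping boundary variance rows. The implementation is
  cross-checked against lme4's `glmer` (nAGQ-matched) in the test suite.
- **Logistic regression** is IRLS via statsmodels GLM behind the package's
  interface, wrapped with explicit degenerate-outcome, rank-deficiency and
  separation detection (diverging estimates / pinned fitted probabilities
  raise a `SeparationError` naming the offending column; no Firth-type
  penalisation is applied).
- **Covariate coding**: co-twin sex F = 0 / M = 1; co-twin age at last
  information centred and scaled to decades, so its odds ratio is per
  decade of age.
- **BH-FDR**: the step-up procedure with adjusted p-values
  min over j ≥ rank of (m·p(j)/j), clamped at 1, so rejection ⇔ adjusted
  p ≤ q; q defaults to 0.05.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, plus the
features of ascertained clinical twin samples that exercise every code
path: proband ascertainment with doubly-ascertained pairs, an optional
triplet, multi-syndrome co-occurrence, and sex/age covariates.

Per pair, liabilities over (members × the three syndrome dimensions) are
drawn from a zero-mean MVN assembled from ACE components —
Σ = a²(M ⊗ R) + c²(J ⊗ I) + e²I, with M the member matrix (zygosity
factor off-diagonal), R the within-person cross-dimension correlation and
J all-ones — which is positive semi-definite by construction and gives
cross-twin same-dimension correlations of exactly a² + c² (MZ) and
½a² + c² (DZ). An individual is affected on a dimension iff liability plus
the additive covariate shift exceeds t. Affected individuals receive the
dimension's core symptoms: both with probability `theta_both`, else one at
random — so the broad syndrome coincides with dimension affection
(population risk exactly K) and the narrow syndrome has risk
K·`theta_both`. Ascertainment flags each affected individual as a proband
independently with probability π and keeps pairs with ≥ 1 proband.

Reference defaults, chosen once as the package's study conditions:
a² = 0.81 (a realistic narrow-positive-syndrome heritability on the
liability scale), c² = 0, K = 0.01 per dimension (the order of magnitude
of lifetime schizophrenia morbid risk), 5 000 population pairs per
zygosity, π = 0.9 (systematic ascertainment with doubly-ascertained pairs
present), `theta_both` = 0.5, R off-diagonal 0.4 (moderate syndrome
co-occurrence), no covariate effects (β_sex = β_age = 0), ages uniform on
20–70 years with twins sharing age, DZ sexes independent fair coin flips.
Calibration and recovery analyses use `theta_both` = 1 so that the
analysed narrow phenotype coincides with dimension affection and its
population risk equals the generative K.

The `two_pathway` preset encodes the hypothesis that delusions and
hallucinations arising *without* disorganisation carry more environmental
influence: each pair belongs to a high-heritability pathway (probability
`mix_weight`, positive-dimension a² = `a2_high`, positive cases also carry
disorganised symptoms) or a low-heritability pathway (`a2_low`, positive
cases without them). The coupling mechanism is the generator's own choice —
only the directional consequence (lower MZ concordance for positive cases
without disorganisation) is asserted, not a particular effect size.

What the generator does **not** emulate — so what passing tests do *not*
establish about real data: diagnostic measurement error and rater
disagreement, age-of-onset/censoring processes (affection is a lifetime
state), dominance or assortative mating, informative missingness of
symptom ratings (simulated ratings are complete; missingness handling is
exercised by hand-built fixtures), and real sampling frames (ascertainment
is an idealised per-individual Bernoulli).

## Statistical behaviour worth knowing

- **Probandwise double-entry and regression models.** Units from a doubly
  ascertained pair are *always* concordant by construction (both members
  must carry the syndrome for both units to exist), so multi-unit pair
  clusters carry deterministic duplicate outcomes. Two consequences,
  both verified empirically: the plain logistic Wald test on probandwise
  units is anticonservative in proportion to the duplicated fraction; and
  a pair-level random intercept is not identified from such clusters — its
  variance estimate diverges (lme4 behaves identically). Type-I
  calibration of the zygosity test is therefore demonstrated in the
  near-single-ascertainment regime (π small), where essentially every pair
  contributes one unit; the calibration study in the test suite uses
  π = 0.05 with 20 000 population pairs per zygosity over 2 000 replicate
  cohorts. The pair random effect remains the right tool where clusters
  carry non-deterministic repeated outcomes (triplets, pooled designs),
  and the sample random intercept is well identified whenever multiple
  samples are pooled.
- **Missingness is conservative.** Syndromes whose truth value depends on
  a missing symptom are *indeterminate* under Kleene logic; indeterminate
  co-twins leave the concordance denominator (complete-case), and
  indeterminate probands contribute no units. Nothing is imputed.
- **Problem sizes.** Simulation-based checks use cohorts of 20 000–100 000
  population pairs and 3–5 seeds for recovery, and 2 000 replicates for
  calibration; these sizes put Monte-Carlo error comfortably inside the
  asserted tolerances.

## Known limitations and source-data caveats

- Published headline estimates for the real twin samples this workflow
  targets (e.g. MZ concordances near 40%, h² ≈ 0.81) are not reproducible
  without the pair-level records and the unpublished per-syndrome morbid
  risks; the package reproduces the *methods* and verifies them on
  synthetic data and in-text worked examples (such as the 0/8-concordant
  boundary case).
- One published report of this design prints an abstract confidence
  interval (1.04–1.54) inconsistent with the same quantity in its results
  text (1.04–11.54); neither is reproducible without raw data. The
  discrepancy is noted here so users comparing outputs are not misled.
- Whether historical analyses retained pairs with unknown co-twin symptom
  status is not documented; the complete-case rule is this package's
  decision, logged per syndrome at run time.
- The GLMM implements random intercepts only; random slopes and crossed
  (non-nested) designs are out of scope.
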