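# Methods

This note documents the models and procedures `gcsimpute` implements,
the design decisions taken where the design was genuinely open, and
what results on synthetic cohorts do and do not demonstrate.

## The problem

Outcome models after traumatic brain injury adjust for baseline injury
severity through the Glasgow Coma Scale (GCS, 3–15, sum of eye 1–4,
verbal 1–5 and motor 1–6 responses), its motor component alone (GCSm),
and pupil reactivity (coded as the number of pupils unreactive to
light, 0–2; more unreactive = worse).  These are recorded at up to four
early time points — pre-hospital, arrival at a referring hospital's ED
(secondary transfers only), arrival at the study hospital's ED, and ED
discharge ("post-stabilisation") — with different reliability and
missingness at each, and the verbal (intubation) and motor
(sedation/paralysis) components may be untestable.  The package
compares ways of producing one baseline value per patient and measures
the downstream consequences for outcome-model fit.

## Substitution strategies and sub-score policies

Five strategies produce a derived baseline per variable:
sequential fallbacks `impact` (ed_disch → study_arr → ref_arr → preh),
`tarn` (ref_arr → study_arr → preh) and `erasmus` (study_arr →
ref_arr → preh), and the extrema `best` / `worst` over all available
time points (for pupils, best = fewest unreactive).  Sub-score
policies handle unavailable verbal/motor components when forming the
sum: `nc_if_either`, `nc_if_m_v1` (NC only if motor missing,
substitute verbal = 1), `nc_if_v_m1`, and `both_1`; for the motor
score, `nc_if_m` and `m_1`.  Substituted components contribute exactly
1; a missing eye component always makes the sum not calculable.

Open points resolved as package design choices:

* the policy is applied per time point *before* the strategy fallback,
  so a not-calculable time point is skipped rather than terminating
  the search (required for policy choice to change missingness under a
  fixed strategy);
* `best`/`worst` select each variable independently across time
  points, the only reading consistent with per-variable availability;
  ties break toward the later time point so the source distribution is
  deterministic (the tie does not affect the value);
* for non-transferred patients the `tarn` order is study_arr → preh
  (the referring slot does not exist);
* untestable and simply not-recorded components are pooled for policy
  application but kept distinguishable in the data (flag columns; the
  CSV writes untestable cells as `UT`);
* a time point with pupils recorded but a not-calculable GCS is
  skipped in `best`/`worst` GCS selection;
* severity bands are fixed at severe 3–8 / moderate 9–12 / mild 13–15.

## Chained-equations imputation

`mice` produces M completed datasets.  Each starts from an independent
random fill drawn from the observed marginals, then runs a fixed
number of sweeps (default 5) over the variables in a fixed visit
order: covariates (glucose, haemoglobin, EDH, tSAH, Marshall), then
per-time-point assessment scores, then GOSE at 3, 6 and 12 months.
Defaults are M = 200 and 5 sweeps; tests and the acceptance script run
M = 20 at n = 2000, the package's desk-scale conditions.

Conditional models and their posterior draws:

* **gaussian_linear** (glucose, haemoglobin): Bayesian linear
  regression with the standard conjugate draw — residual variance from
  a scaled inverse-chi-square at the least-squares fit, coefficients
  from their conditional normal, imputations from the predictive
  normal.
* **binary_logistic** (EDH, tSAH): logistic MLE; parameters drawn from
  a normal approximation at the MLE (inverse observed information);
  imputations Bernoulli.
* **ordinal_proportional_odds** (Marshall 1–6, GOSE 1–8, GCS sum
  3–15, GCSm 1–6, pupils 0–2): cumulative-logit MLE; the same normal
  approximation; category draws from the predictive distribution,
  restricted to the observed category support.  Cutpoints are drawn in
  their natural space; a draw with non-monotone cutpoints is redrawn
  (up to 8 times) and finally isotonised with a tiny epsilon — at the
  fitted information this is rare.

Missing hypoxia and hypotension are defaulted to "absent" before
imputation; age must be complete.  3- and 12-month GOSE serve as
mutual auxiliaries with the 6-month outcome (the direction of
auxiliary use is not uniquely determined; mutual imputation is the
symmetric choice).  GCS is imputed on the sum scale (13 ordinal
categories), not component-wise.  Referring-ED assessments are imputed
only within the secondary-transfer subset and are never predictors of
other variables.  Patients with no GOSE at any follow-up are kept
during imputation and deleted afterwards from every completed dataset.

Conditional fits that fail, fail to converge, or show separation are
retried through a ridge schedule (penalties 1.0 then 10.0 on the slope
block only) before raising; small strata subsets make separation
likely, and the mild penalty is documented here as the stabilisation
mechanism.

## Outcome models and McFadden pseudo-R²

Survival (GOSE ≥ 2 vs GOSE = 1) is modelled by logistic regression and
the full ordinal GOSE by proportional-odds regression, both on age,
glucose, haemoglobin, Marshall (as an ordered numeric term), tSAH and
EDH plus one candidate GCS-type variable (linear numeric) and one
pupil variable.  Hypoxia and hypotension enter the imputation but not
the outcome models by default (a flag includes them).  Both fitters
are full-Newton maximum likelihood with analytic Hessians, converging
at 1e-8 relative log-likelihood change; cutpoints are kept strictly
increasing; empty outcome categories are collapsed before ordinal
fitting.  The fitters are cross-checked in the test suite against
statsmodels and against a grid-search maximiser, and the two-category
proportional-odds fit reproduces the logistic fit analytically.

McFadden's pseudo-R² is `1 − logL(model)/logL(null)` with the null
being intercept-only (logistic) or cutpoints-only (proportional odds).
One fit per completed dataset yields an M-vector of R² values; the
distribution (median, quartiles, extremes) is the reported quantity.
R² values are never Rubin-pooled; Rubin's rules are available for
coefficients only.  Residual missingness in a derived candidate is
handled by per-model complete-case deletion — substitution is being
evaluated as-is, without further imputation of the candidate.

## Synthetic cohort generator

A latent severity score S ~ N(0, 1) per patient (higher = worse)
drives every correlated feature:

* **Assessments.** Latent neuro state at time point t (0-based):
  x_t = −S + drift·t + ε_t, ε_t ~ N(0, σ_t²) with σ = (1.0, 0.6, 0.5,
  0.4) — pre-hospital least reliable — and drift = 0.15 per time point
  (resuscitation improves the latent state).  Components are
  thresholds of x_t plus per-patient component offsets (SD 0.3), so
  E/V/M are correlated but not collinear, and with zero noise and
  drift all time points reproduce identical components.  Pupils
  threshold S − drift·t with noise proportional to the same σ_t
  (assessment reliability applies to the whole neurological exam).
* **Stratum and transfer.** ED / hospital / ICU admission from
  severity plus noise (SD 0.8), thresholded at the mixture quantiles
  (defaults 0.25 / 0.275 / 0.475; the ICU share matches the roughly
  half-ICU composition of large European TBI registries); secondary
  transfer is Bernoulli(0.30), independent.
* **Covariates.** Age 45 ± 20 (complete, uncorrelated with severity by
  default), glucose 7.5 ± 2.5 mmol/L (loading +0.8·S), haemoglobin
  13.5 ± 1.8 g/dL (−0.5·S), Marshall class a 6-category threshold of
  S + noise, and logistic links in S for tSAH, EDH, hypoxia and
  hypotension.  These marginals are field-plausible placeholders, not
  calibrated to any specific registry (the registry's own
  characteristics are published separately and access-controlled).
* **Outcomes.** GOSE at 6 months from a proportional-odds model:
  latent u = −(1.6·S + 0.5·age_z + 0.15·glu_z − 0.15·hb_z +
  0.2·(Marshall−2) + 0.3·tSAH − 0.2·EDH + 0.3·hypoxia +
  0.4·hypotension) + logistic noise, cut at seven thresholds (≈12%
  mortality, ≈47% ICU share at defaults).  The 3- and 12-month scores
  are noisy ordinal copies of the same linear predictor shifted by a
  recovery drift (±0.3), giving the auxiliary-variable imputation real
  signal.  No absorbing-death consistency is enforced across
  follow-ups (a known simplification).
* **Untestability.** Intubation (masks verbal) and sedation/paralysis
  (masks motor) are Bernoulli with logistic links non-decreasing in
  severity, drawn independently at each recorded time point.
* **Missingness.** An assessment is documented or not as a whole: one
  MAR draw per patient and time point masks all four cells together,
  with probabilities (0.35, 0.12, 0.08, 0.05) decreasing along the
  care pathway (documentation improves from scene to discharge;
  per-cell marginals equal these values exactly).  Covariates and GOSE
  have per-variable probabilities; stratum, transfer, untestability
  flags and age are never masked.  The mechanism depends only on fully
  observed fields, so the imputation's MAR assumption holds by
  construction; an MNAR severity-shift switch exists for sensitivity
  work and defaults off.

What the generator does *not* emulate: real pre-hospital physiology
(hypoxia/hypotension are correlated with severity, not causal
confounders of the GCS), informative untestability beyond the severity
link, inter-rater GCS error structure, centre effects, and real
registry marginals.  Passing tests therefore demonstrate that the
pipeline's machinery behaves correctly and that its qualitative
contrasts (time-point reliability ordering, strategy missingness
orderings, all-strata vs ICU performance) follow from the stated
construction — not that any particular strategy is optimal on real
TBI data.

## Numerical choices

* Convergence: 1e-8 relative (penalised) log-likelihood change,
  maximum 200 Newton iterations with step-halving; proportional-odds
  steps that break cutpoint monotonicity are halved.
* Separation: flagged when a slope exceeds 12 in absolute value or the
  fit fails to converge; the ridge schedule (0, 1, 10) then applies.
* Probabilities are floored at 1e-300 inside ordinal likelihoods;
  category-probability rows are exact simplexes by construction.
* Determinism: every stage seeds `numpy.random.default_rng` from the
  configured seed plus a fixed stage tag; the M imputation streams are
  spawned from a `SeedSequence`, so results are bit-reproducible for a
  given configuration on a given platform.
* Tiny negative pseudo-R² from finite tolerances (|R²| < 1e-10) is
  clamped to exactly 0.

## Scale of the shipped experiments

Tests and the acceptance script run n = 2000 patients with M = 20
imputations and 5 sweeps, and the time-point comparison averages 10
independent seeds; these are the package's desk-scale study
conditions.  M = 200 (the library default) reproduces the same
qualitative orderings with tighter R² distributions.

## Known limitations

* The proportional-odds posterior approximation (normal at the MLE) is
  asymptotic; with very sparse categories the ridge fallback perturbs
  the draw slightly.
* GCS sum imputation on the sum scale cannot reconstruct component
  patterns; component-wise imputation is out of scope.
* The presenting-ED vs ED-discharge R² difference is small by
  construction (adjacent reliability levels) and model-dependent;
  only the pre-hospital deficit and the seed-averaged logistic
  ordering are stable findings at desk scale.
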