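# Methods

This note documents the models, the synthetic-data generator, the estimation
machinery, and the numerical and design choices behind `patfit`.

## 1. Study design

The quantity of interest is the effect of a father's age at an offspring's
birth on that offspring's evolutionary fitness, proxied by survival, marriage
and completed number of children.  Naive (between-family) regressions of
offspring outcomes on paternal age are confounded: families that reproduce
late differ in wealth, social position and standing genetic load.  The design
implemented here compares **full siblings**, who share both parents: paternal
age is decomposed into the family mean `ā_f` (between) and each anchor's
deviation `a_i − ā_f` (within), and only the within coefficient is interpreted
causally.  Grandpaternal ages support an analogous cousin comparison within
extended families.

Outcomes are organized as **selective episodes**: e1 survival of the first
year, e2 survival to the 15th birthday given e1, e3 ever marrying given e2,
e4 number of children given e3 (with number of spouses as a covariate), and e5
divorce given e3 where a divorce flag exists.  Reproductive success as the
headline outcome uses *all* anchors, coding those who died young or never
married as zeros; the hurdle-Poisson family separates that zero process from
the positive counts.

## 2. Synthetic pedigrees

The generator emulates the family structure and vital-rate regime of four
populations through presets whose paternal/maternal age means and sds,
sex-specific infant mortality, and married-female completed fertility
(mean and sd) are transcribed from the study populations' descriptive
statistics.  Juvenile mortality (1–15) and the probability of ever marrying
are not published in that table and are set to regime-typical values
(historical populations: 0.10–0.15 and 0.80–0.90; twentieth-century Sweden:
0.004 and 0.70).  These two rates only shift episode baselines; no calibration
target depends on them.

Generative flow, one seeded `numpy` generator throughout:

* **Founder couples.**  Father birth years uniform over the preset window
  shifted by the mean paternal age.  A fraction (default 0.3) of founder
  fathers are brothers sharing a generation-0 grandfather, creating cousin
  groups; each founder mother gets her own grandfather stub, so both
  grandpaternal ages are derivable.
* **Paternal ages.**  Each child's paternal age is an iid draw from a
  truncated normal on [15, 80] whose underlying parameters are solved (2-d
  root finding on the truncated moments) so the *realized* mean and sd equal
  the preset exactly; naive truncation would bias the mean upward by more
  than the Monte-Carlo error at the scales used.  Children are ordered by
  paternal age (birth order).  The within-family age span is capped at 34
  years by a symmetric squeeze about the family mid-range (mean-preserving for
  normal draws) so the single mother's reproductive span stays in [15, 50].
  Within-family birth spacing is therefore not calibrated to observed
  inter-birth intervals — only the marginal paternal-age distribution is.
* **Maternal ages.**  One mother per family; her birth year is the father's
  plus a gap drawn around the preset difference in mean parental ages (sd 3),
  clipped to keep her fertile span feasible.  Maternal age thus moves in
  lockstep with paternal age within a family — as in real sibships — which is
  why the analysis bins maternal age rather than entering it linearly.
* **Mutation load.**  Child *i* receives `M_i ~ Poisson(c₃₀ + m·(a_i − 30))`
  mutations (defaults c₃₀ = 60, m = 2/yr, mean floored at 0.1).  Relative
  fitness is `w_i = (1 − s̄)^{M_i}` (default s̄ = 0.004), partitioned
  multiplicatively across episodes with weights (0.5, 0.1, 0.4) on infant
  survival, juvenile survival and fertility — the generative model is not
  published, and the partition default echoes the observed pattern that
  infant survival and reproduction carry most of the effect.  Because the
  partition weights sum to 1, the expected total effect on reproductive
  success is `E[(1−s̄)^{ΔM}] = exp(−s̄·2·10) ≈ (1−s̄)^{20}` per decade
  (−7.7% at defaults), which is the analytic truth used by the recovery tests.
* **Fertility.**  Completed fertility of married women must match both the
  preset mean and sd.  Over-dispersed presets use a family-level gamma
  frailty with a conditional Poisson (marginal: negative binomial with the
  preset moments); the under-dispersed twentieth-century preset uses a
  moment-matched binomial.  Two *independent* frailties are drawn per family —
  one for the founders' sibship size, one shared by the anchors' own
  fertility — because a single shared frailty would size-bias the anchors'
  fertility mean above the preset (large sibships contribute more anchors).
  The shared anchor frailty is what the family random intercept captures.
* **Confounding (optional).**  A log-normal family quality `Q_f` (sd
  `confounder_sd`, mean 1) multiplies episode success probabilities (√Q) and
  fertility (Q).  With `confounder_timing_coupling = κ ≠ 0`, every paternal
  age in family *f* is shifted by `κ·z_f` years (z the standardized
  log-quality): high-quality families reproduce later, so the naive
  between-family estimate is biased upward while the within-family estimate
  is not.
* **Trisomy stand-ins (optional).**  With `maternal_age_effect = r`, anchors
  of mothers 35+ become, with probability r, zero-fertility and
  halved-survival cases, supporting the robustness variant that excludes
  them.
* **Vital events.**  Infant deaths at uniform(0,1) years, juvenile deaths at
  uniform(1,15), adult deaths at uniform(45,90); founder deaths after their
  last birth; 3% of adult death years missing (exercising the "unknown"
  parental-loss bin).  Marriages at ~N(25,4) years of age, 10% remarry.
  Generation-3 individuals are identity-and-parent-link stubs: the analysis
  needs anchors' child counts, not their life histories.  Divorce is not
  generated, so e5 is structurally missing in synthetic data.

What passing tests on these pedigrees shows: the estimator recovers known
within-family effects under realistic family structure, censoring-free
observation, and family-level confounding.  What they cannot show: robustness
to migration, record linkage error, unrecorded infant deaths, parish-level
heterogeneity or secular trends, none of which are simulated.

## 3. Estimation

All families except the Gaussian one are fitted by the package's own engine:

* **Marginal likelihood.**  The family random intercept is integrated out by
  adaptive Gauss–Hermite quadrature: each family's integrand is re-centered
  at its posterior mode (damped, step-capped Newton, vectorized across
  families) and re-scaled by the local curvature.  Default 21 nodes; two
  random effects (intercept + paternal-age slope) use a product grid capped
  at 9 nodes per dimension.  Against a dense-grid trapezoid oracle the
  relative error is below 1e-8 on small instances for all families.
* **Score.**  The gradient of the marginal log likelihood is the posterior
  expectation of the complete-data score, evaluated with the same nodes —
  no finite differences during optimization.
* **Priors / MAP.**  Weakly informative defaults: Normal(0, 2.5) on
  coefficients of internally standardized predictors, Normal(0, 10) on the
  intercept, half-Normal(1) on σ_f (maximized in log σ with the Jacobian, so
  the estimate stays off the boundary).  A "tight" set (1.0/5/0.5) and flat
  priors (≈ maximum likelihood) are available; with flat priors and no group
  term the estimates match an ordinary GLM to 1e-6.
* **Optimization.**  Models without random effects use penalized Newton with
  the closed-form Hessian (falling back to L-BFGS if the cauchit link's
  non-concavity bites); mixed models use L-BFGS with warm-started family
  modes.  Internal column standardization conditions the problem.
* **Intervals.**  Normal (Laplace) approximation from the inverse Hessian of
  the penalized objective at the MAP — analytic for fixed-effect models,
  forward-difference of the analytic score otherwise.  Reported intervals are
  ±1.96 se; the null-calibration test shows ~95% empirical coverage.  A full
  MCMC backend (for posterior-median effect sizes) would satisfy the same
  contracts but is not bundled.
* **Hurdle factorization.**  The hurdle-Poisson likelihood separates exactly
  into a Bernoulli model for clearing the hurdle (any children) and a
  zero-truncated Poisson for positive counts.  The hurdle part uses a logit
  link, carries the same fixed-effect design including the paternal-age
  terms, and no random effect; the count part carries the family intercept.
  This choice lets the response-scale effect capture the survival/marriage
  channel as well as the fertility channel.
* **Gaussian variant.**  The normal-outcome robustness variant is ordinary
  least squares with family-clustered (sandwich) standard errors — a standard
  step delegated to statsmodels; a random-intercept LMM adds nothing for a
  robustness check and is less stable under the battery's collinear designs.
* **Model comparison.**  Exact K-fold (default 10) cross-validation by
  family: held-out families' *marginal* log predictive density, elpd standard
  errors over families, pairwise contrasts against the best model.

## 4. Effect sizes

`per_decade_effect` reports the percentage change in the model-expected
outcome for a 10-year within-family increase in paternal age, other covariates
at their mean (continuous) or reference (categorical) level and the family
mean at its sample average, random effects at zero.  For a single log-link
part this is exactly `(exp(10β_w) − 1)·100` with endpoints transformed from
the coefficient interval; for hurdle (and any multi-part or non-log) models
the point is the plug-in response ratio and the interval comes from 4,000
seeded draws of the Laplace normal approximation.  `episode_contrast` applies
the same machinery to absolute ages (default 25 vs 35).
`marginal_effect_curve` evaluates a spline model over an age grid with a 95%
band and overlays a straight line fitted through the curve weighted by inverse
squared standard errors — a visual linearity check.

The spline is a natural-cubic basis on quantile knots (default df 8) with the
span of {1, age} regressed out on the fitting data, making the smooth
identifiable next to the intercept and the linear term; the residualization
coefficients are stored so the basis evaluates consistently at new ages.

## 5. Model set and robustness battery

m1 (linear paternal age, no family term), m2 (family term, no paternal age),
m3 (both; the baseline), m4 (m3 + spline).  The battery perturbs m3:

| variant | change |
|---|---|
| r2 | birth cohort as the only covariate |
| r3 | continuous birth order instead of binned order + born-last |
| r4 | dependent siblings (younger than 5, alive at anchor's birth) instead of birth order |
| r5 | continuous birth order × sibship size interaction |
| r6 | no birth-order adjustment |
| r7 | parental loss only in the first 5 years (binary) |
| r8 | first-/last-born adult son indicators |
| r9 | thin-plate-style smooth of birth year instead of 5-year bins |
| r10 | family random slope for paternal age (diagonal intercept+slope) |
| r11 | grouping by father instead of by couple |
| r12 | sex main effect and sex × paternal-age moderation |
| r13 | father's age at his first recorded birth as a covariate |
| r14 | per-family fixed effects instead of the random intercept |
| r17 | trisomy-like cases excluded (needs the simulator truth table) |
| r18 | hurdle-Poisson and Poisson families swapped |
| r19 | Gaussian outcome (OLS, family-clustered errors) |
| r20 | no maternal-age adjustment |
| r21 | maternal age continuous instead of binned |
| r23 | tighter weakly informative priors |
| r24 | flat priors (≈ ML) |
| r26 | separate parental-age contributions: continuous maternal dev + family mean + teen-mother indicator |

Notes.  r11 on synthetic data coincides with m3 re-grouped by father because
all simulated sibships are full sibships; truly crossed parental effects are
not implemented.  r14 refits on an evenly spaced family subsample (default cap
1,000 families) when the input is larger: per-family indicator designs make
each Newton step cubic in the number of families, and a robustness check does
not need the full sample's precision.  r21/r26 are only weakly identified on
synthetic data because maternal and paternal age differences coincide exactly
within families — their intervals are correspondingly wide, which is the
honest answer the real analyses faced in the pre-industrial populations.
Variants tied to unsimulated data features (relaxed exclusions on raw
registers, region/parish moderation, migration status) are not supported and
are rejected by the configuration check.

## 6. Mutation calibration

Forward: an assumed mean selective cost per mutation s̄ and slope m
mutations/year imply a per-decade fitness effect `(1−s̄)^{10m} − 1`.
Inverse: a fitted per-decade effect is compounded over
`(reference mutations)/(slope)/10` decades (30 years at 60 mutations and
2/year), giving the fitness decline from one generation's full mutation
complement — the child of an average 30-year-old father versus a hypothetical
mutation-free father.  The two maps are exact inverses up to the exponent:
`decline(predicted(s̄, 2)) = 1 − (1−s̄)⁶⁰`.  The parameter-space scan tabulates
U·s̄ products, per-decade effects, and 25-vs-35 infant-survival contrasts
under a configurable infancy share (default 0.5), flagging the published
non-synonymous U·s̄ band (0.016–0.031).  Because paternal age predicts rather
than equals the mutation count, a paternal-age-based estimate should sit
slightly below U·s̄; the scan reports, and does not enforce, that ordering.

The compounding formula reproduces the worked value 0.20 for a −7.3%/decade
effect; applied to the other populations' point estimates it yields values
that differ from some published roundings (e.g. 0.099 where 0.14 is printed),
presumably because those were computed from unrounded model internals.  The
formula here is documented and fixed; no attempt is made to reverse-engineer
the other printed values.

## 7. Scales used by the verification suite

Simulation sizes in the test suite were chosen so the whole run stays at desk
scale: preset-calibration checks use 20,000–25,000 families (Monte-Carlo
standard errors small enough to resolve the published descriptives, with a
family-cluster-robust SE for the frailty-correlated fertility outcome);
parameter recovery uses 20 replicates of 5,000 families; null interval
calibration uses 100 replicates of 2,000 families; the sign-flip scenario
uses 20 replicates of 5,000 families with s̄ = 0.006, quality sd 0.15 and
timing coupling 8 years/sd — the selection strength sits at the upper end of
the plausible range so that the within-family effect (−11.3% per decade
analytically) is unambiguous relative to the estimator's sampling noise at
that scale, while the coupling produces the clearly positive naive estimate
that defines the scenario.  The battery truth-tracking check runs the full
battery on two independent 3,000-family simulations and requires every
variant's interval to cover the analytic truth in at least one — a variant
that systematically diverges fails in both, while one unlucky joint draw of a
single dataset does not.

## 8. Known limitations

* No censoring, migration or record-quality processes; completeness filters
  are exercised structurally, not against realistic missingness.
* The hurdle part's family effect is omitted by default (option available in
  the engine); under strong family-level confounding of survival this leaves
  mild population-averaging attenuation in the hurdle channel.
* Divorce (e5) and region moderation exist in the schema but not in the
  generator.
* MAP + Laplace intervals are asymptotic; at very small family counts
  (< ~300) they can undercover, and the MCMC-backend contract is unfilled.
* The simulator's within-family age spacing and the marriage market are
  deliberately unrealistic simplifications (iid sorted ages; spouses outside
  the pedigree).
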