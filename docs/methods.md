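# Methods

## Model

The population moves on three states: 1 = free of cognitive impairment
(CI-free), 2 = cognitively impaired (CI), 3 = dead. Allowed transitions are
1→2 (onset), 1→3 (mortality while CI-free) and 2→3 (mortality with CI);
recovery 2→1 is structurally excluded, so any observed recovery must be a
recording error and is handled at preparation time (below). The process is
a continuous-time Markov chain whose intensities are log-linear in age
(Gompertz-type) with proportional covariate effects:

    q_rs(a, x) = exp( β0_rs + βage_rs · (a − a_ref) + β_rs' x )

Age is the only time scale; there are no period or cohort effects. The
reference age `a_ref` (default 80) only centres the baseline for numerical
conditioning. Setting `age_effect=False` gives age-constant intensities,
for which every formula below is exact rather than piecewise. As a
sensitivity alternative to the log-linear form, `age_bands` fits a
step-function age effect instead: knot ages (typically every 5 years)
split age into bands and each transition gets one log-intensity offset per
band above the first.

A "Cox proportional hazards model with rates constant across observed
intervals" — the usual verbal description of this kind of panel analysis —
is realised here as this parametric proportional-intensity model: a
semiparametric partial likelihood is not computable from interval-censored
panel states, and the log-linear age effect is its standard parametric
counterpart.

## Transition probabilities

Over an age interval the 3×3 transition matrix P(a0, a1) is built from
pieces of at most `piece_step` years (default 0.25). Within a piece the
generator is frozen at the piece midpoint and the constant-rate closed form
applied:

    P11 = exp(−(q12+q13)Δ)
    P22 = exp(−q23Δ)
    P12 = q12 (e^{−(q12+q13)Δ} − e^{−q23Δ}) / (q23 − q12 − q13)

with the analytic limit `q12·Δ·e^{−q23Δ}` when |q23 − q12 − q13| < 1e−8
(the two-exponential form loses all precision there). Pieces compose by
matrix multiplication (Chapman–Kolmogorov). The midpoint freeze makes the
discretisation error O(step²) per interval; halving the step moves
probabilities by < 1e−4 at default settings (tested). Probabilities are
clipped into [0,1] only within 1e−12; anything worse raises a numeric
failure rather than being silently repaired.

The closed form is checked against two independent oracles — scipy's
matrix exponential and high-resolution integration of the Kolmogorov
forward equations dP/dt = PQ — to 1e−8 over random rate draws. Near the
degenerate ray q23 ≈ q12 + q13 the generator is almost defective and the
Padé-based matrix exponential itself degrades, so there only the ODE oracle
is used.

## Likelihood

Each subject contributes a product over consecutive *known* states:

- living pair (s at t0, s′ at t1): P_{ss′}(t0, t1) — onset between waves is
  thereby interval-censored automatically;
- exactly observed death at t after last known living state s at t0:
  Σ_{r∈{1,2}} P_{sr}(t0, t) · q_{r3}(t), with the intensity evaluated at
  the death age (left limit), the standard convention for exactly observed
  absorbing times;
- right censoring (alive at t1, state unknown): Σ_r P_{sr}(t0, t1).

Missing living states between two known states contribute nothing — the
bridging interval spans them — and a final missing living state becomes a
right-censoring contribution. A zero-probability path yields −∞ with a
warning rather than an exception so optimizers can back away from it.

Post-stratification weights enter as frequency weights multiplying each
subject's log-likelihood. The covariance is the inverse observed
information (numerically differentiated Hessian, `statsmodels`'s
`approx_hess`), not sandwich-corrected; with informative weights the
reported standard errors are therefore approximate. A sandwich correction
would be the natural extension.

Fitting is quasi-Newton (BFGS) with finite-difference gradients on the
*mean* log-likelihood (per unit weight), which keeps gradient tolerances
scale-free. Start values are crude occurrence/exposure rates (observed
direct transitions over person-years, with a 0.5 continuity add) and zero
age/covariate effects. A transition with no directly observed events is
flagged non-identified and its standard error reported as undefined. Fits
are deterministic given data and settings.

## Life table

State-occupancy curves P_{1r}(a0, u) and P_{22}(a0, u) are propagated cell
by cell over a uniform age grid (default: monthly steps to age 110) and
integrated by the trapezoidal rule:

    CIFLE = e11 = ∫ P11 du,   CILE = e12 = ∫ P12 du,   TLE = e11 + e12

so TLE = CIFLE + CILE holds exactly by construction. The probability still
alive at the grid's maximum age (truncation mass) is reported; above 1e−3
it warns, above 0.05 it raises — raise the maximum age instead of accepting
a visibly truncated expectancy. Monthly trapezoids keep the quadrature
error far below the 0.1-year reporting precision (halving the step moves
expectancies by < 0.01 y, tested; constant-rate closed forms are matched
to 0.1%).

Adjusted expectancies are computed at a stated covariate profile (exposure
set to each level, confounders at reference values). Because expectancies
are linear in the occupancy curves, `averaged_expectancies` alternatively
averages over an observed confounder distribution; which of the two an
analysis uses is an explicit choice in the calling code, since "after
adjustment" is ambiguous between them.

## Comparisons and classification

Differences (comparison minus reference) in TLE, CIFLE and the percentage
of remaining life CI-free get 95% percentile bootstrap intervals:
subjects are resampled with replacement — implemented as multinomial
frequency weights on the compiled panel, which is equivalent and avoids
recompiling per replicate — the model is refit warm-started at the point
estimate, and expectancies are recomputed. Percentile (not BCa) intervals
are used; the replicate count defaults to 500. Failed replicates are
dropped and counted; more than 10% failures flags the result unreliable.
Weights can be recomputed per replicate through a callback.

The change classification is one deterministic rule (`classify_change`),
chosen so that it reproduces the published classifications of every
comparison whose direction the source study's results state, and kept in a
single function so alternative rules can be swapped:

1. if the CI of Δproportion lies below 0 → **relative reduction**;
2. else if the CI of ΔCIFLE lies above 0 and ΔCILE < 0 (impaired years do
   not grow — every gained year is CI-free) → **absolute increase**;
3. else if the CI of ΔCIFLE lies above 0, ΔCILE ≥ 0, and the CI of
   Δproportion lies above 0 → **relative increase**;
4. else **no change**.

The sign of ΔCILE = ΔTLE − ΔCIFLE is the discriminator between absolute
and relative gains; ties (ΔCILE = 0 at printed precision) fall to the
proportion criterion. Swapping the comparison direction can never classify
both directions as gains, nor both as reductions (property-tested).

## Synthetic cohorts

The generator emulates the design of a longitudinal survey of Chinese
oldest-old and defines the conditions under which the machinery is
validated:

- entry ages 65–105, drawn from bands (65–80, 80–90, 90–100, 100–105) with
  weights (0.30, 0.30, 0.30, 0.10) — the designed oversampling of the
  oldest old that the post-stratification weights exist to correct;
- waves at 0, 3, 6, 9, 12 years after entry (three-yearly spacing over a
  twelve-year window); deaths within the window recorded with exact ages;
  survivors right-censored at their last wave;
- each living wave observation after baseline is missing with probability
  0.05 (baseline is known by design);
- administrative horizon at age 110;
- default truth: baselines at age 80 of 0.050/y (onset), 0.041/y (CI-free
  mortality), 0.135/y (mortality with CI) with age slopes 0.08, 0.09,
  0.07 per year — mortality roughly doubling every 8–10 years, plausible
  for this population — and a binary exposure with hazard ratio 1.5 on
  onset, prevalence 0.5.

Simulation is exact (competing exponentials) when intensities are
age-constant; with age effects the hazard is frozen over 0.25-year steps
(midpoint), an O(step) scheme that the occupancy-recovery tests bound in
practice. The generator emits states directly; cMMSE score classification
is tested on explicit score fixtures instead, so item-level response
generation is out of scope.

What the generator does *not* emulate: irregular wave participation
(dropout is approximated by right censoring at the last emitted wave, and
is non-informative by construction), covariate missingness (synthetic
covariates are complete; imputation is therefore untestable and excluded),
misclassification of cognitive states, and time-varying covariates.
Passing recovery tests shows the estimator is correct under these
conditions; it cannot show robustness to informative dropout or
state misclassification in real data.

## Preparation rules

- cMMSE scores map to states by education-specific cutoffs: ≤17 CI for no
  formal schooling, ≤20 for 1–6 years, ≤24 for 7+ years; a missing score
  is a missing state. "Unable to answer" items are assumed already scored
  incorrect upstream of the final score.
- Diet is healthy iff at least three of fruit, green leafy vegetables,
  legumes, fish are consumed at least weekly.
- Risk profiles count three protective components — never smoking *and*
  healthy diet; in marriage; any of four leisure activities — mapping
  0,1,2,3 components to high, medium-high, medium-low, low risk.
- Observed recoveries are censored, not overwritten: the offending later
  CI-free observation is set to missing, which discards the contradiction
  without fabricating a CI state. (Recoding to CI would be the other
  defensible reading; censoring is the more conservative one.)
- Subjects with a missing baseline state are excluded with a logged count.
  Covariate missingness is not imputed; subjects must arrive complete.
- Weighting strata default to 5-year age bands 65–99 plus 100+, crossed
  with sex and residence, matching census tabulation granularity. Weights
  are target/sample proportion ratios normalised to mean 1.
- Sensitivity filters remove subjects with CI at the first follow-up
  observation and/or death within one year of baseline, for
  reverse-causation checks.

## Validation experiment sizes

The acceptance checks run at these scales, chosen to give stable
statistics at desk scale: 1,000 random rate draws for the
transition-probability oracles; 100 rate triples for the constant-rate
closed forms; 100 replicates of n = 3,000 (4 waves) for Wald coverage;
one cohort of n = 10,000 followed from 65 to 110 for end-to-end expectancy
recovery (tolerance three Monte-Carlo standard errors of the truth-table
means); 50 repetitions at B = 200 and n = 500 for the bootstrap null
(B scaled down from the 500 used for reported intervals — the null
coverage check needs repetitions more than replicate resolution).

## Known limitations

- No hidden-Markov misclassification layer: states are taken at face
  value. Sparse observed recoveries are censored instead.
- No sandwich covariance under informative weights.
- Percentile bootstrap only; BCa would need jackknife acceleration.
- The piecewise-constant simulation and likelihood share the same
  freezing idea but not the same grid, so their discretisation errors do
  not cancel; both are driven well below statistical error at defaults.
- Expectancies truncate at the grid maximum (default 110); the truncation
  mass is reported rather than extrapolated.
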