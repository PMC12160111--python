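# Methods

## The model

A day is a four-part composition **x** = (SB, LPA, MVPA, sleep) in minutes,
carrying only relative information once closed to the 1440-minute day.
Compositions are mapped to three unconstrained coordinates by the isometric
log-ratio (ilr) transform built from a sequential binary partition (SBP):
the first split isolates one behaviour against the other three, the second
splits the remaining three, the third splits the last pair.  For a partition
row with r parts in the numerator group and s in the denominator group the
balance coefficients are +sqrt(s/(r(r+s))) and −sqrt(r/(s(r+s))); stacking
the three rows gives a 4×3 contrast matrix V with orthonormal, zero-sum
columns, and ilr(x) = ln(x)·V.  With the pivot-first partition,

    ilr1 = sqrt(3/4) · ln( x1 / (x2·x3·x4)^(1/3) ),

i.e. the pivot behaviour relative to the geometric mean of the rest.  The
partition is rotated four times so that each behaviour takes the x1 role;
the four fits are exact linear reparameterisations of one another (tested),
but rotation makes each behaviour's "relative to the rest" coefficient
directly readable.

Day-level coordinates are decomposed into a between-person part (the
participant's mean coordinate vector, which equals the ilr of their
compositional centre) and a within-person part (the day's mean-centred
deviation).  The affect model for each outcome (happiness, anxiousness,
tiredness, each a 0–10 daily mean of up to three EMA responses) is a
Gaussian random-intercept regression at the participant-day level:

    y_pd = α + β_B·ilrB_p + β_W·ilrW_pd + γ·covariates_p + u_p + ε_pd,
    u_p ~ N(0, τ²),  ε_pd ~ N(0, σ²).

Life satisfaction (one 0–10 rating per participant) is modelled
cross-sectionally by OLS on the between-person coordinates only.  Both
models are fitted unadjusted and adjusted for age band, gender, ethnicity
(multi-select indicators, most frequent category as reference) and
deprivation decile (numeric, 1–10).

Isotemporal substitution moves δ ∈ {5, 10, 15, 20} minutes from a donor
behaviour to a recipient starting at the sample's closed *arithmetic*-mean
composition.  Per posterior draw the predicted outcome difference is
β·(ilr(reallocated) − ilr(reference)) using the exact ilr of the perturbed
composition — no linearisation — and the 95% interval is the 2.5/97.5
percentile of those draws.  The arithmetic mean is used as reference
because the geometric-mean MVPA (~8 min) cannot donate 10–20 minutes; the
arithmetic mean (~21 min) supports the full 12-pair grid.  Infeasible cells
are emitted explicitly, never dropped.  Between-level substitutions perturb
the person-mean coordinates with within terms at zero; within-level
substitutions perturb the deviations.  Covariates cancel in the difference
for this linear model.

## Inference

No Hamiltonian-Monte-Carlo backend is assumed: the affect model's posterior
is simulated by a blocked Gibbs sampler written for exactly this model
class.  Priors are weakly informative — Normal(0, 10) on the intercept and
all regression coefficients, half-Student-t(3, 0, 5) on both standard
deviations.  The half-t priors enter through their inverse-gamma mixture
representation (Huang–Wand), so every full conditional is closed-form:
(β, u) are drawn jointly from their exact multivariate-normal conditional
(joint blocking removes the mixing bottleneck between person-level
predictors and random intercepts), then σ², τ² and the two mixture
auxiliaries from inverse-gamma conditionals.  Defaults: 4 chains × 1000
warmup + 1000 kept draws.  Split-R̂ and bulk ESS are computed per parameter
with ArviZ; a fit raises if any R̂ exceeds 1.01 (gate switchable for
deliberately short diagnostic runs).  On the default synthetic cohort the
sampler reaches R̂ < 1.005 and ESS > 1500 in seconds, so the full-size
parameter-recovery checks run inside the ordinary test suite.

Because rows are sorted internally and chain seeds derive from a single
`SeedSequence`, fits are invariant to input row order and exactly
reproducible at a fixed seed.

## Zero imputation

MVPA below the detection limit (default 1 min/day, the instrument's day
resolution) may be recorded as zero.  Zeros are treated as censored and
imputed by expectation–maximisation on additive log-ratio coordinates
(reference = the part with fewest zeros): the E-step replaces each censored
coordinate with the conditional expectation of a normal truncated above
the limit's log-ratio given the row's observed coordinates; the M-step
re-estimates the coordinate mean and covariance; iteration stops when
parameters change by less than 1e-6 (max 100 iterations).  Imputed minutes
are clipped into (0, limit) and the observed parts of each row are rescaled
so the row still closes to 1440 — observed values are never altered beyond
this re-closure.  Tables with fewer than 10 rows fall back to multiplicative
replacement at 0.65 × limit: a 3-dimensional log-ratio covariance cannot be
estimated stably from fewer complete rows, and the truncated-normal E-step
then wanders far from any defensible value.  Multiplicative replacement is
also shipped as the package's independent reference implementation and is
cross-checked against scikit-bio's in the tests.

Day-level missingness (whole days absent) is handled by exclusion, not
imputation; only within-row rounded zeros are imputed.

## The synthetic cohort

The generator emulates the study conditions the pipeline assumes:

| parameter | default | rationale |
|---|---|---|
| participants × days | 211 × 7 | cohort size and wear protocol |
| population composition | (682, 278, 8, 471) min | sample compositional centre |
| between-person ilr SDs | (0.25, 0.25, 1.4) | see below |
| within-person ilr SDs | (0.15, 0.2, 1.4) | see below |
| affect means (happy/anx/tired) | 7.05 / 2.43 / 4.29 | observed day-level means |
| β_B happiness | (−1.54, 0.5, 0.15) | adjusted between-person scale |
| β_B anxiousness | (1.89, 0.0, −0.30) | adjusted between-person scale |
| β_B tiredness | (−0.88, 0.54, −0.24) | adjusted between-person scale |
| β_W (all affects) | (0, 0, 0) | no within effects detected at this design |
| person-intercept SD / residual SD | 1.5 / 1.2 | reproduces 0–10 score spreads ~2.3–2.8 |
| prompts/day, response prob. | 3, 0.4 | ~8 answered prompts per person-week |
| life-satisfaction effect | null, mean 7.28, SD 1.9 | cross-sectional null at this n |
| compliance mixture | 50% low-wear (90% exceedance) / 50% good (30%) | ~55% survive the filters with ~4.5–4.9 valid days |

Compositions are logistic-normal: person-mean ilr vectors scatter around
the population coordinates, day vectors around the person mean, and both
map back through the inverse ilr — the conjugate structure to the analysis
model.  The third-coordinate SDs (MVPA vs sleep balance) are wide (1.4 per
level) so that the arithmetic mean of MVPA sits near 21 min/day while its
geometric mean stays near 8 — the signature divergence of a strongly
right-skewed MVPA distribution — and so that 20-minute MVPA donations are
feasible from the arithmetic-mean reference.  Affect scores are clamped to
[0, 10] and rounded to one decimal like a slider response; intercepts are
chosen so the population-mean latent affect equals the target mean at the
population composition.  Non-wear minutes come from a two-class compliance
mixture (gamma-distributed, mostly < 30 min on good days, > 121 min on
exceedance days).  An optional censoring switch records MVPA below the
detection limit as 0 to exercise the imputation path.

What the generator does *not* emulate: accelerometer measurement error and
the raw-signal classifier, day-of-week and diurnal affect structure,
serial correlation across days, informative (affect-dependent) EMA
non-response, correlated covariates, and any real within-person effect of
behaviour on affect (the within coefficients default to zero and are
generator parameters, not estimates).  Passing recovery tests therefore
show that the pipeline estimates what this data-generating process encodes
— not that the cohort's published coefficients are reproduced, which is
impossible without the restricted data.

## Numerical choices and degenerate inputs

- Closure tolerance 1e-9; orthonormality of generated bases holds to 1e-12;
  ilr round-trips to 1e-10 (all asserted in tests).
- Non-positive parts are rejected with a message directing to imputation;
  compositions whose raw parts sum elsewhere than 1440 are re-closed, not
  rejected (wear time varies).
- A day with non-wear of exactly 120 min is valid (the rule is strictly
  greater than two hours); a participant with exactly 2 valid days is
  retained.
- More than 3 EMA responses in a person-day raises (protocol violation).
- Zero-variance predictors (e.g. an all-equal composition) raise with the
  column named rather than producing a silently singular fit.
- Substitution with δ = 0 returns an exact 0 with a (0, 0) interval; a
  donor that would be driven non-positive raises with its reference
  minutes; the reporting layout shows the diagonal as "Not Applicable".
- Posterior intervals are equal-tailed percentile intervals; significance
  means the 95% interval excludes zero (affects), p < 0.05 (OLS).

## Problem sizes used in the checks

The default test suite runs the full-size scenario (211 × 7) once for the
decomposition and recovery checks, a 20-replicate coverage study at n = 60
with 2 × 500 kept draws, and small fixtures everywhere else; the whole
suite completes in well under a minute on one core because the Gibbs
sampler is vectorised over its sufficient statistics.  The acceptance
script regenerates a full-size cohort and refits from scratch at the
default 4 × 1000 sampler settings.

## Known limitations

- The Gaussian likelihood ignores the boundedness of the 0–10 scores;
  clamping in the generator mildly attenuates recovered coefficients at
  extreme means (visible only as z-scores well inside the 2-SD band).
- The EM imputation conditions on each row's observed reference part when
  setting the censoring threshold, a standard approximation; imputed MVPA
  below 1 min pulls the sample geometric mean of MVPA below the population
  value — a faithful consequence of genuinely tiny censored values.
- Within-person substitution tables are computed with the same reference
  composition as the between-person tables.
- No random slopes, autocorrelation, ordinal likelihoods or model
  comparison; deciles enter linearly.
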