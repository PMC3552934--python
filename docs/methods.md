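# Methods

## Model

Subjects fall into G groups ordered a priori by expected exposure.  For
subject *i* of group *g*:

- true exposure: X_gi ~ N(μ_g, σ_b²), with μ₁ ≤ … ≤ μ_G;
- observed exposure: W_gi = X_gi + η_gi, η_gi ~ N(0, σ_η²) — classical,
  non-differential, mutually independent error;
- outcome: Y_gi = β₀ + β₁X_gi + ε_gi with ε_gi ~ N(0, σ_ε²) (linear family),
  or Y_gi | X_gi ~ Bernoulli(expit(β₀ + β₁X_gi)) (logistic family).

Outcomes are observed for everyone; W may be missing completely at random
for part of the subjects, so the missingness mechanism is ignorable and
never modelled.  Exposures are assumed normal on the analysis scale —
log-transform upstream for log-normal concentrations.  σ_η² is treated as
known throughout: with one measurement per subject it is not separable from
σ_b², so it must come from external replicate studies or be swept over a
sensitivity grid (`fit --sensitivity`, or refitting in a loop).

One notational point: the residual outcome variance is written σ_ε²
everywhere; it plays the role sometimes denoted σ_θ² in expected
log-likelihood expressions — a single `sigma_eps2` field represents it.

## Estimators

**Naive.** Complete-case ML regression of Y on W (statsmodels OLS/Logit).
Under classical error the linear slope estimates λβ₁ with
λ = var(X)/var(W) = (σ_b² + var_g(μ))/(σ_b² + var_g(μ) + σ_η²); at the
default simulation design λ ≈ 0.61, i.e. ≈ 39–40% attenuation.

**GBS / CGBS.** Each subject receives their group's observed-exposure sample
mean as a score (GBS), or the weighted isotonic projection of those means
(CGBS; weights = observed sample sizes), followed by a standard regression
of *all* outcomes on the scores.  The isotonic projection is computed by
pool-adjacent-violators: scan left to right, pool any adjacent strict
decrease into a block carrying the weighted block average, back-merging as
needed.  Ties are not pooled (they already satisfy the constraint; the
least-squares solution is identical either way).  Zero-weight (unmeasured)
groups are an error for GBS/CGBS — there is nothing to assign — while CEM
handles them through the prior.  Reported SEs from these fits are flagged
`se_inflated`: by treating all group members as observed at one exposure
value, the model-based SE absorbs within-group exposure variability.

**CEM.** Maximum likelihood under the full model by EM, treating X (and the
unobserved W* of missing-exposure records) as latent.

- *E-step, linear family (exact).*  X | (y, w) is normal with precision
  1/σ_b² + 1/σ_η² + β₁²/σ_ε² and mean the precision-weighted combination of
  μ_g, w and (y − β₀)/β₁.  For records with missing exposure,
  (X*, W*) | y* is bivariate normal with common mean
  (σ_ε²μ_g + β₁σ_b²(y*−β₀))/(σ_ε² + β₁²σ_b²); W* only adds measurement
  noise, so its terms are constant in every estimated parameter and drop
  from the optimization.
- *E-step, logistic family (Monte Carlo).*  Self-normalized importance
  sampling per record: proposal = the Gaussian "prior × measurement"
  posterior N((σ_b²w + σ_η²μ_g)/(σ_b²+σ_η²), σ_b²σ_η²/(σ_b²+σ_η²)) for
  observed records (exact when β₁ = 0) and the group prior N(μ_g, σ_b²) for
  missing records, with Bernoulli outcome likelihood as weight.  The
  effective sample size is monitored per record; falling below the floor
  (default 20) triggers escalation to the final draw count.
- *M-step (alternating, constrained).*  First the group means: per-group
  averages of E[X] over all records, isotonized by the same weighted PAVA
  with total group counts as weights (all records inform E[X], measured or
  not).  Then σ_b² ← mean E[(X−μ_g)²]; then the outcome parameters — normal
  equations in (E[X], E[X²]) and σ_ε² ← mean E[(Y−β₀−β₁X)²] for the linear
  family, Newton iterations on the importance-weighted expected Bernoulli
  log-likelihood for the logistic family.  Each block update increases the
  expected complete-data log-likelihood, so the procedure is a generalized
  EM and the observed-data log-likelihood ascends (exactly, for the linear
  family — this is asserted in the tests).
- *Initialization.*  Naive regression estimates for β; observed group means
  (PAVA-projected if constrained) for μ; pooled within-group variance of W
  minus σ_η², floored at 1e−4, for σ_b²; naive residual variance for σ_ε².
- *Convergence.*  Maximum relative parameter change below tol (1e−5 linear;
  1e−3 logistic, the Monte-Carlo noise floor), assessed on parameters
  averaged over the last 5 iterations for the logistic family; max_iter 500.
  Draws escalate from 200 to 2000 per record after iteration 20.  For the
  logistic family the returned estimate is the average over the last
  smoothing window — standard damping of MC jitter; with fixed draw counts
  the iteration never settles below that jitter, so non-convergence at
  max_iter is reported on the result rather than raised.
- *Standard errors.*  Empirical information: per-subject observed-data
  scores via Fisher's identity (conditional expectations of the
  complete-data scores, reusing the E-step machinery), centered outer
  products summed and inverted.  On a single small dataset this fluctuates
  around the numeric observed information by O_p(n^{−1/2}) — agreement is
  within ~5% on average from roughly 60–100 subjects per group, verified
  against a finite-difference Hessian of the observed-data log-likelihood.

## Simulation engine

`Scenario` defaults are the study conditions of the bias experiment: G = 5,
n_y = 30 subjects per group, μ_g = 0.2 + (g−1)δ with δ = 0.3, σ_b² = 0.6,
σ_η² = 0.5, β₀ = −2, β₁ = 0.3 (disease risk ≈ 12% in the logistic case),
200 replications.  σ_ε² = 1.0 for the linear family — the slope's *relative*
bias is insensitive to it, since it scales outcome noise, not attenuation.
The grid spans δ ∈ {0.3, 0.5}, σ_b² ∈ {0.3, 0.6, 0.9},
σ_η² ∈ {0.25, 0.5, 0.75} and n_x ∈ {10, 20, 30}.  Every replication
regenerates the dataset and its MCAR missingness pattern from a seed derived
deterministically from (scenario seed, cell index, replication index) via
`numpy.random.SeedSequence`.  Replications where a fit fails (logistic
separation, detected as diverging ML estimates; non-convergence) are dropped
and counted.  "Bias" is 100·(mean(β̂₁) − β₁)/β₁; MSE is on the raw β̂₁
scale; a Monte-Carlo SE of the bias accompanies every cell.

What the generator emulates: normal within-group exposures, classical
additive error, MCAR subsampling of measurements, linear/logistic outcomes.
What it does not: repeated measurements per subject, heterogeneous
between-subject variances across groups, non-normal or time-varying
exposure, differential or correlated error, informative missingness.
Passing tests therefore certify the estimators under the stated model, not
robustness to those violations.

`generate_carbonblack_like` builds a purely synthetic cohort shaped like an
8-job-category occupational study (published group sizes 245…53, mean
spacing 0.36, σ_b² = 0.41, σ_η² = 0.92) for integration tests and examples;
it does not reproduce any real-data estimate.

## Numerical and design notes

- The closed-form posterior of X given (y, w) is implemented in the
  standard precision-weighted form and verified against brute-force
  quadrature to 1e−6; likewise the bivariate missing-record posterior
  (2-D quadrature, 1e−5) and the linear observed-data likelihood
  (closed bivariate-normal form vs Gauss–Hermite quadrature, 1e−8).
- PAVA is hand-implemented (it is the core primitive); tests cross-check it
  against exhaustive max-min block enumeration, an exact partition-
  enumeration QP oracle, and scikit-learn's weighted isotonic regression.
- Variance updates are floored at 1e−8 to survive degenerate noiseless
  inputs; the σ_b² initialization floor is 1e−4 (method-of-moments starts
  can go negative when σ_η² is large).
- Logistic M-step Newton steps are clipped at ±5 per coordinate; a singular
  Hessian raises rather than silently stalling.
- Group labels are 1-based everywhere at the interface, matching how
  exposure categories are numbered in practice.

## Known limitations

- **Group-score bias is a heavy-tailed statistic.**  When the observed group
  means are noisy enough that isotonization pools them into nearly flat
  scores, the fitted slope becomes near-unidentified and single
  replications can produce extreme values; the replication-mean bias of
  GBS/CGBS then moves by several percentage points between seeds even at
  200 replications.  The reported Monte-Carlo SEs make this visible; read
  small printed bias differences between group-score methods with that SE
  in hand.
- Small-sample logistic ML is itself biased away from the null (≈ +4% for
  the slope at 150 subjects with ~12% prevalence, measured by regressing on
  the *true* exposures).  CEM removes attenuation but inherits this
  finite-sample bias; no Firth-type correction is applied.
- σ_η² is never estimated; a misstated value propagates directly into the
  slope (see `examples/sensitivity_to_error_variance.py`).
- The acceptance script runs the logistic EM cell with 1000 final draws
  per record and 150 EM iterations (the linear cells use full defaults);
  every cell uses the study's 200 replications.
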