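# semieco

Constrained estimation of exposure–disease associations in **semi-ecological
studies**: designs where health outcomes are ascertained for every subject but
exposure is measured with error — and often only for a subsample — at the
level of ordered groups (job categories, work areas, exposure zones).

## The problem and the estimators

For subject *i* of group *g* the observed exposure follows a classical
measurement-error model

```
W_gi = X_gi + η_gi ,   X_gi ~ N(μ_g, σ_b²),   η_gi ~ N(0, σ_η²),
```

with ordered group means μ₁ ≤ … ≤ μ_G, and the outcome follows a linear
(`Y = β₀ + β₁X + ε`, ε ~ N(0, σ_ε²)) or logistic
(`P(Y=1|X) = expit(β₀ + β₁X)`) model.  Exposure may be missing completely at
random for part of the subjects; outcomes are never missing.  Naively
regressing Y on W attenuates the slope by the reliability ratio
λ = var(X)/var(W).

The package implements four estimators of (β₀, β₁):

- **naive** — complete-case regression of Y on W, ignoring the error;
- **GBS** (group-based strategy) — every subject is assigned the sample mean
  of the observed exposures in their group (single imputation) before a
  standard regression;
- **CGBS** — GBS after projecting the observed group means onto the known
  ordering by **weighted isotonic regression** (pool-adjacent-violators, with
  the observed sample sizes as weights), correcting order reversals caused by
  small measurement campaigns;
- **CEM** — a constrained (Monte-Carlo) EM that treats the true exposures as
  latent: closed-form normal E-step for the linear family, importance-sampled
  E-step for the logistic family, and an M-step whose group-mean update is
  isotonized by the same weighted PAVA.  Standard errors come from the
  empirical (Meilijson) information matrix.  The error variance σ_η² is a
  required *known* input (it is not identifiable from single measurements);
  a sensitivity grid is supported.

A simulation engine reproduces the bias study that motivates all of this:
G = 5 groups of n_y = 30 subjects, μ_g = 0.2 + (g−1)δ, β₀ = −2, β₁ = 0.3,
with n_x ≤ 30 exposures measured per group.

## Worked example

`python examples/isotonize_group_means.py`:

```
observed group means : [0.7755, 0.6229, 1.8207, 2.2878, 1.7054]
observed sample sizes: [4, 3, 5, 3, 4]
isotonized scores    : [0.7101, 0.7101, 1.8207, 1.955, 1.955]
pooled blocks (0-based index ranges): [(0, 1), (2, 2), (3, 4)]
```

Groups 1–2 and 4–5 violated the hypothesized increasing order; each pooled
score is the sample-size-weighted mean of its block, and the weighted total
exposure is conserved.

`python examples/fit_four_estimators.py` simulates one cohort (true slope
0.3, error variance 0.5, 10 of 30 exposures measured per group) and prints:

```
method    beta1_hat  se(beta1)  notes
naive        0.2559     0.1169  complete cases, error ignored
gbs          0.2187     0.1253  raw group means (SE inflated)
cgbs         0.2187     0.1253  isotonized group means (SE inflated)
cem          0.3215     0.1418  converged=True after 77 iterations
```

The naive and group-score slopes are attenuated toward the null; CEM models
the latent exposure and lands nearest the truth, with a model-based SE that
is not inflated by within-group exposure variability.  A single dataset is
noisy — `examples/bias_experiment.py` runs the replicated comparison, and
`examples/sensitivity_to_error_variance.py` shows the σ_η² sensitivity grid.

## Command line

```
semieco isotonize means.csv
semieco fit --method cem --family linear --sigma-eta2 0.5 --in data.csv --out result.csv
semieco simulate --config grid.yaml --out bias_table.csv
```

Datasets are CSV with header `group,y,w` (1-based ordered group index; empty
`w` = missing).  All randomness flows from `--seed`.

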