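# Methods note

This note documents the statistical model, its assumptions and parameters,
the synthetic-data generator and its realism limits, the numerical choices,
and the known limitations of `fibresub`.

## 1. Two-part habitual-intake model

Let `Y_ij` be person *i*'s intake of the quantity of interest (grams of a
bread category, total bread grams, or fibre grams) on recall day
*j = 1 … n_i* (`n_i` = 2 in the default survey design). Habitual intake is
the long-run mean `E[Y_i]`, which two recall days cannot estimate directly.
Following the two-part tradition of the Multiple Source Method and the NCI
method, the model factorizes habitual intake as

```
habitual_i = P(consume on a day)_i × E[amount | consumption day]_i
```

### Part 1 — consumption probability

The day-level indicator `1{Y_ij > 0}` is regressed (linear probability
model, least squares) on person-level covariates (age group, sex) plus the
person's observed reporting frequency; the fitted person value is clipped to
[0, 1]. Because every regressor is person-constant, the projection
reproduces each person's observed reporting frequency exactly; the covariate
structure matters only when the model is extended with day-level regressors.

### Part 2 — consumption-day amount

Positive-day amounts are transformed, `z_ij = g(y_ij)` with `g = log1p` by
default (`identity` and Box–Cox are available). Covariate fixed effects are
removed by OLS, and the residual variance is decomposed by unbalanced
one-way method-of-moments ANOVA on the person grouping into between-person
`σ²_b` and within-person `σ²_w` components (a negative moment estimate of
`σ²_b` is clipped to zero). Each person's residual mean `r̄_i` is shrunk
toward its covariate prediction with

```
λ_i = σ²_b / (σ²_b + σ²_w / n_i)
```

so the transformed-scale usual level is `μ_i = x_i'β + λ_i r̄_i`.

### Mean-consistent back-transform

Two sources of transformed-scale dispersion must be integrated out for the
original-scale population mean to be preserved:

1. **Day-to-day noise** — Duan-type smearing over the pooled within-person
   residual deviations. Observed deviations carry only `(1 − 1/n_i)` of
   `σ²_w`, so each person's deviations are rescaled by `sqrt(n_i/(n_i−1))`
   before pooling. The pool is summarized by a deterministic 128-point
   quantile sketch (memory bound, no randomness).
2. **Post-shrinkage person-effect uncertainty** — shrinkage removes
   `Var(b_i | r̄_i) = (1 − λ_i)·σ²_b` of person-level variance. This is
   restored by 11-node Gauss–Hermite quadrature over a normal person effect.

The usual consumption-day amount is the double average
`mean_{a,k} g⁻¹(μ_i + q_a + s_k)`, floored at zero. For log-type transforms
under normality this reproduces the closed-form lognormal mean exactly; for
the identity transform both corrections vanish by linearity. Plain pooled
smearing was rejected because it splits the lognormal factor
`exp(λr̄)·exp((1−λ)r̄)` across independent averages, losing the covariance
term `exp(λ(1−λ)·Var(r̄))` — about a 10% downward bias at the default survey
calibration; the estimator above is within 1% on the same fixture.

Two exact limits are enforced by tests: with zero within-person variance the
estimates equal the observed values (to 1e-9), and with shrinkage off the
estimator reduces to the observed consumption-day mean.

### Assumptions

- Recall days are exchangeable given the person (no day-of-week effects).
- Covariates are person-constant; amount residuals are additive on the
  transformed scale with homoscedastic within-person noise.
- The person effect is approximately normal on the transformed scale (used
  only by the Gauss–Hermite variance-restoration step).
- Probability and amount parts are fitted independently (no shared random
  effect between the parts).

## 2. Synthetic cohort generator

Daily consumption of each bread category is zero-inflated log-normal: a
Bernoulli consumption indicator per (person, day, category) and, on
consumption days, `log(amount) = μ_stratum + σ_b·b_i + σ_w·e_ij` with
standard-normal person and day effects. Person-level heterogeneity in the
probability part comes from a latent Gaussian propensity passed through a
logistic link; the intercept of that link is calibrated by Gauss–Hermite
quadrature (41 nodes) and Brent root-finding so that the *marginal*
consumption probability equals the configured preference exactly — the
configured value is what a large sample reproduces, not a heuristic input.

### Calibration to the reference survey

Per (age group, sex, category) stratum, the published tabulation reports the
share `q` of participants with no reported intake in either recall and the
stratum-mean daily contribution `C` (g/day). Under independent recall days,
the daily consumption probability solves `(1 − p)² = q`; the consumption-day
mean is `M = C / p`; and the log-normal location is
`μ = ln M − (σ²_b + σ²_w)/2` so that `E[amount] = M`. Default log-scale SDs
are `σ_b = 0.40`, `σ_w = 0.50`. These choices reproduce the published
per-stratum "mean intake among reporters" to about 1%.

**Event-count realism.** The generator records at most one event per
(person, day, category), whereas real recalls log every eating occasion.
With the calibrated probabilities a 1,345-person cohort produces ≈ 1,746
expected events, not the ≈ 3,045 *entries* of the reference survey. A
separate `occasion_matched_cohort_config` scales the probabilities so the
expected event count matches 3,045 (used where the entry count itself is the
quantity of interest); the calibrated config remains the default study
condition because it preserves the non-reporter and contribution margins.

Adolescents carry missing values for education, employment and smoking,
mirroring the survey design. Bread-sample fibre values are truncated-normal
draws per category; a frozen 29-sample bakery "wholegrain" fixture (mean
4.57, SD 1.21 g/100 g, exactly 3 samples at/above the threshold) ships with
the package for the reclassification analyses.

## 3. Wholegrain fibre threshold

```
T = (p·F_wg + (1 − p)·F_w) / (1 + w)
```

with defaults `p = 0.8` (regulatory minimum wholegrain-flour share),
`F_wg = 10.6` and `F_w = 2.7` g fibre /100 g flour, and `w = 0.7` g water per
g flour (maximal practical dough hydration), giving `T = 5.3059` g/100 g.
The boundary is inclusive. Retail-labelled wholegrain is trusted;
small-bakery "wholegrain" below `T` is reclassified as mixed.

## 4. Substitution scenarios

A scenario replaces fraction `r` of the mass of every white-wheat event by
wholegrain (event mass conserved); scenarios A and B use `r = 0.3` and
`r = 0.5`. The full pipeline is re-run on the substituted events, so deltas
include all model nonlinearity. In the no-noise limit the per-person delta
has the closed form `r · W · (f_wg − f_ww)/100` for constant daily intake
`W`, which the tests verify to 1e-9 against a brute-force event-level
oracle.

## 5. Adaptive LASSO

The determinants analysis solves

```
min_β  (1/2n)·‖y − Xβ‖² + λ·Σ_j w_j·|β_j|,   w_j = 1/|β_init,j|^γ,  γ = 1
```

by cyclic coordinate descent (convergence when the largest coefficient
change in a sweep is below 1e-7), on columns standardized to unit variance,
with `β_init` from OLS (ridge fallback when singular or `n ≤ p`; zero
initial coefficients are capped at weight 1e12). The penalty path is 50
geometrically spaced values from the analytic null threshold
`max_j |x_j'y/n|/w_j` down by a factor 1e-3, warm-started; `λ` is chosen by
K = 10-fold cross-validation with the one-standard-error rule. Response:
per-person habitual bread fibre density (g fibre /100 g bread). Factors
undefined for adolescents (education, employment, smoking) are assessed in a
second fit on the adult subsample. The solver is validated against the
orthonormal soft-threshold closed form, an L-BFGS-B split-variable QP
oracle, and scikit-learn's `Lasso` via penalty-weight rescaling.

## 6. Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence` spawn streams
  (persons / events / samples are independent substreams), so results are
  identical across platforms for a given seed; derived seeds stay below 2³¹.
- Variance decomposition uses the unbalanced method-of-moments `n₀`
  correction; SDs are `ddof = 1` (undefined for n = 1 and reported as NaN).
- Presentation rounding is half-away-from-zero, matching how survey tables
  are printed (`round_half_away`), while all computation is full precision.
- CSVs round-trip exactly (`float_precision="round_trip"` on read).
- PNGs are written without software metadata; the pipeline manifest hashes
  the text artifacts (SHA-256) and normalizes the output directory, so two
  same-seed runs give byte-identical manifests anywhere.
- Parameter-recovery test design: 2,000 persons, two recall days and a 1:1
  between:within variance ratio with `σ_b = σ_w = 0.35` and certain daily
  consumption. With two days and a 1:1 ratio, roughly half of the observed
  person-mean signal is noise, so the attainable correlation between
  estimated and true habitual intake is bounded well below 1; at this
  calibration it is ≈ 0.94 (larger log-scale variances or episodic
  consumption push it below 0.9 for purely design reasons, not estimator
  defects).

## 7. Limitations

- The habitual model is a transparent reimplementation of the two-part
  shrinkage idea, not a port of any specific proprietary program; no
  bit-compatibility with external MSM/NCI software is claimed.
- The linear probability model for part 1 is exact only because regressors
  are person-level; day-level covariates would require a logistic part.
- The generator's one-event-per-day-and-category cap understates occasion
  counts (see §2); occasion-level realism is out of scope.
- Substitution scenarios change bread composition only; energy balance,
  displacement of other foods and behavioural responses are not modelled.
- The 1-SE adaptive LASSO is conservative but not immune to a stray spurious
  level under pure noise; selection results should be read at the variable,
  not the coefficient, level.
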