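# Methods

## Data-generating model

A cohort of `n` individuals has four covariate/outcome blocks:

- **sex** ~ Bernoulli(0.5), coded 0 = male, 1 = female;
- **maternal education** (`mumed`) in {0 = O-level/lower, 1 = A-level,
  2 = degree+} with probabilities (0.5, 0.25, 0.25);
- **breastfeeding duration** (`bf`) in {0 = never/<1 month, 1 = 1–<3 months,
  2 = 3–<6 months, 3 = 6+ months}, conditional on education with rows
  (0.5, 0.15, 0.15, 0.2), (0.3, 0.1, 0.2, 0.4), (0.15, 0.1, 0.15, 0.6) —
  longer breastfeeding with higher education. The implied marginal is
  (0.3625, 0.125, 0.1625, 0.35);
- the **outcome** ("IQ") is linear in sex, education and breastfeeding
  dummies with coefficients β = (−0.4, −0.1, 0.4, 0.8, 0.1, 0.2, 0.3) plus
  N(0, σ²) noise; the **proxy** ("KS4") is ρ·IQ plus N(0, φ²) noise, with
  optional direct sex/education effects for sensitivity analyses.

Everything is in SD units: σ² and φ² are solved *exactly* so that both the
outcome and the proxy have variance 1. The solver enumerates the 24-cell
joint covariate distribution (sex independent of the education×breastfeeding
pair) and computes the linear predictor's first two moments from it; at the
defaults σ² = 0.83875 (Var of the predictor 0.16125), E[predictor] = 0, and
φ² = 1 − ρ². When the proxy has direct covariate effects, φ² additionally
subtracts the covariate-part variance and twice its covariance with ρ·IQ,
again from the exact table, so Var(KS4) = 1 whatever the effects — i.e. the
proxy is re-standardised after adding covariate effects.

Covariates are sampled by inverse-CDF on uniforms from one RNG stream, so a
single seed determines a whole cohort.

## Missingness mechanisms

Outcome observation follows an identity-link (linear-probability) model with
fixed covariate coefficients γ₁…γ₆ = (0.04, 0.075, 0.10, 0.08, 0.12, 0.14),
an outcome slope γ₇ (0 for MAR; 0.05/0.1/0.2 for MNAR), and optional
exposure-by-outcome interaction slopes (γ₈, 2γ₈, 3γ₈) with γ₈ = −0.025 —
the outcome slope is 0.1 in the never-breastfed group and drops by 0.025 per
category. Identity link means predictions can leave [0, 1]: a negative
prediction is missing with certainty (this is part of the mechanism, and the
count of such individuals is a reported diagnostic), a prediction above 1 is
observed with certainty (the only behaviour consistent with a probability —
the discussion of truncation in the source design covers only the negative
side), and otherwise a Bernoulli draw decides.

**Intercept calibration.** The starting value
α₀ = (1 − target missing) − E[non-intercept terms] is exact (covariate terms
from the 24-cell table; E[IQ] from the outcome model; interaction
expectations E[bf_k·IQ] = E[bf_k·linear predictor]). If no prediction is
truncated at α₀, α₀ is returned as-is. Otherwise Brent root-finding adjusts α
against the *expected* missing fraction mean(1 − clip(raw, 0, 1)) on a fixed
calibration cohort of n = 10⁶ drawn from a stream independent of the
analysis replicates; the expectation is deterministic in α (piecewise linear
and monotone, so the root is unique) and already includes the deterministic
missingness from negative predictions. The calibration tolerance is 0.002;
at n = 10⁶ the residual sampling error in the calibration cohort is an order
of magnitude below that. α is fixed once per mechanism (it does not depend
on ρ or on the proxy factor), so the 100 scenarios need 20 calibrations.

Proxy missingness is Pr(observed) = clip(π + δ·KS4, 0, 1) with π = 0.8
(≈20% missing, since E[KS4] = 0) and δ ∈ {−0.10, +0.10}.

## MI engine

Chained equations with **proper normal-linear draws**, implemented directly:

1. fit OLS of the target on its predictors over the target-observed cases;
2. draw the residual variance from its scaled inverse-χ² posterior,
   σ*² = RSS / χ²(n_obs − p);
3. draw coefficients from N(β̂, σ*²(X′X)⁻¹) via the Cholesky factor of X′X;
4. impute each missing cell as its drawn linear predictor plus fresh
   N(0, σ*²) noise.

Missing cells are initialised by resampling observed values, then the
conditional models are cycled in declaration order. The outcome is imputed
from all analysis-model covariates plus the proxy; an incomplete proxy is
imputed from the covariates plus the outcome. Defaults: M = 100 imputations,
10 cycles (both configurable). With a single incomplete variable the chain
has no memory — the model is always fitted on the same observed cases — so
any number of cycles is distributionally identical to one univariate proper
draw; the test suite uses this as an oracle, and trend tests over the
scenario grid exploit it to run monotone scenarios with one cycle.

**Pooling** follows Rubin's rules: Q̄ = mean estimate, W = mean
within-imputation variance, B = between variance ((M−1) denominator),
T = W + (1 + 1/M)B, r = (1 + 1/M)B/W, ν = (M−1)(1 + 1/r)². The reported FMI
is the degrees-of-freedom-adjusted (r + 2/(ν+3))/(r+1), matching what
mainstream MI software prints; the large-sample λ = (1 + 1/M)B/T is exposed
alongside. Degenerate cases: B = 0 gives FMI = 0; W = 0 gives FMI = 1.

## Scenario grid and seeding

100 scenarios: a main set of 64 crossing missing fraction (20/40/60/80%) with
γ₇ (MAR only at ρ = 0.7; each MNAR level at ρ ∈ {0.1, 0.3, 0.5, 0.7, 0.9}),
plus 20 interaction scenarios (γ₇ = 0.1, γ₈ = −0.025, all ρ × missing) and
16 incomplete-proxy scenarios (γ₇ = 0.1, ρ ∈ {0.5, 0.7}, δ = ±0.1, all
missing levels). Scenario ids are stable strings encoding the factor levels
(e.g. `m40_r070_g100_intN_pxneg10`) and act as join keys across the output
CSVs — and as seed keys: replicate k of a scenario draws from
SeedSequence([master, crc32(id)]).spawn(k), so results are invariant to which
other scenarios run. Each replicate spawns separate substreams for cohort
generation, the two missingness draws, and the M imputations, so changing M
does not reshuffle anything upstream.

Per-coefficient Monte-Carlo summaries: bias (mean estimate − truth), percent
bias (100·bias/truth, e.g. 0.083 vs 0.1 → −17%), empirical SE (SD of point
estimates), MSE (mean squared deviation from truth, which equals
bias² + empSE²·(R−1)/R), mean FMI over replicates, and percent gain in
precision 100·(Var_CR/Var_MI − 1) from the replicate point-estimate
variances. Only the three exposure coefficients are summarised; nuisance
coefficients are estimated but not reported.

## Problem sizes and profiles

The `paper` profile is the full study scale: R = 1000 replicates, n = 10,000,
M = 100, 10 cycles. The `reduced` profile (R = 200, M = 25, 5 cycles) is used
for MI-based checks so the suite runs comfortably on one CPU; at R = 200 the
Monte-Carlo SE of a percent-bias estimate for β₄ is ≈2.3 points (empirical
SE ≈ 0.033), which sets the tolerances used in the end-to-end tests. Five
cycles is conservative for this linear-Gaussian chain with at most two
incomplete variables (monotone patterns are exact after one cycle). Trend
tests across ρ use R = 24, M = 20 with one cycle: FMI is a per-replicate
quantity whose mean stabilises quickly, and those scenarios are monotone.

## What the generator does and does not emulate

It reproduces the study conditions exactly: the stated covariate
distributions, SD-unit outcome and proxy, the linear outcome-proxy link, and
linear-probability missingness. It does **not** emulate real-cohort features
such as the 10-confounder covariate set, raw IQ/attainment point scales,
non-linear outcome-proxy relationships, missingness in covariates, or
unmeasured predictors of missingness. Passing tests therefore demonstrate
correctness of the method's operating characteristics under these idealised
conditions, not robustness to (for example) non-linear proxies or
missingness driven by unmeasured factors — under which the bias reduction
from a linked proxy can be smaller, or in adversarial causal structures
negative.

## Numerical and design choices

- OLS via Cholesky-factored normal equations (the factor is reused for the
  proper coefficient draws); verified against statsmodels to 1e-10.
- Singular imputation designs raise an error naming removable (collinear)
  columns; models with fewer complete cases than parameters + 1 refuse to fit.
- MAR scenarios are run only at ρ = 0.7 and the secondary factors only in
  their stated combinations; the grid builder enforces these constraints.
- Replicate-level failures are counted and re-raised once they exceed 1% of
  R, never silently dropped.
- FMI per scenario is reported as the mean over replicates (the FMI estimator
  at M = 25 carries a small upward finite-M adjustment of order 2/(ν+3) ≈ 1.5
  points at FMI ≈ 50%).
- The reduced-profile bias/FMI checks target the study's tabulated values;
  precision-gain estimates are noisier at M = 25 (the extra B/M term in the
  MI point-estimate variance lowers measured gains relative to M = 100), so
  gains are reported but not used as pass/fail checks at reduced scale.
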