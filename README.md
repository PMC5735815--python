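# proxymi

Monte-Carlo evaluation of multiple imputation (MI) with a **linked proxy
outcome** when a continuous study outcome is **missing not at random (MNAR)**.

## The problem

In longitudinal cohorts, the study outcome is often lost to follow-up in a way
that depends on the outcome itself (MNAR). A complete-records regression is
then biased, and standard MI cannot fix it from the analysis variables alone.
But cohorts can often be linked to administrative registers that hold a
*proxy* of the missing outcome — for example a school attainment score as a
proxy for adolescent IQ — with much better coverage than the study itself.
Including that proxy as an **auxiliary variable** in the imputation model (it
never enters the substantive model) recovers much of the missing information.

`proxymi` implements the full simulation machinery to quantify this: a
synthetic birth-cohort generator, linear-probability missingness mechanisms
with intercept calibration, a from-scratch chained-equations MI engine with
proper normal-linear draws and Rubin's-rules pooling (including the fraction
of missing information, FMI), and a 100-scenario factorial study runner.
It is intended for biostatisticians who want to reproduce the study design or
re-run tailored versions of it for their own missingness settings.

## The model

Each cohort of n = 10,000 has sex, three-level maternal education, a
four-level breastfeeding exposure (distribution depending on education), a
standardised outcome and a standardised proxy:

    IQ  = β₀ + β₁·sex + β₂·mumed₁ + β₃·mumed₂ + β₄·bf₁ + β₅·bf₂ + β₆·bf₃ + ε
    KS4 = ρ·IQ + τ

with ε ~ N(0, σ²), τ ~ N(0, φ²), and σ², φ² solved exactly (from the
enumerated covariate distribution) so that Var(IQ) = Var(KS4) = 1. Defaults:
β = (−0.4, −0.1, 0.4, 0.8, 0.1, 0.2, 0.3), so the true exposure effects are
(0.1, 0.2, 0.3) and σ² = 0.83875.

Outcome missingness is an identity-link ("linear probability") model

    Pr(IQ observed) = α + γ₁·sex + … + γ₆·bf₃ + γ₇·IQ + γ₈·(bf₁·IQ) + γ₉·(bf₂·IQ) + γ₁₀·(bf₃·IQ)

γ₇ = 0 gives MAR; γ₇ ∈ {0.05, 0.1, 0.2} gives increasingly strong MNAR.
Negative predictions set the outcome missing with certainty; α is calibrated
by trial and improvement so each scenario hits its target missing percentage
(20/40/60/80%) exactly despite truncation. The proxy can itself be MNAR:
Pr(KS4 observed) = π + δ·KS4 with π = 0.8, δ = ±0.10.

Each scenario is analysed by complete-records OLS and by chained-equations MI
(M = 100 imputations) with the proxy as auxiliary variable, and summarised
over R = 1000 replicates as bias, percent bias, empirical SE, MSE, percent
gain in precision of MI over complete records, and FMI.

## Worked example

One MNAR scenario (20% missing outcome, γ₇ = 0.1, a strong proxy ρ = 0.9) at
the reduced profile (R = 200 replicates, M = 25 imputations):

```python
from proxymi import RunConfig, ScenarioSpec, run_scenario

spec = ScenarioSpec(missing_fraction=0.2, rho=0.9, gamma7=0.1)
cfg = RunConfig.profile("reduced", seed=2017)
res = run_scenario(spec, cfg)
print("scenario:", spec.scenario_id, " alpha =", round(res.alpha, 5))
cols = ["method", "coef", "mean_estimate", "pct_bias", "emp_se", "mse",
        "precision_gain_pct", "mean_fmi_pct"]
print(res.summary[cols].round(4).to_string(index=False))
```

prints

```
scenario: m20_r090_g100_intN_pxNone  alpha = 0.66507
          method coef  mean_estimate  pct_bias  emp_se    mse  precision_gain_pct  mean_fmi_pct
complete_records  bf1         0.0854  -14.6398  0.0373 0.0016                 NaN           NaN
complete_records  bf2         0.1742  -12.8799  0.0306 0.0016                 NaN           NaN
complete_records  bf3         0.2603  -13.2238  0.0279 0.0024                 NaN           NaN
              mi  bf1         0.0971   -2.9205  0.0350 0.0012             13.7499        6.9590
              mi  bf2         0.1958   -2.1053  0.0289 0.0008             12.0571        5.7542
              mi  bf3         0.2891   -3.6419  0.0251 0.0007             23.7860        5.7828
```

Complete-records analysis under-estimates all three exposure effects by
13–15% because high-outcome individuals are preferentially observed; MI with
the strongly-correlated proxy shrinks that bias to a few percent, is more
precise, and reports a low FMI (~6–7%) despite 20% of outcomes being missing.

The same study is available from the shell:

```bash
proxymi grid                                   # list the 100 scenarios
proxymi run --scenario-id m20_r090_g100_intN_pxNone --profile reduced --out results
proxymi summarize --replicates results/replicates.csv --out results/table.csv
proxymi calibrate --scenario-id m80_r070_g100_intN_pxNone
```

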