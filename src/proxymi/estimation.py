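"""Analysis-model fitting (complete records and MI) and Monte-Carlo metrics.

The analysis model is the outcome regression on sex, maternal-education
dummies and breastfeeding dummies — the same linear model that generated the
outcome.  The linked proxy never enters the analysis model; under MI it
appears only in the imputation models as an auxiliary variable.

Per-scenario performance over R replicates is summarised per coefficient as
bias, percent bias, empirical SE (SD of the point estimates), MSE, the mean
fraction of missing information, and the percent gain in precision of MI over
complete records, 100 * (Var_CR / Var_MI - 1) computed from the replicate
point-estimate variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SimulatedCohort
from .linmod import ols
from .mi import ImputationModelSpec, PooledEstimate, chained_impute, pool_rubin

__all__ = [
    "ANALYSIS_TERMS",
    "BF_TERMS",
    "TRUE_BF_EFFECTS",
    "FitResult",
    "fit_full_data",
    "fit_complete_records",
    "fit_mi",
    "summarize_replications",
]

ANALYSIS_TERMS = ["intercept", "sex", "mumed1", "mumed2", "bf1", "bf2", "bf3"]
BF_TERMS = ["bf1", "bf2", "bf3"]
#: true breastfeeding effects under the default generating model
TRUE_BF_EFFECTS = {"bf1": 0.1, "bf2": 0.2, "bf3": 0.3}


@dataclass
class FitResult:
    method: str  # full_data | complete_records | mi
    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    n_used: int
    pooled: PooledEstimate | None = None

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def fmi(self, name: str) -> float:
        if self.pooled is None:
            raise ValueError("FMI only defined for MI fits")
        return float(self.pooled.fmi[self.names.index(name)])


def _fit_ols(cohort: SimulatedCohort, mask: np.ndarray, method: str) -> FitResult:
    X = cohort.design_matrix()
    fit = ols(X[mask], cohort.iq[mask], names=ANALYSIS_TERMS)
    return FitResult(
        method=method,
        names=list(ANALYSIS_TERMS),
        estimates=fit.beta,
        se=fit.se,
        n_used=int(mask.sum()),
    )


def fit_full_data(cohort: SimulatedCohort) -> FitResult:
    """Analysis-model OLS on the complete cohort (before any missingness)."""
    return _fit_ols(cohort, np.ones(len(cohort), dtype=bool), "full_data")


def fit_complete_records(cohort: SimulatedCohort) -> FitResult:
    """Analysis-model OLS restricted to individuals with the outcome observed.

    Covariates and exposure are always complete, so complete records are
    exactly the outcome-observed individuals; the proxy plays no role here.
    """
    return _fit_ols(cohort, cohort.iq_observed, "complete_records")


def fit_mi(
    cohort: SimulatedCohort,
    m: int = 100,
    cycles: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> FitResult:
    """MI estimate: chained imputation with the proxy as auxiliary, then pooling.

    The outcome is imputed from all analysis-model covariates plus the proxy;
    if the proxy is itself incomplete it is imputed from the covariates plus
    the outcome, and the two models are cycled.
    """
    covariate_names = ["sex", "mumed1", "mumed2", "bf1", "bf2", "bf3"]
    dummies = cohort.covariate_dummies()
    values: dict[str, np.ndarray] = {
        name: dummies[:, j] for j, name in enumerate(covariate_names)
    }
    values["iq"] = cohort.iq
    values["ks4"] = cohort.ks4

    specs = [ImputationModelSpec("iq", tuple(covariate_names) + ("ks4",))]
    observed = {"iq": cohort.iq_observed}
    if not cohort.ks4_observed.all():
        specs.append(ImputationModelSpec("ks4", tuple(covariate_names) + ("iq",)))
        observed["ks4"] = cohort.ks4_observed

    imputed = chained_impute(values, observed, specs, m=m, cycles=cycles, seed=seed)

    X = cohort.design_matrix()
    est = np.empty((m, len(ANALYSIS_TERMS)))
    var = np.empty_like(est)
    for i, completed in enumerate(imputed.completed):
        fit = ols(X, completed["iq"], names=ANALYSIS_TERMS)
        est[i] = fit.beta
        var[i] = fit.se**2
    pooled = pool_rubin(est, var, names=ANALYSIS_TERMS)
    return FitResult(
        method="mi",
        names=list(ANALYSIS_TERMS),
        estimates=pooled.qbar,
        se=pooled.se,
        n_used=len(cohort),
        pooled=pooled,
    )


def summarize_replications(
    replicates: pd.DataFrame,
    truth: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo summary per (method, coefficient).

    ``replicates`` is a long DataFrame with columns ``replicate``, ``method``,
    ``coef``, ``estimate`` and optionally ``fmi``.  Returns one row per
    (method, coef) with mean estimate, bias, percent bias, empirical SE, MSE,
    mean FMI and — for MI rows when a complete-records counterpart exists —
    the percent gain in precision.
    """
    truth = TRUE_BF_EFFECTS if truth is None else truth
    required = {"replicate", "method", "coef", "estimate"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicates must have columns {sorted(required)}")
    counts = replicates.groupby(["method", "coef"])["estimate"].count()
    if counts.nunique() > 1:
        raise ValueError("mismatched replicate counts across method/coefficient cells")
    if counts.min() < 2:
        raise ValueError("need at least 2 replicates to summarise")

    rows = []
    var_by_cell: dict[tuple[str, str], float] = {}
    for (method, coef), grp in replicates.groupby(["method", "coef"]):
        est = grp["estimate"].to_numpy(float)
        beta = truth[coef]
        mean = est.mean()
        bias = mean - beta
        emp_se = est.std(ddof=1)
        mse = float(np.mean((est - beta) ** 2))
        var_by_cell[(method, coef)] = est.var(ddof=1)
        rows.append(
            {
                "method": method,
                "coef": coef,
                "n_reps": len(est),
                "mean_estimate": mean,
                "bias": bias,
                "pct_bias": 100.0 * bias / beta,
                "emp_se": emp_se,
                "mse": mse,
                "mean_fmi_pct": (
                    100.0 * grp["fmi"].mean() if "fmi" in grp and grp["fmi"].notna().any() else np.nan
                ),
            }
        )
    out = pd.DataFrame(rows)
    gains = []
    for _, row in out.iterrows():
        key_cr = ("complete_records", row["coef"])
        if row["method"] == "mi" and key_cr in var_by_cell:
            gains.append(100.0 * (var_by_cell[key_cr] / var_by_cell[("mi", row["coef"])] - 1.0))
        else:
            gains.append(np.nan)
    out["precision_gain_pct"] = gains
    return out.sort_values(["method", "coef"]).reset_index(drop=True)
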