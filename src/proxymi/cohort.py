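"""Synthetic birth-cohort generator.

Simulates a cohort resembling a UK birth cohort followed to adolescence:
binary sex, three-level maternal education, a four-level breastfeeding-duration
exposure whose distribution depends on maternal education, a continuous
cognitive outcome ("IQ", standardised to mean 0 / variance 1), and a linked
school-attainment proxy ("KS4", also standardised) that is linearly related to
the outcome.

The outcome model is

    IQ = b0 + b1*sex + b2*mumed1 + b3*mumed2 + b4*bf1 + b5*bf2 + b6*bf3 + eps

with eps ~ N(0, sigma2) and sigma2 solved exactly so that Var(IQ) = 1 under
the enumerated covariate distribution.  The proxy model is

    KS4 = rho*IQ + c1*sex + c2*mumed1 + c3*mumed2 + tau

with tau ~ N(0, phi2) and phi2 solved so that Var(KS4) = 1 (phi2 = 1 - rho^2
when the optional covariate effects are zero).

Covariates are sampled by inverse-CDF on uniforms from a single RNG stream,
so one seed fully determines a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "SimulatedCohort",
    "enumerate_covariate_distribution",
    "solve_outcome_noise_variance",
    "solve_proxy_noise_variance",
    "mean_linear_predictor",
    "generate_cohort",
]

#: default outcome-model coefficients (b0..b6), outcome in SD units
DEFAULT_BETA = (-0.4, -0.1, 0.4, 0.8, 0.1, 0.2, 0.3)

#: maternal education: O-level/lower, A-level, degree+
DEFAULT_MUMED_PROBS = (0.5, 0.25, 0.25)

#: P(breastfeeding category | maternal education); rows sum to 1.
#: categories: never/<1 month, 1-<3 months, 3-<6 months, 6+ months
DEFAULT_BF_PROBS = (
    (0.50, 0.15, 0.15, 0.20),
    (0.30, 0.10, 0.20, 0.40),
    (0.15, 0.10, 0.15, 0.60),
)


class ConfigurationError(ValueError):
    """Raised when parameter values are inconsistent with a unit-variance outcome/proxy."""


def _check_probs(p: Sequence[float], name: str) -> None:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-10):
        raise ConfigurationError(f"{name} must be non-negative and sum to 1, got {list(arr)}")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the data-generating model for one cohort.

    Attributes
    ----------
    n : cohort size.
    beta : outcome-model coefficients (intercept, sex, mumed1, mumed2, bf1, bf2, bf3).
    mumed_probs : marginal maternal-education probabilities.
    bf_probs_given_mumed : row-stochastic 3x4 matrix of breastfeeding probabilities.
    rho : outcome-proxy correlation (slope of the proxy on the outcome).
    proxy_cov_coeffs : optional direct effects of (sex, mumed1, mumed2) on the proxy.
    """

    n: int = 10_000
    beta: tuple[float, ...] = DEFAULT_BETA
    mumed_probs: tuple[float, ...] = DEFAULT_MUMED_PROBS
    bf_probs_given_mumed: tuple[tuple[float, ...], ...] = DEFAULT_BF_PROBS
    rho: float = 0.7
    proxy_cov_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError(f"cohort size must be positive, got {self.n}")
        if len(self.beta) != 7:
            raise ConfigurationError("beta must have 7 entries (b0..b6)")
        _check_probs(self.mumed_probs, "mumed_probs")
        if len(self.bf_probs_given_mumed) != 3:
            raise ConfigurationError("bf_probs_given_mumed must have 3 rows")
        for i, row in enumerate(self.bf_probs_given_mumed):
            if len(row) != 4:
                raise ConfigurationError("each bf_probs_given_mumed row must have 4 entries")
            _check_probs(row, f"bf_probs_given_mumed[{i}]")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError(f"rho must be in [0, 1], got {self.rho}")

    def with_n(self, n: int) -> "CohortParams":
        return replace(self, n=n)


def enumerate_covariate_distribution(params: CohortParams) -> pd.DataFrame:
    """Exact joint distribution over sex x mumed x bf (24 cells).

    Sex is independent of the education/breastfeeding pair; breastfeeding is
    conditional on maternal education.  Returns a DataFrame with columns
    ``sex``, ``mumed``, ``bf``, ``prob``; probabilities sum to 1.  This table
    is the exact-expectation oracle behind the noise-variance solvers and
    intercept calibration.
    """
    rows = []
    for sex in (0, 1):
        for m in range(3):
            for b in range(4):
                p = 0.5 * params.mumed_probs[m] * params.bf_probs_given_mumed[m][b]
                rows.append((sex, m, b, p))
    table = pd.DataFrame(rows, columns=["sex", "mumed", "bf", "prob"])
    return table


def _cell_dummies(table: pd.DataFrame) -> np.ndarray:
    """Design rows (sex, mumed1, mumed2, bf1, bf2, bf3) for each joint cell."""
    sex = table["sex"].to_numpy(float)
    m = table["mumed"].to_numpy(int)
    b = table["bf"].to_numpy(int)
    return np.column_stack(
        [sex, m == 1, m == 2, b == 1, b == 2, b == 3]
    ).astype(float)


def _lp_moments(params: CohortParams) -> tuple[float, float]:
    """Exact mean and variance of the outcome linear predictor (incl. intercept)."""
    table = enumerate_covariate_distribution(params)
    z = _cell_dummies(table)
    p = table["prob"].to_numpy()
    lp = params.beta[0] + z @ np.asarray(params.beta[1:], float)
    mean = float(p @ lp)
    var = float(p @ lp**2 - mean**2)
    return mean, var


def mean_linear_predictor(params: CohortParams) -> float:
    """Exact E[linear predictor] of the outcome model (should be 0 at the defaults)."""
    return _lp_moments(params)[0]


def solve_outcome_noise_variance(params: CohortParams) -> float:
    """sigma2 such that Var(outcome) = 1, i.e. 1 - Var(linear predictor)."""
    _, var_lp = _lp_moments(params)
    sigma2 = 1.0 - var_lp
    if sigma2 < 0:
        raise ConfigurationError(
            f"Var(linear predictor) = {var_lp:.6f} > 1; outcome cannot have unit variance"
        )
    return sigma2


def solve_proxy_noise_variance(params: CohortParams) -> float:
    """phi2 such that Var(proxy) = 1.

    The proxy predictor is rho*IQ + c.(sex, mumed1, mumed2).  Because the
    outcome has unit variance by construction, Var = rho^2 + Var(c-part)
    + 2*rho*Cov(LP, c-part), all moments exact from the 24-cell table.
    """
    c = np.asarray(params.proxy_cov_coeffs, dtype=float)
    if np.all(c == 0.0):
        phi2 = 1.0 - params.rho**2
    else:
        table = enumerate_covariate_distribution(params)
        z = _cell_dummies(table)
        p = table["prob"].to_numpy()
        lp = params.beta[0] + z @ np.asarray(params.beta[1:], float)
        g = z[:, :3] @ c  # covariate part of the proxy predictor
        mean_g = p @ g
        var_g = p @ g**2 - mean_g**2
        mean_lp = p @ lp
        cov_lp_g = p @ (lp * g) - mean_lp * mean_g
        # Var(rho*IQ) = rho^2 * 1 since the outcome noise is solved first
        solve_outcome_noise_variance(params)  # validates unit-variance outcome
        phi2 = 1.0 - (params.rho**2 + var_g + 2.0 * params.rho * cov_lp_g)
    if phi2 < -1e-12:
        raise ConfigurationError(
            f"proxy predictor variance exceeds 1 (implied phi2 = {phi2:.6f})"
        )
    return max(phi2, 0.0)


@dataclass
class SimulatedCohort:
    """One generated cohort with observation flags.

    ``pr_iq_obs`` holds the raw (untruncated) per-individual observation
    probability from the missingness mechanism once it has been applied; it is
    retained for diagnostics such as counting negative predictions.
    """

    sex: np.ndarray
    mumed: np.ndarray
    bf: np.ndarray
    iq: np.ndarray
    ks4: np.ndarray
    iq_observed: np.ndarray
    ks4_observed: np.ndarray
    pr_iq_obs: np.ndarray | None = None
    params: CohortParams | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.sex.shape[0]

    def design_matrix(self) -> np.ndarray:
        """Analysis-model design: intercept, sex, mumed dummies, bf dummies."""
        n = len(self)
        return np.column_stack(
            [
                np.ones(n),
                self.sex,
                self.mumed == 1,
                self.mumed == 2,
                self.bf == 1,
                self.bf == 2,
                self.bf == 3,
            ]
        ).astype(float)

    def covariate_dummies(self) -> np.ndarray:
        """Covariate dummies without intercept (sex, mumed1, mumed2, bf1, bf2, bf3)."""
        return self.design_matrix()[:, 1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "sex": self.sex,
                "mumed": self.mumed,
                "bf": self.bf,
                "iq": self.iq,
                "ks4": self.ks4,
                "iq_observed": self.iq_observed,
                "ks4_observed": self.ks4_observed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_cohort(
    params: CohortParams, seed: int | np.random.SeedSequence | np.random.Generator
) -> SimulatedCohort:
    """Draw a complete cohort (all observation flags true).

    Covariates are sampled by inverse CDF on uniforms; the outcome and proxy
    add normal noise with variances solved to give both unit variance.
    Reproducible: the same seed yields an identical cohort.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n

    sex = (rng.random(n) >= 0.5).astype(np.int8)
    cum_mumed = np.cumsum(params.mumed_probs)
    mumed = np.searchsorted(cum_mumed, rng.random(n), side="right").astype(np.int8)
    cum_bf = np.cumsum(np.asarray(params.bf_probs_given_mumed, float), axis=1)
    bf = (rng.random(n)[:, None] >= cum_bf[mumed]).sum(axis=1).astype(np.int8)

    beta = np.asarray(params.beta, float)
    lp = (
        beta[0]
        + beta[1] * sex
        + beta[2] * (mumed == 1)
        + beta[3] * (mumed == 2)
        + beta[4] * (bf == 1)
        + beta[5] * (bf == 2)
        + beta[6] * (bf == 3)
    )
    sigma2 = solve_outcome_noise_variance(params)
    iq = lp + rng.standard_normal(n) * np.sqrt(sigma2)

    c = np.asarray(params.proxy_cov_coeffs, float)
    proxy_lp = params.rho * iq + c[0] * sex + c[1] * (mumed == 1) + c[2] * (mumed == 2)
    phi2 = solve_proxy_noise_variance(params)
    ks4 = proxy_lp + rng.standard_normal(n) * np.sqrt(phi2)

    return SimulatedCohort(
        sex=sex,
        mumed=mumed,
        bf=bf,
        iq=iq,
        ks4=ks4,
        iq_observed=np.ones(n, dtype=bool),
        ks4_observed=np.ones(n, dtype=bool),
        params=params,
    )
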