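"""Linear-probability missingness mechanisms for the outcome and the proxy.

The probability that the outcome is observed is an identity-link (linear
probability) model in the covariates, the outcome itself, and optional
exposure-by-outcome interactions:

    Pr(IQ observed) = alpha + g1*sex + g2*mumed1 + g3*mumed2
                      + g4*bf1 + g5*bf2 + g6*bf3 + g7*IQ
                      + g8*(bf1*IQ) + g9*(bf2*IQ) + g10*(bf3*IQ)

Predictions can fall outside [0, 1]: a negative prediction sets the outcome
missing with certainty (the "negative-prediction rule"), a prediction above 1
is observed with certainty, and anything in between decides by a Bernoulli
draw.  With g7 = ... = g10 = 0 the mechanism is MAR given covariates;
a nonzero outcome slope makes it MNAR.

The intercept alpha is calibrated by trial and improvement (an exact starting
value from the enumerated covariate distribution, then root-finding against
the missing fraction realised on a large calibration cohort) so that each
scenario hits its target missing-data percentage despite truncation.

The proxy mechanism is Pr(KS4 observed) = pi + delta*KS4, missingness
depending only on the proxy itself.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    CohortParams,
    SimulatedCohort,
    enumerate_covariate_distribution,
    _cell_dummies,
    generate_cohort,
)

__all__ = [
    "OutcomeMissingnessSpec",
    "ProxyMissingnessSpec",
    "CalibrationError",
    "outcome_observation_probability",
    "expected_nonintercept_terms",
    "calibrate_alpha",
    "apply_outcome_missingness",
    "apply_proxy_missingness",
    "negative_prediction_count",
]

#: fixed covariate coefficients g1..g6 of the outcome-observation model
FIXED_GAMMA = (0.04, 0.075, 0.10, 0.08, 0.12, 0.14)


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class OutcomeMissingnessSpec:
    """Specification of the outcome-observation model.

    ``gamma`` is (g1..g10): six covariate coefficients, the outcome slope g7
    (0 for MAR), and three exposure-by-outcome interaction slopes.  ``alpha``
    is the intercept, usually left None and set by :func:`calibrate_alpha`.
    """

    gamma: tuple[float, ...]
    target_missing: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        if len(self.gamma) != 10:
            raise ValueError("gamma must have 10 entries (g1..g10)")
        if not 0.0 < self.target_missing < 1.0:
            raise ValueError("target_missing must be in (0, 1)")

    @classmethod
    def mar(cls, target_missing: float) -> "OutcomeMissingnessSpec":
        """Missing at random: observation probability depends on covariates only."""
        return cls(gamma=FIXED_GAMMA + (0.0, 0.0, 0.0, 0.0), target_missing=target_missing)

    @classmethod
    def mnar(
        cls, gamma7: float, target_missing: float, gamma8: float = 0.0
    ) -> "OutcomeMissingnessSpec":
        """MNAR with outcome slope ``gamma7``; a nonzero ``gamma8`` adds the
        exposure-by-outcome interaction with slopes (g8, 2*g8, 3*g8)."""
        return cls(
            gamma=FIXED_GAMMA + (gamma7, gamma8, 2.0 * gamma8, 3.0 * gamma8),
            target_missing=target_missing,
        )

    def with_alpha(self, alpha: float) -> "OutcomeMissingnessSpec":
        return replace(self, alpha=alpha)

    @property
    def is_mar(self) -> bool:
        return all(g == 0.0 for g in self.gamma[6:])


@dataclass(frozen=True)
class ProxyMissingnessSpec:
    """Pr(proxy observed) = pi + delta * proxy; delta=0 with pi=1 leaves it complete."""

    pi: float = 0.8
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


def _nonintercept_terms(cohort: SimulatedCohort, spec: OutcomeMissingnessSpec) -> np.ndarray:
    g = np.asarray(spec.gamma, float)
    z = cohort.covariate_dummies()  # sex, mumed1, mumed2, bf1, bf2, bf3
    terms = z @ g[:6] + g[6] * cohort.iq
    if np.any(g[7:] != 0.0):
        terms = terms + (z[:, 3:6] * cohort.iq[:, None]) @ g[7:]
    return terms


def outcome_observation_probability(
    cohort: SimulatedCohort, spec: OutcomeMissingnessSpec, alpha: float | None = None
) -> np.ndarray:
    """Raw per-individual Pr(outcome observed): the linear predictor, untruncated.

    Values may fall outside [0, 1]; truncation happens when the missingness is
    applied, so callers can detect negative predictions.
    """
    a = spec.alpha if alpha is None else alpha
    if a is None:
        raise ValueError("spec.alpha is unset; calibrate it or pass alpha explicitly")
    return a + _nonintercept_terms(cohort, spec)


def expected_nonintercept_terms(params: CohortParams, spec: OutcomeMissingnessSpec) -> float:
    """Exact E[non-intercept terms of the observation model].

    Covariate terms come from the enumerated 24-cell table; E[outcome] is the
    mean linear predictor (the noise has mean 0), and the interaction terms use
    E[bf_k * outcome] = E[bf_k * linear predictor], again exact from the table.
    """
    g = np.asarray(spec.gamma, float)
    table = enumerate_covariate_distribution(params)
    z = _cell_dummies(table)
    p = table["prob"].to_numpy()
    beta = np.asarray(params.beta, float)
    lp = beta[0] + z @ beta[1:]
    expect = float((p * (z @ g[:6])).sum())
    expect += g[6] * float(p @ lp)
    for k in range(3):  # interactions with bf1..bf3
        expect += g[7 + k] * float(p @ (z[:, 3 + k] * lp))
    return expect


@functools.lru_cache(maxsize=8)
def _calibration_cohort(params: CohortParams, n_calib: int, seed: int) -> SimulatedCohort:
    # shared across missingness specs: the outcome distribution does not
    # depend on the mechanism being calibrated
    return generate_cohort(params.with_n(n_calib), np.random.SeedSequence([seed, 0x5A1B]))


def calibrate_alpha(
    params: CohortParams,
    spec: OutcomeMissingnessSpec,
    tol: float = 0.002,
    seed: int = 0,
    n_calib: int = 1_000_000,
) -> float:
    """Intercept producing the target missing fraction, by trial and improvement.

    The starting point ``alpha0 = (1 - target) - E[non-intercept terms]`` is
    exact when no prediction needs truncation, in which case it is returned
    directly.  Otherwise Brent root-finding adjusts alpha against the expected
    missing fraction ``mean(1 - clip(raw, 0, 1))`` on a large calibration
    cohort, which accounts for deterministic missingness from negative
    predictions and for clamping above 1.  Deterministic given ``seed``.
    """
    target = spec.target_missing
    alpha0 = (1.0 - target) - expected_nonintercept_terms(params, spec)
    cohort = _calibration_cohort(params, n_calib, seed)
    terms = _nonintercept_terms(cohort, spec)

    raw0 = alpha0 + terms
    if raw0.min() >= 0.0 and raw0.max() <= 1.0:
        return alpha0  # no truncation: expectation matches the target exactly

    def realized_minus_target(alpha: float) -> float:
        return float(np.mean(1.0 - np.clip(alpha + terms, 0.0, 1.0))) - target

    lo, hi = alpha0 - 1.0, alpha0 + 1.0
    for _ in range(8):
        if realized_minus_target(lo) > 0.0 > realized_minus_target(hi):
            break
        lo -= 1.0
        hi += 1.0
    else:
        raise CalibrationError("could not bracket the calibration root")
    alpha = float(brentq(realized_minus_target, lo, hi, xtol=1e-8))
    err = realized_minus_target(alpha)
    if abs(err) > tol:
        raise CalibrationError(
            f"calibration residual {err:+.4f} exceeds tolerance {tol} "
            f"(alpha={alpha:.5f}, target={target})"
        )
    return alpha


def apply_outcome_missingness(
    cohort: SimulatedCohort,
    spec: OutcomeMissingnessSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> SimulatedCohort:
    """Set ``iq_observed`` from the calibrated observation model.

    Raw prediction < 0: missing with certainty; > 1: observed with certainty;
    otherwise a Bernoulli(p) draw.  The raw predictions are retained on the
    returned cohort (``pr_iq_obs``) for diagnostics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = outcome_observation_probability(cohort, spec)
    p = np.clip(raw, 0.0, 1.0)
    observed = rng.random(len(cohort)) < p
    return replace(cohort, iq_observed=observed, pr_iq_obs=raw)


def apply_proxy_missingness(
    cohort: SimulatedCohort,
    spec: ProxyMissingnessSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> SimulatedCohort:
    """Set ``ks4_observed`` from Pr(observed) = clip(pi + delta*ks4, 0, 1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.clip(spec.pi + spec.delta * cohort.ks4, 0.0, 1.0)
    observed = rng.random(len(cohort)) < p
    return replace(cohort, ks4_observed=observed)


def negative_prediction_count(cohort: SimulatedCohort) -> int:
    """Number of individuals set missing deterministically by the negative-prediction rule."""
    if cohort.pr_iq_obs is None:
        raise ValueError("outcome missingness has not been applied to this cohort")
    return int(np.sum(cohort.pr_iq_obs < 0.0))
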