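"""The factorial scenario grid and the replication driver.

One hundred scenarios vary five factors:

1. percent missing outcome data: 20, 40, 60, 80;
2. outcome-proxy correlation rho: 0.1, 0.3, 0.5, 0.7, 0.9;
3. MNAR strength (outcome slope gamma7 of the observation model):
   0 (MAR), 0.05, 0.10, 0.20;
4. whether the outcome slope varies with the breastfeeding exposure
   (interaction slopes -0.025, -0.050, -0.075 added to gamma7 = 0.10);
5. missingness in the proxy itself (none, or 20% with slope delta = +/-0.10).

The main set (64 scenarios) crosses factors 1-3 with MAR run only at
rho = 0.7; the secondary sets add 20 interaction scenarios and 16
incomplete-proxy scenarios (gamma7 = 0.10, rho in {0.5, 0.7}).

Each scenario runs R independent replicates of: generate cohort, impose
missingness, fit by complete records and (optionally) by MI, with the
intercept alpha calibrated once per missingness mechanism.  Seeding is
hierarchical so replicate k of a scenario does not depend on which other
scenarios run, and cohort generation is invariant to the number of
imputations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortParams, generate_cohort
from .estimation import (
    BF_TERMS,
    TRUE_BF_EFFECTS,
    fit_complete_records,
    fit_mi,
    summarize_replications,
)
from .missingness import (
    OutcomeMissingnessSpec,
    ProxyMissingnessSpec,
    apply_outcome_missingness,
    apply_proxy_missingness,
    calibrate_alpha,
    negative_prediction_count,
)

__all__ = [
    "ScenarioSpec",
    "RunConfig",
    "build_table1_grid",
    "run_scenario",
    "run_grid",
    "AlphaCache",
]

MISSING_LEVELS = (0.2, 0.4, 0.6, 0.8)
RHO_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)
GAMMA7_LEVELS = (0.05, 0.1, 0.2)
INTERACTION_GAMMA8 = -0.025
PROXY_DELTAS = (-0.10, 0.10)
PROXY_RHOS = (0.5, 0.7)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design."""

    missing_fraction: float
    rho: float
    gamma7: float
    interaction: bool = False
    proxy_delta: float | None = None

    def __post_init__(self) -> None:
        if self.gamma7 == 0.0 and self.rho != 0.7:
            raise ValueError("MAR scenarios are run only at rho = 0.7")
        if self.interaction and self.gamma7 != 0.1:
            raise ValueError("interaction scenarios use gamma7 = 0.1")
        if self.proxy_delta is not None:
            if self.gamma7 != 0.1 or self.interaction:
                raise ValueError("incomplete-proxy scenarios use gamma7 = 0.1, no interaction")
            if self.rho not in PROXY_RHOS:
                raise ValueError(f"incomplete-proxy scenarios use rho in {PROXY_RHOS}")

    @property
    def scenario_id(self) -> str:
        px = (
            "None"
            if self.proxy_delta is None
            else ("neg10" if self.proxy_delta < 0 else "pos10")
        )
        return (
            f"m{int(round(100 * self.missing_fraction)):02d}"
            f"_r{int(round(100 * self.rho)):03d}"
            f"_g{int(round(1000 * self.gamma7)):03d}"
            f"_int{'Y' if self.interaction else 'N'}"
            f"_px{px}"
        )

    def cohort_params(self, n: int) -> CohortParams:
        return CohortParams(n=n, rho=self.rho)

    def outcome_spec(self) -> OutcomeMissingnessSpec:
        if self.gamma7 == 0.0:
            return OutcomeMissingnessSpec.mar(self.missing_fraction)
        g8 = INTERACTION_GAMMA8 if self.interaction else 0.0
        return OutcomeMissingnessSpec.mnar(self.gamma7, self.missing_fraction, gamma8=g8)

    def proxy_spec(self) -> ProxyMissingnessSpec | None:
        if self.proxy_delta is None:
            return None
        return ProxyMissingnessSpec(pi=0.8, delta=self.proxy_delta)

    def to_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "missing_fraction": self.missing_fraction,
            "rho": self.rho,
            "gamma7": self.gamma7,
            "interaction": self.interaction,
            "proxy_delta": np.nan if self.proxy_delta is None else self.proxy_delta,
        }


def build_table1_grid() -> list[ScenarioSpec]:
    """All 100 scenarios: 64 main (factors 1-3), 20 interaction, 16 incomplete-proxy."""
    grid: list[ScenarioSpec] = []
    for miss in MISSING_LEVELS:
        grid.append(ScenarioSpec(miss, 0.7, 0.0))  # MAR, rho = 0.7 only
        for g7 in GAMMA7_LEVELS:
            for rho in RHO_LEVELS:
                grid.append(ScenarioSpec(miss, rho, g7))
    for miss in MISSING_LEVELS:
        for rho in RHO_LEVELS:
            grid.append(ScenarioSpec(miss, rho, 0.1, interaction=True))
    for miss in MISSING_LEVELS:
        for delta in PROXY_DELTAS:
            for rho in PROXY_RHOS:
                grid.append(ScenarioSpec(miss, rho, 0.1, proxy_delta=delta))
    return grid


@dataclass
class RunConfig:
    """Execution profile for one or more scenarios.

    The ``paper`` profile (R=1000, M=100, n=10,000, 10 cycles) reproduces the
    full study scale; the ``reduced`` profile (R=200, M=25, 5 cycles) keeps
    MI-based checks tractable on one CPU.
    """

    seed: int = 2017
    reps: int = 1000
    m: int = 100
    n: int = 10_000
    cycles: int = 10
    run_mi: bool = True
    calib_n: int = 1_000_000
    calib_tol: float = 0.002
    max_failure_fraction: float = 0.01

    @classmethod
    def profile(cls, name: str, seed: int = 2017, **overrides) -> "RunConfig":
        presets = {
            "paper": dict(reps=1000, m=100, cycles=10),
            "reduced": dict(reps=200, m=25, cycles=5),
        }
        if name not in presets:
            raise ValueError(f"unknown profile {name!r}; choose from {sorted(presets)}")
        kwargs = {**presets[name], "seed": seed, **overrides}
        return cls(**kwargs)


class AlphaCache:
    """Memoised intercept calibration.

    Alpha depends only on the cohort parameters that shape the outcome (not on
    rho or the proxy factor) and on the observation-model gammas and target,
    so the 100 scenarios need only 20 distinct calibrations.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self._cache: dict[tuple, float] = {}

    def alpha_for(self, spec: ScenarioSpec) -> float:
        params = CohortParams(n=self.config.n, rho=0.7)  # rho irrelevant to alpha
        mspec = spec.outcome_spec()
        key = (mspec.gamma, mspec.target_missing)
        if key not in self._cache:
            self._cache[key] = calibrate_alpha(
                params,
                mspec,
                tol=self.config.calib_tol,
                seed=self.config.seed,
                n_calib=self.config.calib_n,
            )
        return self._cache[key]


def _scenario_seed_key(scenario_id: str) -> int:
    return zlib.crc32(scenario_id.encode()) & 0x7FFFFFFF


def replicate_seedseqs(config: RunConfig, spec: ScenarioSpec) -> list[np.random.SeedSequence]:
    root = np.random.SeedSequence([config.seed, _scenario_seed_key(spec.scenario_id)])
    return root.spawn(config.reps)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    alpha: float
    summary: pd.DataFrame
    replicates: pd.DataFrame
    diagnostics: pd.DataFrame
    failures: int = 0


def run_scenario(
    spec: ScenarioSpec,
    config: RunConfig,
    alpha: float | None = None,
    progress=None,
) -> ScenarioResult:
    """Run R replicates of one scenario and summarise.

    Per replicate, separate RNG substreams drive cohort generation, the two
    missingness draws, and the M imputations, so results are invariant to M
    for everything upstream of imputation.  Replicate failures are counted;
    more than ``max_failure_fraction`` aborts the scenario.
    """
    if alpha is None:
        alpha = AlphaCache(config).alpha_for(spec)
    mspec = spec.outcome_spec().with_alpha(alpha)
    pspec = spec.proxy_spec()
    params = spec.cohort_params(config.n)

    rep_rows: list[dict] = []
    diag_rows: list[dict] = []
    failures = 0
    for k, ss in enumerate(replicate_seedseqs(config, spec)):
        gen_ss, miss_ss, proxy_ss, mi_ss = ss.spawn(4)
        try:
            cohort = generate_cohort(params, gen_ss)
            cohort = apply_outcome_missingness(cohort, mspec, miss_ss)
            if pspec is not None:
                cohort = apply_proxy_missingness(cohort, pspec, proxy_ss)
            cr = fit_complete_records(cohort)
            fits = [cr]
            if config.run_mi:
                fits.append(fit_mi(cohort, m=config.m, cycles=config.cycles, seed=mi_ss))
            for fit in fits:
                for coef in BF_TERMS:
                    rep_rows.append(
                        {
                            "scenario_id": spec.scenario_id,
                            "replicate": k,
                            "method": fit.method,
                            "coef": coef,
                            "estimate": fit.coef(coef),
                            "fmi": fit.fmi(coef) if fit.method == "mi" else np.nan,
                        }
                    )
            diag_rows.append(
                {
                    "scenario_id": spec.scenario_id,
                    "replicate": k,
                    "negative_predictions": negative_prediction_count(cohort),
                    "iq_missing_fraction": float(1.0 - cohort.iq_observed.mean()),
                    "ks4_missing_fraction": float(1.0 - cohort.ks4_observed.mean()),
                    "n_complete_records": int(cohort.iq_observed.sum()),
                }
            )
        except Exception:  # noqa: BLE001 - replicate-level failures are counted
            failures += 1
            if failures > config.max_failure_fraction * config.reps:
                raise
        if progress is not None:
            progress()

    replicates = pd.DataFrame(rep_rows)
    diagnostics = pd.DataFrame(diag_rows)
    summary = summarize_replications(replicates, truth=TRUE_BF_EFFECTS)
    summary.insert(0, "scenario_id", spec.scenario_id)
    for col, val in list(spec.to_row().items())[1:]:
        summary[col] = val
    summary["alpha"] = alpha
    summary["mean_negative_predictions"] = diagnostics["negative_predictions"].mean()
    summary["mean_iq_missing_fraction"] = diagnostics["iq_missing_fraction"].mean()
    return ScenarioResult(
        spec=spec,
        alpha=alpha,
        summary=summary,
        replicates=replicates,
        diagnostics=diagnostics,
        failures=failures,
    )


def run_grid(
    specs: list[ScenarioSpec],
    config: RunConfig,
    progress=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run several scenarios, sharing calibrations; returns (summary, replicates, diagnostics)."""
    cache = AlphaCache(config)
    summaries, reps, diags = [], [], []
    for spec in specs:
        result = run_scenario(spec, config, alpha=cache.alpha_for(spec), progress=progress)
        summaries.append(result.summary)
        reps.append(result.replicates)
        diags.append(result.diagnostics)
    return (
        pd.concat(summaries, ignore_index=True),
        pd.concat(reps, ignore_index=True),
        pd.concat(diags, ignore_index=True),
    )
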