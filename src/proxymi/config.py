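"""YAML configuration for a study run.

A config file has up to four blocks::

    cohort:                  # CohortParams fields (n, beta, mumed_probs, ...)
      n: 10000
      rho: 0.7
    missingness:             # outcome + proxy observation models
      target_missing: 0.4
      gamma7: 0.1
      gamma8: 0.0
      proxy_pi: 0.8
      proxy_delta: null      # null = proxy fully observed
    mi:
      m: 100
      cycles: 10
    run:
      seed: 2017
      reps: 1000
      run_mi: true

Category encodings: sex 0 = male, 1 = female; mumed 0 = O-level/lower,
1 = A-level, 2 = degree+; bf 0 = never/<1 month, 1 = 1-<3, 2 = 3-<6,
3 = 6+ months.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .cohort import CohortParams
from .missingness import OutcomeMissingnessSpec, ProxyMissingnessSpec
from .scenarios import RunConfig

__all__ = ["StudyConfig", "load_config"]


class StudyConfig:
    """Parsed configuration bundle."""

    def __init__(
        self,
        cohort: CohortParams,
        outcome_missingness: OutcomeMissingnessSpec,
        proxy_missingness: ProxyMissingnessSpec | None,
        run: RunConfig,
    ):
        self.cohort = cohort
        self.outcome_missingness = outcome_missingness
        self.proxy_missingness = proxy_missingness
        self.run = run


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(x) for x in obj)
    return obj


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}

    cohort_kwargs = {k: _tupleize(v) for k, v in (raw.get("cohort") or {}).items()}
    cohort = CohortParams(**cohort_kwargs)

    mblock = raw.get("missingness") or {}
    target = float(mblock.get("target_missing", 0.2))
    gamma7 = float(mblock.get("gamma7", 0.0))
    gamma8 = float(mblock.get("gamma8", 0.0))
    if gamma7 == 0.0:
        outcome = OutcomeMissingnessSpec.mar(target)
    else:
        outcome = OutcomeMissingnessSpec.mnar(gamma7, target, gamma8=gamma8)
    if "alpha" in mblock and mblock["alpha"] is not None:
        outcome = outcome.with_alpha(float(mblock["alpha"]))

    proxy = None
    if mblock.get("proxy_delta") is not None:
        proxy = ProxyMissingnessSpec(
            pi=float(mblock.get("proxy_pi", 0.8)), delta=float(mblock["proxy_delta"])
        )

    miblock = raw.get("mi") or {}
    runblock = raw.get("run") or {}
    run = RunConfig(
        seed=int(runblock.get("seed", 2017)),
        reps=int(runblock.get("reps", 1000)),
        m=int(miblock.get("m", 100)),
        n=cohort.n,
        cycles=int(miblock.get("cycles", 10)),
        run_mi=bool(runblock.get("run_mi", True)),
        calib_n=int(runblock.get("calib_n", 1_000_000)),
        calib_tol=float(runblock.get("calib_tol", 0.002)),
    )
    return StudyConfig(cohort, outcome, proxy, run)
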