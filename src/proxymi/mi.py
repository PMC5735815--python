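"""Multiple imputation by chained equations with proper normal-linear draws,
and Rubin's-rules pooling with the fraction of missing information.

Each incomplete variable is imputed from a normal linear regression fitted to
the cases where it is observed.  A *proper* draw propagates parameter
uncertainty: the residual variance is drawn from its scaled inverse-chi-square
posterior, the coefficients from a normal centred on the least-squares fit
with covariance scaled by the drawn variance, and each missing cell gets the
drawn linear predictor plus fresh normal noise.

With several incomplete variables, missing cells are initialised by random
draws from each variable's observed values and the conditional models are
cycled (chained equations).  With a single incomplete variable the chain has
no memory: any number of cycles is distributionally identical to one
univariate proper draw, a fact the test suite uses as an oracle.

Pooling across the M completed datasets follows Rubin's rules:
Qbar = mean estimate, W = mean within-imputation variance, B = between
variance, T = W + (1 + 1/M) B, r = (1 + 1/M) B / W,
nu = (M - 1)(1 + 1/r)^2, and the degrees-of-freedom-adjusted fraction of
missing information FMI = (r + 2/(nu + 3)) / (r + 1).  The large-sample
variant lambda = (1 + 1/M) B / T is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linmod import ols, TooFewCasesError

__all__ = [
    "ImputationModelSpec",
    "ImputedDatasets",
    "PooledEstimate",
    "proper_normal_linear_draw",
    "chained_impute",
    "pool_rubin",
]


@dataclass(frozen=True)
class ImputationModelSpec:
    """Conditional model for one incomplete variable.

    ``predictors`` name columns of the variable dictionary passed to
    :func:`chained_impute` (complete covariates and/or other incomplete
    variables); an intercept is always included and the target never predicts
    itself.
    """

    target: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.target in self.predictors:
            raise ValueError(f"target {self.target!r} cannot be its own predictor")


@dataclass
class ImputedDatasets:
    """M completed copies of the incomplete variables.

    ``completed[m][name]`` is the full-length array for variable ``name`` in
    imputation ``m``; observed cells are identical across copies.
    """

    completed: list[dict[str, np.ndarray]]
    observed: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.completed)


def proper_normal_linear_draw(
    X: np.ndarray,
    y: np.ndarray,
    observed: np.ndarray,
    rng: np.random.Generator,
    names: list[str] | None = None,
) -> np.ndarray:
    """One proper imputation of the missing cells of ``y`` given design ``X``.

    Returns a completed copy of ``y``.  If nothing is missing the data are
    returned unchanged.
    """
    missing = ~observed
    if not missing.any():
        return y.copy()
    n_obs = int(observed.sum())
    p = X.shape[1]
    if n_obs < p + 1:
        raise TooFewCasesError(
            f"{n_obs} complete cases are too few for a {p}-column imputation model"
        )
    fit = ols(X[observed], y[observed], names=names)
    # scaled inverse-chi-square posterior draw for the residual variance
    sigma2_star = fit.rss / rng.chisquare(fit.df)
    beta_star = fit.sample_beta(sigma2_star, rng)
    out = y.copy()
    n_mis = int(missing.sum())
    out[missing] = X[missing] @ beta_star + rng.standard_normal(n_mis) * np.sqrt(sigma2_star)
    return out


def _design(values: dict[str, np.ndarray], predictors: tuple[str, ...]) -> np.ndarray:
    n = len(next(iter(values.values())))
    cols = [np.ones(n)] + [values[p] for p in predictors]
    return np.column_stack(cols)


def chained_impute(
    values: dict[str, np.ndarray],
    observed: dict[str, np.ndarray],
    specs: list[ImputationModelSpec],
    m: int,
    cycles: int,
    seed: int | np.random.SeedSequence,
) -> ImputedDatasets:
    """Chained-equations imputation of every variable with a model spec.

    ``values`` maps names to full-length float arrays (complete covariates may
    appear too, as predictors); ``observed`` maps each incomplete variable to
    its boolean observation mask.  Missing cells are initialised by resampling
    observed values, then ``cycles`` sweeps re-impute each target in
    declaration order via :func:`proper_normal_linear_draw`.  The M imputations
    are independent, each on its own RNG substream, so changing M leaves
    earlier draws untouched.
    """
    if m < 2:
        raise ValueError("need at least 2 imputations")
    if cycles < 1:
        raise ValueError("need at least 1 cycle")
    targets = [s.target for s in specs]
    for t in targets:
        if t not in values or t not in observed:
            raise ValueError(f"incomplete variable {t!r} missing from values/observed")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    completed: list[dict[str, np.ndarray]] = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        cur = dict(values)
        for t in targets:
            arr = values[t].copy()
            mask = observed[t]
            n_mis = int((~mask).sum())
            if n_mis:
                arr[~mask] = rng.choice(arr[mask], size=n_mis, replace=True)
            cur[t] = arr
        for _ in range(cycles):
            for spec in specs:
                X = _design(cur, spec.predictors)
                cur[spec.target] = proper_normal_linear_draw(
                    X,
                    cur[spec.target],
                    observed[spec.target],
                    rng,
                    names=["intercept", *spec.predictors],
                )
        completed.append({t: cur[t] for t in targets})
    return ImputedDatasets(completed=completed, observed={t: observed[t] for t in targets})


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M per-imputation fits."""

    names: list[str]
    qbar: np.ndarray  # pooled point estimates
    within: np.ndarray  # W
    between: np.ndarray  # B
    total: np.ndarray  # T = W + (1 + 1/M) B
    r: np.ndarray  # relative increase in variance
    df: np.ndarray  # nu = (M - 1)(1 + 1/r)^2
    fmi: np.ndarray  # df-adjusted fraction of missing information
    lambda_large_sample: np.ndarray  # (1 + 1/M) B / T
    m: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total)


def pool_rubin(
    estimates: np.ndarray,
    variances: np.ndarray,
    names: list[str] | None = None,
) -> PooledEstimate:
    """Pool an (M, k) array of estimates and squared standard errors.

    B uses the (M-1)-denominator sample variance.  When B = 0 the relative
    increase r is 0, nu is infinite and FMI reduces to 0.
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    var = np.atleast_2d(np.asarray(variances, float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have the same shape")
    m = est.shape[0]
    if m < 2:
        raise ValueError("Rubin's rules need M >= 2 (between-imputation variance undefined)")
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(w > 0, (1.0 + 1.0 / m) * b / w, np.inf)
        r = np.where((w == 0) & (b == 0), 0.0, r)
        nu = np.where(r > 0, (m - 1) * (1.0 + 1.0 / r) ** 2, np.inf)
        fmi = (r + 2.0 / (nu + 3.0)) / (r + 1.0)  # r=0 -> nu=inf -> fmi=0
        fmi = np.where(np.isinf(r), 1.0, fmi)  # W = 0: all information missing
        lam = np.where(t > 0, (1.0 + 1.0 / m) * b / t, 0.0)
    k = est.shape[1]
    return PooledEstimate(
        names=list(names) if names is not None else [f"q{i}" for i in range(k)],
        qbar=qbar,
        within=w,
        between=b,
        total=t,
        r=r,
        df=nu,
        fmi=fmi,
        lambda_large_sample=lam,
        m=m,
    )
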