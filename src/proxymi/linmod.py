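"""Fast ordinary-least-squares helper shared by the analysis and imputation models.

Solves the normal equations by Cholesky factorisation; the factor is kept so
that proper imputation can draw coefficients from N(beta_hat, s2 * (X'X)^-1)
cheaply.  Cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = ["OLSFit", "ols", "SingularDesignError", "TooFewCasesError"]


class SingularDesignError(np.linalg.LinAlgError):
    pass


class TooFewCasesError(ValueError):
    pass


@dataclass
class OLSFit:
    beta: np.ndarray
    se: np.ndarray
    sigma2: float  # residual variance estimate (RSS / df)
    rss: float
    df: int  # n - p
    _chol_lower: np.ndarray  # lower Cholesky factor of X'X

    def sample_beta(self, sigma2_draw: float, rng: np.random.Generator) -> np.ndarray:
        """Draw from N(beta, sigma2_draw * (X'X)^-1)."""
        z = rng.standard_normal(self.beta.shape[0])
        # (X'X)^-1 = L^-T L^-1, so L^-T z has the right covariance
        return self.beta + np.sqrt(sigma2_draw) * solve_triangular(
            self._chol_lower.T, z, lower=False
        )


def ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """OLS of ``y`` on ``X`` (which must already include any intercept column)."""
    n, p = X.shape
    if n < p + 1:
        raise TooFewCasesError(f"need at least {p + 1} cases for a {p}-column design, got {n}")
    xtx = X.T @ X
    try:
        c, low = cho_factor(xtx, lower=True)
    except np.linalg.LinAlgError as exc:
        cols = _suspect_columns(X, names)
        raise SingularDesignError(f"singular design matrix; collinear columns: {cols}") from exc
    beta = cho_solve((c, low), X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv_diag = cho_solve((c, low), np.eye(p)).diagonal()
    se = np.sqrt(sigma2 * xtx_inv_diag)
    return OLSFit(beta=beta, se=se, sigma2=sigma2, rss=rss, df=df, _chol_lower=np.tril(c))


def _suspect_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    # name columns whose removal leaves the rank unchanged
    rank = np.linalg.matrix_rank(X)
    labels = names if names is not None else [f"col{i}" for i in range(X.shape[1])]
    flagged = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            flagged.append(labels[j])
    return flagged or labels
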