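"""Fast ordinary-least-squares primitives shared by the scan and EWAS stages.

All model fitting in the pipeline reduces to OLS on modest design matrices
(n of a few hundred, p of a few dozen), fitted once per CpG.  A thin QR-based
solver is used rather than a full statsmodels fit per CpG to keep genome-scale
loops cheap; statsmodels serves as the cross-check oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegeneratePredictorError(ValueError):
    """Raised when a predictor is constant or the design is rank deficient."""


@dataclass
class OlsFit:
    """Coefficients and inference for one OLS fit.

    Attributes
    ----------
    beta, se, t, p : ndarray
        Per-coefficient estimate, standard error, t statistic and two-sided
        P value (df = n - rank).
    rss : float
        Residual sum of squares.
    df_resid : int
        Residual degrees of freedom.
    rank : int
        Column rank of the design.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    df_resid: int
    rank: int


def ols_fit(X: np.ndarray, y: np.ndarray, check_rank: bool = True,
            colnames: list[str] | None = None) -> OlsFit:
    """OLS of ``y`` on ``X`` (X must already contain an intercept column).

    Raises :class:`DegeneratePredictorError` naming aliased columns when the
    design is rank deficient and ``check_rank`` is set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if check_rank and rank < p:
        aliased = np.where(diag <= tol)[0]
        names = ([colnames[i] for i in aliased] if colnames is not None
                 else [f"col{i}" for i in aliased])
        raise DegeneratePredictorError(
            f"design matrix is rank deficient; aliased columns: {names}")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    if df <= 0:
        raise DegeneratePredictorError("no residual degrees of freedom")
    tss = float(y @ y)
    if tss > 0 and rss <= tss * 1e-20:
        rss = 0.0  # numerically perfect fit
    sigma2 = rss / df
    Rinv = np.linalg.solve(R, np.eye(p))
    var = sigma2 * (Rinv @ Rinv.T).diagonal()
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    # perfect-fit convention: zero residual variance -> p reported as 0
    pvals = np.where(np.isinf(t), 0.0, pvals)
    pvals = np.where((se == 0) & (beta == 0), 1.0, pvals)
    return OlsFit(beta=beta, se=se, t=np.asarray(t), p=pvals, rss=rss,
                  df_resid=df, rank=rank)


def residualize(M: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project the columns of ``M`` off the span of ``covariates``.

    ``covariates`` must include the intercept.  Uses a thin QR of the
    covariate block so repeated calls on the same block can share it.
    """
    Q, _ = np.linalg.qr(covariates)
    M = np.asarray(M, dtype=float)
    return M - Q @ (Q.T @ M)


def covariate_projector(covariates: np.ndarray) -> np.ndarray:
    """Return the orthonormal basis Q of the covariate span (for reuse)."""
    Q, _ = np.linalg.qr(np.asarray(covariates, dtype=float))
    return Q
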