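"""Compositional variance partitioning between systems.

How much of the variation in one compositional system (T cell populations,
nasal or rectal microbiota) can another system, or an age variable, explain?
Compositions are mapped to unconstrained coordinates with the isometric
log-ratio (ILR) transform, then modeled with a multivariate linear model.
Variance explained is summarized by an adjusted R-squared contrasting a full
against a reduced predictor set,

    R2_adj = 1 - MSE_full / MSE_reduced,

where each MSE is the total sum of squared residuals of the response matrix
divided by its residual degrees of freedom.  Association is tested with
Wilks' lambda (Rao's F approximation), and candidate age models are ranked
by a BIC-type score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.composition import ilr, multi_replace

_RIDGE = 1e-8


@dataclass
class IlrMatrix:
    """ILR coordinates (samples x (J-1)) of a filtered composition block."""

    coords: pd.DataFrame
    feature_ids: list
    pseudocount: float
    basis: str = "sequential-binary (Helmert-type)"


@dataclass
class MultivariateFit:
    """Least-squares multivariate linear fit bookkeeping."""

    residuals: np.ndarray     # n x q
    n_obs: int
    n_params: int             # predictor columns incl. intercept
    dim: int                  # response dimension q

    @property
    def sse(self) -> float:
        return float((self.residuals ** 2).sum())

    @property
    def mse(self) -> float:
        return self.sse / (self.n_obs - self.n_params)

    def crossprod(self) -> np.ndarray:
        return self.residuals.T @ self.residuals


@dataclass
class ManovaResult:
    r2_adj: float
    wilks_lambda: float
    p_value: float
    n_obs: int
    n_params_full: int
    n_params_reduced: int
    dim: int


def prepare_block(matrix: pd.DataFrame, *, var_threshold: float = 1e-4,
                  pseudocount: float | None = None) -> IlrMatrix:
    """Filter, renormalize and ILR-transform a composition block.

    Features with variance below ``var_threshold`` are removed, rows are
    renormalized to sum to one, zeros are replaced multiplicatively (default
    pseudocount: half the smallest nonzero proportion), and the ILR with
    skbio's fixed sequential-binary basis is applied.  A uniform composition
    maps to the zero vector.
    """
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("compositions must be nonnegative")
    keep = arr.var(axis=0) >= var_threshold
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 features exceed variance threshold {var_threshold}")
    arr = arr[:, keep]
    rowsum = arr.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("all-zero composition row")
    arr = arr / rowsum
    if pseudocount is None:
        nz = arr[arr > 0]
        pseudocount = 0.5 * float(nz.min())
    if (arr == 0).any():
        arr = multi_replace(arr, delta=pseudocount)
    coords = ilr(arr)
    kept = [f for f, k in zip(matrix.columns, keep) if k]
    return IlrMatrix(
        coords=pd.DataFrame(coords, index=matrix.index,
                            columns=[f"ilr_{i}" for i in range(coords.shape[1])]),
        feature_ids=kept, pseudocount=float(pseudocount))


def _design(predictors: pd.DataFrame | np.ndarray | None,
            n: int) -> np.ndarray:
    """Intercept-augmented design matrix; aliased columns dropped."""
    if predictors is None:
        return np.ones((n, 1))
    arr = np.asarray(predictors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    x = np.column_stack([np.ones(n), arr])
    # drop aliased columns (rank-deficient designs) with a warning
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} aliased predictor column(s)",
                      stacklevel=2)
        x = x[:, keep]
    return x


def _fit(y: np.ndarray, x: np.ndarray) -> MultivariateFit:
    n, q = y.shape
    if n <= x.shape[1]:
        raise ValueError("need more observations than parameters")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return MultivariateFit(residuals=y - x @ beta, n_obs=n,
                           n_params=x.shape[1], dim=q)


def _wilks_rao(e_full: np.ndarray, e_reduced: np.ndarray, n: int,
               p_full: int, p_reduced: int, q: int) -> tuple[float, float]:
    """Wilks' lambda and p-value via Rao's F approximation."""
    h = e_reduced - e_full
    sign_e, ld_e = np.linalg.slogdet(e_full)
    sign_t, ld_t = np.linalg.slogdet(e_full + h)
    if sign_e <= 0 or sign_t <= 0:
        e_full = e_full + _RIDGE * np.trace(e_full) / q * np.eye(q)
        sign_e, ld_e = np.linalg.slogdet(e_full)
        sign_t, ld_t = np.linalg.slogdet(e_full + h)
    lam = float(np.exp(ld_e - ld_t))
    m = p_full - p_reduced          # tested predictors
    ve = n - p_full                 # error df
    if q * q + m * m - 5 > 0:
        t = np.sqrt((q ** 2 * m ** 2 - 4) / (q ** 2 + m ** 2 - 5))
    else:
        t = 1.0
    df1 = q * m
    df2 = (ve + p_full - (q + m + 1) / 2 - (q * m) / 2 + 1) * t - q * m / 2 + 1
    df2 = max(df2, 1.0)
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else np.nan
    return lam, p


def manova_r2(response: IlrMatrix | pd.DataFrame,
              predictors_full: pd.DataFrame | np.ndarray,
              predictors_reduced: pd.DataFrame | np.ndarray | None = None,
              ) -> ManovaResult:
    """Adjusted variance explained by the full over the reduced predictors.

    The reduced model defaults to intercept-only.  To adjust a cross-system
    comparison for age, put PMA in both sets (reduced = PMA only): the
    resulting R2_adj is the additional variance the system of interest
    explains beyond age.
    """
    y = response.coords if isinstance(response, IlrMatrix) else response
    y = y.to_numpy(dtype=float) if not isinstance(y, np.ndarray) else y
    n, q = y.shape
    x_full = _design(predictors_full, n)
    x_red = _design(predictors_reduced, n)
    fit_full = _fit(y, x_full)
    fit_red = _fit(y, x_red)
    r2 = 1.0 - fit_full.mse / fit_red.mse
    lam, p = _wilks_rao(fit_full.crossprod(), fit_red.crossprod(), n,
                        fit_full.n_params, fit_red.n_params, q)
    return ManovaResult(r2_adj=float(r2), wilks_lambda=lam, p_value=p,
                        n_obs=n, n_params_full=fit_full.n_params,
                        n_params_reduced=fit_red.n_params, dim=q)


def fit_multivariate(response: IlrMatrix | pd.DataFrame | np.ndarray,
                     predictors: pd.DataFrame | np.ndarray | None,
                     ) -> MultivariateFit:
    """Fit the multivariate linear model used by :func:`manova_bic`."""
    y = (response.coords if isinstance(response, IlrMatrix)
         else response)
    y = y.to_numpy(dtype=float) if not isinstance(y, np.ndarray) else y
    return _fit(y, _design(predictors, y.shape[0]))


def manova_bic(fit: MultivariateFit, *, formula: str = "n_log_p") -> float:
    """BIC-type score of a multivariate fit: -2 loglik(beta) + penalty.

    The log-likelihood is the multivariate normal density of the residuals
    at the MLE covariance (residual cross-products divided by n).  The
    default penalty is ``n * log(p)`` with p the number of predictor
    parameters; this is the form used when ranking the candidate age models,
    and differs from the textbook ``p * log(n)``, which is available via
    ``formula='p_log_n'``.  Singular residual covariances are
    ridge-regularized by 1e-8 * trace / dim.
    """
    n, q, p = fit.n_obs, fit.dim, fit.n_params
    sigma = fit.crossprod() / n
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        warnings.warn("singular residual covariance; ridge-regularizing",
                      stacklevel=2)
        sigma = sigma + _RIDGE * np.trace(sigma) / q * np.eye(q)
        sign, logdet = np.linalg.slogdet(sigma)
    # MLE plug-in: tr(Sigma^{-1} S) = n q
    loglik = -0.5 * n * (q * np.log(2 * np.pi) + logdet + q)
    if formula == "n_log_p":
        penalty = n * np.log(p)
    elif formula == "p_log_n":
        penalty = p * np.log(n)
    else:
        raise ValueError(f"unknown BIC formula {formula!r}")
    return float(-2.0 * loglik + penalty)
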