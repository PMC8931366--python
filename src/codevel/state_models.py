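"""Dirichlet-multinomial mixture (DMM) state types.

Community state types (CSTs) and immune state types (ISTs) are the
components of a Dirichlet-multinomial mixture fitted to normalized count
compositions.  The number of components is chosen by minimizing the Laplace
approximation of the negative log model evidence over a range of K, samples
are assigned to the component with the highest posterior probability, and
components are enumerated by the average postmenstrual age of their
assigned samples, so state 1 is the "youngest" archetype.

The fit is plain EM: responsibilities in the E-step, and in the M-step each
component's Dirichlet parameter vector is updated by quasi-Newton ascent on
log(alpha) with the analytic digamma gradient (a generalized EM step, so
the observed-data log-likelihood is still non-decreasing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, digamma, polygamma
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_MONOTONE_SLACK = 1e-8
#: rate of the weak exponential prior on each Dirichlet parameter used in
#: the model evidence (a soft constraint, as in the reference mixture
#: implementation).  Without it, near-duplicate components at large K carry
#: almost no curvature and the Laplace criterion goes flat; the prior
#: charges every component its prior mass, so superfluous components raise
#: the negative log evidence.
PRIOR_RATE = 0.1


@dataclass
class NormalizedCounts:
    """Depth-normalized integer counts: floor(relative_abundance * constant)."""

    counts: pd.DataFrame       # samples x features, nonnegative integers
    depth_constant: int

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.columns)


@dataclass
class DMMFit:
    """A fitted K-component Dirichlet-multinomial mixture."""

    k: int
    alpha: np.ndarray           # K x J, strictly positive
    weights: np.ndarray         # K simplex
    loglik: float
    neg_log_evidence: float     # Laplace approximation
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    feature_ids: list = field(default_factory=list)


@dataclass
class StateAssignment:
    """Posterior state memberships with PMA-ordered hard labels (1..K)."""

    posterior: pd.DataFrame       # samples x K (enumerated order), rows sum to 1
    label: pd.Series              # sample -> state in 1..K
    mean_pma_per_state: pd.Series  # enumerated state -> mean PMA (NaN if empty)
    label_map: dict               # fitted component index (0-based) -> state label


def filter_prevalence(counts: pd.DataFrame,
                      min_prevalence: float = 0.05) -> pd.DataFrame:
    """Keep features nonzero in at least ``min_prevalence`` of samples.

    ``min_prevalence=0`` disables the filter.  Column order is preserved.
    """
    if min_prevalence == 0:
        return counts
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must lie in (0, 1), or 0 to disable")
    keep = (counts > 0).mean(axis=0) >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"no features present in >= {min_prevalence:.0%} of samples")
    return counts.loc[:, keep]


def normalize_counts(relabund: pd.DataFrame,
                     depth_constant: int) -> NormalizedCounts:
    """Convert compositions to counts: entry = floor(p_ij * depth_constant).

    Normalizing every library to a common depth prevents high-count
    libraries from dominating the mixture fit.  Row sums are at most the
    constant (flooring loses at most J-1 counts per sample).
    """
    if depth_constant < 1:
        raise ValueError("depth_constant must be >= 1")
    arr = relabund.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative proportions")
    rowsum = arr.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    counts = np.floor(arr / rowsum * depth_constant).astype(np.int64)
    return NormalizedCounts(
        counts=pd.DataFrame(counts, index=relabund.index,
                            columns=relabund.columns),
        depth_constant=int(depth_constant))


def dirmult_loglik(x: np.ndarray, alpha: np.ndarray) -> float:
    """log DM(x | alpha) = lnG(A) - lnG(N+A) + sum_j [lnG(x_j+a_j) - lnG(a_j)].

    A = sum(alpha), N = sum(x).  The zero vector has probability one.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x and alpha dimensions differ")
    if (alpha <= 0).any():
        raise ValueError("alpha must be strictly positive")
    a = alpha.sum()
    return float(gammaln(a) - gammaln(x.sum() + a)
                 + (gammaln(x + alpha) - gammaln(alpha)).sum())


def _loglik_matrix(x: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """n x K matrix of log DM(x_i | alpha_k); vectorized over samples."""
    n_tot = x.sum(axis=1)
    out = np.empty((x.shape[0], alphas.shape[0]))
    for k, alpha in enumerate(alphas):
        a = alpha.sum()
        out[:, k] = (gammaln(a) - gammaln(n_tot + a)
                     + (gammaln(x + alpha[None, :]) - gammaln(alpha)[None, :])
                     .sum(axis=1))
    return out


def _weighted_dm_objective(log_alpha: np.ndarray, x: np.ndarray,
                           w: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative r-weighted DM log-likelihood and its gradient in log(alpha)."""
    alpha = np.exp(log_alpha)
    a = alpha.sum()
    n_tot = x.sum(axis=1)
    ll = (w * (gammaln(a) - gammaln(n_tot + a))).sum() + \
         (w[:, None] * (gammaln(x + alpha[None, :]) - gammaln(alpha)[None, :])
          ).sum()
    # d/d alpha_j: sum_i w_i [psi(A) - psi(N_i+A) + psi(x_ij+a_j) - psi(a_j)]
    g_common = (w * (digamma(a) - digamma(n_tot + a))).sum()
    grad = g_common + (w[:, None] * (digamma(x + alpha[None, :])
                                     - digamma(alpha)[None, :])).sum(axis=0)
    return -ll, -grad * alpha  # chain rule for log-parameterization


def _mstep_alpha(x: np.ndarray, w: np.ndarray, alpha0: np.ndarray,
                 maxiter: int = 40) -> np.ndarray:
    res = minimize(_weighted_dm_objective, np.log(alpha0), args=(x, w),
                   jac=True, method="L-BFGS-B",
                   bounds=[(-12.0, 12.0)] * len(alpha0),
                   options={"maxiter": maxiter})
    new = np.exp(res.x)
    # generalized EM: only accept if the weighted objective did not worsen
    if _weighted_dm_objective(res.x, x, w)[0] <= \
            _weighted_dm_objective(np.log(alpha0), x, w)[0]:
        return new
    return alpha0


def _init_responsibilities(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seed EM with k-means on row proportions (soft one-hot labels)."""
    props = x / np.maximum(x.sum(axis=1, keepdims=True), 1.0)
    if k == 1:
        return np.ones((x.shape[0], 1))
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(props)
    r = np.full((x.shape[0], k), 0.05 / max(k - 1, 1))
    r[np.arange(x.shape[0]), km.labels_] = 0.95
    return r / r.sum(axis=1, keepdims=True)


def _laplace_neg_evidence(x: np.ndarray, r: np.ndarray, alphas: np.ndarray,
                          loglik: float) -> float:
    """Laplace approximation of the negative log model evidence.

    -(loglik + log prior)(theta_hat) - P*ln(2*pi)/2 + ln|H|/2 with
    P = K*J free Dirichlet parameters, a weak exponential prior of rate
    ``PRIOR_RATE`` on every alpha entry, and H the block-diagonal (per
    component) Hessian of the
    negative log-likelihood in log(alpha) coordinates at the optimum, built
    from trigamma terms of the responsibility-weighted component fits.  The
    log parameterization is the natural one for the positivity-constrained
    Dirichlet parameters (it is also the space the M-step optimizes in);
    at a stationary point |H_log| = |H_alpha| * prod(alpha_j^2).  Mixture
    weights are treated as known, matching the parameter count P = K*J.
    """
    n_tot = x.sum(axis=1)
    logdet = 0.0
    log_prior = float((np.log(PRIOR_RATE) - PRIOR_RATE * alphas).sum())
    for k, alpha in enumerate(alphas):
        a = alpha.sum()
        w = r[:, k]
        c = (w * (polygamma(1, a) - polygamma(1, n_tot + a))).sum()
        d = (w[:, None] * (polygamma(1, x + alpha[None, :])
                           - polygamma(1, alpha)[None, :])).sum(axis=0)
        h = -(np.full((len(alpha), len(alpha)), c) + np.diag(d))
        sign, ld = np.linalg.slogdet(h)
        if sign <= 0:
            # saddle or flat directions: fall back to the PSD part
            eig = np.linalg.eigvalsh(h)
            ld = float(np.log(np.maximum(eig, 1e-10)).sum())
        logdet += ld + 2.0 * np.log(alpha).sum()
    p_free = alphas.size
    return float(-(loglik + log_prior) - p_free * np.log(2 * np.pi) / 2.0
                 + logdet / 2.0)


def fit_dmm(counts: NormalizedCounts | pd.DataFrame, k: int, *, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 1000,
            max_restarts: int = 3) -> DMMFit:
    """Fit a K-component DMM by (generalized) EM.

    The observed-data log-likelihood is recorded each iteration and is
    non-decreasing up to numerical slack; convergence is declared when its
    relative change drops below ``tol``.  A component losing essentially all
    responsibility mass triggers a restart from a new k-means seed, up to
    ``max_restarts`` attempts.
    """
    frame = counts.counts if isinstance(counts, NormalizedCounts) else counts
    x = frame.to_numpy(dtype=float)
    n, j = x.shape
    if not 1 <= k <= n:
        raise ValueError("need 1 <= K <= n_samples")

    last_error: Exception | None = None
    for attempt in range(max_restarts):
        try:
            return _fit_dmm_once(x, k, seed + 1000 * attempt, tol, max_iter,
                                 list(frame.columns))
        except _DegenerateComponent as exc:
            last_error = exc
            logger.warning("DMM K=%d attempt %d degenerate: %s", k, attempt, exc)
    raise RuntimeError(
        f"DMM fit failed for K={k} after {max_restarts} restarts: {last_error}")


class _DegenerateComponent(RuntimeError):
    pass


def _fit_dmm_once(x: np.ndarray, k: int, seed: int, tol: float,
                  max_iter: int, feature_ids: list) -> DMMFit:
    n, j = x.shape
    r = _init_responsibilities(x, k, seed)
    alphas = np.empty((k, j))
    mean_props = x / np.maximum(x.sum(axis=1, keepdims=True), 1.0)
    for kk in range(k):
        w = r[:, kk]
        m = (w[:, None] * mean_props).sum(axis=0) / w.sum()
        alphas[kk] = np.maximum(m, 1e-4)  # precision-1 start at component mean
    pi = r.mean(axis=0)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step (alpha first so iteration 1 improves on the k-means start)
        for kk in range(k):
            if r[:, kk].sum() < 1e-8:
                raise _DegenerateComponent(f"component {kk} lost all mass")
            alphas[kk] = _mstep_alpha(x, r[:, kk], alphas[kk])
        pi = np.maximum(r.mean(axis=0), 1e-12)
        pi = pi / pi.sum()

        # E-step
        logp = _loglik_matrix(x, alphas) + np.log(pi)[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        r = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        if trace and ll < trace[-1] - _MONOTONE_SLACK:
            logger.warning("loglik decreased by %.3g at iter %d",
                           trace[-1] - ll, it)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) \
                <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break

    nle = _laplace_neg_evidence(x, r, alphas, trace[-1])
    return DMMFit(k=k, alpha=alphas, weights=pi, loglik=trace[-1],
                  neg_log_evidence=nle, n_iter=it, converged=converged,
                  loglik_trace=trace, feature_ids=feature_ids)


def select_k(counts: NormalizedCounts | pd.DataFrame,
             k_range: range | list[int] = range(1, 21), *,
             seed: int = 0, tol: float = 1e-6,
             max_iter: int = 1000) -> tuple[int, dict[int, DMMFit]]:
    """Fit the DMM over ``k_range`` (default 1..20) and return the K that
    minimizes the Laplace negative log evidence (ties break to smaller K).

    Individual K failures are logged and excluded; only total failure raises.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    fits: dict[int, DMMFit] = {}
    for k in ks:
        try:
            fits[k] = fit_dmm(counts, k, seed=seed, tol=tol, max_iter=max_iter)
        except Exception as exc:  # noqa: BLE001 - fit errors are data-dependent
            logger.warning("K=%d fit failed: %s", k, exc)
    if not fits:
        raise RuntimeError("every K in range failed to fit")
    best_k = min(sorted(fits), key=lambda k: (fits[k].neg_log_evidence, k))
    return best_k, fits


def assign_and_enumerate(fit: DMMFit, counts: NormalizedCounts | pd.DataFrame,
                         pma: pd.Series) -> StateAssignment:
    """Posterior assignment with components renumbered 1..K by mean PMA.

    Hard label is the argmax posterior (ties to the lower enumerated
    label).  Components with no assigned samples keep their label with
    mean PMA = NaN and sort last.
    """
    frame = counts.counts if isinstance(counts, NormalizedCounts) else counts
    x = frame.to_numpy(dtype=float)
    pma = pma.reindex(frame.index)
    if pma.isna().any():
        raise ValueError("pma missing for some samples")

    logp = _loglik_matrix(x, fit.alpha) + np.log(fit.weights)[None, :]
    m = logp.max(axis=1, keepdims=True)
    post = np.exp(logp - m)
    post /= post.sum(axis=1, keepdims=True)
    hard = post.argmax(axis=1)  # argmax ties -> lowest fitted index

    mean_pma_fitted = np.full(fit.k, np.nan)
    for kk in range(fit.k):
        mask = hard == kk
        if mask.any():
            mean_pma_fitted[kk] = float(pma.to_numpy()[mask].mean())
    # ascending mean PMA; NaN (empty components) last; stable for ties
    order = np.argsort(np.where(np.isnan(mean_pma_fitted), np.inf,
                                mean_pma_fitted), kind="stable")
    label_map = {int(fitted): rank + 1 for rank, fitted in enumerate(order)}

    columns = [f"state_{label_map[kk]}" for kk in range(fit.k)]
    posterior = pd.DataFrame(post, index=frame.index, columns=columns)
    posterior = posterior[[f"state_{s}" for s in range(1, fit.k + 1)]]
    label = pd.Series([label_map[int(h)] for h in hard], index=frame.index,
                      name="state")
    mean_pma = pd.Series({label_map[kk]: mean_pma_fitted[kk]
                          for kk in range(fit.k)}).sort_index()
    mean_pma.name = "mean_pma"
    return StateAssignment(posterior=posterior, label=label,
                           mean_pma_per_state=mean_pma, label_map=label_map)
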