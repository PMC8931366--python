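"""Enrichment of state types by prematurity and perinatal exposures.

Two complementary questions about a fitted set of state types:

* Are a state's samples enriched in infants of lower gestational age?  Each
  sample contributes a binary in-state/not-in-state outcome; repeated
  measures within a subject are handled with a logistic mixed model (random
  subject intercept, Laplace/MAP fit), adjusting for delivery mode,
  maternal antibiotics, breastmilk and infant antibiotic exposure.
* Do perinatal exposures (maternal antibiotics, chorioamnionitis, prolonged
  membrane rupture, CMV) predict whether a subject *ever* enters a state?
  One row per subject, logistic regression with a natural cubic spline on
  gestational age plus delivery mode, race and sex; exposures are modeled
  jointly and corrected by Benjamini-Hochberg FDR at 10%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats
from scipy.special import expit
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests
from threadpoolctl import threadpool_limits

logger = logging.getLogger(__name__)

ENRICHMENT_CONFOUNDERS = ["delivery_mode", "maternal_abx",
                          "milk_months_gt50pct", "milk_any",
                          "abx_inpatient_days", "abx_outpatient_courses"]
EXPOSURE_CONFOUNDERS = ["delivery_mode", "race", "sex"]
DEFAULT_EXPOSURES = ["maternal_abx", "chorioamnionitis", "rom_gt18h",
                     "cmv_positive"]


def _encode(frame: pd.DataFrame) -> pd.DataFrame:
    """Booleans to 0/1, categoricals to dummies, numerics passed through."""
    out = {}
    for col in frame.columns:
        s = frame[col]
        if s.dtype == bool:
            out[col] = s.astype(float)
        elif pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in d.columns:
                out[c] = d[c]
    return pd.DataFrame(out, index=frame.index)


def _wald_record(effect: float, se: float) -> dict:
    z = effect / se if se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return dict(effect=float(effect), ci_low=float(effect - 1.96 * se),
                ci_high=float(effect + 1.96 * se), p_value=float(p))


def enrichment_by_term(label: pd.Series, samples: pd.DataFrame,
                       subjects: pd.DataFrame, *,
                       term: str = "ga_birth",
                       confounders: list[str] = ENRICHMENT_CONFOUNDERS,
                       ) -> pd.DataFrame:
    """Per-state log-odds of state membership per unit of ``term``.

    Binomial GLMM with a random subject intercept, fitted by MAP (Laplace);
    on failure falls back to a fixed-effects logistic GEE with
    subject-cluster robust errors, flagged in the ``model`` column.

    Parameters
    ----------
    label
        Hard state label per sample (aligned to ``samples.index``).
    samples
        Sample frame with a ``subject_id`` column.
    subjects
        Subject frame carrying ``term`` and the confounders.
    """
    df = samples[["subject_id"]].copy()
    df["state"] = label.reindex(df.index)
    covs = _encode(subjects[[term] + list(confounders)])
    # standardize for a well-conditioned Laplace fit; the term's effect is
    # rescaled back to per-unit afterwards
    scales = covs.std(ddof=0).replace(0, 1.0)
    covs = (covs - covs.mean()) / scales
    design = covs.loc[df["subject_id"]].set_index(df.index)
    term_col = design.columns[0]
    term_scale = float(scales.iloc[0])

    records = []
    for state in sorted(pd.unique(df["state"].dropna())):
        y = (df["state"] == state).astype(float)
        per_subject = y.groupby(df["subject_id"]).agg(["min", "max"])
        mixed = (per_subject["min"] != per_subject["max"]).sum()
        if y.sum() == 0:
            logger.info("state %s has no samples; skipped", state)
            continue
        if mixed < 2:
            logger.info("state %s: <2 subjects with mixed membership; skipped",
                        state)
            continue
        exog = sm.add_constant(design.to_numpy(), has_constant="add")
        groups, _ = pd.factorize(df["subject_id"])
        try:
            vc = np.zeros((len(y), groups.max() + 1))
            vc[np.arange(len(y)), groups] = 1.0
            model = BinomialBayesMixedGLM(y.to_numpy(), exog, vc,
                                          ident=np.zeros(vc.shape[1], dtype=int))
            # statsmodels draws the MAP start values from the global numpy
            # RNG; pin it (and BLAS threads) so the fit is reproducible
            rng_state = np.random.get_state()
            np.random.seed(20220301)
            try:
                with warnings_suppressed(), threadpool_limits(limits=1):
                    res = model.fit_map()
            finally:
                np.random.set_state(rng_state)
            effect, se = float(res.fe_mean[1]), float(res.fe_sd[1])
            model_name = "binomial_glmm_map"
            if not np.isfinite(effect) or not np.isfinite(se) or se == 0:
                raise RuntimeError("non-finite GLMM estimate")
        except Exception as exc:  # noqa: BLE001 - fall back, flagged
            logger.warning("GLMM failed for state %s (%s); GEE fallback",
                           state, exc)
            gee = sm.GEE(y.to_numpy(), exog, groups=groups,
                         family=sm.families.Binomial(),
                         cov_struct=sm.cov_struct.Independence())
            with warnings_suppressed():
                res = gee.fit()
            effect, se = float(res.params[1]), float(res.bse[1])
            model_name = "logistic_gee_fallback"
        rec = _wald_record(effect / term_scale, se / term_scale)
        rec.update(state=state, term=term_col, model=model_name)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["q_value"] = q
    return out


def _firth_logit(x: np.ndarray, y: np.ndarray, *, max_iter: int = 100,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-penalized (Firth-type) logistic fit; returns (beta, se)."""
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        xw = x * w[:, None]
        info = x.T @ xw
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, x)
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = x @ beta
    w = expit(eta) * (1 - expit(eta))
    se = np.sqrt(np.diag(np.linalg.pinv(x.T @ (x * w[:, None]))))
    return beta, se


def exposure_model(ever_in_state: pd.Series, subjects: pd.DataFrame, *,
                   exposures: list[str] = DEFAULT_EXPOSURES,
                   confounders: list[str] = EXPOSURE_CONFOUNDERS,
                   ga_col: str = "ga_birth", spline_df: int = 3,
                   fdr: float = 0.10) -> pd.DataFrame:
    """Joint logistic model of ever entering a state on perinatal exposures.

    Gestational age enters as a natural cubic spline (default 3 df); the
    exposures form a joint block and are each tested by a Wald z-test, with
    Benjamini-Hochberg correction across the exposure family at 10% FDR.
    Complete separation triggers a Firth-type (Jeffreys-penalized) refit,
    flagged in the ``model`` column.
    """
    y = ever_in_state.reindex(subjects.index).astype(float)
    if y.nunique() < 2:
        raise ValueError("ever_in_state has no variation")
    ga = subjects[ga_col].astype(float)
    # cr basis columns sum to one; drop the first so the smooth spans
    # spline_df degrees of freedom jointly with the model intercept
    spline = np.asarray(dmatrix(f"cr(x, df={spline_df}) - 1",
                                {"x": ga}, return_type="matrix"))[:, 1:]
    expo = _encode(subjects[list(exposures)])
    confs = _encode(subjects[list(confounders)])
    x = np.column_stack([np.ones(len(y)), expo.to_numpy(),
                         confs.to_numpy(), spline])
    model_name = "logistic"
    try:
        with warnings_suppressed():
            res = sm.Logit(y.to_numpy(), x).fit(disp=0, maxiter=200)
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.abs(params).max() > 15:
            raise RuntimeError("separation suspected")
    except Exception:  # noqa: BLE001 - separation or non-convergence
        params, bse = _firth_logit(x, y.to_numpy())
        model_name = "logistic_firth"
        logger.warning("exposure model used Firth-type penalization")

    records = []
    for j, name in enumerate(expo.columns, start=1):
        rec = _wald_record(float(params[j]), float(bse[j]))
        rec.update(exposure=name, model=model_name)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    rej, q, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
    out["q_value"] = q
    out["significant"] = rej
    return out


class warnings_suppressed:
    def __enter__(self):
        import warnings
        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)
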