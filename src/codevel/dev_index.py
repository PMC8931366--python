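"""The Developmental Index: cross-validated age prediction and BLUP trajectories.

A subject's maturation is quantified in two steps.  First, an elastic net
predicts log2(postmenstrual age) from a system's compositional features
(microbiota taxa, or T cell populations), with the subject's entire
longitudinal record held out of the fold that predicts it: the held-out
predictions are an unbiased "microbiota age" / "immune age" per sample.
Second, the held-out predictions are regressed on observed age with a
random-intercept-and-slope linear mixed model,

    yhat - log2(37) ~ log2(PMA/37) + (1 + log2(PMA/37) | subject),

and each subject's best linear unbiased predictor (BLUP) of the 37-week
intercept and maturation slope, divided by its conditional standard error
after median-centering, gives the subject's z-scored trajectory features.
The four features (intercept and slope for each system) form the
Developmental Index (DI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet

from .cohort_sim import (Cohort, DAYS_PER_WEEK, IMMUNE_SITES,
                         MICROBIOTA_SITES, TERM_WEEKS)

logger = logging.getLogger(__name__)

MICROBIOME_BLOCKS = {"nasal": "nasal", "rectal": "rectal"}


@dataclass
class FeatureBlockSet:
    """Per-sample feature vectors with whole-block missingness.

    Rows are (subject, DOL) observation units; each named block's columns
    are either fully present or fully NaN for a row (e.g. a visit with only
    a nasal swab has its rectal block missing).
    """

    x: pd.DataFrame                    # rows x features (NaN = missing block)
    blocks: dict[str, list[str]]       # block name -> its columns
    subject_id: pd.Series
    pma_days: pd.Series


@dataclass
class PMAPredictions:
    """Held-out log2(PMA weeks) predictions from grouped cross-validation."""

    yhat: pd.Series
    y: pd.Series
    fold: pd.Series
    subject_id: pd.Series
    alpha: float        # elastic-net mixing parameter in [0, 1]
    lam: float          # overall penalty
    r2_backtransformed: float
    r2_log: float


@dataclass
class TrajectoryIndex:
    """Per-subject BLUP 37-week intercepts/slopes with conditional SEs."""

    table: pd.DataFrame   # alpha, beta, se_alpha, se_beta, z_alpha, z_beta
    fixed_intercept: float
    fixed_slope: float
    diagonal_refit: bool = False


def assemble_features(cohort: Cohort, system: str, *, max_dol: int = 450,
                      min_taxa_prevalence: float = 0.03) -> FeatureBlockSet:
    """Collect one system's per-visit feature rows.

    ``system='microbiome'`` merges nasal and rectal relative abundances per
    (subject, DOL); taxa present in fewer than ``min_taxa_prevalence`` of a
    site's samples are removed.  ``system='immune'`` merges the two assay
    panels (already block-normalized relative abundances).  Samples at or
    after DOL ``max_dol`` are excluded.  Standardization is deferred to the
    training folds of the predictor.
    """
    if system == "microbiome":
        sites = MICROBIOTA_SITES
    elif system == "immune":
        sites = IMMUNE_SITES
    else:
        raise ValueError("system must be 'microbiome' or 'immune'")

    pieces, blocks = [], {}
    for site in sites:
        meta = cohort.samples[(cohort.samples["site"] == site)
                              & (cohort.samples["dol"] < max_dol)]
        if meta.empty:
            continue
        feats = cohort.features[site].loc[meta.index]
        if system == "microbiome":
            present = (feats > 0).mean(axis=0) >= min_taxa_prevalence
            feats = feats.loc[:, present]
            totals = feats.sum(axis=1).replace(0, 1.0)
            feats = feats.div(totals, axis=0)
        feats = feats.copy()
        feats.index = pd.MultiIndex.from_frame(
            meta[["subject_id", "dol"]].reset_index(drop=True))
        blocks[site] = list(feats.columns)
        pieces.append(feats)
    if not pieces:
        raise ValueError(f"no usable samples for system {system!r}")
    x = pd.concat(pieces, axis=1, join="outer").sort_index()
    subj = pd.Series([i[0] for i in x.index], index=x.index, name="subject_id")
    dol = np.array([i[1] for i in x.index], dtype=float)
    ga_days = cohort.subjects.loc[subj, "ga_birth"].to_numpy() * DAYS_PER_WEEK
    pma = pd.Series(ga_days + dol, index=x.index, name="pma_days")
    x = x.reset_index(drop=True)
    x.index.name = "row"
    subj.index = x.index
    pma.index = x.index
    return FeatureBlockSet(x=x, blocks=blocks, subject_id=subj, pma_days=pma)


def _grouped_folds(subjects: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Fold id per row; whole subjects assigned to folds in shuffled order."""
    uniq = np.unique(subjects)
    order = rng.permutation(uniq)
    fold_of = {s: i % n_folds for i, s in enumerate(order)}
    return np.array([fold_of[s] for s in subjects])


def _impute_scale(train: np.ndarray, test: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute and z-score using training-fold statistics only."""
    mean = np.nanmean(train, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    tr = np.where(np.isnan(train), mean, train)
    te = np.where(np.isnan(test), mean, test)
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd[sd == 0] = 1.0
    return (tr - mu) / sd, (te - mu) / sd


def _cv_mse(x: np.ndarray, y: np.ndarray, folds: np.ndarray, alpha: float,
            lam: float) -> float:
    errs = []
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        xtr, xte = _impute_scale(x[tr], x[te])
        net = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000)
        net.fit(xtr, y[tr])
        errs.append(float(((net.predict(xte) - y[te]) ** 2).sum()))
    return sum(errs) / len(y)


def tune_and_predict(features: FeatureBlockSet, *, seed: int = 0,
                     n_draws: int = 50, tune_folds: int = 5,
                     predict_folds: int = 10,
                     lam_range: tuple[float, float] = (0.001, 0.5),
                     ) -> PMAPredictions:
    """Subject-held-out elastic-net prediction of log2(PMA).

    Tuning draws ``n_draws`` uniform (alpha, lambda) pairs, alpha in [0, 1]
    and lambda in [0.001, 0.5], scoring each by test MSE under 5-fold
    subject-grouped cross-validation (log2 scale).  The winning pair is
    refit with 10-fold grouped CV to produce a held-out prediction for
    every sample; R-squared is reported both on the log2 scale and on the
    back-transformed 2^yhat scale.  Block-missing features are imputed with
    training-fold means and z-scored with training-fold statistics, inside
    every fold.
    """
    rng = np.random.default_rng(seed)
    x = features.x.to_numpy(dtype=float)
    subjects = features.subject_id.to_numpy()
    y = np.log2(features.pma_days.to_numpy(dtype=float) / DAYS_PER_WEEK)

    n_subj = len(np.unique(subjects))
    tune_folds = min(tune_folds, n_subj)
    if min(tune_folds, predict_folds) > n_subj:
        raise ValueError("fewer subjects than folds")
    if predict_folds > n_subj:
        logger.warning("reducing predict_folds to %d subjects", n_subj)
        predict_folds = n_subj

    folds5 = _grouped_folds(subjects, tune_folds, rng)
    draws = [(float(rng.uniform(0.0, 1.0)),
              float(rng.uniform(*lam_range))) for _ in range(n_draws)]
    scores = [_cv_mse(x, y, folds5, a, l) for a, l in draws]
    best = int(np.argmin(scores))
    alpha, lam = draws[best]

    folds10 = _grouped_folds(subjects, predict_folds, rng)
    yhat = np.empty_like(y)
    for f in np.unique(folds10):
        tr, te = folds10 != f, folds10 == f
        xtr, xte = _impute_scale(x[tr], x[te])
        net = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=5000)
        net.fit(xtr, y[tr])
        yhat[te] = net.predict(xte)

    pma_w = features.pma_days.to_numpy(dtype=float) / DAYS_PER_WEEK
    back = 2.0 ** yhat
    r2_back = 1.0 - ((back - pma_w) ** 2).sum() / \
        ((pma_w - pma_w.mean()) ** 2).sum()
    r2_log = 1.0 - ((yhat - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    idx = features.x.index
    return PMAPredictions(
        yhat=pd.Series(yhat, index=idx, name="yhat_log2_pma"),
        y=pd.Series(y, index=idx, name="log2_pma"),
        fold=pd.Series(folds10, index=idx, name="fold"),
        subject_id=features.subject_id,
        alpha=alpha, lam=lam, r2_backtransformed=float(r2_back),
        r2_log=float(r2_log))


def fit_trajectories(predictions: PMAPredictions) -> TrajectoryIndex:
    """Random-slope mixed model of held-out age predictions on observed age.

    REML fit of ``yhat - log2(37) ~ x + (1 + x | subject)`` with
    x = log2(PMA/37 weeks) and correlated random effects.  Per subject,
    alpha = fixed + random intercept (37-week maturity offset, log2 units)
    and beta = fixed + random slope (maturation rate per PMA doubling);
    conditional SEs come from the conditional covariance of the random
    effects, and z-scores follow (value - cohort median) / conditional SE.
    A singular random-effects covariance triggers a refit with independent
    (diagonal) random effects, flagged on the result.
    """
    yc = predictions.yhat.to_numpy() - np.log2(TERM_WEEKS)
    xs = predictions.y.to_numpy() - np.log2(TERM_WEEKS)  # log2(PMA/37)
    groups = predictions.subject_id.to_numpy()
    exog = sm.add_constant(xs)

    def _run(free=None):
        import warnings
        model = sm.MixedLM(yc, exog, groups=groups, exog_re=exog)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=True, free=free, method=["lbfgs", "powell"])

    diagonal = False
    try:
        res = _run()
        cov_re = np.asarray(res.cov_re)
        if np.linalg.eigvalsh(cov_re).min() <= 1e-10:
            raise np.linalg.LinAlgError("singular random-effects covariance")
    except Exception as exc:  # noqa: BLE001 - refit with diagonal structure
        logger.warning("correlated random effects failed (%s); "
                       "refitting with diagonal covariance", exc)
        from statsmodels.regression.mixed_linear_model import MixedLMParams
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2))
        res = _run(free=free)
        diagonal = True

    fe_int, fe_slope = float(res.fe_params[0]), float(res.fe_params[1])
    re = res.random_effects
    cond_cov = res.random_effects_cov
    rows = []
    for sid, eff in re.items():
        c = np.asarray(cond_cov[sid])
        rows.append(dict(subject_id=sid,
                         alpha=fe_int + float(eff.iloc[0]),
                         beta=fe_slope + float(eff.iloc[1]),
                         se_alpha=float(np.sqrt(max(c[0, 0], 0.0))),
                         se_beta=float(np.sqrt(max(c[1, 1], 0.0)))))
    table = pd.DataFrame(rows).set_index("subject_id").sort_index()
    for comp in ("alpha", "beta"):
        med = table[comp].median()
        se = table[f"se_{comp}"].replace(0, np.nan)
        table[f"z_{comp}"] = (table[comp] - med) / se
    return TrajectoryIndex(table=table, fixed_intercept=fe_int,
                           fixed_slope=fe_slope, diagonal_refit=diagonal)


def developmental_index(microbiome: TrajectoryIndex,
                        immune: TrajectoryIndex) -> pd.DataFrame:
    """The 4-feature DI: z-scored intercepts and slopes of both systems.

    Subjects fitted in either system are kept (union); entries for a system
    a subject is missing from are NaN, to be imputed downstream.
    """
    m = microbiome.table[["z_alpha", "z_beta"]].rename(
        columns={"z_alpha": "micro_z_alpha", "z_beta": "micro_z_beta"})
    t = immune.table[["z_alpha", "z_beta"]].rename(
        columns={"z_alpha": "immune_z_alpha", "z_beta": "immune_z_beta"})
    out = m.join(t, how="outer")
    if out.dropna(how="all").empty or m.index.intersection(t.index).empty:
        raise ValueError("no subjects shared between systems")
    return out[["micro_z_alpha", "micro_z_beta",
                "immune_z_alpha", "immune_z_beta"]]
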