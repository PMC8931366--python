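"""Random-forest prediction of the respiratory outcome (PRD).

Compares the predictive skill of (a) clinical risk factors and (b) the
4-feature Developmental Index.  Hyperparameters (mtry / ntree / nodesize in
random-forest parlance: max_features, n_estimators, min_samples_leaf) are
tuned by seeded random search under 5-fold stratified cross-validation;
skill is then evaluated with 20-fold stratified cross-validation and
summarized as the per-fold AUC mean and standard error.  A clamped-grid
partial-dependence surface exposes the joint effect of two features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CLINICAL_FEATURES = ["race", "maternal_education", "sex", "ga_birth",
                     "birthweight", "season", "fio2_14d"]


@dataclass
class RFHyperparameters:
    mtry: int           # max_features
    ntree: int          # n_estimators
    nodesize: int       # min_samples_leaf
    cv_auc: float       # mean tuning AUC of the winner


@dataclass
class RFEvaluation:
    feature_set: str
    hyperparameters: RFHyperparameters
    fold_aucs: list[float]
    mean_auc: float
    se_auc: float
    importances: pd.Series
    model: RandomForestClassifier


def encode_clinical(subjects: pd.DataFrame,
                    columns: list[str] = CLINICAL_FEATURES) -> pd.DataFrame:
    """Dummy-encode the clinical risk-factor set."""
    out = {}
    for col in columns:
        s = subjects[col]
        if pd.api.types.is_numeric_dtype(s) or s.dtype == bool:
            out[col] = s.astype(float)
        else:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in d.columns:
                out[c] = d[c]
    return pd.DataFrame(out, index=subjects.index)


def _impute_median(train: np.ndarray, test: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    return (np.where(np.isnan(train), med, train),
            np.where(np.isnan(test), med, test))


def _forest(hp: RFHyperparameters | tuple, seed: int) -> RandomForestClassifier:
    mtry, ntree, nodesize = ((hp.mtry, hp.ntree, hp.nodesize)
                             if isinstance(hp, RFHyperparameters) else hp)
    return RandomForestClassifier(n_estimators=int(ntree),
                                  max_features=int(mtry),
                                  min_samples_leaf=int(nodesize),
                                  random_state=seed, n_jobs=1)


def _cv_auc(x: np.ndarray, y: np.ndarray, hp: tuple, n_folds: int,
            seed: int) -> list[float]:
    """Per-fold out-of-fold AUCs; folds without both classes are merged
    forward into their neighbor."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, pending_scores, pending_y = [], None, None
    for f, (tr, te) in enumerate(skf.split(x, y)):
        xtr, xte = _impute_median(x[tr], x[te])
        clf = _forest(hp, seed + f)
        clf.fit(xtr, y[tr])
        scores = clf.predict_proba(xte)[:, 1]
        yte = y[te]
        if pending_scores is not None:
            scores = np.concatenate([pending_scores, scores])
            yte = np.concatenate([pending_y, yte])
            pending_scores = pending_y = None
        if len(np.unique(yte)) < 2:
            logger.info("fold %d lacks both classes; merging with neighbor", f)
            pending_scores, pending_y = scores, yte
            continue
        aucs.append(float(roc_auc_score(yte, scores)))
    if pending_scores is not None and aucs:
        logger.info("trailing single-class fold merged into last AUC fold")
    return aucs


def rf_tune(features: pd.DataFrame, outcome: pd.Series, *, seed: int = 0,
            n_draws: int = 50, n_folds: int = 5,
            ntree_range: tuple[int, int] = (250, 2000),
            nodesize_range: tuple[int, int] = (1, 20)) -> RFHyperparameters:
    """Random search over (mtry, ntree, nodesize) maximizing mean CV AUC."""
    y = outcome.reindex(features.index).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    x = features.to_numpy(dtype=float)
    p = x.shape[1]
    rng = np.random.default_rng(seed)
    best, best_auc = None, -np.inf
    for _ in range(n_draws):
        hp = (int(rng.integers(1, p + 1)),
              int(rng.integers(ntree_range[0], ntree_range[1] + 1)),
              int(rng.integers(nodesize_range[0], nodesize_range[1] + 1)))
        aucs = _cv_auc(x, y, hp, n_folds, seed)
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best, best_auc = hp, mean_auc
    return RFHyperparameters(mtry=best[0], ntree=best[1], nodesize=best[2],
                             cv_auc=best_auc)


def rf_evaluate(features: pd.DataFrame, outcome: pd.Series,
                hyperparameters: RFHyperparameters, *, seed: int = 0,
                n_folds: int = 20,
                feature_set: str = "features") -> RFEvaluation:
    """Evaluate tuned hyperparameters with stratified 20-fold CV.

    Reports the per-fold out-of-fold AUCs, their mean and standard error,
    permutation variable importances from a full-data refit, and the
    refitted forest (for partial dependence)."""
    y = outcome.reindex(features.index).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    x = features.to_numpy(dtype=float)
    n_folds = min(n_folds, int(np.bincount(y).min()) * 2, len(y))
    aucs = _cv_auc(x, y, hyperparameters, n_folds, seed)
    mean_auc = float(np.mean(aucs))
    se_auc = float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))) \
        if len(aucs) > 1 else np.nan

    x_full, _ = _impute_median(x, x)
    clf = _forest(hyperparameters, seed)
    clf.fit(x_full, y)
    imp = permutation_importance(clf, x_full, y, n_repeats=10,
                                 random_state=seed, scoring="roc_auc")
    importances = pd.Series(imp.importances_mean, index=features.columns,
                            name="permutation_importance")
    return RFEvaluation(feature_set=feature_set,
                        hyperparameters=hyperparameters, fold_aucs=aucs,
                        mean_auc=mean_auc, se_auc=se_auc,
                        importances=importances, model=clf)


def partial_dependence(model: RandomForestClassifier, features: pd.DataFrame,
                       feature_pair: tuple[str, str],
                       grid: tuple[np.ndarray, np.ndarray] | int = 20,
                       ) -> pd.DataFrame:
    """Mean predicted outcome probability over a 2-feature clamped grid.

    Every grid point clamps the pair to fixed values across the whole data
    set and averages the forest's predicted probability; the result is a
    tidy frame (feature_a, feature_b, mean_prediction, extrapolated) ready
    for contour plotting.  Grid points outside the observed range are
    flagged as extrapolation with a warning.
    """
    fa, fb = feature_pair
    x = features.to_numpy(dtype=float)
    x, _ = _impute_median(x, x)
    ia, ib = features.columns.get_loc(fa), features.columns.get_loc(fb)
    if isinstance(grid, int):
        ga = np.linspace(x[:, ia].min(), x[:, ia].max(), grid)
        gb = np.linspace(x[:, ib].min(), x[:, ib].max(), grid)
    else:
        ga, gb = (np.asarray(g, dtype=float) for g in grid)
    lo_a, hi_a = x[:, ia].min(), x[:, ia].max()
    lo_b, hi_b = x[:, ib].min(), x[:, ib].max()
    rows = []
    for va in ga:
        for vb in gb:
            xx = x.copy()
            xx[:, ia] = va
            xx[:, ib] = vb
            pred = float(model.predict_proba(xx)[:, 1].mean())
            extrap = not (lo_a <= va <= hi_a and lo_b <= vb <= hi_b)
            rows.append({fa: float(va), fb: float(vb),
                         "mean_prediction": pred, "extrapolated": extrap})
    out = pd.DataFrame(rows)
    if out["extrapolated"].any():
        logger.warning("%d partial-dependence grid points extrapolate beyond "
                       "the observed range", int(out["extrapolated"].sum()))
    return out
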