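"""End-to-end driver: simulate/load -> state types -> variance -> enrichment
-> durations + association scan -> developmental index -> outcome model.

Stages are cached on the driver object, so the CLI subcommands can request a
single stage and only its dependencies are computed.  Every output file
carries the seed and a hash of the resolved configuration in '#' header
comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort_sim import (ALL_SITES, Cohort, IMMUNE_SITES, MICROBIOTA_SITES,
                         SimConfig, generate_cohort)
from .dev_index import (assemble_features, developmental_index,
                        fit_trajectories, tune_and_predict)
from .duration_axis import (DurationTable, apply_inclusion, association_scan,
                            build_durations, confounder_frame)
from .outcome_model import (encode_clinical, partial_dependence, rf_evaluate,
                            rf_tune)
from .state_associations import enrichment_by_term, exposure_model
from .state_models import (assign_and_enumerate, filter_prevalence,
                           normalize_counts, select_k)
from .variance_partition import (fit_multivariate, manova_bic, manova_r2,
                                 prepare_block)

logger = logging.getLogger(__name__)

DEFAULT_DEPTH_CONSTANTS = {"nasal": 1200, "rectal": 2250,
                           "immune_tphe": 50000, "immune_ics": 50000}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (see the bundled demo.yaml)."""

    seed: int = 0
    output_dir: str = "codevel_out"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    states: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    dev_index: dict = field(default_factory=dict)
    outcome: dict = field(default_factory=dict)
    inputs: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, {f.name for f in dataclasses.fields(cls)}, "config")
        cfg = cls(**raw)
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        _check_keys(cfg.simulate, sim_fields - {"seed"}, "simulate")
        _check_keys(cfg.states, {"k_min", "k_max", "min_prevalence",
                                 "depth_constants", "tol", "max_iter"},
                    "states")
        _check_keys(cfg.scan, {"preset", "fdr", "fdr_scope", "max_vois",
                               "min_voi_obs", "min_state_frac"}, "scan")
        _check_keys(cfg.dev_index, {"n_draws", "max_dol",
                                    "min_taxa_prevalence"}, "dev_index")
        _check_keys(cfg.outcome, {"n_draws", "eval_folds"}, "outcome")
        if cfg.inputs is not None:
            _check_keys(cfg.inputs, {"metadata"} | set(ALL_SITES), "inputs")
            for key, p in cfg.inputs.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"inputs.{key}: {p}")
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded,
        so the same analysis written elsewhere hashes identically)."""
        d = dataclasses.asdict(self)
        for key in ("output_dir", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_cohort(inputs: dict) -> Cohort:
    """Assemble a cohort from on-disk tables (metadata TSV + per-site
    feature tables); microbiota tables are counts, immune tables relative
    abundances.  Sample ids must be '<subject>_<site>_d<dol>'."""
    subjects = cio.read_tsv(inputs["metadata"])
    sample_rows, features = [], {}
    for site in ALL_SITES:
        if site not in inputs:
            continue
        if site in MICROBIOTA_SITES:
            mat = cio.read_counts(inputs[site])
        else:
            mat = cio.read_tsv(inputs[site])
        features[site] = mat
        for sample_id in mat.index:
            subject_id, _, dtag = sample_id.rsplit("_", 2)
            dol = int(dtag.lstrip("d"))
            sample_rows.append(dict(
                sample_id=sample_id, subject_id=subject_id, site=site,
                dol=dol,
                pma_days=float(subjects.loc[subject_id, "ga_birth"]) * 7 + dol,
                illness=False))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    cohort = Cohort(subjects=subjects, samples=samples, features=features)
    cohort.validate()
    return cohort


def site_composition(cohort: Cohort, site: str) -> pd.DataFrame:
    """Relative-abundance matrix of a site (counts renormalized; immune
    tables pass through)."""
    feats = cohort.features[site]
    if site in MICROBIOTA_SITES:
        totals = feats.sum(axis=1).replace(0, 1.0)
        return feats.div(totals, axis=0)
    return feats


def match_cross_system(cohort: Cohort, site_a: str, site_b: str,
                       tol_days: int = 45) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-wise pairing of two sites: each site-a sample is matched to the
    nearest same-subject site-b sample within ``tol_days``; unmatched
    samples are deleted case-wise."""
    meta = cohort.samples
    a = meta[meta["site"] == site_a].reset_index()
    b = meta[meta["site"] == site_b].reset_index()
    pairs = []
    for sid, ga in a.groupby("subject_id"):
        gb = b[b["subject_id"] == sid]
        if gb.empty:
            continue
        for _, row in ga.iterrows():
            d = (gb["dol"] - row["dol"]).abs()
            j = d.idxmin()
            if d.loc[j] <= tol_days:
                pairs.append((row["sample_id"], gb.loc[j, "sample_id"]))
    if not pairs:
        raise ValueError(f"no matched samples between {site_a} and {site_b}")
    ia, ib = zip(*pairs)
    comp_a = site_composition(cohort, site_a).loc[list(ia)]
    comp_b = site_composition(cohort, site_b).loc[list(ib)]
    comp_b.index = comp_a.index
    return comp_a, comp_b


class PipelineDriver:
    """Caches stage outputs; see :func:`run_pipeline` for the one-shot API."""

    def __init__(self, config: RunConfig):
        self.config = config
        self._cache: dict[str, object] = {}
        self.timings: dict[str, float] = {}

    def _stage(self, name: str, fn):
        if name not in self._cache:
            t0 = time.perf_counter()
            self._cache[name] = fn()
            self.timings[name] = time.perf_counter() - t0
            logger.info("stage %-12s %.1fs", name, self.timings[name])
        return self._cache[name]

    # -- stages ---------------------------------------------------------
    @property
    def cohort(self) -> Cohort:
        def build():
            if self.config.inputs:
                return load_cohort(self.config.inputs)
            sim = SimConfig(**self.config.simulate, seed=self.config.seed)
            return generate_cohort(sim)
        return self._stage("cohort", build)

    def states(self) -> dict:
        def build():
            cfg = self.config.states
            k_range = range(int(cfg.get("k_min", 1)), int(cfg.get("k_max", 7)) + 1)
            depth = {**DEFAULT_DEPTH_CONSTANTS,
                     **cfg.get("depth_constants", {})}
            out = {}
            for site in ALL_SITES:
                if site not in self.cohort.features:
                    continue
                comp = site_composition(self.cohort, site)
                if site in MICROBIOTA_SITES:
                    counts = filter_prevalence(
                        self.cohort.features[site],
                        cfg.get("min_prevalence", 0.05))
                    comp = comp[counts.columns]
                norm = normalize_counts(comp, depth[site])
                best_k, fits = select_k(
                    norm, k_range, seed=self.config.seed,
                    tol=float(cfg.get("tol", 1e-6)),
                    max_iter=int(cfg.get("max_iter", 1000)))
                pma = self.cohort.samples.loc[norm.counts.index, "pma_days"]
                assignment = assign_and_enumerate(fits[best_k], norm, pma)
                out[site] = dict(best_k=best_k, fit=fits[best_k],
                                 assignment=assignment)
            return out
        return self._stage("states", build)

    def variance(self) -> pd.DataFrame:
        def build():
            cohort = self.cohort
            rows = []
            # age models per site, controlling for preterm birth
            for site in ALL_SITES:
                comp = site_composition(cohort, site)
                block = prepare_block(comp)
                meta = cohort.samples.loc[comp.index]
                preterm = cohort.subjects.loc[meta["subject_id"],
                                              "preterm"].astype(float).to_numpy()
                for age in ("pma_days", "dol"):
                    x_age = meta[age].to_numpy(dtype=float)
                    full = np.column_stack([preterm, x_age])
                    res = manova_r2(block, full, preterm[:, None])
                    bic = manova_bic(fit_multivariate(block, full))
                    rows.append(dict(pair=f"{age}->{site}", adjustment="preterm",
                                     r2_adj=res.r2_adj, wilks_p=res.p_value,
                                     bic=bic, n=res.n_obs))
            # cross-system pairs, unadjusted and PMA-adjusted
            pairs = [("immune_tphe", "nasal"), ("immune_tphe", "rectal"),
                     ("nasal", "rectal")]
            for sa, sb in pairs:
                try:
                    comp_a, comp_b = match_cross_system(cohort, sa, sb)
                except ValueError:
                    continue
                resp = prepare_block(comp_a)
                pred = prepare_block(comp_b).coords.to_numpy()
                meta = cohort.samples.loc[comp_a.index]
                pma = meta["pma_days"].to_numpy(dtype=float)[:, None]
                res0 = manova_r2(resp, pred)
                rows.append(dict(pair=f"{sb}->{sa}", adjustment="none",
                                 r2_adj=res0.r2_adj, wilks_p=res0.p_value,
                                 bic=np.nan, n=res0.n_obs))
                res1 = manova_r2(resp, np.column_stack([pma, pred]), pma)
                rows.append(dict(pair=f"{sb}->{sa}", adjustment="pma",
                                 r2_adj=res1.r2_adj, wilks_p=res1.p_value,
                                 bic=np.nan, n=res1.n_obs))
            return pd.DataFrame(rows)
        return self._stage("variance", build)

    def enrichment(self) -> dict[str, pd.DataFrame]:
        def build():
            out = {}
            for site, st in self.states().items():
                label = st["assignment"].label
                mask = self.cohort.samples["site"] == site
                out[site] = enrichment_by_term(
                    label, self.cohort.samples.loc[mask], self.cohort.subjects)
            return out
        return self._stage("enrichment", build)

    def exposures(self) -> dict[str, pd.DataFrame]:
        def build():
            out = {}
            for site in IMMUNE_SITES:
                if site not in self.states():
                    continue
                st = self.states()[site]
                label = st["assignment"].label
                subj = self.cohort.samples.loc[label.index, "subject_id"]
                for state in sorted(label.unique()):
                    ever = label.eq(state).groupby(subj.to_numpy()).any()
                    ever = ever.reindex(self.cohort.subjects.index,
                                        fill_value=False)
                    if ever.nunique() < 2:
                        continue
                    try:
                        tab = exposure_model(ever, self.cohort.subjects)
                    except ValueError:
                        continue
                    tab.insert(0, "state", state)
                    tab.insert(0, "site", site)
                    out.setdefault(site, []).append(tab)
            return {site: pd.concat(tabs, ignore_index=True)
                    for site, tabs in out.items()}
        return self._stage("exposures", build)

    def immune_vois(self) -> dict[str, pd.DataFrame]:
        """Per-timepoint (subject x VOI) tables: T cell population relative
        abundances plus IST indicators; NaN marks unobserved subjects."""
        def build():
            cohort = self.cohort
            tables: dict[str, list[pd.DataFrame]] = {
                "birth": [], "discharge": [], "one_year": []}
            for site in IMMUNE_SITES:
                if site not in cohort.features:
                    continue
                meta = cohort.samples[cohort.samples["site"] == site]
                feats = cohort.features[site].loc[meta.index].add_prefix(
                    f"{site}:")
                if site in self.states():
                    lab = self.states()[site]["assignment"].label.loc[meta.index]
                    ind = pd.get_dummies(lab, prefix=f"{site}:ist",
                                         dtype=float)
                    feats = pd.concat([feats, ind], axis=1)
                tp = pd.Series(np.where(meta["dol"] <= 14, "birth",
                               np.where(meta["dol"] >= 300, "one_year",
                                        "discharge")), index=meta.index)
                for name in tables:
                    sel = meta.index[tp == name]
                    if len(sel) == 0:
                        continue
                    block = feats.loc[sel].copy()
                    block.index = meta.loc[sel, "subject_id"]
                    block = block[~block.index.duplicated()]
                    tables[name].append(block)
            return {name: pd.concat(parts, axis=1)
                    for name, parts in tables.items() if parts}
        return self._stage("immune_vois", build)

    def durations(self) -> dict[str, DurationTable]:
        def build():
            out = {}
            for site in MICROBIOTA_SITES:
                if site not in self.states():
                    continue
                st = self.states()[site]
                mask = self.cohort.samples["site"] == site
                samp = self.cohort.samples.loc[mask, ["subject_id", "dol"]].copy()
                samp["state"] = st["assignment"].label.loc[samp.index]
                dur = build_durations(samp)
                dur = apply_inclusion(dur, samp,
                                      self.cohort.subjects["discharge_dol"])
                out[site] = dur
            return out
        return self._stage("durations", build)

    def associations(self) -> pd.DataFrame:
        def build():
            cfg = self.config.scan
            vois = self.immune_vois()
            max_vois = cfg.get("max_vois")
            if max_vois:
                vois = {tp: tab.iloc[:, :int(max_vois)]
                        for tp, tab in vois.items()}
            confs = confounder_frame(self.cohort.subjects,
                                     cfg.get("preset", "adjusted"))
            parts = []
            for site, dur in self.durations().items():
                scan = association_scan(
                    dur, vois, confs,
                    min_voi_obs=int(cfg.get("min_voi_obs", 10)),
                    min_state_frac=float(cfg.get("min_state_frac", 0.10)),
                    fdr=float(cfg.get("fdr", 0.10)),
                    fdr_scope=cfg.get("fdr_scope", "global"))
                if not scan.empty:
                    scan.insert(0, "site", site)
                parts.append(scan)
            return pd.concat(parts, ignore_index=True)
        return self._stage("associations", build)

    def dev_index(self) -> dict:
        def build():
            cfg = self.config.dev_index
            out: dict = {"systems": {}}
            for system in ("microbiome", "immune"):
                try:
                    feats = assemble_features(
                        self.cohort, system,
                        max_dol=int(cfg.get("max_dol", 450)),
                        min_taxa_prevalence=float(
                            cfg.get("min_taxa_prevalence", 0.03)))
                except (ValueError, KeyError) as exc:
                    logger.warning("system %s unavailable (%s); DI restricted",
                                   system, exc)
                    continue
                preds = tune_and_predict(feats, seed=self.config.seed,
                                         n_draws=int(cfg.get("n_draws", 50)))
                traj = fit_trajectories(preds)
                out["systems"][system] = dict(predictions=preds,
                                              trajectories=traj)
            systems = out["systems"]
            if {"microbiome", "immune"} <= systems.keys():
                out["di"] = developmental_index(
                    systems["microbiome"]["trajectories"],
                    systems["immune"]["trajectories"])
            elif systems:
                only = next(iter(systems.values()))["trajectories"].table
                out["di"] = only[["z_alpha", "z_beta"]]
            else:
                raise RuntimeError("no system has usable developmental data")
            return out
        return self._stage("dev_index", build)

    def outcome(self) -> dict:
        def build():
            cfg = self.config.outcome
            subjects = self.cohort.subjects
            prd = subjects["prd"]
            clinical = encode_clinical(subjects)
            di = self.dev_index()["di"].reindex(subjects.index)
            combined = clinical.join(di)
            feature_sets = {"clinical": clinical, "di": di,
                            "combined": combined}
            res = {}
            for name, feats in feature_sets.items():
                hp = rf_tune(feats, prd, seed=self.config.seed,
                             n_draws=int(cfg.get("n_draws", 50)))
                res[name] = rf_evaluate(
                    feats, prd, hp, seed=self.config.seed,
                    n_folds=int(cfg.get("eval_folds", 20)),
                    feature_set=name)
            if {"micro_z_alpha", "immune_z_beta"} <= set(di.columns):
                res["partial_dependence"] = partial_dependence(
                    res["di"].model, di,
                    ("micro_z_alpha", "immune_z_beta"), grid=15)
            return res
        return self._stage("outcome", build)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and persist the artifact bundle to
    ``config.output_dir``; returns the in-memory artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    driver = PipelineDriver(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]

    cohort = driver.cohort
    cio.write_tsv(cohort.subjects, out / "subjects.tsv", comments=tag)
    cio.write_tsv(cohort.samples, out / "samples.tsv", comments=tag)
    if cohort.truth is not None:
        from .cohort_sim import truth_table
        cio.write_tsv(truth_table(cohort), out / "truth.tsv", comments=tag)
    for site in cohort.features:
        cio.write_counts(cohort.features[site].round(6),
                         out / f"features_{site}.tsv", comments=tag)

    states = driver.states()
    for site, st in states.items():
        fitd = dict(k=st["best_k"], alpha=st["fit"].alpha.tolist(),
                    weights=st["fit"].weights.tolist(),
                    loglik=st["fit"].loglik,
                    neg_log_evidence=st["fit"].neg_log_evidence)
        (out / f"dmm_{site}.json").write_text(json.dumps(fitd, indent=1))
        assign = pd.DataFrame({
            "state": st["assignment"].label,
            "max_posterior": st["assignment"].posterior.max(axis=1)})
        cio.write_tsv(assign, out / f"states_{site}.tsv", comments=tag, float_format="%.6g")

    cio.write_tsv(driver.variance(), out / "variance.tsv", comments=tag,
                  index=False, float_format="%.6g")
    for site, tab in driver.enrichment().items():
        if not tab.empty:
            cio.write_tsv(tab, out / f"enrichment_{site}.tsv", comments=tag,
                          index=False, float_format="%.6g")
    for site, tab in driver.exposures().items():
        cio.write_tsv(tab, out / f"exposures_{site}.tsv", comments=tag,
                      index=False, float_format="%.6g")
    for site, dur in driver.durations().items():
        tidy = dur.days.copy()
        tidy["total_days"] = dur.total_days
        tidy["included"] = dur.included
        tidy["reason"] = dur.reason
        cio.write_tsv(tidy, out / f"durations_{site}.tsv", comments=tag, float_format="%.6g")
    cio.write_tsv(driver.associations(), out / "associations.tsv",
                  comments=tag, index=False, float_format="%.6g")

    dev = driver.dev_index()
    for system, block in dev["systems"].items():
        preds = block["predictions"]
        cio.write_tsv(pd.DataFrame({
            "subject_id": preds.subject_id, "fold": preds.fold,
            "log2_pma": preds.y, "yhat": preds.yhat}),
            out / f"pma_predictions_{system}.tsv", comments=tag, float_format="%.6g")
        cio.write_tsv(block["trajectories"].table,
                      out / f"trajectories_{system}.tsv", comments=tag, float_format="%.6g")
    cio.write_tsv(dev["di"], out / "developmental_index.tsv", comments=tag, float_format="%.6g")

    res = driver.outcome()
    summary = {name: dict(mean_auc=ev.mean_auc, se_auc=ev.se_auc,
                          fold_aucs=ev.fold_aucs,
                          hyperparameters=dataclasses.asdict(
                              ev.hyperparameters))
               for name, ev in res.items() if hasattr(ev, "mean_auc")}
    (out / "prd_evaluation.json").write_text(json.dumps(summary, indent=1))
    if "partial_dependence" in res:
        cio.write_tsv(res["partial_dependence"],
                      out / "partial_dependence.tsv", comments=tag,
                      index=False, float_format="%.6g")
    (out / "timings.json").write_text(json.dumps(driver.timings, indent=1))
    return dict(driver=driver, states=states, dev_index=dev, outcome=res)
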