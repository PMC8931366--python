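"""Synthetic longitudinal cohorts of microbiota and T cell samples.

Generates a mixed preterm/full-term birth cohort with the data structure the
downstream stages assume: weekly inpatient and monthly outpatient microbiota
sampling (nasal + rectal 16S count tables), T cell population compositions at
birth / discharge / one year (two assays, CD4 and CD8 blocks), per-subject
maturation heterogeneity, latent PMA-ordered community states emitting
Dirichlet-multinomial counts, and a binary respiratory outcome (PRD) coupled
to the subject's true developmental-index features.

Every latent quantity is retained in a ground-truth block so recovery of
states, trajectories and outcome signal can be tested against known values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

MICROBIOTA_SITES = ("nasal", "rectal")
IMMUNE_SITES = ("immune_tphe", "immune_ics")
ALL_SITES = MICROBIOTA_SITES + IMMUNE_SITES

#: days per gestational week; PMA_days = GA_birth_days + DOL
DAYS_PER_WEEK = 7.0
TERM_WEEKS = 37.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults emulate the structure of a mixed preterm/full-term birth
    cohort followed through the first year: gestational ages spanning 23-42
    weeks, weekly inpatient then monthly outpatient microbiota swabs, blood
    draws at three timepoints, and a ~30% prevalence respiratory outcome.
    """

    n_subjects: int = 80
    preterm_fraction: float = 0.55
    ga_range_weeks: tuple[float, float] = (23.0, 42.0)
    n_taxa_nasal: int = 40
    n_taxa_rectal: int = 40
    n_immune_pops: int = 26
    k_states: int = 13
    #: Dirichlet precision of each latent state's composition; np.inf collapses
    #: each state onto its mean composition (multinomial-only noise).
    state_concentration: float = 50.0
    depth_range: tuple[int, int] = (1200, 5000)
    inpatient_interval_days: int = 7
    outpatient_interval_days: int = 30
    followup_days: int = 450
    #: (intercept_sd, slope_sd) of per-subject maturation deviations around
    #: the population trajectory m(t) = log2(PMA / 37wk).
    trajectory_sd: tuple[float, float] = (0.15, 0.15)
    #: logistic scale of the cumulative-logit state model (smaller = states
    #: track maturation more deterministically).
    state_scale: float = 0.12
    #: logistic coefficients of PRD on the 4 true developmental-index
    #: features (micro intercept, micro slope, immune intercept, immune
    #: slope), each expressed per SD of the generating law.
    prd_coefs: tuple[float, float, float, float] = (-0.8, 0.0, 0.0, 0.8)
    prd_intercept: float = -1.0
    illness_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_taxa_nasal", "n_taxa_rectal",
                     "n_immune_pops", "k_states"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_states < 2:
            raise ValueError("k_states must be >= 2")
        if not 0.0 <= self.preterm_fraction <= 1.0:
            raise ValueError("preterm_fraction must lie in [0, 1]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        lo, hi = self.ga_range_weeks
        if not (lo < TERM_WEEKS < hi):
            raise ValueError("ga_range_weeks must straddle 37 weeks")
        if any(s < 0 for s in self.trajectory_sd):
            raise ValueError("trajectory_sd components must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth retained by the generator for recovery tests."""

    #: per-subject frame: trajectory deviations, DI z-features, PRD probability
    subjects: pd.DataFrame
    #: per-sample latent state index (0-based), aligned to Cohort.samples
    latent_state: pd.Series


@dataclass
class Cohort:
    """A simulated or loaded cohort.

    subjects
        One row per subject (indexed by ``subject_id``): gestational age,
        discharge day, covariates and the binary PRD outcome.
    samples
        One row per sample (indexed by ``sample_id``): subject, site, DOL,
        PMA in days, illness flag.
    features
        Per-site feature matrices (rows = sample_ids of that site).
        Microbiota sites hold integer counts; immune sites hold relative
        abundances summing to one within each (assay, CD4/CD8) block.
    """

    subjects: pd.DataFrame
    samples: pd.DataFrame
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: Optional[CohortTruth] = None

    def validate(self) -> None:
        if not self.samples["subject_id"].isin(self.subjects.index).all():
            raise ValueError("sample refers to unknown subject_id")
        pma = (self.subjects.loc[self.samples["subject_id"], "ga_birth"].to_numpy()
               * DAYS_PER_WEEK + self.samples["dol"].to_numpy())
        if not np.allclose(pma, self.samples["pma_days"].to_numpy()):
            raise ValueError("pma_days != GA_birth_days + DOL")
        dup = self.samples.duplicated(subset=["subject_id", "site", "dol"])
        if dup.any():
            raise ValueError("duplicate (subject, site, dol) keys")


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # Substream per subject: adding subjects never perturbs existing ones.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1_000_000 + site_index,)))


def _state_means(rng: np.random.Generator, k: int, n_features: int) -> np.ndarray:
    """K x J matrix of state mean compositions, one taxon block boosted per state."""
    logits = rng.normal(0.0, 0.5, size=(k, n_features))
    blocks = np.array_split(np.arange(n_features), k)
    for s, idx in enumerate(blocks):
        logits[s, idx] += 2.5
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def _state_thresholds(config: SimConfig) -> np.ndarray:
    """Cumulative-logit cutpoints evenly spaced over the maturation range."""
    lo = np.log2(config.ga_range_weeks[0] / TERM_WEEKS)
    hi = np.log2((config.ga_range_weeks[1]
                  + config.followup_days / DAYS_PER_WEEK) / TERM_WEEKS)
    k = config.k_states
    return lo + (hi - lo) * np.arange(1, k) / k


def _draw_state(rng: np.random.Generator, m: float, cuts: np.ndarray,
                scale: float) -> int:
    """Ordinal draw: P(S <= s) = expit((c_s - m) / scale); returns 0-based state."""
    cdf = expit((cuts - m) / scale)
    u = rng.random()
    return int(np.searchsorted(cdf, u))


def _sampling_days(discharge_dol: int, config: SimConfig) -> list[int]:
    """Weekly inpatient visits, then monthly outpatient through follow-up."""
    days = list(range(3, int(discharge_dol) + 1, config.inpatient_interval_days))
    out_start = int(discharge_dol) + config.outpatient_interval_days
    days += list(range(out_start, config.followup_days + 1,
                       config.outpatient_interval_days))
    return sorted(set(days))


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a cohort; deterministic given ``config.seed``.

    Latent maturation of subject i at postmenstrual age t (days) is
    ``m_i(t) = a_i + (1 + b_i) * log2(t / 37wk)`` with intercept/slope
    deviations (a_i, b_i) drawn from zero-mean normals with the configured
    SDs.  Each sample's latent state follows a cumulative-logit ordinal model
    on m_i(t), so the state index rises stochastically with PMA; microbiota
    counts are Dirichlet-multinomial draws from the state's composition, and
    immune compositions are state-specific Dirichlet draws within each
    (assay, CD4/CD8) block.  PRD is Bernoulli with logistic probability in
    the subject's four true developmental-index features.
    """
    n_taxa = {"nasal": config.n_taxa_nasal, "rectal": config.n_taxa_rectal}
    min_features = min(config.n_taxa_nasal, config.n_taxa_rectal,
                       (config.n_immune_pops + 1) // 2)
    if config.k_states > min_features:
        raise ValueError("k_states exceeds the smallest feature-block size")
    if config.followup_days < config.inpatient_interval_days:
        raise ValueError("followup_days shorter than one sampling interval")

    cuts = _state_thresholds(config)
    site_means: dict[str, np.ndarray] = {}
    for si, site in enumerate(MICROBIOTA_SITES):
        site_means[site] = _state_means(_site_rng(config.seed, si),
                                        config.k_states, n_taxa[site])
    # immune assays: separate state-mean structure per (assay, CD4/CD8) block
    n_cd4 = (config.n_immune_pops + 1) // 2
    immune_blocks = {"CD4": n_cd4, "CD8": config.n_immune_pops - n_cd4}
    immune_means: dict[tuple[str, str], np.ndarray] = {}
    for si, site in enumerate(IMMUNE_SITES):
        for bi, (block, nb) in enumerate(immune_blocks.items()):
            if nb == 0:
                continue
            immune_means[site, block] = _state_means(
                _site_rng(config.seed, 100 + 10 * si + bi), config.k_states, nb)

    taxa_ids = {site: [f"{site[:3]}_taxon_{j:03d}" for j in range(n_taxa[site])]
                for site in MICROBIOTA_SITES}
    immune_ids = [f"CD4_pop{j:02d}" for j in range(n_cd4)] + \
                 [f"CD8_pop{j:02d}" for j in range(config.n_immune_pops - n_cd4)]

    sd_a, sd_b = config.trajectory_sd
    subj_rows, sample_rows, truth_rows = [], [], []
    feat_rows: dict[str, list[np.ndarray]] = {s: [] for s in ALL_SITES}
    feat_index: dict[str, list[str]] = {s: [] for s in ALL_SITES}
    latent: dict[str, int] = {}

    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        sid = f"S{i:04d}"
        preterm = rng.random() < config.preterm_fraction
        if preterm:
            ga = rng.uniform(config.ga_range_weeks[0], TERM_WEEKS)
            discharge = int(np.clip(rng.normal((39.0 - ga) * 7.0, 7.0), 3, 160))
        else:
            ga = rng.uniform(TERM_WEEKS, config.ga_range_weeks[1])
            discharge = int(rng.integers(2, 5))
        ga_days = ga * DAYS_PER_WEEK

        a_m, a_t = rng.normal(0.0, sd_a, size=2)
        b_m, b_t = rng.normal(0.0, sd_b, size=2)
        z = np.array([a_m / sd_a if sd_a else 0.0, b_m / sd_b if sd_b else 0.0,
                      a_t / sd_a if sd_a else 0.0, b_t / sd_b if sd_b else 0.0])
        prd_prob = float(expit(config.prd_intercept + np.dot(config.prd_coefs, z)))
        prd = bool(rng.random() < prd_prob)

        covs = dict(
            delivery_mode=("cesarean" if rng.random() < (0.6 if preterm else 0.4)
                           else "vaginal"),
            sex=("female" if rng.random() < 0.45 else "male"),
            race=("nonwhite" if rng.random() < 0.3 else "white"),
            milk_any=bool(rng.random() < 0.85),
            milk_months_gt50pct=float(np.clip(rng.exponential(3.5), 0, 12)),
            abx_inpatient_days=int(rng.poisson(12)) if preterm else 0,
            abx_outpatient_courses=int(rng.poisson(1.0)),
            maternal_abx=bool(rng.random() < 0.3),
            chorioamnionitis=bool(rng.random() < (0.06 if preterm else 0.03)),
            rom_gt18h=bool(rng.random() < 0.12),
            cmv_positive=bool(rng.random() < 0.07),
            birthweight=float(np.clip(rng.normal(120 * ga - 1500, 350), 400, 5000)),
            maternal_education=int(rng.integers(1, 4)),
            season=["winter", "spring", "summer", "fall"][int(rng.integers(4))],
            fio2_14d=float(21.0 + (rng.exponential(6.0) if preterm else 0.0)),
        )
        subj_rows.append(dict(subject_id=sid, ga_birth=float(ga), preterm=preterm,
                              discharge_dol=discharge, prd=prd, **covs))
        truth_rows.append(dict(subject_id=sid, alpha_micro=a_m, beta_micro=b_m,
                               alpha_immune=a_t, beta_immune=b_t,
                               z_micro_alpha=z[0], z_micro_beta=z[1],
                               z_immune_alpha=z[2], z_immune_beta=z[3],
                               prd_prob=prd_prob))

        def emit(site: str, dol: int, vec: np.ndarray, state: int,
                 illness: bool) -> None:
            sample_id = f"{sid}_{site}_d{dol:04d}"
            pma = ga_days + dol
            sample_rows.append(dict(sample_id=sample_id, subject_id=sid,
                                    site=site, dol=int(dol), pma_days=float(pma),
                                    illness=bool(illness)))
            feat_rows[site].append(vec)
            feat_index[site].append(sample_id)
            latent[sample_id] = state

        # microbiota: weekly inpatient, monthly outpatient
        for dol in _sampling_days(discharge, config):
            pma = ga_days + dol
            m = a_m + (1.0 + b_m) * np.log2(pma / (TERM_WEEKS * DAYS_PER_WEEK))
            for site in MICROBIOTA_SITES:
                state = _draw_state(rng, m, cuts, config.state_scale)
                mean = site_means[site][state]
                if np.isinf(config.state_concentration):
                    p = mean
                else:
                    p = rng.dirichlet(config.state_concentration * mean)
                depth = int(rng.integers(config.depth_range[0],
                                         config.depth_range[1] + 1))
                counts = rng.multinomial(depth, p).astype(np.int64)
                ill = rng.random() < config.illness_rate * (
                    1.0 + (config.k_states - 1 - state) / config.k_states)
                emit(site, dol, counts, state, ill)

        # immune: birth, discharge, ~one year
        for dol in (0, discharge, config.followup_days):
            pma = ga_days + max(dol, 1)
            m = a_t + (1.0 + b_t) * np.log2(pma / (TERM_WEEKS * DAYS_PER_WEEK))
            for site in IMMUNE_SITES:
                state = _draw_state(rng, m, cuts, config.state_scale)
                parts = []
                for block, nb in immune_blocks.items():
                    if nb == 0:
                        continue
                    mean = immune_means[site, block][state]
                    if np.isinf(config.state_concentration):
                        parts.append(mean)
                    else:
                        parts.append(rng.dirichlet(
                            config.state_concentration * mean))
                emit(site, dol, np.concatenate(parts), state, False)

    subjects = pd.DataFrame(subj_rows).set_index("subject_id")
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    features = {}
    for site in MICROBIOTA_SITES:
        features[site] = pd.DataFrame(np.vstack(feat_rows[site]),
                                      index=feat_index[site],
                                      columns=taxa_ids[site])
    for site in IMMUNE_SITES:
        features[site] = pd.DataFrame(np.vstack(feat_rows[site]),
                                      index=feat_index[site],
                                      columns=immune_ids)
    truth = CohortTruth(
        subjects=pd.DataFrame(truth_rows).set_index("subject_id"),
        latent_state=pd.Series({k: latent[k] for k in samples.index},
                               name="latent_state"),
    )
    cohort = Cohort(subjects=subjects, samples=samples, features=features,
                    truth=truth)
    cohort.validate()
    return cohort


def truth_table(cohort: Cohort, site: str = "nasal") -> pd.DataFrame:
    """Per-subject ground truth: trajectory deviations, DI z-features, PRD
    probability, and days spent in each true latent state at ``site``.

    Latent-state days use the same midpoint interval rule as the observed
    duration axis, with the first interval always anchored at day 0, so per
    subject the state days sum exactly to the observed span.
    """
    if cohort.truth is None:
        raise ValueError("cohort has no ground-truth block")
    from .duration_axis import build_durations

    mask = cohort.samples["site"] == site
    sub = cohort.samples.loc[mask, ["subject_id", "dol"]].copy()
    sub["state"] = cohort.truth.latent_state.loc[sub.index].to_numpy()
    durations = build_durations(sub, early_start_max_dol=np.inf)
    day_cols = durations.days.add_prefix("true_state_days_")
    out = cohort.truth.subjects.join(day_cols, how="left")
    out["true_observed_days"] = durations.total_days.reindex(out.index)
    return out
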