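# codevel

Longitudinal analysis of microbiota–T cell co-development in infancy.

In preterm and full-term birth cohorts, both the mucosal microbiota and the
circulating T cell compartment mature along trajectories indexed by
postmenstrual age (PMA — weeks since conception; gestational age at birth
plus postnatal age). `codevel` implements, as a tested Python pipeline, the
statistical machinery needed to study such co-development and its link to
later respiratory disease:

* **State typing.** Community state types (CSTs) and immune state types
  (ISTs) are components of a Dirichlet-multinomial mixture (DMM) fitted to
  depth-normalized compositions. The number of components minimizes the
  Laplace approximation of the negative log model evidence over K = 1..20;
  samples take the component with highest posterior probability, and states
  are enumerated 1..K by the mean PMA of their samples.
* **Variance partitioning.** How much of one system's compositional
  variation another system or an age variable explains, via the isometric
  log-ratio (ILR) transform and multivariate linear models:
  `R²_adj = 1 − MSE_full / MSE_reduced`, with Wilks' Λ tests and BIC-type
  scores for competing age models.
* **Enrichment and exposures.** Per-state logistic mixed models of state
  membership on gestational age (random subject intercept), and per-subject
  joint logistic models of ever-entering-a-state on perinatal exposures
  (maternal antibiotics, chorioamnionitis, prolonged membrane rupture, CMV)
  with a spline on gestational age, at 10% Benjamini–Hochberg FDR.
* **Duration axis.** Days spent in each state from midpoint-to-midpoint
  interval arithmetic on sampled days of life, then a quasi-Poisson scan of
  days-in-state on every immune variable at birth / discharge / one year,
  FDR-controlled across the whole scan.
* **Developmental Index (DI).** An elastic net predicts log2(PMA) from a
  system's features with each subject's entire record held out; a
  random-slope mixed model on the held-out predictions,
  `ŷ − log2 37 ~ log2(PMA/37) + (1 + log2(PMA/37) | subject)`,
  yields each subject's BLUP 37-week intercept and maturation slope, which
  are median-centered and divided by their conditional SE. The four
  z-features (both systems × intercept/slope) form the DI.
* **Outcome prediction.** Tuned random forests compare the DI against
  clinical risk factors for predicting persistent respiratory disease
  (PRD), with stratified 20-fold cross-validated AUC and a two-feature
  partial-dependence surface.

Real cohorts of this design are controlled-access, so the package ships a
first-class synthetic cohort generator (`codevel.cohort_sim`) with known
ground truth — latent PMA-ordered states, per-subject maturation intercepts
and slopes, and an outcome wired to the true DI — against which every stage
is validated.

## Worked example

```bash
codevel run-all --config src/codevel/data/demo.yaml --out demo_out
```

runs the full pipeline on a 40-subject synthetic cohort. Stage summaries can
also be printed individually, e.g.

```bash
codevel dev-index --config src/codevel/data/demo.yaml --out demo_out
```

which on this demo prints

```
microbiome: held-out R2=0.766 (alpha=0.01, lambda=0.097)
immune: held-out R2=0.288 (alpha=0.09, lambda=0.271)
```

— the subject-held-out R² of each system's PMA prediction on the
back-transformed (weeks) scale, with the tuned elastic-net mixing (alpha)
and penalty (lambda). The microbiome is sampled densely (weekly inpatient,
monthly outpatient) and predicts age well; the immune system is sampled at
only three timepoints in a 40-subject demo, so its held-out R² is modest. `demo_out/` then contains, per site, the DMM fit JSON
and state assignments, the variance-partition table, enrichment and
exposure tables, duration tables, the association scan, per-subject
trajectory tables with the 4-feature DI, and the PRD evaluation JSON; every
file carries the seed and a configuration hash in `#` header comments, and
reruns with the same seed are byte-identical.

In library form:

```python
from codevel import SimConfig, generate_cohort, assemble_features, \
    tune_and_predict, fit_trajectories

cohort = generate_cohort(SimConfig(n_subjects=150, seed=1))
feats = assemble_features(cohort, "microbiome")
preds = tune_and_predict(feats, seed=0)        # grouped-CV age prediction
traj = fit_trajectories(preds)                 # BLUP intercepts and slopes
print(traj.table[["alpha", "beta", "z_alpha", "z_beta"]].head())
```

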