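# Methods

This note documents the models implemented in `codevel`, the parameter
choices that matter, what the synthetic cohort generator does and does not
emulate, and the numerical decisions taken where the design was open.

## The synthetic cohort generator

`cohort_sim` produces the data structure every downstream stage assumes,
with full ground truth. Per subject i, a latent maturation trajectory

    m_i(t) = a_i + (1 + b_i) · log2(PMA_i(t) / 37 weeks)

is drawn with intercept and slope deviations (a_i, b_i) from independent
zero-mean normals (`trajectory_sd`, default (0.15, 0.15), in log2-PMA
units); separate deviations are drawn for the microbiota and immune
systems. At each sample, a latent state is drawn from a cumulative-logit
ordinal model on m_i(t) — cutpoints evenly spaced over the attainable
maturation range, logistic scale `state_scale` (default 0.12) — so the
state index rises stochastically with PMA. Microbiota counts are
Dirichlet-multinomial draws from the state's composition (per-component
precision `state_concentration`, default 50; sequencing depth uniform on
`depth_range`, default 1200–5000 reads). Immune samples at birth,
discharge and one year are state-specific Dirichlet compositions drawn
within each (assay, CD4/CD8) block, each block summing to one. The binary
outcome (PRD) is Bernoulli with logistic probability in the subject's four
true developmental-index z-features (`prd_coefs`, default
(−0.8, 0, 0, 0.8): risk rises with an immature microbiota at term
equivalent and an accelerated immune slope; intercept −1.0 gives ~30%
prevalence).

Default dimensions follow the cohort design the generator emulates: ~55%
preterm of gestational ages 23–42 weeks, weekly inpatient then monthly
outpatient swabs through day of life 450, 13 latent states per system,
40 taxa per body site, 26 T cell populations per assay. With these
settings the subject-held-out age-prediction R² lands at ~0.74–0.79, in
the range deep longitudinal infant cohorts of this design achieve;
choosing markedly less noise would make the simulation unrealistically
clean.

Determinism: one global seed; each subject draws from a substream spawned
from (seed, subject index), so enlarging the cohort never perturbs
existing subjects. Features the generator does **not** emulate: taxonomic
phylogeny (no UniFrac-style structure), compositional trends *within* a
state (counts depend on age only through the discrete state), illness-
driven extra visits, batch effects, and missingness mechanisms beyond
block-wise absence of assays.

## Dirichlet-multinomial mixture state types

The component density is the exchangeable per-sequence (Pólya urn)
probability

    log DM(x|α) = lnΓ(A) − lnΓ(N+A) + Σ_j [lnΓ(x_j+α_j) − lnΓ(α_j)],

A = Σα, N = Σx. The multinomial coefficient is constant across components,
cancels in responsibilities, and is omitted — matching the convention of
the standard mixture implementation of this model class; tests verify the
density against exhaustive urn enumeration.

Before fitting, features present in under 5% of samples are dropped and
each sample's relative abundances are multiplied by a fixed depth constant
and floored (1200 nasal / 2250 rectal — the QC minimum-read cutoffs — and
50,000 for immune compositions), so high-count libraries cannot dominate.

Fitting is EM: responsibilities in the E-step; in the M-step, mixture
weights are responsibility means and each component's α maximizes the
responsibility-weighted log-likelihood by L-BFGS in log α with the
analytic digamma gradient (a generalized EM step — the observed-data
log-likelihood is non-decreasing, recorded per iteration, and asserted in
tests). Initialization is seeded k-means on row proportions (softened
one-hot responsibilities); convergence at relative log-likelihood change
below 1e-6 (max 1000 iterations); a component losing all responsibility
mass triggers a restart from a new k-means seed (up to 3). Ties everywhere
break to the lowest index.

K is selected over 1..20 by minimizing the Laplace approximation of the
negative log model evidence:

    NLE = −(loglik + log prior)(θ̂) − (K·J/2)·ln 2π + ½ ln|H|

with H block-diagonal across components. Two constructions deserve
flagging. (1) H is computed in **log α** coordinates — the positivity-
respecting space the M-step optimizes in — via |H_log| = |H_α|·Πα², with
trigamma-based blocks; a non-positive-definite block falls back to its
positive eigenvalue part. (2) A weak exponential prior (rate 0.1) on every
α entry contributes its mass at the optimum. Without the prior the Laplace
curve is flat in K: near-duplicate components at large K carry almost no
curvature penalty, and K=18–20 can edge out the true K on three-component
data. The prior-mass term charges each component ~J·(2.3 + 0.1·Σα), after
which model selection recovers the true K on separated data and K=1 on
single-component data. Mixture weights are treated as known (parameter
count K·J), consistent with the reference construction's spirit.

Samples take the argmax-posterior component (ties to the lower label);
components are renumbered 1..K by ascending mean PMA of their assigned
samples, empty components last (mean PMA = NaN).

## Compositional variance partitioning

Both systems in a comparison are joined case-wise (cross-system pairs are
matched within subject to the nearest sampling day, 45-day tolerance, in
the pipeline driver). Features with variance < 1e-4 are removed, rows
renormalized, zeros replaced multiplicatively with half the smallest
nonzero proportion (configurable), and the ILR applied with skbio's fixed
sequential-binary basis, so a uniform composition maps to the origin.

Variance explained contrasts nested multivariate linear fits:
R²_adj = 1 − MSE_full/MSE_reduced with each MSE the total squared residual
over its residual degrees of freedom; the age-adjusted variant puts PMA in
both sets (reduced = PMA only). Association is tested by Wilks' Λ with
Rao's F approximation; under a simulated null its type-I error is within
5% ± 2% (500 replicates). The BIC-type score is −2·loglik + n·log p, with
the multivariate-normal log-likelihood at the MLE residual covariance
(divide by n). The n·log p penalty is the form used when ranking candidate
age models here; it differs from the textbook p·log n, which is available
via `formula="p_log_n"`. Since model ranks at fixed n compare models of
different p, both penalties order models identically when n is shared;
the printed form is the default. Singular residual covariances are
ridge-regularized by 1e-8·trace/dim.

## State associations

Per-state enrichment: each sample contributes a binary in-state outcome,
modeled with a binomial GLMM — fixed effects for gestational age and the
confounder set (delivery mode, maternal antibiotics, months of >50%
breastmilk feedings, any breastmilk, inpatient antibiotic days, outpatient
antibiotic courses), random subject intercept — fitted by MAP/Laplace with
standardized predictors (effects rescaled to per-unit afterwards). States
need ≥2 subjects observed both in and out; failures fall back to a
cluster-robust logistic GEE, flagged in the output. The MAP start values
come from numpy's global RNG in the underlying library, so the fit pins
the RNG state (and BLAS threads) for reproducibility.

Exposure models: one row per subject, logistic regression of
ever-in-state on the joint exposure block (maternal antibiotics,
chorioamnionitis, membrane rupture >18 h, CMV) plus delivery mode, race,
sex, and a natural cubic spline on gestational age (3 df total with the
intercept; the paper-free choice of smoother is configurable). Complete
separation triggers a Jeffreys-penalized (Firth-type) refit, flagged.
Exposure families are corrected by Benjamini–Hochberg at 10% FDR.

## Duration axis

Each assigned sample owns the half-open interval from the midpoint with
its predecessor to the midpoint with its successor; the first interval is
anchored at day 0 only if the first sample fell within 14 days of life
(otherwise the first sample contributes nothing), and the final state
persists for half the last inter-sample gap. Days are continuous
(midpoints at half-days). An independent oracle assigns every half-day
tick to the nearest sampled day (ties to the earlier sample) and agrees
exactly with the interval arithmetic for all integer day-of-life inputs;
an integer-day grid would agree only when consecutive sampled days share
parity. Subjects with under one sample per 30 inpatient days or fewer
than six post-discharge samples are excluded, with machine-readable
reasons.

The scan fits, per (state, immune variable, timepoint), a quasi-Poisson
regression of floor(days-in-state) on the z-scored variable plus
confounders and z-scored log observed days; gestational age enters as
GA − 37 weeks, other numeric covariates as z-scores. Dispersion is the
Pearson χ²/df of the full model; the variable's p-value is the
dispersion-scaled deviance difference against the dropped-variable model
on χ²(1). Variables with under 10 complete observations are filtered
before the scan, as are states occupied in under 10% of the remaining
observations; zero-variance variables and failed fits are recorded with
reasons and excluded from the FDR family. BH correction is global across
the scan by default (per-timepoint by flag); a baseline confounder preset
adjusting only for premature birth is available alongside the fully
adjusted set.

## Developmental index

Feature assembly keeps samples before day of life 450, removes taxa
present in under 3% of a site's samples, renormalizes, and merges sites
per (subject, day) with whole-block missingness. All standardization is
deferred to training folds.

Tuning draws 50 (alpha, lambda) pairs uniformly — mixing alpha on [0, 1],
overall penalty lambda on [0.001, 0.5] (linear, as only the ranges are
given) — under the objective ½n⁻¹‖y−Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²) with
target log2(PMA in weeks). Model selection uses 5-fold cross-validation
grouped by subject (whole longitudinal records held out), scoring test MSE
on the log2 scale; the winner is refit with 10-fold grouped CV to produce
a held-out prediction for every sample. Within each training fold,
block-missing entries are imputed with training means and features
z-scored with training statistics; the identical transforms are applied to
the test fold. R² is reported on the back-transformed 2^ŷ scale and on the
log scale.

Trajectories come from a REML linear mixed model of ŷ − log2 37 on
x = log2(PMA/37 weeks) with correlated random intercept and slope per
subject; a singular random-effects covariance triggers a diagonal refit,
flagged. BLUPs give each subject's 37-week intercept (fixed + random
intercept) and slope; conditional SEs come from the conditional covariance
of the random effects; z-features are (value − cohort median) / own
conditional SE. Subjects with a single sample keep their (heavily shrunk)
BLUP without special-casing. The DI is the ordered 4-vector
(micro intercept z, micro slope z, immune intercept z, immune slope z);
subjects missing one system carry NaNs for downstream imputation.

Verified properties: with a permuted (sample-level) target, held-out R²
is ≈ 0 — the leakage gate for the grouped-CV/fold-local imputation
machinery. Note that permuting whole trajectories *between* subjects is
not a null for this design: all subjects share the population age trend,
so genuine skill survives such a permutation.

On simulated cohorts at the settled defaults (150 subjects, trajectory
SDs 0.15), intercept recovery is strong (Spearman ≈ 0.82–0.90), while
slope recovery averages ≈ 0.6 (range ≈ 0.45–0.75 across seeds). This is
an information ceiling of the generator's discrete-state design, not an
estimator defect: with counts emitted purely from an ordinal latent
state, the per-subject slope's conditional SE
(≈ residual SD / (√n_i · SD of x within subject) ≈ 0.15) matches the
slope heterogeneity itself, capping the attainable correlation near 0.7;
driving the state noise to zero raises prediction R² to ~0.82 —
unrealistically clean — without lifting slope recovery. Passing intercept
tests therefore say more about real-data behavior than slope tests do.

## Outcome model

Clinical features are race, maternal education, sex, gestational age,
birthweight, season of birth, and oxygen supplementation integrated over
the first 14 days; the DI set is the four z-features. Hyperparameters
(max_features, n_estimators in 250–2000, min_samples_leaf in 1–20) are
tuned by seeded random search (default 50 draws, mirroring the
elastic-net budget) maximizing mean 5-fold stratified CV AUC; evaluation
is 20-fold stratified CV with per-fold out-of-fold AUCs (mean ± SE;
per-fold-then-average by default, folds lacking a class merged into a
neighbor). Missing DI entries are median-imputed inside training folds.
Permutation importances come from a full-data refit. Partial dependence
clamps a feature pair to grid values across the whole data set and
averages predicted probabilities; grid points beyond the observed range
are flagged as extrapolation.

## Problem sizes and runtime choices

Test and acceptance computations use deliberately scaled simulation sizes:
DMM selection on 600 samples × 10 taxa over K = 1..20 (5 seeds), duration
oracle on 1000 random subjects, FDR calibration over 20 null replicates,
DI recovery on three 150-subject cohorts with 25 tuning draws, MANOVA
calibration over 500 replicates at n = 60, and outcome evaluation on
400-subject cohorts with an 8-draw search. The bundled demo configuration
runs the full pipeline on 40 subjects with reduced budgets. All analysis
tables are written with 6-significant-digit precision so identical runs
hash identically.

## Known limitations

* The generator's discrete-state emission bounds trajectory-slope
  recovery (above); real compositional data carry continuous age trends
  the generator omits.
* The Laplace evidence treats mixture weights as fixed and uses
  block-diagonal curvature; absolute evidence values are approximate, and
  only differences across K are used.
* The enrichment GLMM uses a MAP/Laplace fit with a single scalar random
  effect; crossed or nested designs are out of scope.
* The quasi-Poisson scan floors continuous day totals; for spans under a
  few days this loses up to one day per state.
* BIOM support covers the JSON serialization (HDF5 BIOM is not written).
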