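"""DMM state typing: density oracle, EM behavior, model selection, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from codevel import (assign_and_enumerate, dirmult_loglik, filter_prevalence,
                     fit_dmm, normalize_counts, select_k)
from conftest import simulate_dm_counts


# ---------------------------------------------------------------- filtering
def test_prevalence_filter_drops_rare_feature():
    mat = pd.DataFrame(0, index=range(100), columns=["rare", "common"])
    mat.iloc[:4, 0] = 5      # present in 4% of samples
    mat.iloc[:, 1] = 1
    kept = filter_prevalence(mat, 0.05)
    assert list(kept.columns) == ["common"]


def test_prevalence_filter_disabled_and_exact_boundary():
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(0, index=range(100),
                       columns=[f"f{p}" for p in range(1, 11)])
    for i, p in enumerate(range(1, 11)):   # prevalences 1%..10%
        rows = rng.choice(100, size=p, replace=False)
        mat.iloc[rows, i] = 1
    assert filter_prevalence(mat, 0).equals(mat)
    kept = filter_prevalence(mat, 0.05)
    assert kept.shape[1] == 6              # 5%..10% survive


# ------------------------------------------------------------- normalization
@pytest.mark.parametrize("row,const,expected", [
    ((0.5, 0.3, 0.2), 2250, (1125, 675, 450)),
    ((1 / 3, 1 / 3, 1 / 3), 100, (33, 33, 33)),
])
def test_normalize_counts_floors(row, const, expected):
    out = normalize_counts(pd.DataFrame([row]), const)
    assert tuple(out.counts.iloc[0]) == expected
    assert out.counts.iloc[0].sum() <= const


def test_normalize_immune_composition_at_50000():
    comp = pd.DataFrame([[0.123456, 0.876544]])
    out = normalize_counts(comp, 50000)
    assert tuple(out.counts.iloc[0]) == (int(0.123456 * 50000),
                                         int(0.876544 * 50000))


def test_normalize_rejects_negative():
    with pytest.raises(ValueError, match="negative"):
        normalize_counts(pd.DataFrame([[-0.1, 1.1]]), 100)


# ------------------------------------------------------------------ density
def _urn_sequence_logprob(x, alpha):
    """Exhaustive Polya-urn oracle: sum the urn probability over every
    distinct ordering of the draws, then divide by the number of orderings
    (the component density is the exchangeable per-sequence probability;
    the multinomial coefficient is constant across components)."""
    draws = [j for j, c in enumerate(x) for _ in range(c)]
    total = 0.0
    perms = set(itertools.permutations(draws))
    for perm in perms:
        a = list(map(float, alpha))
        big_a = sum(a)
        p = 1.0
        for d in perm:
            p *= a[d] / big_a
            a[d] += 1.0
            big_a += 1.0
        total += p
    return np.log(total / len(perms))


def test_dirmult_loglik_trivial_cases():
    assert dirmult_loglik(np.zeros(4), np.ones(4)) == 0.0
    assert dirmult_loglik(np.array([1, 0]), np.ones(2)) == pytest.approx(
        np.log(0.5), abs=1e-12)


def test_dirmult_loglik_matches_urn_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 12:
        x = rng.integers(0, 4, size=3)
        if not 1 <= x.sum() <= 6:
            continue
        alpha = rng.uniform(0.2, 3.0, size=3)
        assert dirmult_loglik(x, alpha) == pytest.approx(
            _urn_sequence_logprob(x, alpha), abs=1e-10)
        checked += 1


def test_dirmult_loglik_rejects_bad_alpha():
    with pytest.raises(ValueError):
        dirmult_loglik(np.array([1, 1]), np.array([1.0, 0.0]))


# ----------------------------------------------------------------- EM fits
def test_k1_fit_matches_direct_single_component_optimizer():
    from scipy.optimize import minimize
    from scipy.special import gammaln
    rng = np.random.default_rng(3)
    alpha_true = np.array([5.0, 3.0, 2.0])
    x = np.empty((120, 3))
    for i in range(120):
        x[i] = rng.multinomial(200, rng.dirichlet(alpha_true))

    def neg_ll(log_a):
        a = np.exp(log_a)
        big_a = a.sum()
        n = x.sum(axis=1)
        return -(gammaln(big_a) - gammaln(n + big_a)
                 + (gammaln(x + a) - gammaln(a)).sum(axis=1)).sum()

    direct = minimize(neg_ll, np.zeros(3), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-10,
                               "maxiter": 5000})
    counts = pd.DataFrame(x.astype(int))
    fit = fit_dmm(counts, 1, seed=0)
    assert fit.loglik == pytest.approx(-direct.fun, abs=1e-6)


def test_single_component_parameter_recovery():
    rng = np.random.default_rng(9)
    alpha_true = np.array([5.0, 2.0, 1.0, 0.5])
    x = np.empty((500, 4), dtype=int)
    for i in range(500):
        p = rng.dirichlet(alpha_true)
        x[i] = rng.multinomial(800, p)
    fit = fit_dmm(pd.DataFrame(x), 1, seed=0)
    rel_err = np.abs(fit.alpha[0] - alpha_true) / alpha_true
    assert (rel_err[alpha_true >= 0.5] < 0.15).all()


def test_fit_is_deterministic_and_loglik_monotone():
    counts, _ = simulate_dm_counts(150, 2, 6, seed=4)
    f1 = fit_dmm(counts, 2, seed=5)
    f2 = fit_dmm(counts, 2, seed=5)
    assert f1.loglik == f2.loglik
    trace = np.array(f1.loglik_trace)
    assert (np.diff(trace) >= -1e-8).all()


def test_fit_rejects_bad_k():
    counts, _ = simulate_dm_counts(10, 2, 5, seed=0)
    with pytest.raises(ValueError):
        fit_dmm(counts, 0)
    with pytest.raises(ValueError):
        fit_dmm(counts, 11)


# ----------------------------------------------------------- model selection
def test_select_k_default_range_is_1_to_20():
    import inspect
    sig = inspect.signature(select_k)
    assert list(sig.parameters["k_range"].default) == list(range(1, 21))


def test_select_k_recovers_three_components():
    counts, labels = simulate_dm_counts(600, 3, 10, precision=50, seed=1)
    best_k, fits = select_k(counts, range(1, 7), seed=0)
    assert best_k == 3
    pma = pd.Series(np.arange(len(counts), dtype=float), index=counts.index)
    assign = assign_and_enumerate(fits[3], counts, pma)
    assert adjusted_rand_score(labels, assign.label) >= 0.8


def test_select_k_single_component_data():
    rng = np.random.default_rng(2)
    x = np.empty((300, 6), dtype=int)
    alpha = np.array([4.0, 3.0, 2.0, 2.0, 1.0, 1.0])
    for i in range(300):
        x[i] = rng.multinomial(500, rng.dirichlet(alpha))
    best_k, _ = select_k(pd.DataFrame(x), range(1, 5), seed=0)
    assert best_k == 1


def test_state_recovery_on_simulated_cohort():
    """With well-separated state compositions, DMM assignment recovers the
    generator's latent states (ARI >= 0.8)."""
    from codevel import SimConfig, generate_cohort, normalize_counts
    cohort = generate_cohort(SimConfig(n_subjects=60, seed=17, k_states=4,
                                       state_concentration=200.0))
    counts = filter_prevalence(cohort.features["nasal"], 0.05)
    comp = counts.div(counts.sum(axis=1), axis=0)
    norm = normalize_counts(comp, 1200)
    fit = fit_dmm(norm, 4, seed=0)
    pma = pd.Series(
        cohort.samples.loc[norm.counts.index, "pma_days"])
    assign = assign_and_enumerate(fit, norm, pma)
    truth = cohort.truth.latent_state.loc[norm.counts.index]
    assert adjusted_rand_score(truth, assign.label) >= 0.8


# ------------------------------------------------------------- assignment
def test_assignment_k1_and_posterior_normalization():
    counts, _ = simulate_dm_counts(80, 2, 6, seed=6)
    pma = pd.Series(np.linspace(200, 600, 80), index=counts.index)
    fit1 = fit_dmm(counts, 1, seed=0)
    a1 = assign_and_enumerate(fit1, counts, pma)
    assert (a1.label == 1).all()
    assert np.allclose(a1.posterior.to_numpy(), 1.0)

    fit2 = fit_dmm(counts, 2, seed=0)
    a2 = assign_and_enumerate(fit2, counts, pma)
    assert np.allclose(a2.posterior.sum(axis=1), 1.0, atol=1e-8)
    assert a2.mean_pma_per_state.is_monotonic_increasing


def test_enumeration_orders_states_by_mean_pma():
    counts, labels = simulate_dm_counts(200, 2, 6, seed=8)
    # young samples in component of label 1, old in label 0
    pma = pd.Series(np.where(labels == 1, 30 * 7.0, 40 * 7.0),
                    index=counts.index)
    fit = fit_dmm(counts, 2, seed=0)
    assign = assign_and_enumerate(fit, counts, pma)
    state_of_young = assign.label[pma == 30 * 7.0].mode()[0]
    assert state_of_young == 1
    # relabeling is a bijection
    assert sorted(assign.label_map.values()) == [1, 2]
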