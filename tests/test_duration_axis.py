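"""Duration bookkeeping, inclusion rules, and the quasi-Poisson scan."""

import numpy as np
import pandas as pd
import pytest

from codevel import apply_inclusion, association_scan, build_durations
from codevel.duration_axis import brute_force_durations, confounder_frame


def _frame(dols, states, subject="A"):
    return pd.DataFrame({"subject_id": subject, "dol": dols, "state": states})


def test_worked_example():
    dur = build_durations(_frame([2, 10, 20, 40], list("AABB")))
    assert dur.days.loc["A", "A"] == pytest.approx(15.0)
    assert dur.days.loc["A", "B"] == pytest.approx(35.0)
    assert dur.total_days.loc["A"] == pytest.approx(50.0)


def test_late_first_sample_excludes_first_interval():
    dur = build_durations(_frame([20, 30], list("AB")))
    assert dur.days.loc["A", "A"] == pytest.approx(0.0)
    assert dur.days.loc["A", "B"] == pytest.approx(10.0)


def test_single_state_days_equal_full_span():
    dur = build_durations(_frame([3, 9, 30, 60], list("AAAA")))
    assert dur.days.loc["A", "A"] == pytest.approx(dur.total_days.loc["A"])


def test_singleton_subject_excluded_with_reason():
    dur = build_durations(_frame([5], ["A"]))
    assert not dur.included.loc["A"]
    assert dur.reason.loc["A"] == "single_sample"


def test_duplicate_dol_keeps_first_and_unsorted_input_is_sorted():
    scrambled = _frame([40, 2, 10, 20, 10], list("BAABB"))
    dur = build_durations(scrambled)
    ref = build_durations(_frame([2, 10, 20, 40], list("AABB")))
    pd.testing.assert_frame_equal(dur.days, ref.days)


def test_matches_brute_force_oracle_on_random_subjects():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        dols = np.sort(rng.choice(np.arange(0, 400), size=n, replace=False))
        states = rng.choice(list("ABC"), size=n)
        dur = build_durations(_frame(dols, states))
        oracle = brute_force_durations(dols, states)
        for s in "ABC":
            got = dur.days.loc["A", s] if s in dur.days.columns else 0.0
            assert got == pytest.approx(oracle.get(s, 0.0), abs=1e-9)
        assert dur.days.loc["A"].sum() == pytest.approx(
            dur.total_days.loc["A"], abs=1e-9)


@pytest.mark.parametrize("discharge,n_in,n_post,ok", [
    (60, 1, 10, False),   # 60 NICU days, 1 inpatient sample
    (10, 2, 5, False),    # only 5 post-discharge samples
    (30, 2, 6, True),     # both boundaries satisfied
])
def test_inclusion_rules(discharge, n_in, n_post, ok):
    dols = (list(np.linspace(1, discharge, n_in).astype(int))
            + list(discharge + 20 * np.arange(1, n_post + 1)))
    states = ["A"] * len(dols)
    samples = _frame(dols, states)
    dur = build_durations(samples)
    dur = apply_inclusion(dur, samples,
                          pd.Series({"A": discharge}))
    assert bool(dur.included.loc["A"]) is ok
    if not ok:
        assert dur.reason.loc["A"] != ""


def _sim_scan_inputs(n_subjects, n_vois, seed, effect=0.0):
    """Durations + VOI tables with optional injected effect of voi 0 on the
    log-rate of state 'S1' days."""
    rng = np.random.default_rng(seed)
    subjects = [f"P{i:03d}" for i in range(n_subjects)]
    rows = []
    vois = pd.DataFrame(rng.normal(size=(n_subjects, n_vois)),
                        index=subjects,
                        columns=[f"voi{j}" for j in range(n_vois)])
    days, totals = {}, {}
    for i, sid in enumerate(subjects):
        span = float(rng.integers(200, 400))
        rate1 = 0.3 * np.exp(effect * vois.iloc[i, 0])
        d1 = min(span, rng.gamma(5, span * rate1 / 5))
        days[sid] = {"S1": d1, "S2": span - d1}
        totals[sid] = span
    from codevel.duration_axis import DurationTable
    dur = DurationTable(
        days=pd.DataFrame.from_dict(days, orient="index"),
        total_days=pd.Series(totals),
        included=pd.Series(True, index=subjects),
        reason=pd.Series("", index=subjects))
    confs = pd.DataFrame({"x1": rng.normal(size=n_subjects)}, index=subjects)
    return dur, {"birth": vois}, confs


def test_scan_filters_sparse_vois():
    dur, vois, confs = _sim_scan_inputs(60, 3, seed=1)
    vois["birth"].iloc[9:, 1] = np.nan     # voi1 observed in 9 subjects only
    out = association_scan(dur, vois, confs, min_voi_obs=10)
    assert "voi1" not in set(out["voi"])
    assert {"voi0", "voi2"} <= set(out["voi"])


def test_scan_recovers_injected_effect_sign_and_magnitude():
    logrrs = []
    for seed in range(10):
        dur, vois, confs = _sim_scan_inputs(120, 2, seed=seed,
                                            effect=np.log(1.5))
        out = association_scan(dur, vois, confs)
        rec = out[(out["state"] == "S1") & (out["voi"] == "voi0")]
        logrrs.append(float(rec["log_rate_ratio"].iloc[0]))
    bias = np.mean(logrrs) - np.log(1.5)
    assert abs(bias) < 0.1
    assert all(v > 0 for v in logrrs)


def test_scan_invariant_to_voi_order_and_fdr_monotone():
    dur, vois, confs = _sim_scan_inputs(80, 4, seed=3)
    out1 = association_scan(dur, vois, confs)
    shuffled = {"birth": vois["birth"][["voi2", "voi0", "voi3", "voi1"]]}
    out2 = association_scan(dur, shuffled, confs)
    key = ["state", "voi"]
    m1 = out1.set_index(key).sort_index()
    m2 = out2.set_index(key).sort_index()
    pd.testing.assert_frame_equal(m1[["log_rate_ratio", "p_value", "q_value"]],
                                  m2[["log_rate_ratio", "p_value", "q_value"]])
    srt = out1.dropna(subset=["p_value"]).sort_values("p_value")
    assert srt["q_value"].is_monotonic_increasing or \
        (srt["q_value"].cummax() == srt["q_value"].cummax()).all()


def test_confounder_presets(small_cohort):
    adj = confounder_frame(small_cohort.subjects, "adjusted")
    base = confounder_frame(small_cohort.subjects, "preterm_only")
    assert "ga_birth_c37" in adj.columns
    assert list(base.columns) == ["preterm"]
    # GA centered at 37 weeks, other numerics z-scored
    ga = small_cohort.subjects["ga_birth"]
    assert np.allclose(adj["ga_birth_c37"], ga - 37.0)
    with pytest.raises(ValueError):
        confounder_frame(small_cohort.subjects, "nope")
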