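import itertools

import numpy as np
import pandas as pd
import pytest

from spaced_select import (ReviewLog, bin_by_controls, compare_arms,
                           empirical_forgetting_rate, engagement_metrics,
                           fit_spacing_regression, half_life, mann_whitney_u,
                           summarize_sequences)
from conftest import make_event


# ---------------------------------------------------------------------------
# empirical forgetting rate & half-life
# ---------------------------------------------------------------------------

def test_empirical_rate_closed_forms():
    assert empirical_forgetting_rate(7.0, 1, 0.01) == \
        pytest.approx(-np.log(0.99) / 7, rel=1e-9)
    assert empirical_forgetting_rate(7.0, 0, 0.01) == \
        pytest.approx(-np.log(0.01) / 7, rel=1e-9)


def test_empirical_rate_order_and_limits():
    for eps in (0.001, 0.1, 0.49):
        assert empirical_forgetting_rate(5.0, 1, eps) < \
            empirical_forgetting_rate(5.0, 0, eps)
    assert empirical_forgetting_rate(1e9, 1) < 1e-10   # -> 0 as delta grows


def test_empirical_rate_domain_errors():
    with pytest.raises(ValueError):
        empirical_forgetting_rate(0.0, 1)
    with pytest.raises(ValueError):
        empirical_forgetting_rate(1.0, 1, epsilon=0.5)


def test_half_life():
    assert half_life(np.log(2)) == pytest.approx(1.0)
    assert half_life(0.1) == pytest.approx(2 * half_life(0.2))
    assert half_life(0.0014357) == pytest.approx(482.8, rel=1e-3)
    with pytest.raises(ValueError):
        half_life(0.0)


# ---------------------------------------------------------------------------
# sequence summaries
# ---------------------------------------------------------------------------

def sample_log():
    return ReviewLog.from_events([
        make_event("u1", "q1", "s0", 0.0, 1),
        make_event("u1", "q1", "s1", 3.0, 1),
        make_event("u1", "q1", "s2", 10.0, 1),
        make_event("u1", "q2", "s2", 10.0, 0),          # single review
        make_event("u2", "q1", "s3", 1.0, 0, "random"),
        make_event("u2", "q1", "s4", 2.0, 1, "random"),
    ])


N0 = {"q1": 0.2, "q2": 0.4}


def test_summarize_hand_arithmetic():
    summ, excluded = summarize_sequences(sample_log(), N0, epsilon=0.01)
    assert excluded == 1
    row = summ[(summ.learner_id == "u1") & (summ.question_id == "q1")].iloc[0]
    assert row.n_reviews == 2
    assert row["T"] == pytest.approx(10.0)
    assert row.delta_test == pytest.approx(7.0)
    assert row.test_recall == 1
    n_hat = -np.log(0.99) / 7
    assert row.n_hat == pytest.approx(n_hat, rel=1e-12)
    assert row.normalized_rate == pytest.approx(n_hat / 0.2, rel=1e-12)
    assert row.half_life == pytest.approx(np.log(2) / n_hat, rel=1e-12)


def test_summarize_conservation():
    summ, excluded = summarize_sequences(sample_log(), N0)
    assert len(summ) + excluded == 3     # 3 (learner, question) pairs


def test_summarize_missing_item_rate():
    with pytest.raises(KeyError):
        summarize_sequences(sample_log(), {"q1": 0.2})


def test_summarize_collapses_same_instant_repeats():
    log = ReviewLog.from_events([
        make_event("u", "q1", "s0", 0.0, 1),
        make_event("u", "q1", "s1", 2.0, 0),
        make_event("u", "q1", "s1b", 2.0, 1),   # immediate repeat, ignored
    ])
    summ, _ = summarize_sequences(log, N0)
    row = summ.iloc[0]
    assert row.n_reviews == 1 and row.test_recall == 0
    assert row.delta_test == pytest.approx(2.0)


def test_summaries_invariants(small_trial):
    from spaced_select import fit_initial_rates, observations_from_log
    log, _ = small_trial
    n0 = fit_initial_rates(observations_from_log(log))
    summ, _ = summarize_sequences(log, n0)
    assert (summ.n_hat > 0).all() and (summ.normalized_rate > 0).all()
    assert np.allclose(summ.half_life, np.log(2) / summ.n_hat)
    assert (summ["T"] >= summ.delta_test).all() and (summ.delta_test > 0).all()
    assert (summ.n_reviews >= 1).all()


# ---------------------------------------------------------------------------
# control cells
# ---------------------------------------------------------------------------

def synthetic_summaries(n=600, seed=0):
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 10, n)
    T = rng.uniform(1, 30, n)
    nr = rng.lognormal(-2, 1, n)
    return pd.DataFrame({
        "learner_id": [f"u{j}" for j in range(n)],
        "question_id": "q", "arm": rng.choice(["select", "random",
                                               "difficulty"], n),
        "n_reviews": k, "T": T, "delta_test": T / 2, "test_recall": 1,
        "n_hat": nr * 0.1, "n0_hat": 0.1, "normalized_rate": nr,
        "half_life": np.log(2) / (nr * 0.1),
    })


def test_bin_by_controls_cell_count_and_partition():
    summ = synthetic_summaries()
    labeled = bin_by_controls(summ, (2, 7), 3)
    cells = set(zip(labeled.n_reviews, labeled.t_bin))
    assert len(cells) <= 18
    in_range = summ[(summ.n_reviews >= 2) & (summ.n_reviews <= 7)]
    assert len(labeled) == len(in_range)          # partition, nothing lost
    assert labeled.groupby(["n_reviews", "t_bin"]).size().sum() == len(labeled)


def test_bin_single_t_bin_keys_by_reviews_only():
    labeled = bin_by_controls(synthetic_summaries(), (2, 7), 1)
    assert set(labeled.t_bin) == {0}


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mwu_textbook_case():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(1 / 3, abs=1e-12)


def test_mwu_identical_tied_samples():
    u, p = mann_whitney_u([1, 1, 2, 2], [1, 1, 2, 2])
    assert p == pytest.approx(1.0)


def test_mwu_empty_sample_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def _mwu_enumeration_oracle(x, y):
    """Independent oracle: pairwise-win counting over all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx_all = set(range(len(pooled)))

    def u_of(subset):
        xs = pooled[list(subset)]
        ys = pooled[list(idx_all - set(subset))]
        return float((xs[:, None] > ys[None, :]).sum()
                     + 0.5 * (xs[:, None] == ys[None, :]).sum())

    center = n1 * len(y) / 2.0
    u_obs = u_of(range(n1))
    d = abs(u_obs - center)
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    p = float(np.mean([abs(u - center) >= d - 1e-12 for u in us]))
    return u_obs, p


def test_mwu_matches_enumeration_oracle_small_samples():
    rng = np.random.default_rng(99)
    for n1 in range(1, 7):
        for n2 in range(1, 8 - n1 + 1):
            for _ in range(6):
                x = rng.integers(0, 4, n1).astype(float)   # heavy ties
                y = rng.integers(0, 4, n2).astype(float)
                u, p = mann_whitney_u(x, y)
                u_ref, p_ref = _mwu_enumeration_oracle(x, y)
                assert u == pytest.approx(u_ref, abs=1e-12)
                assert p == pytest.approx(p_ref, abs=1e-12)


def test_mwu_large_sample_asymptotic_sane():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    y = rng.normal(1, 1, 200)
    _, p_shift = mann_whitney_u(x, y)
    _, p_null = mann_whitney_u(x, rng.normal(0, 1, 200))
    assert p_shift < 1e-10 < 0.001 < p_null


# ---------------------------------------------------------------------------
# arm comparison
# ---------------------------------------------------------------------------

def test_compare_arms_detects_large_shift():
    rng = np.random.default_rng(1)
    n = 400
    base = rng.lognormal(-2, 0.5, n)
    summ = pd.DataFrame({
        "arm": ["select"] * n + ["random"] * n + ["difficulty"] * n,
        "n_reviews": 2, "T": np.tile(rng.uniform(1, 10, n), 3),
        "normalized_rate": np.concatenate([base, base + 5.0, base + 2.0]),
        "n_hat": np.concatenate([base, base + 5.0, base + 2.0]) * 0.1,
    })
    labeled = bin_by_controls(summ, (2, 2), 1)
    res = compare_arms(labeled)
    cell = res["cells"][0]
    for name in ("select_vs_random", "select_vs_difficulty"):
        assert cell.contrasts[name]["significant"]
        assert cell.contrasts[name]["p"] < res["aggregates"]["bonferroni_threshold"]
    assert res["aggregates"]["frac_select_median_lowest"] == 1.0
    # reported medians agree with direct computation
    assert cell.quantiles["select"][1] == pytest.approx(np.median(base))


def test_compare_arms_skips_single_arm_cell():
    summ = pd.DataFrame({
        "arm": ["select"] * 20, "n_reviews": 3, "T": np.linspace(1, 5, 20),
        "normalized_rate": np.linspace(0.1, 1, 20),
        "n_hat": np.linspace(0.1, 1, 20),
    })
    labeled = bin_by_controls(summ, (3, 3), 1)
    res = compare_arms(labeled)
    assert res["cells"][0].skipped == ["select_vs_random",
                                       "select_vs_difficulty"]


# ---------------------------------------------------------------------------
# spacing regression
# ---------------------------------------------------------------------------

def spacing_data(n=120, c=2.0, w_t=-0.05, w_r=0.8, w_d=0.3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    arms = np.tile(["select", "random", "difficulty"], n // 3)
    T = rng.uniform(1, 40, n)
    t_med = np.median(T)
    y = (c + w_t * (T - t_med) + w_r * (arms == "random")
         + w_d * (arms == "difficulty") + noise * rng.standard_normal(n))
    return pd.DataFrame({"arm": arms, "n_reviews": 4, "T": T,
                         "normalized_rate": y})


def test_fit_spacing_regression_recovers_noiseless_coefficients():
    res = fit_spacing_regression(spacing_data(), 4)
    assert res.c == pytest.approx(2.0, abs=1e-6)
    assert res.w_T == pytest.approx(-0.05, abs=1e-6)
    assert res.w_random == pytest.approx(0.8, abs=1e-6)
    assert res.w_difficulty == pytest.approx(0.3, abs=1e-6)


def test_fit_spacing_regression_huber_resists_gross_outliers():
    import statsmodels.api as sm
    df = spacing_data(n=300, noise=0.05, seed=3)
    rng = np.random.default_rng(4)
    hit = rng.choice(len(df), size=15, replace=False)     # 5% gross outliers
    df.loc[hit, "normalized_rate"] += 50.0
    truth = np.array([2.0, -0.05, 0.8, 0.3])

    res = fit_spacing_regression(df, 4)
    huber_err = np.max(np.abs(np.array([res.c, res.w_T, res.w_random,
                                        res.w_difficulty]) - truth))
    t_med = df["T"].median()
    X = np.column_stack([np.ones(len(df)), df["T"] - t_med,
                         (df.arm == "random").astype(float),
                         (df.arm == "difficulty").astype(float)])
    ols_err = np.max(np.abs(sm.OLS(df.normalized_rate.to_numpy(), X)
                            .fit().params - truth))
    assert huber_err < ols_err


def test_fit_spacing_regression_missing_arm_names_it():
    df = spacing_data()
    df = df[df.arm != "difficulty"]
    with pytest.raises(ValueError, match="difficulty"):
        fit_spacing_regression(df, 4)


def test_fit_spacing_regression_requires_enough_data():
    with pytest.raises(ValueError, match=">= 10"):
        fit_spacing_regression(spacing_data(n=9), 4)


# ---------------------------------------------------------------------------
# engagement
# ---------------------------------------------------------------------------

def test_engagement_hand_tally():
    events = []

    def sessions(lid, arm, days):
        for j, d in enumerate(days):
            events.append(make_event(lid, "q1", f"{lid}-s{j}", d, 1, arm))

    sessions("L1", "select", [0, 5])        # returns in 4-7 d
    sessions("L2", "select", [0, 1])        # early stopper
    sessions("L3", "random", [0, 4])        # returns
    sessions("L4", "random", [0, 2])        # early stopper (span == 2)
    sessions("L5", "difficulty", [0, 8])    # neither
    sessions("L6", "difficulty", [0, 6, 20])  # returns
    met = engagement_metrics(ReviewLog.from_events(events))
    per = met["per_arm"]
    assert per["select"] == {"n_learners": 2, "return_4_7_frac": 0.5,
                             "early_stop_frac": 0.5}
    assert per["random"] == {"n_learners": 2, "return_4_7_frac": 0.5,
                             "early_stop_frac": 0.5}
    assert per["difficulty"]["return_4_7_frac"] == 0.5
    assert per["difficulty"]["early_stop_frac"] == 0.0
    assert met["relative_to_random"]["difficulty"]["early_stop_frac"] == -1.0
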