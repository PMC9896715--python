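import numpy as np
import pytest
from scipy import stats
from scipy.special import comb

from mrde.survstats import (
    bh_fdr,
    bonferroni,
    chisq_gof,
    chisq_independence,
    fisher_exact_2x2,
    fisher_rxc,
    km_estimate,
    weighted_logrank,
    wilcoxon_rank_sum,
)


# ------------------------------------------------------------- Kaplan-Meier

def test_km_hand_computed_product_limit():
    km = km_estimate([1, 2, 3], [1, 0, 1]).set_index("time")
    assert km.loc[1.0, "survival"] == pytest.approx(2 / 3)
    assert km.loc[3.0, "survival"] == pytest.approx(0.0)


def test_km_no_events_flat_and_closed_form():
    km = km_estimate([5, 6, 7], [0, 0, 0])
    assert (km["survival"] == 1.0).all()
    times = np.arange(1, 6)
    km2 = km_estimate(times, np.ones(5)).set_index("time")
    for i, t in enumerate(times, start=1):
        assert km2.loc[float(t), "survival"] == pytest.approx((5 - i) / 5)
    surv = km2["survival"].to_numpy()
    assert np.all(np.diff(surv) <= 0)  # non-increasing step function


# ----------------------------------------------------------- weighted logrank

def _brute_weighted_logrank(times, events, groups, weight):
    """Hand-enumerated risk sets following the stated weight definitions."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    u = v = 0.0
    s_left = 1.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n = at.sum()
        n1 = (at & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        w = {"logrank": 1.0, "peto": s_left, "modified_peto": s_left * n / (n + 1)}[weight]
        u += w * (d1 - d * n1 / n)
        if n > 1:
            v += w**2 * d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
        s_left *= 1 - d / (n + 1)
    return u**2 / v


@pytest.mark.parametrize("weight", ["logrank", "peto", "modified_peto"])
def test_weighted_logrank_matches_bruteforce_oracle(weight):
    times = [1, 2, 3, 10, 11, 12]
    events = [1, 1, 1, 1, 1, 1]
    groups = ["A", "A", "A", "B", "B", "B"]
    res = weighted_logrank(times, events, groups, weight=weight)
    assert res.statistic == pytest.approx(_brute_weighted_logrank(times, events, groups, weight))
    assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 1))


def test_weighted_logrank_identical_groups_zero():
    times = [1, 2, 3, 1, 2, 3]
    events = [1, 0, 1, 1, 0, 1]
    groups = ["A"] * 3 + ["B"] * 3
    res = weighted_logrank(times, events, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_weighted_logrank_single_event_time_weights_cancel():
    times = [5, 5, 5, 5, 9, 9]
    events = [1, 1, 0, 0, 0, 0]
    groups = ["A", "B", "A", "B", "A", "B"]
    a = weighted_logrank(times, events, groups, weight="logrank").statistic
    b = weighted_logrank(times, events, groups, weight="modified_peto").statistic
    assert a == pytest.approx(b)


def test_weighted_logrank_agrees_with_lifelines_unweighted():
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(0)
    times = rng.exponential(100, 60)
    events = rng.random(60) < 0.8
    groups = np.repeat(["A", "B", "C"], 20)
    res = weighted_logrank(times, events.astype(int), groups, weight="logrank")
    ref = multivariate_logrank_test(times, groups, events)
    assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
    assert res.df == 2


def test_weighted_logrank_no_events_warns_p_one():
    with pytest.warns(UserWarning):
        res = weighted_logrank([1, 2], [0, 0], ["A", "B"])
    assert res.p == 1.0


# ----------------------------------------------------------------- Wilcoxon

def test_wilcoxon_exact_small_sample():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], side="less")
    assert res.method == "wilcoxon_exact"
    assert res.p == pytest.approx(1 / comb(6, 3))
    mirrored = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], side="greater")
    assert mirrored.p == pytest.approx(res.p)


def test_wilcoxon_identical_samples_approximation():
    res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4], side="two")
    assert res.method == "wilcoxon_normal_approx"  # ties force the normal path
    assert res.p > 0.95


def test_wilcoxon_exact_two_sided_symmetric():
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], side="two")
    assert res.p == pytest.approx(2 / comb(6, 3))


# -------------------------------------------------------------- contingency

def test_fisher_2x2_published_sex_table():
    res = fisher_exact_2x2([[4, 10], [38, 26]])
    assert res.p == pytest.approx(0.043, abs=0.001)


def test_fisher_2x2_degenerate_margin():
    assert fisher_exact_2x2([[0, 0], [5, 7]]).p == 1.0


def test_fisher_2x2_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a, b, c, d = rng.integers(0, 8, 4)
        table = np.array([[a, b], [c, d]])
        res = fisher_exact_2x2(table)
        # enumerate the hypergeometric support
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2
        lo, hi = max(0, c1 - r2), min(r1, c1)
        probs = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
        p_obs = probs[a]
        p_enum = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
        assert res.p == pytest.approx(min(1.0, p_enum), abs=1e-9)


def test_fisher_rxc_agrees_with_exact_2x2_and_is_seeded():
    table = [[4, 10], [38, 26]]
    res = fisher_rxc(table, n_mc=20_000, seed=3)
    exact = fisher_exact_2x2(table)
    assert abs(res.p - exact.p) < 0.01
    res2 = fisher_rxc(table, n_mc=20_000, seed=3)
    assert res.p == res2.p


def test_fisher_rxc_block_diagonal_extreme():
    res = fisher_rxc([[20, 0, 0], [0, 20, 0], [0, 0, 20]], n_mc=5000, seed=0)
    assert res.p <= 0.01


def test_chisq_independence_examples():
    res = chisq_independence([[30, 10], [10, 30]])
    assert res.statistic == pytest.approx(20.0)
    assert res.df == 1
    same = chisq_independence([[5, 5], [10, 10]])
    assert same.statistic == pytest.approx(0.0)
    assert same.p == pytest.approx(1.0)
    perm = chisq_independence([[10, 30], [30, 10]])
    assert perm.statistic == pytest.approx(20.0)


def test_chisq_gof_residuals_and_identity():
    res = chisq_gof([600, 250, 150])
    assert res.statistic == pytest.approx(335.0, abs=0.1)
    resid = res.extras["residuals"]
    np.testing.assert_allclose(resid, [14.606, -4.564, -10.042], atol=5e-3)
    assert (resid**2).sum() == pytest.approx(res.statistic)
    flat = chisq_gof([10, 10, 10])
    assert flat.statistic == 0.0
    np.testing.assert_allclose(flat.extras["residuals"], 0.0)


# ------------------------------------------------------------- multiplicity

def test_bh_stepup_hand_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    p = np.random.default_rng(0).random(50)
    assert np.all(bh_fdr(p) >= p - 1e-12)


def test_bonferroni():
    np.testing.assert_allclose(bonferroni([0.01, 0.2]), [0.02, 0.4])
    assert bonferroni([1.0, 1.0])[1] == 1.0
    p = np.random.default_rng(0).random(10)
    assert np.all(bonferroni(p) >= p)


# --------------------------------------------------------------- calibration

def test_modified_peto_type1_error_quick():
    """Under equal hazards the test rejects at ~alpha (coarse check; the
    full-rate simulation lives in the acceptance suite)."""
    rng = np.random.default_rng(6)
    rejections = 0
    reps = 200
    for _ in range(reps):
        times = rng.exponential(100, 80)
        censor = rng.uniform(0, 300, 80)
        obs = np.minimum(times, censor)
        events = (times <= censor).astype(int)
        groups = np.repeat(["A", "B"], 40)
        if weighted_logrank(obs, events, groups).p < 0.05:
            rejections += 1
    assert 0.01 <= rejections / reps <= 0.11
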