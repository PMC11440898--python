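import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from shadea.indicators import (
    RTEDistribution,
    compare_groups,
    compute_indicators,
    compute_stability,
    kruskal_wallis,
    pairwise_mann_whitney,
    shannon_entropy_pct,
)


def _dist(scores):
    scores = np.asarray(scores, dtype=float)
    return RTEDistribution("S1", "input", [f"a{i}" for i in range(scores.shape[0])], scores)


class TestIndicators:
    def test_counting_example(self):
        ind = compute_indicators(_dist([[1.0, 0.8], [0.6, 1.0]]))
        assert ind.rte_mean == pytest.approx(0.85)
        assert ind.p_efficient_pct == pytest.approx(50.0)
        assert ind.p_inefficient_pct == pytest.approx(50.0)
        assert ind.p_above_075_pct == pytest.approx(75.0)

    def test_degenerate_distribution(self):
        ind = compute_indicators(_dist([[0.7, 0.7], [0.7, 0.7]]))
        assert ind.rte_variance == 0.0
        assert ind.entropy_pct == 0.0

    def test_probabilities_sum_to_100_exactly(self):
        rng = np.random.default_rng(0)
        ind = compute_indicators(_dist(rng.uniform(0, 1, size=(13, 7))))
        assert ind.p_efficient_pct + ind.p_inefficient_pct == 100.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, size=(6, 9))
        a = compute_indicators(_dist(scores))
        shuffled = scores[rng.permutation(6)][:, rng.permutation(9)]
        b = compute_indicators(_dist(shuffled))
        for k, v in a.as_dict().items():
            if k != "error_pct":  # error averages per-area means, so area-wise only
                assert v == pytest.approx(b.as_dict()[k], rel=1e-12, nan_ok=True)

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            _dist([[1.2, 0.5]])


class TestEntropy:
    def test_one_score_per_decile_bin_is_maximal(self):
        scores = np.arange(10) / 10.0 + 0.05
        assert shannon_entropy_pct(scores, bins=10) == pytest.approx(100.0)

    def test_single_bin_is_zero(self):
        assert shannon_entropy_pct(np.full(20, 0.42), bins=10) == 0.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, 50)
        assert shannon_entropy_pct(s) == shannon_entropy_pct(rng.permutation(s))

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            shannon_entropy_pct(np.array([0.5]), bins=1)


class TestStability:
    def test_zero_delta_is_completely_stable(self):
        values = np.ones((4, 3, 2))
        called = []
        out = compute_stability(values, lambda v: called.append(1), np.ones((3, 4)), delta=0.0)
        assert out == 100.0 and not called

    def test_full_tolerance_is_completely_stable(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(1, 2, size=(6, 4, 3))
        base = rng.uniform(0, 1, size=(4, 6))
        solve = lambda v: rng.uniform(0, 1, size=(4, 6))
        assert compute_stability(values, solve, base, delta=0.05, epsilon=1.0) == 100.0

    def test_zero_tolerance_on_continuous_scores_is_unstable(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(1, 2, size=(6, 4, 3))
        base = rng.uniform(0, 1, size=(4, 6))
        solve = lambda v: v.mean(axis=2).T  # continuous in the perturbation
        assert compute_stability(values, solve, base, delta=0.05, epsilon=0.0) == 0.0

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            compute_stability(np.ones((1, 1, 1)), lambda v: v, np.ones((1, 1)), delta=-0.1)


def _manual_kruskal(groups):
    """Independent midrank implementation of tie-corrected H."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n = len(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return H / tie


class TestKruskalWallis:
    def test_worked_three_group_example(self):
        # ranks 1..9, rank sums 6, 15, 24 -> H = 7.2
        H, df, p, eta = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)
        assert df == 2
        assert eta == pytest.approx((7.2 - 3 + 1) / (9 - 3))
        assert eta == pytest.approx(0.8667, abs=5e-5)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_groups_no_effect(self):
        H, df, p, eta = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert H == 0.0 and p == 1.0
        assert eta <= 0.0

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_midrank_computation(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        groups = [rng.integers(0, 8, size=rng.integers(3, 10)).astype(float) for _ in range(k)]
        if len(np.unique(np.concatenate(groups))) == 1:
            return
        H, _, _, _ = kruskal_wallis(groups)
        assert H == pytest.approx(_manual_kruskal(groups), rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestMannWhitney:
    def test_complete_separation(self):
        (res,) = pairwise_mann_whitney([[1.0, 2.0], [3.0, 4.0]])
        assert res.r_biserial == pytest.approx(1.0)
        assert res.U in (0.0, 4.0)

    def test_identical_groups_have_zero_effect(self):
        (res,) = pairwise_mann_whitney([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.U == pytest.approx(4.5)  # n1*n2/2
        assert res.r_biserial == pytest.approx(0.0)

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 12) for _ in range(4)]
        results = pairwise_mann_whitney(groups)
        assert len(results) == 6
        for r in results:
            assert r.p_bonferroni == min(1.0, r.p_raw * 6)
            assert r.p_bonferroni <= 1.0
            assert 0.0 <= r.r_biserial <= 1.0

    def test_effect_size_grows_with_shift(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 60)
        r_by_shift = []
        for shift in (0.2, 1.0, 3.0):
            (res,) = pairwise_mann_whitney([base, base + shift])
            r_by_shift.append(res.r_biserial)
        assert r_by_shift[0] < r_by_shift[1] < r_by_shift[2]


def test_compare_groups_bundles_omnibus_and_pairs():
    rng = np.random.default_rng(10)
    groups = [rng.normal(m, 1, 30) for m in (0.0, 0.5, 2.0)]
    comp = compare_groups(groups, labels=["S1", "S2", "S3"])
    assert comp.kw_df == 2
    assert len(comp.pairwise) == 3
    assert comp.pairwise[0].pair == ("S1", "S2")
    assert 0.0 <= comp.eta_sq_H <= 1.0
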