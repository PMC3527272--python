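"""Moving averages, permutation correlation and rank-sum comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topotx.trends import (
    moving_average_trend,
    pearson_with_permutation,
    quartile_stratified_trend,
    rank_sum_compare,
)


def brute_force_windows(x, y, window):
    order = np.lexsort((np.arange(len(x)), x))
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]
    pts = [
        (xs[i : i + window].mean(), ys[i : i + window].mean())
        for i in range(len(xs) - window + 1)
    ]
    return np.array(pts)


def test_constant_response_gives_flat_curve():
    curve = moving_average_trend(np.arange(50.0), np.full(50, 3.25), window=7)
    np.testing.assert_allclose(curve.y_points, 3.25, atol=1e-12)
    assert curve.n_windows == 50 - 7 + 1


def test_full_window_collapses_to_single_mean_point():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    y = np.array([0.0, 2.0, 4.0, 6.0])
    curve = moving_average_trend(x, y, window=4)
    assert curve.n_windows == 1
    assert curve.x_points[0] == pytest.approx(x.mean())
    assert curve.y_points[0] == pytest.approx(y.mean())


def test_small_example_matches_bruteforce_enumeration():
    x = np.arange(1.0, 11.0)
    y = x.copy()
    curve = moving_average_trend(x, y, window=3)
    expected = brute_force_windows(x, y, 3)
    assert curve.n_windows == 8
    np.testing.assert_allclose(curve.x_points, expected[:, 0])
    np.testing.assert_allclose(curve.y_points, expected[:, 1])


def test_input_order_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    ids = np.array([f"g{i:02d}" for i in range(40)])
    curve = moving_average_trend(x, y, window=5, ids=ids)
    perm = rng.permutation(40)
    shuffled = moving_average_trend(x[perm], y[perm], window=5, ids=ids[perm])
    np.testing.assert_allclose(curve.x_points, shuffled.x_points)
    np.testing.assert_allclose(curve.y_points, shuffled.y_points)


def test_curve_x_is_nondecreasing_property():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(5, 60)
        w = int(rng.integers(1, n + 1))
        x = rng.normal(size=n)
        curve = moving_average_trend(x, rng.normal(size=n), window=w)
        assert np.all(np.diff(curve.x_points) >= -1e-12)


def test_window_larger_than_n_raises():
    with pytest.raises(ValueError, match="smaller window"):
        moving_average_trend(np.arange(5.0), np.arange(5.0), window=6)


def test_pearson_trivial_correlations():
    x = np.arange(10.0)
    res = pearson_with_permutation(x, 2 * x + 1, n_perm=200, seed=0)
    assert res["r"] == pytest.approx(1.0)
    res_neg = pearson_with_permutation(x, -x, n_perm=200, seed=0)
    assert res_neg["r"] == pytest.approx(-1.0)
    assert res_neg["p"] <= 2 / 201


def test_pearson_exact_path_equals_exhaustive_enumeration():
    x = np.array([0.3, -1.2, 0.7, 2.0, -0.5])
    y = np.array([1.1, 0.2, -0.4, 1.9, 0.8])
    res = pearson_with_permutation(x, y, n_perm=10000)
    assert res["method"] == "exact"
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = xs @ ys / 5
    count = sum(
        1
        for p in itertools.permutations(range(5))
        if abs(xs @ ys[list(p)] / 5) >= abs(r_obs) - 1e-12
    )
    assert res["p"] == pytest.approx(count / 120)


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_with_permutation(np.ones(10), np.arange(10.0), n_perm=10)
    with pytest.raises(ValueError, match="at least 3"):
        pearson_with_permutation([1.0, 2.0], [1.0, 2.0])


def test_pearson_sampled_p_stable_under_more_permutations():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    y = 0.3 * x + rng.normal(size=30)
    p1 = pearson_with_permutation(x, y, n_perm=2000, seed=1)["p"]
    p2 = pearson_with_permutation(x, y, n_perm=4000, seed=1)["p"]
    assert 0 < p1 <= 1 and 0 < p2 <= 1
    assert abs(p1 - p2) < 0.05


def test_ranksum_identical_groups_and_separated_groups():
    same = rank_sum_compare([1, 2, 2, 3], [1, 2, 2, 3])
    assert same["p"] >= 0.99
    sep = rank_sum_compare([1, 2, 3], [4, 5, 6])
    assert sep["U"] == 0.0
    assert sep["p"] == pytest.approx(0.1)  # 2 of 20 arrangements as extreme


def test_ranksum_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        ours = rank_sum_compare(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours["method"] == "exact"
        assert ours["p"] == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_ranksum_exact_matches_label_permutation_oracle_with_ties():
    # independent oracle: enumerate group-label permutations directly
    a = np.array([1.0, 2.0, 2.0, 5.0])
    b = np.array([2.0, 3.0, 4.0])
    ours = rank_sum_compare(a, b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    n_a = len(a)
    mu = n_a * len(b) / 2.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(combined)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    assert ours["p"] == pytest.approx(count / total)


def test_ranksum_normal_approximation_close_to_exact_at_boundary():
    # exact path vs the large-sample path on the same 6+6 data
    from topotx.trends import _exact_ranksum_pvalue

    rng = np.random.default_rng(4)
    for _ in range(20):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        ranks = stats.rankdata(np.concatenate([a, b]))
        p_exact = _exact_ranksum_pvalue(ranks, 6)
        p_approx = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
        assert abs(p_exact - p_approx) < 0.02


def test_ranksum_empty_group_raises():
    with pytest.raises(ValueError):
        rank_sum_compare([], [1.0])


def test_quartile_trend_sizes_and_single_point_windows():
    rng = np.random.default_rng(6)
    n = 41
    abundance = np.full(n, 5.0)  # all ties: stable near-equal split
    plast = rng.normal(size=n)
    slr = rng.normal(size=n)
    curves = quartile_stratified_trend(abundance, plast, slr, window=10)
    sizes = [c.n_windows + 10 - 1 for c in curves]
    assert sum(sizes) == n
    assert max(sizes) - min(sizes) <= 1

    # window equal to the quartile size: one point per quartile = quartile mean
    n = 40
    abundance = np.arange(n, dtype=float)
    plast = rng.normal(size=n)
    slr = rng.normal(size=n)
    curves = quartile_stratified_trend(abundance, plast, slr, window=10)
    order = np.argsort(-abundance)
    for q, curve in enumerate(curves):
        sel = order[q * 10 : (q + 1) * 10]
        assert curve.n_windows == 1
        assert curve.y_points[0] == pytest.approx(slr[sel].mean())


def test_quartile_trend_window_too_large_raises():
    with pytest.raises(ValueError, match="quartile"):
        quartile_stratified_trend(
            np.arange(40.0), np.arange(40.0), np.arange(40.0), window=11
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
        ),
        min_size=3,
        max_size=25,
    ),
    window=st.integers(1, 25),
)
def test_moving_average_matches_bruteforce_property(data, window):
    x = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    if window > len(x):
        return
    curve = moving_average_trend(x, y, window=window)
    expected = brute_force_windows(x, y, window)
    np.testing.assert_allclose(curve.x_points, expected[:, 0], atol=1e-9)
    np.testing.assert_allclose(curve.y_points, expected[:, 1], atol=1e-9)
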