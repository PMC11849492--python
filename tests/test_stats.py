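"""Statistical primitives against closed forms and independent oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dermalink.stats import (
    adjusted_spearman,
    bh_fdr,
    mann_whitney_u,
    percentile_75,
    spearman_rho,
)


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 1, 2], -0.5),  # 1 - 6*6/(3*8)
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y).rho == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman_rho([1, 2, 3], [5, 5, 5])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30) + 0.5 * x
            ours = spearman_rho(x, y)
            ref = sps.spearmanr(x, y)
            assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True)
    )
    def test_invariant_under_monotone_transform(self, x):
        rng = np.random.default_rng(7)
        x = np.asarray(x, dtype=float)
        y = rng.permutation(len(x)).astype(float)
        base = spearman_rho(x, y).rho
        transformed = spearman_rho(x**3, y).rho  # strictly monotone transform
        assert transformed == pytest.approx(base, abs=1e-10)


class TestAdjustedSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        assert adjusted_spearman(x, x, z).rho == pytest.approx(1.0)

    def test_covariate_nearly_equal_to_y_kills_correlation(self):
        # exact collinearity is a contract error; a covariate carrying
        # essentially all of y's signal must drive the partial rho to ~0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        covariate = y + 0.05 * rng.standard_normal(200)
        assert abs(adjusted_spearman(x, y, covariate).rho) < 0.2

    def test_exactly_collinear_covariate_is_contract_error(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            adjusted_spearman(x, y, y.copy())

    def test_rank_orthogonal_covariate_reduces_to_plain(self):
        # covariate whose ranks are exactly orthogonal to both x and y ranks
        x = np.arange(8, dtype=float)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        # build a covariate by searching small permutations for orthogonality
        rng = np.random.default_rng(3)
        plain = spearman_rho(x, y)
        for _ in range(2000):
            z = rng.permutation(8).astype(float)
            rz = sps.rankdata(z) - 4.5
            if abs(np.dot(rz, sps.rankdata(x) - 4.5)) < 1e-9 and abs(
                np.dot(rz, sps.rankdata(y) - 4.5)
            ) < 1e-9:
                adj = adjusted_spearman(x, y, z)
                assert adj.rho == pytest.approx(plain.rho, abs=1e-6)
                return
        pytest.skip("no rank-orthogonal permutation found")

    def test_matches_pingouin_partial_correlation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(60),
                "y": rng.standard_normal(60),
                "z": rng.standard_normal(60),
            }
        )
        df["y"] += 0.5 * df["z"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        ours = adjusted_spearman(df["x"], df["y"], df["z"])
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)

    def test_collinear_covariate_rejected(self):
        x = np.arange(10, dtype=float)
        y = np.arange(10, dtype=float)[::-1]
        with pytest.raises(ValueError, match="collinear"):
            adjusted_spearman(x, y, x.copy())


def _enumeration_p(a, b):
    """Independent oracle: two-sided exact p by enumerating every
    assignment of the pooled ranks to group a."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean = n1 * n2 / 2
    count = total = 0
    for comb in combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean) >= abs(u_obs - mean) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.u_statistic == pytest.approx(4.5)  # n1*n2/2

    def test_singletons(self):
        res = mann_whitney_u([1], [2])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_exact_p_equals_enumeration_for_all_small_inputs(self):
        rng = np.random.default_rng(5)
        for n in range(2, 11):
            for n1 in range(1, n):
                vals = rng.standard_normal(n)
                for split in combinations(range(n), n1):
                    a = vals[list(split)]
                    b = np.delete(vals, list(split))
                    res = mann_whitney_u(a, b)
                    assert res.method == "exact"
                    assert res.p_value == pytest.approx(_enumeration_p(a, b), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        from dermalink.stats import _normal_approx_p

        rng = np.random.default_rng(6)
        for _ in range(100):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            approx = _normal_approx_p(res.u_statistic, 8, 8, np.concatenate([a, b]))
            assert abs(res.p_value - approx) <= 0.02

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = rng.standard_normal(6)
            b = rng.standard_normal(7)
            ours = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestBhFdr:
    def test_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_fdr([0.5])[0] == pytest.approx(0.5)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])

    def test_matches_brute_force_step_up(self):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            for pos, idx in enumerate(order):
                q[idx] = min(
                    min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0
                )
            return q

        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute(p), atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_sorted_q_values_monotone(self, p):
        p_sorted = np.sort(p)
        q = bh_fdr(p_sorted)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q <= 1.0)
        assert np.all(q >= p_sorted - 1e-12)


class TestPercentile75:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3, 4], 3.25), ([7], 7.0), ([5, 5, 5, 5], 5.0)],
    )
    def test_known_values(self, values, expected):
        assert percentile_75(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_75([])

    def test_matches_numpy_linear_interpolation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            v = rng.standard_normal(rng.integers(1, 100))
            assert percentile_75(v) == pytest.approx(np.percentile(v, 75), abs=1e-12)
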