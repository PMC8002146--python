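"""The quadratic-form multivariate test, V0 estimation, and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import zmanova as zm
from zmanova.exceptions import IllConditionedError


def corr2(r):
    return pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])


class TestEstimateV0:
    def test_identical_columns_give_unit_correlation(self):
        col = np.random.default_rng(0).standard_normal(50)
        z = pd.DataFrame({"a": col, "b": col})
        v0 = zm.estimate_v0(z)
        assert v0.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.standard_normal((20000, 3)), columns=list("abc"))
        v0 = zm.estimate_v0(z)
        off = v0.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05  # sampling error ~ 1/sqrt(20000)

    def test_recovers_true_correlation(self):
        z = zm.simulate_null_z(20000, zm.equicorrelated(2, 0.6), seed=2)
        v0 = zm.estimate_v0(z)
        assert v0.iloc[0, 1] == pytest.approx(0.6, abs=0.03)

    def test_null_filter_restricts_contributing_snps(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.standard_normal((5000, 2)), columns=["a", "b"])
        z.iloc[:50] += 40.0  # huge shared signals would inflate the correlation
        contaminated = zm.estimate_v0(z)
        filtered = zm.estimate_v0(z, null_filter=2.0)
        assert contaminated.iloc[0, 1] > 0.5
        assert abs(filtered.iloc[0, 1]) < 0.1

    def test_zero_variance_trait_named_in_error(self):
        z = pd.DataFrame({"a": [1.0, 2.0, 3.0], "dead": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="dead"):
            zm.estimate_v0(z)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            zm.estimate_v0(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}))


class TestManovaScore:
    def test_identity_v0_reduces_to_sum_of_squares(self):
        assert zm.manova_score([3.0, 0.0], np.eye(2)) == pytest.approx(9.0)

    def test_hand_inverted_two_by_two(self):
        # V0 = [[1,.5],[.5,1]] => z'V0^{-1}z = (4+4-2*2)/0.75 = 16/3
        assert zm.manova_score([2.0, 2.0], corr2(0.5)) == pytest.approx(16 / 3)

    def test_zero_vector_scores_zero(self):
        assert zm.manova_score(np.zeros(4), zm.equicorrelated(4, 0.3)) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            zm.manova_score([1.0, 2.0, 3.0], corr2(0.2))

    def test_ill_conditioned_v0_errors_and_names_shrinkage(self):
        v0 = corr2(1 - 1e-12)
        with pytest.raises(IllConditionedError, match="shrink"):
            zm.manova_score([1.0, 1.0], v0)
        shrunk = zm.shrink_v0(v0, 0.01)
        assert np.isfinite(zm.manova_score([1.0, 1.0], shrunk))

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((40, 3))
        v0 = zm.equicorrelated(3, 0.4)
        batch = zm.manova_scores(z, v0)
        singles = [zm.manova_score(row, v0) for row in z]
        np.testing.assert_allclose(batch, singles, rtol=1e-10)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_trait_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(4)
        v0 = zm.estimate_v0(pd.DataFrame(rng.standard_normal((60, 4)))).to_numpy()
        perm = rng.permutation(4)
        t2 = zm.manova_score(z, v0)
        t2p = zm.manova_score(z[perm], v0[np.ix_(perm, perm)])
        assert t2p == pytest.approx(t2, rel=1e-9)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_single_trait_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(3)
        v0 = zm.estimate_v0(pd.DataFrame(rng.standard_normal((60, 3)))).to_numpy()
        flip = np.diag([-1.0, 1.0, 1.0])
        assert zm.manova_score(flip @ z, flip @ v0 @ flip) == pytest.approx(
            zm.manova_score(z, v0), rel=1e-9
        )

    def test_identity_v0_equals_sum_sq_to_machine_precision(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((100, 5))
        np.testing.assert_allclose(
            zm.manova_scores(z, np.eye(5)), (z ** 2).sum(axis=1), atol=1e-12
        )


class TestPvalues:
    def test_zero_score_has_p_one(self):
        assert zm.manova_pvalue(0.0, 3) == 1.0

    def test_chi2_95th_percentile(self):
        assert zm.manova_pvalue(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_df1_equals_squared_normal(self):
        assert zm.manova_pvalue(9.0, 1) == pytest.approx(2 * stats.norm.sf(3), rel=1e-9)

    def test_strictly_decreasing_in_t2(self):
        t2 = np.linspace(0, 50, 200)
        p = zm.manova_pvalue(t2, 6)
        assert np.all(np.diff(p) < 0)

    def test_log10p_survives_extreme_scores(self):
        # a score far in the tail underflows the linear p but not the log
        lg = zm.manova_log10p(1600.0, 9)
        assert np.isfinite(lg) and lg < -330
        assert zm.manova_pvalue(1600.0, 9) == 0.0  # linear scale underflows


class TestThresholdAndLambda:
    @pytest.mark.parametrize(
        "n_snp,n_groups,expected",
        [(493742, 3, 3.3756e-8), (1, 1, 0.05), (100, 2, 2.5e-4)],
    )
    def test_bonferroni(self, n_snp, n_groups, expected):
        assert zm.bonferroni_threshold(n_snp, n_groups) == pytest.approx(
            expected, rel=1e-4
        )

    def test_uniform_quantiles_give_lambda_one(self):
        n = 10001
        p = (np.arange(1, n + 1) - 0.5) / n
        for df in (1, 3, 9):
            assert zm.inflation_factor(p, df) == pytest.approx(1.0, abs=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        chi = stats.chi2.rvs(3, size=20001, random_state=rng)
        p1 = stats.chi2.sf(chi, 3)
        p2 = stats.chi2.sf(2 * chi, 3)
        lam1 = zm.inflation_factor(p1, 3)
        lam2 = zm.inflation_factor(p2, 3)
        assert lam2 / lam1 == pytest.approx(2.0, rel=1e-9)

    def test_null_lambda_near_one(self):
        z = zm.simulate_null_z(50000, zm.equicorrelated(9, 0.3), seed=7)
        groups = [zm.TraitGroup("g", z.traits)]
        res = zm.run_mvgwas(z, groups)
        assert 0.98 <= res.attrs["lambda"]["g"] <= 1.02

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            zm.inflation_factor(np.array([]), 3)


class TestRunMvgwas:
    def test_single_trait_group_reduces_to_two_sided_normal(self):
        z = zm.simulate_null_z(200, pd.DataFrame(np.eye(2)), seed=8,
                               trait_names=["a", "b"])
        res = zm.run_mvgwas(z, [zm.TraitGroup("solo", ["a"])])
        expected = 2 * stats.norm.sf(np.abs(z.z["a"].to_numpy()))
        np.testing.assert_allclose(res["pvalue"].to_numpy(), expected, rtol=1e-9)

    def test_long_format_shape(self):
        z = zm.simulate_null_z(1000, zm.equicorrelated(18, 0.3), seed=9,
                               trait_names=[f"t{i}" for i in range(18)])
        groups = [
            zm.TraitGroup("MMass", [f"t{i}" for i in range(9)]),
            zm.TraitGroup("MFat", [f"t{i}" for i in range(9, 15)]),
            zm.TraitGroup("MMeat", [f"t{i}" for i in range(15, 18)]),
        ]
        res = zm.run_mvgwas(z, groups)
        assert len(res) == 3000
        assert set(res["df"]) == {9, 6, 3}

    def test_group_v0_is_submatrix_of_full(self):
        z = zm.simulate_null_z(5000, zm.equicorrelated(5, 0.4), seed=10,
                               trait_names=list("abcde"))
        full = zm.estimate_v0(z)
        res_sub = zm.run_mvgwas(z, [zm.TraitGroup("g", list("abc"))])
        res_full = zm.run_mvgwas(z, [zm.TraitGroup("g", list("abc"))], v0_full=full)
        np.testing.assert_allclose(
            res_sub["t2"].to_numpy(), res_full["t2"].to_numpy(), rtol=1e-10
        )

    def test_null_t2_follows_chi2(self):
        z = zm.simulate_null_z(50000, zm.equicorrelated(6, 0.5), seed=12,
                               trait_names=[f"t{i}" for i in range(6)])
        res = zm.run_mvgwas(z, [zm.TraitGroup("g", z.traits)])
        ks = stats.kstest(res["t2"].to_numpy(), "chi2", args=(6,))
        assert ks.pvalue > 0.001
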