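"""Score vector, covariance, quadratic-form statistic and mixture p-values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from modality_iwas.modality_test import (
    AdjustmentSet,
    DegenerateTestError,
    bonferroni_adjust,
    build_adjustment,
    cov_score,
    idp_specific_test,
    mixture_chisq_pvalue,
    modality_test,
    score_result,
    score_vector,
    test_statistic as quad_statistic,
)
from modality_iwas.stage1 import WeightMatrix


def adj(A2):
    A2 = np.atleast_2d(A2)
    return AdjustmentSet(A2, [f"c{i}" for i in range(A2.shape[1])])


class TestScoreVector:
    def test_empty_adjustment_reduces_to_a1t_z(self):
        A1 = np.array([[1.0], [2.0]])
        z = np.array([0.5, -1.0])
        np.testing.assert_allclose(score_vector(A1, None, np.eye(2), z), [-1.5])

    def test_identical_tested_and_adjusted_column_annihilates(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 1))
        R = np.corrcoef(rng.normal(size=(50, 4)), rowvar=False)
        z = rng.normal(size=4)
        S = score_vector(a, adj(a), R, z)
        np.testing.assert_allclose(S, 0.0, atol=1e-10)

    def test_two_snp_hand_computation(self):
        # A1 = e1, A2 = e2, R = I, z = (1, 2): projection leaves A1'z = 1
        A1 = np.array([[1.0], [0.0]])
        A2 = np.array([[0.0], [1.0]])
        z = np.array([1.0, 2.0])
        S = score_vector(A1, adj(A2), np.eye(2), z)
        np.testing.assert_allclose(S, [1.0])


class TestCovScore:
    def test_empty_adjustment_identity_ld(self):
        rng = np.random.default_rng(1)
        A1 = rng.normal(size=(5, 2))
        np.testing.assert_allclose(cov_score(A1, None, np.eye(5)), A1.T @ A1)

    def test_r_orthogonal_adjustment_leaves_cov_unchanged(self):
        # columns orthogonal under the R inner product: correction term is 0
        R = np.diag([1.0, 1.0])
        A1 = np.array([[1.0], [0.0]])
        A2 = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(
            cov_score(A1, adj(A2), R), A1.T @ R @ A1, atol=1e-12
        )

    def test_a1_in_span_of_a2_gives_zero_cov(self):
        rng = np.random.default_rng(2)
        R = np.corrcoef(rng.normal(size=(40, 2)), rowvar=False)
        a = rng.normal(size=(2, 1))
        C = cov_score(a, adj(2.5 * a), R)
        np.testing.assert_allclose(C, 0.0, atol=1e-10)

    def test_psd_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            J = rng.integers(3, 8)
            R = np.corrcoef(rng.normal(size=(5 * J, J)), rowvar=False)
            A1 = rng.normal(size=(J, 2))
            A2 = rng.normal(size=(J, 2))
            lam = np.linalg.eigvalsh(cov_score(A1, adj(A2), R))
            assert lam.min() >= -1e-8 * max(lam.max(), 1.0)


class TestTestStatistic:
    @pytest.mark.parametrize("S,expected", [([1.0], 1.0), ([3.0, 4.0], 25.0)])
    def test_squared_norm(self, S, expected):
        assert quad_statistic(np.array(S)) == expected

    @given(c=st.floats(0.1, 10), s=st.lists(st.floats(-5, 5), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, c, s):
        S = np.array(s)
        assert quad_statistic(c * S) == pytest.approx(c**2 * quad_statistic(S), rel=1e-12)


def independent_mixture_sf(T, lam):
    """Convolution-based survival function for a 2-component mixture:
    P(l1 X + l2 Y > T) by direct 1-D integration over X's density."""
    l1, l2 = lam
    f = lambda x: stats.chi2.pdf(x, 1) * stats.chi2.sf(max(T - l1 * x, 0.0) / l2, 1)
    val, _ = integrate.quad(f, 0, max(10 * T / l1, 50), limit=400)
    return val


class TestMixtureChisqPvalue:
    def test_single_eigenvalue_matches_chi2_1(self):
        p, method = mixture_chisq_pvalue(3.841459, [1.0])
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_two_equal_eigenvalues_match_chi2_2(self):
        p, _ = mixture_chisq_pvalue(5.991465, [1.0, 1.0])
        assert p == pytest.approx(0.05, abs=1e-6)

    @pytest.mark.parametrize("K", range(1, 11))
    def test_equal_eigenvalues_match_k_df_chisq(self, K):
        T = 1.7 * K
        p, _ = mixture_chisq_pvalue(T, np.full(K, 1.0))
        assert p == pytest.approx(stats.chi2.sf(T, K), abs=1e-6)

    def test_scaled_equal_eigenvalues(self):
        p, _ = mixture_chisq_pvalue(2 * 5.991465, [2.0, 2.0])
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_davies_matches_convolution_oracle(self):
        p, method = mixture_chisq_pvalue(7.0, [2.0, 1.0], method="davies")
        assert method == "davies"
        assert p == pytest.approx(independent_mixture_sf(7.0, (2.0, 1.0)), abs=1e-6)

    def test_monte_carlo_matches_davies_within_3_se(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            lam = rng.uniform(0.2, 3.0, size=rng.integers(2, 6))
            T = rng.uniform(0.5, 3.0) * lam.sum()
            p_d, _ = mixture_chisq_pvalue(T, lam, method="davies")
            draws = 200_000
            p_mc, _ = mixture_chisq_pvalue(T, lam, method="monte_carlo",
                                           mc_draws=draws, seed=5)
            se = np.sqrt(p_d * (1 - p_d) / draws)
            assert abs(p_mc - p_d) < 3 * se + 2 / draws

    def test_liu_close_to_davies_in_moderate_tail(self):
        lam = np.array([3.0, 1.0, 0.5])
        T = 9.0
        p_d, _ = mixture_chisq_pvalue(T, lam, method="davies")
        p_l, _ = mixture_chisq_pvalue(T, lam, method="liu")
        assert p_l == pytest.approx(p_d, rel=0.05)

    def test_monte_carlo_never_returns_zero(self):
        p, _ = mixture_chisq_pvalue(1e9, [1.0, 2.0], method="monte_carlo",
                                    mc_draws=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_all_zero_eigenvalues_degenerate(self):
        with pytest.raises(DegenerateTestError):
            mixture_chisq_pvalue(1.0, [0.0, 0.0])

    def test_tiny_eigenvalues_discarded(self):
        # a 1e-14-scale eigenvalue must not inflate the mixture dimension
        p, _ = mixture_chisq_pvalue(3.841459, [1.0, 1e-14])
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_auto_policy_selection(self):
        _, m_small = mixture_chisq_pvalue(3.0, [2.0, 1.0], mc_draws=1000, seed=0)
        assert m_small == "monte_carlo"
        lam = np.linspace(1, 2, 6)
        _, m_large = mixture_chisq_pvalue(6.0, lam)
        assert m_large == "davies"


def random_instance(seed, J=6, K1=2, K2=2):
    rng = np.random.default_rng(seed)
    R = np.corrcoef(rng.normal(size=(8 * J, J)), rowvar=False)
    A1 = rng.normal(size=(J, K1))
    A2 = rng.normal(size=(J, K2))
    z = rng.normal(size=J)
    return A1, A2, R, z


class TestScaleInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scaling_a1_scales_t_and_eigenvalues_leaving_p_fixed(self, seed):
        A1, A2, R, z = random_instance(seed)
        c = 3.7
        base = score_result(A1, adj(A2), R, z)
        scaled = score_result(c * A1, adj(A2), R, z)
        T0, T1 = quad_statistic(base.S), quad_statistic(scaled.S)
        assert T1 == pytest.approx(c**2 * T0, rel=1e-10)
        np.testing.assert_allclose(
            scaled.eigenvalues, c**2 * base.eigenvalues, rtol=1e-10
        )
        p0, _ = mixture_chisq_pvalue(T0, base.eigenvalues, method="davies")
        p1, _ = mixture_chisq_pvalue(T1, scaled.eigenvalues, method="davies")
        assert p1 == pytest.approx(p0, rel=1e-8)


def make_weights(seed=0, J=8, K1=3, K2=2):
    rng = np.random.default_rng(seed)
    R = np.corrcoef(rng.normal(size=(10 * J, J)), rowvar=False)
    snps = [f"rs{i}" for i in range(J)]
    weights = {
        "sMRI": WeightMatrix(snps, [f"s{k}" for k in range(K1)],
                             rng.normal(size=(J, K1)), "sMRI"),
        "dMRI": WeightMatrix(snps, [f"d{k}" for k in range(K2)],
                             rng.normal(size=(J, K2)), "dMRI"),
    }
    z = rng.normal(size=J)
    return weights, R, z


class TestModalityTest:
    def test_k1_equal_1_matches_gaussian_score_test(self):
        weights, R, z = make_weights(K1=1)
        res = modality_test("g", "sMRI", weights, z, R)
        a = weights["sMRI"].W
        A2 = np.column_stack([weights["dMRI"].W, np.ones((len(z), 1))])
        S = score_vector(a, adj(A2), R, z)
        var = cov_score(a, adj(A2), R)[0, 0]
        p_gauss = 2 * stats.norm.sf(abs(S[0]) / np.sqrt(var))
        assert res.p_value == pytest.approx(p_gauss, abs=1e-10)

    def test_deterministic_given_seed(self):
        weights, R, z = make_weights()
        r1 = modality_test("g", "sMRI", weights, z, R, p_method="monte_carlo",
                           mc_draws=5000, seed=42)
        r2 = modality_test("g", "sMRI", weights, z, R, p_method="monte_carlo",
                           mc_draws=5000, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.T == r2.T

    def test_no_adjustment_flags_give_unadjusted_score(self):
        weights, R, z = make_weights()
        res = modality_test("g", "sMRI", weights, z, R,
                            adjust_other_modalities=False, adjust_direct=False)
        S = weights["sMRI"].W.T @ z
        assert res.T == pytest.approx(float(S @ S))
        assert res.adjusted_labels == []

    def test_zero_column_modality_gives_no_test(self):
        weights, R, z = make_weights()
        snps = weights["sMRI"].snp_ids
        weights["fMRI"] = WeightMatrix(snps, [], np.empty((len(snps), 0)), "fMRI")
        res = modality_test("g", "fMRI", weights, z, R)
        assert res.no_test
        assert np.isnan(res.p_value)

    def test_collinear_adjustment_columns_dropped_not_fatal(self):
        weights, R, z = make_weights()
        W = weights["dMRI"].W
        weights["dMRI"] = WeightMatrix(
            weights["dMRI"].snp_ids, ["d0", "d1", "d0_copy"],
            np.column_stack([W, W[:, 0]]), "dMRI",
        )
        res = modality_test("g", "sMRI", weights, z, R)
        assert 0 <= res.p_value <= 1


class TestIdpSpecificTest:
    def test_single_idp_modality_method2_equals_method1(self):
        weights, R, z = make_weights(K1=1)
        m1 = modality_test("g", "sMRI", weights, z, R)
        m2 = idp_specific_test("g", "s0", "sMRI", weights, z, R)
        assert m2.p_value == pytest.approx(m1.p_value, abs=1e-12)

    def test_uv_iwas_formulas_identity_ld(self):
        # unadjusted single-IDP test with R = I: T = (a'z)^2, lambda = a'a
        J = 5
        rng = np.random.default_rng(4)
        a = rng.normal(size=(J, 1))
        z = rng.normal(size=J)
        snps = [f"rs{i}" for i in range(J)]
        weights = {"m": WeightMatrix(snps, ["i0"], a, "m")}
        res = idp_specific_test("g", "i0", "m", weights, z, np.eye(J),
                                adjust_other_modalities=False, adjust_direct=False)
        assert res.T == pytest.approx(float((a[:, 0] @ z) ** 2))
        lam = float(a[:, 0] @ a[:, 0])
        assert res.p_value == pytest.approx(float(stats.chi2.sf(res.T / lam, 1)))

    def test_invariant_to_adjustment_column_order(self):
        weights, R, z = make_weights(K2=3)
        res_a = idp_specific_test("g", "s0", "sMRI", weights, z, R)
        W = weights["dMRI"].W[:, ::-1]
        weights["dMRI"] = WeightMatrix(weights["dMRI"].snp_ids,
                                       ["d2", "d1", "d0"], W, "dMRI")
        res_b = idp_specific_test("g", "s0", "sMRI", weights, z, R)
        assert res_a.p_value == pytest.approx(res_b.p_value, abs=1e-10)


class TestBonferroni:
    def test_strictly_below_threshold_significant(self):
        flags, thr = bonferroni_adjust([0.004], alpha=0.05, m=10)
        assert thr == 0.005
        assert flags[0]

    def test_boundary_not_significant(self):
        flags, _ = bonferroni_adjust([0.005], alpha=0.05, m=10)
        assert not flags[0]

    def test_m_one_threshold_is_alpha(self):
        _, thr = bonferroni_adjust([0.5], alpha=0.05, m=1)
        assert thr == 0.05
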