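import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hta.data import CohortDesign, DataError, ExpressionMatrix
from hta.model import (
    HTAModel,
    SampleErrorModel,
    bh_fdr,
    cohort_posterior,
    degenerate_variance_floor,
    estimate_sample_error_variances,
    hta_test,
    pairwise_difference_variance,
)
from hta.normalization import scaling_normalize


def _matrix(values, samples):
    nf = values.shape[0]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i:05d}" for i in range(nf)], columns=samples)
    )


# ---------------------------------------------------------------- pairwise


class TestPairwiseDifferenceVariance:
    def test_identical_columns_give_zero(self):
        v = np.tile(np.arange(5.0)[:, None], (1, 2))
        m = _matrix(v, ["a", "b"])
        assert pairwise_difference_variance(m, "a", "b") == 0.0

    def test_constant_offset_gives_zero(self):
        v = np.arange(5.0)[:, None] + np.array([[0.0, 3.5]])
        m = _matrix(v, ["a", "b"])
        assert pairwise_difference_variance(m, "a", "b") == pytest.approx(0.0)

    def test_monte_carlo_matches_sum_of_variances(self):
        # two arrays = template + iid N(0, 0.034^2): difference variance
        # should equal 2 * 0.034^2 (independent errors add)
        rng = np.random.default_rng(42)
        nf = 50_000
        template = rng.normal(7.0, 2.0, nf)
        v = template[:, None] + rng.normal(0.0, 0.034, (nf, 2))
        m = _matrix(v, ["a", "b"])
        got = pairwise_difference_variance(m, "a", "b")
        assert got == pytest.approx(2 * 0.034**2, rel=0.05)

    def test_same_sample_rejected(self, tiny_matrix):
        with pytest.raises(DataError, match="distinct"):
            pairwise_difference_variance(tiny_matrix, "t1", "t1")


# ------------------------------------------------------- samplewise model


class TestSampleErrorEstimation:
    def test_identical_arrays_give_zero_variances(self):
        v = np.tile(np.arange(6.0)[:, None], (1, 3))
        m = _matrix(v, ["a", "b", "c"])
        em = estimate_sample_error_variances(m, ["a", "b", "c"])
        assert all(s2 == 0.0 for s2 in em.sigma2.values())

    def test_pair_cohort_splits_difference_variance_evenly(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(100, 2))
        m = _matrix(v, ["a", "b"])
        em = estimate_sample_error_variances(m, ["a", "b"])
        pair_v = pairwise_difference_variance(m, "a", "b")
        assert em.sigma2["a"] == pytest.approx(pair_v / 2)
        assert em.sigma2["b"] == pytest.approx(pair_v / 2)
        # n=2 decomposition identity is exact
        assert em.sigma2["a"] + em.sigma2["b"] == pytest.approx(pair_v, abs=0.0)

    def test_consistency_identity_holds_for_each_sample(self):
        # sigma2_i = (1/2)(1/(n-1)) sum_j sigma2_ij must hold exactly
        rng = np.random.default_rng(4)
        v = rng.normal(size=(200, 4))
        m = _matrix(v, list("abcd"))
        em = estimate_sample_error_variances(m, list("abcd"))
        for i in "abcd":
            total = sum(
                em.pairwise[frozenset((i, j))] for j in "abcd" if j != i
            )
            assert em.sigma2[i] == pytest.approx(total / 6, rel=1e-12)

    def test_recovers_generating_sd_across_cohort_sizes(self):
        # mean estimated samplewise SD within 5% of truth for n in {3,4,8}
        rng = np.random.default_rng(5)
        nf, sd = 20_000, 0.1
        for n in (3, 4, 8):
            template = rng.normal(7.0, 2.0, nf)
            v = template[:, None] + rng.normal(0.0, sd, (nf, n))
            samples = [f"s{i}" for i in range(n)]
            em = estimate_sample_error_variances(_matrix(v, samples), samples)
            mean_sd = np.mean([np.sqrt(s2) for s2 in em.sigma2.values()])
            assert mean_sd == pytest.approx(sd, rel=0.05)

    def test_invariant_under_scaling_normalization(self, medium_null):
        matrix, design = medium_null
        normed, _ = scaling_normalize(matrix)
        before = estimate_sample_error_variances(matrix, design.test_samples)
        after = estimate_sample_error_variances(normed, design.test_samples)
        for s in design.test_samples:
            assert after.sigma2[s] == pytest.approx(before.sigma2[s], rel=1e-9)

    def test_cohort_of_one_rejected(self, tiny_matrix):
        with pytest.raises(DataError, match=">= 2"):
            estimate_sample_error_variances(tiny_matrix, ["t1"])


class TestVarianceFloor:
    def test_above_floor_unchanged(self):
        em = SampleErrorModel(sigma2={"a": 0.1, "b": 0.2})
        out = degenerate_variance_floor(em, 1e-12)
        assert out.sigma2 == em.sigma2 and not out.floored

    def test_zero_variance_raised_and_flagged(self):
        em = SampleErrorModel(sigma2={"a": 0.0, "b": 0.2})
        out = degenerate_variance_floor(em, 1e-12)
        assert out.sigma2["a"] == 1e-12 and out.floored

    def test_nonpositive_floor_rejected(self):
        em = SampleErrorModel(sigma2={"a": 0.1})
        with pytest.raises(ValueError, match="positive"):
            degenerate_variance_floor(em, 0.0)


# -------------------------------------------------------------- posterior


def _grid_product_of_gaussians(values, variances):
    """Independent oracle: multiply Gaussian densities on a fine grid and
    measure the mean/variance of the normalized product."""
    values = np.asarray(values, dtype=float)
    sds = np.sqrt(np.asarray(variances, dtype=float))
    lo = (values - 10 * sds).min()
    hi = (values + 10 * sds).max()
    y = np.linspace(lo, hi, 400_001)
    log_dens = np.zeros_like(y)
    for x, s in zip(values, sds):
        log_dens += stats.norm.logpdf(y, loc=x, scale=s)
    dens = np.exp(log_dens - log_dens.max())
    dens /= np.trapezoid(dens, y)
    mu = np.trapezoid(y * dens, y)
    var = np.trapezoid((y - mu) ** 2 * dens, y)
    return mu, var


class TestCohortPosterior:
    def test_equal_values_equal_variances(self):
        mu, var = cohort_posterior([0.0, 0.0], [0.3, 0.3])
        assert mu == 0.0 and var == pytest.approx(0.15)

    def test_symmetry_with_equal_variances(self):
        mu, var = cohort_posterior([1.0, 3.0], [0.5, 0.5])
        assert mu == pytest.approx(2.0) and var == pytest.approx(0.25)

    def test_unequal_variances_hand_case(self):
        mu, var = cohort_posterior([0.0, 1.0], [1.0, 4.0])
        assert mu == pytest.approx(0.2) and var == pytest.approx(0.8)

    def test_matches_grid_product_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = rng.integers(2, 6)
            values = rng.normal(0.0, 2.0, n)
            variances = rng.uniform(0.05, 2.0, n)
            mu, var = cohort_posterior(values, variances)
            mu_g, var_g = _grid_product_of_gaussians(values, variances)
            assert mu == pytest.approx(mu_g, abs=1e-6)
            assert var == pytest.approx(var_g, abs=1e-6)

    def test_mean_bounded_by_observations(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = rng.normal(size=4)
            variances = rng.uniform(0.01, 5.0, 4)
            mu, var = cohort_posterior(values, variances)
            assert values.min() <= mu <= values.max()
            assert 0 < var < variances.min()

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(DataError, match="positive"):
            cohort_posterior([0.0, 1.0], [0.0, 1.0])


# ------------------------------------------------------------------- FDR


def _bh_stepup_oracle(p):
    """Direct step-up enumeration: q_(i) = min_{k>=i} m*p_(k)/k, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHFDR:
    def test_three_value_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_matches_stepup_oracle_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), _bh_stepup_oracle(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


# ------------------------------------------------------------- full test


class TestHTATest:
    def test_identical_cohorts_give_null_results(self):
        rng = np.random.default_rng(9)
        half = rng.normal(7.0, 1.0, size=(50, 3))
        values = np.hstack([half, half])  # test cohort copies control
        m = _matrix(values, ["t1", "t2", "t3", "c1", "c2", "c3"])
        d = CohortDesign(["t1", "t2", "t3"], ["c1", "c2", "c3"])
        res = hta_test(m, d)
        np.testing.assert_allclose(res["fc_hat"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-9)

    def test_z_is_fc_over_sd_exactly(self, medium_null):
        matrix, design = medium_null
        res = hta_test(matrix, design)
        np.testing.assert_allclose(
            res["z"], res["fc_hat"] / np.sqrt(res["var_fc"]), rtol=1e-12
        )

    def test_fc_variance_constant_so_z_ranking_is_fc_ranking(self, medium_null):
        # the fold-change variance pools samplewise variances only, so it
        # is one number for all features and |z| orders exactly as |fc_hat|
        matrix, design = medium_null
        res = hta_test(matrix, design)
        assert res["var_fc"].nunique() == 1
        by_z = res["z"].abs().sort_values(kind="mergesort").index
        by_fc = res["fc_hat"].abs().sort_values(kind="mergesort").index
        assert list(by_z) == list(by_fc)

    def test_equal_variances_make_posterior_mean_the_plain_mean(self):
        # even sample quality: weighting reduces to the arithmetic mean,
        # so the method's ranking equals plain fold-change ranking
        values = np.array([1.0, 2.0, 6.0])
        mu, _ = cohort_posterior(values, [0.3, 0.3, 0.3])
        assert mu == pytest.approx(values.mean())

    def test_null_z_distribution_is_standard_normal(self, medium_null):
        matrix, design = medium_null
        res = hta_test(matrix, design)
        ks = stats.kstest(res["z"], "norm")
        assert ks.pvalue > 0.01

    def test_unit_fold_change_with_half_variances_gives_z_one(self):
        # cohorts with posterior means 1 and 0, posterior variances 0.5
        # each: z = 1 and the two-sided tail is ~0.3173 (frozen from the
        # standard-normal CDF)
        mu_t, var_t = cohort_posterior([1.0, 1.0], [1.0, 1.0])
        mu_c, var_c = cohort_posterior([0.0, 0.0], [1.0, 1.0])
        z = (mu_t - mu_c) / np.sqrt(var_t + var_c)
        assert z == pytest.approx(1.0)
        assert 2 * stats.norm.sf(z) == pytest.approx(0.3173, abs=5e-4)

    def test_pvalues_match_normal_tail_of_z(self, medium_null):
        matrix, design = medium_null
        res = hta_test(matrix, design)
        np.testing.assert_allclose(
            res["p"], 2 * stats.norm.sf(res["z"].abs()), rtol=1e-9
        )

    def test_robust_variance_close_to_plain_on_clean_data(self, medium_null):
        matrix, design = medium_null
        plain = estimate_sample_error_variances(matrix, design.test_samples)
        robust = estimate_sample_error_variances(
            matrix, design.test_samples, robust=True
        )
        for s in design.test_samples:
            assert robust.sigma2[s] == pytest.approx(plain.sigma2[s], rel=0.1)

    def test_results_object_summary_and_selections(self, medium_null):
        matrix, design = medium_null
        res = HTAModel(matrix, design).fit()
        text = res.summary()
        assert "samplewise error SD" in text
        assert res.selected(0.05) >= res.selected_fdr(0.05)
        assert res.ranking()[0] == res.frame["z"].abs().idxmax()
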