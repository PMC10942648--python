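"""Normalization, precision weights, and the nested activity model."""

import numpy as np
import pytest

from mstarr import model as M
from tests.conftest import make_samples


@pytest.fixture(scope="module")
def design24():
    return M.build_design(make_samples(6))


class TestLogCpm:
    def test_zero_count_analytic(self):
        # log2(0.5 / 1e6 * 1e6) = -1 exactly
        assert M.log_cpm(np.array([[0]]), np.array([999_999]))[0, 0] == -1.0

    def test_full_library_analytic(self):
        lib = 10**6 - 1
        val = M.log_cpm(np.array([[lib]]), np.array([lib]))[0, 0]
        assert val == pytest.approx(np.log2((lib + 0.5) / 10**6 * 1e6), abs=1e-12)

    def test_doubling_count_and_library(self):
        a = M.log_cpm(np.array([[100]]), np.array([10_000]))[0, 0]
        b = M.log_cpm(np.array([[200]]), np.array([20_000]))[0, 0]
        # identical up to the prior-count and +1 library perturbations
        assert abs(a - b) < 0.01

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            M.log_cpm(np.array([[1]]), np.array([0]))


class TestNormalizationFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=50)
        counts = np.tile(col[:, None], (1, 4))
        np.testing.assert_allclose(M.normalization_factors(counts), 1.0, atol=1e-12)

    def test_pure_depth_difference_cancels(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 500, size=200)
        counts = np.column_stack([col, 2 * col, col, col])
        f = M.normalization_factors(counts)
        # doubled depth with identical composition: factors stay ~1
        assert np.all(np.abs(np.log2(f)) < 0.05)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 300, size=(100, 6)) + 1
        f = M.normalization_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_trimmed_mean(self):
        # 10-row fixture, sample 1 doubled on half the rows: the trimmed
        # weighted mean of M values against the reference is reproduced
        ref = np.array([100, 100, 100, 100, 100, 100, 100, 100, 100, 100], float)
        other = np.array([80, 90, 95, 100, 105, 110, 115, 120, 400, 10], float)
        counts = np.column_stack([ref, other])
        lib = counts.sum(axis=0)
        f = M.normalization_factors(counts, lib)
        # oracle: M = log2((y/N)/(yr/Nr)); 30% ratio trim leaves the
        # central ratios; compute directly
        M_vals = np.log2((other / lib[1]) / (ref / lib[0]))
        A_vals = 0.5 * np.log2((other / lib[1]) * (ref / lib[0]))
        w = (lib[1] - other) / (lib[1] * other) + (lib[0] - ref) / (lib[0] * ref)
        import scipy.stats as ss

        n = len(M_vals)
        lM = np.floor(n * 0.3) + 1
        lA = np.floor(n * 0.05) + 1
        keep = (
            (ss.rankdata(M_vals) >= lM) & (ss.rankdata(M_vals) <= n + 1 - lM)
            & (ss.rankdata(A_vals) >= lA) & (ss.rankdata(A_vals) <= n + 1 - lA)
        )
        expected = 2 ** (np.sum(M_vals[keep] / w[keep]) / np.sum(1 / w[keep]))
        expected_pair = np.array([1.0, expected])
        expected_pair /= np.exp(np.mean(np.log(expected_pair)))
        np.testing.assert_allclose(f, expected_pair, rtol=1e-10)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            M.normalization_factors(np.array([[1, 0], [2, 0]]))


class TestPrecisionWeights:
    def test_homoskedastic_weights_flat(self, design24):
        rng = np.random.default_rng(3)
        y = rng.normal(8.0, 1.0, size=(500, 24))
        w, _ = M.precision_weights(y, design24)
        assert np.std(w) / np.mean(w) < 0.2

    def test_nb_like_weights_increase_with_mean(self, design24):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(5), np.log(500), size=800))
        counts = rng.negative_binomial(5, 5 / (5 + mu[:, None]), size=(800, 24))
        lib = np.maximum(counts.sum(axis=0), 1)
        y = M.log_cpm(counts, lib)
        w, _ = M.precision_weights(y, design24, lib)
        lo = w[mu < np.quantile(mu, 0.2)].mean()
        hi = w[mu > np.quantile(mu, 0.8)].mean()
        assert hi > lo

    def test_single_window_uniform_fallback(self, design24):
        y = np.random.default_rng(5).normal(size=(1, 24))
        w, _ = M.precision_weights(y, design24)
        np.testing.assert_array_equal(w, 1.0)


class TestSampleQualityWeights:
    def test_iid_samples_near_one(self, design24):
        rng = np.random.default_rng(6)
        y = rng.normal(0.0, 1.0, size=(600, 24))
        w = M.sample_quality_weights(y, design24)
        assert np.all(np.abs(w - 1.0) < 0.15)

    def test_noisy_sample_downweighted(self, design24):
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.0, size=(600, 24))
        y[:, 5] += rng.normal(0.0, 4.0, size=600)
        w = M.sample_quality_weights(y, design24)
        assert w[5] < 0.5 * np.median(w)

    def test_geometric_mean_constraint(self, design24):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(100, 24)) * rng.uniform(0.5, 2.0, size=24)
        w = M.sample_quality_weights(y, design24)
        assert np.exp(np.mean(np.log(w))) == pytest.approx(1.0, abs=1e-10)


class TestFitWindowModel:
    def test_matches_dense_normal_equations(self, design24):
        rng = np.random.default_rng(9)
        y = rng.normal(size=24)
        w = rng.uniform(0.5, 2.0, size=24)
        fit = M.fit_window_model(y, w, design24)
        X = design24
        beta_oracle = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ np.diag(w) @ y)
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-8)
        resid = y - X @ beta_oracle
        s2 = (w * resid**2).sum() / (24 - 4)
        se_oracle = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ np.diag(w) @ X)))
        np.testing.assert_allclose(fit.se, se_oracle, atol=1e-8)

    def test_equal_weights_reduce_to_ols(self, design24):
        rng = np.random.default_rng(10)
        y = rng.normal(size=24)
        fit_w = M.fit_window_model(y, np.full(24, 3.7), design24)
        beta_ols = np.linalg.lstsq(design24, y, rcond=None)[0]
        np.testing.assert_allclose(fit_w.beta, beta_ols, atol=1e-10)

    def test_saturated_fit_flagged(self):
        samples = make_samples(1)  # 4 samples = 4 coefficients, df = 0
        X = M.build_design(samples)
        fit = M.fit_window_model(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4), X)
        assert not fit.ok

    def test_interaction_p_symmetric_under_condition_swap(self, design24):
        rng = np.random.default_rng(11)
        y = rng.normal(size=24)
        w = rng.uniform(0.5, 2.0, size=24)
        swapped = design24[:, [0, 1, 3, 2]]
        f1 = M.fit_window_model(y, w, design24)
        f2 = M.fit_window_model(y, w, swapped)
        assert f1.p_int == pytest.approx(f2.p_int, rel=1e-10)
        assert f1.beta[2] == pytest.approx(f2.beta[3], abs=1e-10)


class TestModeration:
    def test_equal_variances_unchanged(self, design24):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(50, 24))
        fits = M.fit_windows(y, np.ones_like(y), design24)
        fits.sigma2 = np.full(50, 2.0)
        M.moderate_variances(fits)
        np.testing.assert_allclose(fits.sigma2_post, 2.0, atol=1e-8)

    def test_shrinkage_pulls_toward_pool(self, design24):
        rng = np.random.default_rng(13)
        sig = rng.uniform(0.5, 2.0, size=400)
        y = rng.normal(size=(400, 24)) * sig[:, None]
        fits = M.fit_windows(y, np.ones_like(y), design24)
        raw = fits.sigma2.copy()
        M.moderate_variances(fits)
        assert fits.df_prior > 0
        d0, df = fits.df_prior, fits.df_resid
        # recover the prior variance the shrinkage used; every moderated
        # value must lie between its raw value and that prior
        s20 = (fits.sigma2_post[0] * (d0 + df) - df * raw[0]) / d0
        assert np.all(np.abs(fits.sigma2_post - s20) <= np.abs(raw - s20) + 1e-9)
        between = (fits.sigma2_post - raw) * (s20 - raw) >= -1e-9
        assert between.all()


class TestActivityPvalue:
    def _fits(self, betas, p_unmeth, p_meth):
        n = len(betas)
        f = M.ModelFits(
            beta=np.array(betas, float),
            unscaled_cov=np.tile(np.eye(4), (n, 1, 1)),
            sigma2=np.ones(n),
            df_resid=20,
            ok=np.ones(n, bool),
        )
        f.p_unmeth = np.array(p_unmeth, float)
        f.p_meth = np.array(p_meth, float)
        f.p_int = np.ones(n)
        return f

    def test_rule_application(self):
        fits = self._fits(
            betas=[[0, 0, 1.0, -1.0], [0, 0, -1.0, -1.0], [0, 0, 0.5, 0.5]],
            p_unmeth=[0.001, 0.001, 0.03],
            p_meth=[0.5, 0.001, 0.01],
        )
        p_act = M.activity_pvalue(fits)
        assert p_act[0] == pytest.approx(0.001)  # only b2 positive
        assert p_act[1] == 1.0  # neither positive: excluded
        assert p_act[2] == pytest.approx(0.01)  # min over both positive
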