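"""Generative model, negative-binomial marginal and closed-form inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gpcircuit import (
    Dataset,
    GammaPoissonParams,
    class_posterior,
    class_posterior_batch,
    joint_posterior,
    log_marginal_likelihood,
    nb_log_pmf,
    posterior_mean_intensity,
    sample_dataset,
)
from _oracles import grid_posterior


class TestParamsValidation:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GammaPoissonParams(W=[[0.5, 0.4]], alpha=[1.0], beta=[1.0])

    def test_create_renormalizes(self):
        p = GammaPoissonParams.create(W=[[3.0, 1.0]], alpha=[1.0], beta=[1.0])
        np.testing.assert_allclose(p.W, [[0.75, 0.25]])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            GammaPoissonParams(W=[[1.2, -0.2]], alpha=[1.0], beta=[1.0])
        with pytest.raises(ValueError):
            GammaPoissonParams(W=[[1.0]], alpha=[-1.0], beta=[1.0])

    def test_default_prior_uniform(self, two_class_params):
        np.testing.assert_allclose(two_class_params.prior, [0.5, 0.5])

    def test_lambda_is_mean_intensity(self):
        p = GammaPoissonParams(W=[[1.0]], alpha=[4.0], beta=[2.0])
        assert p.lam[0] == pytest.approx(2.0)


class TestSampling:
    def test_zero_weight_dimension_stays_zero(self):
        p = GammaPoissonParams(W=[[1.0, 0.0]], alpha=[4.0], beta=[2.0])
        d = sample_dataset(p, 100, seed=0)
        assert np.all(d.Y[:, 1] == 0)
        assert np.all(d.Y >= 0)
        assert np.issubdtype(d.Y.dtype, np.integer)

    def test_brightness_moments_match_negative_binomial(self):
        # yhat ~ NB with mean alpha/beta = 2 and variance alpha(beta+1)/beta^2 = 3
        p = GammaPoissonParams(W=[[0.6, 0.4]], alpha=[4.0], beta=[2.0])
        d = sample_dataset(p, 10_000, seed=1)
        b = d.brightness
        se_mean = np.sqrt(3.0 / 10_000)
        assert abs(b.mean() - 2.0) < 3 * se_mean
        assert abs(b.var() - 3.0) < 0.15

    def test_reproducible_given_seed(self, two_class_params):
        d1 = sample_dataset(two_class_params, 50, seed=9)
        d2 = sample_dataset(two_class_params, 50, seed=9)
        np.testing.assert_array_equal(d1.Y, d2.Y)
        np.testing.assert_array_equal(d1.true_c, d2.true_c)

    def test_invalid_arguments(self, two_class_params):
        with pytest.raises(ValueError):
            sample_dataset(two_class_params, 0, seed=0)
        with pytest.raises(ValueError):
            GammaPoissonParams(W=[[1.0]], alpha=[1.0], beta=[1.0], prior=[0.0])


class TestNegativeBinomial:
    def test_zero_count_closed_form(self):
        # P(0) = (beta/(beta+1))^alpha
        assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_normalizes_over_support(self):
        k = np.arange(501)
        total = np.exp(nb_log_pmf(k, 2.0, 3.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("alpha,beta", [(2.0, 3.0), (5.0, 0.7), (0.5, 1.5)])
    def test_matches_scipy_parameterization(self, alpha, beta):
        # NB(k; alpha, 1/(beta+1)) == scipy nbinom(n=alpha, p=beta/(beta+1))
        k = np.arange(0, 60)
        expected = stats.nbinom.logpmf(k, alpha, beta / (beta + 1.0))
        np.testing.assert_allclose(nb_log_pmf(k, alpha, beta), expected, atol=1e-12)

    def test_matches_gamma_poisson_sampling(self):
        # marginal of the two-stage draw z~Gamma, k~Poisson(z)
        rng = np.random.default_rng(3)
        n = 400_000
        z = rng.gamma(2.0, 1.0 / 0.5, size=n)
        k = rng.poisson(z)
        freq = np.mean(k == 3)
        prob = np.exp(nb_log_pmf(3, 2.0, 0.5))
        assert abs(freq - prob) < 4 * np.sqrt(prob * (1 - prob) / n)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, 1.0)


class TestJointPosterior:
    def test_single_class_is_conjugate(self):
        p = GammaPoissonParams(W=[[0.5, 0.5]], alpha=[2.0], beta=[1.0])
        post = joint_posterior([3, 1], p)
        np.testing.assert_allclose(post.s, [1.0])
        assert post.z_shape[0] == pytest.approx(2.0 + 4.0)
        assert post.z_rate[0] == pytest.approx(2.0)
        assert post.z_mean == pytest.approx(3.0)

    def test_identical_classes_symmetric(self):
        W = [[0.3, 0.7], [0.3, 0.7]]
        p = GammaPoissonParams(W=W, alpha=[2.0, 2.0], beta=[1.0, 1.0])
        np.testing.assert_allclose(class_posterior([5, 2], p), [0.5, 0.5], atol=1e-12)

    def test_matches_grid_quadrature(self, rng):
        for _ in range(10):
            C = int(rng.integers(2, 5))
            D = int(rng.integers(2, 11))
            p = GammaPoissonParams.create(
                W=rng.dirichlet(np.ones(D), size=C),
                alpha=rng.uniform(1.0, 8.0, C),
                beta=rng.uniform(0.2, 2.0, C),
                prior=rng.dirichlet(np.ones(C)),
            )
            y = rng.poisson(3.0, size=D).astype(float)
            s_grid, z_grid = grid_posterior(y, p)
            post = joint_posterior(y, p)
            np.testing.assert_allclose(post.s, s_grid, atol=1e-6)
            assert post.z_mean == pytest.approx(z_grid, rel=1e-6)

    def test_shape_blind_case_reduces_to_nb_terms(self):
        # identical W rows: posterior determined by the NB brightness terms
        W = np.tile([[0.2, 0.8]], (2, 1))
        p = GammaPoissonParams(W=W, alpha=[2.0, 8.0], beta=[1.0, 0.5])
        y = np.array([4.0, 6.0])
        log_nb = nb_log_pmf(10.0, p.alpha, p.beta)
        expected = np.exp(log_nb - log_nb.max())
        expected /= expected.sum()
        np.testing.assert_allclose(class_posterior(y, p), expected, atol=1e-12)

    def test_brightness_blind_case_hand_computed(self):
        # equal intensity statistics: only the shape term is left, and for
        # y=[3,0] the weights are 0.9^3 vs 0.1^3
        p = GammaPoissonParams(W=[[0.9, 0.1], [0.1, 0.9]],
                               alpha=[4.0, 4.0], beta=[2.0, 2.0])
        s = class_posterior([3, 0], p)
        np.testing.assert_allclose(s, [0.729 / 0.730, 0.001 / 0.730], atol=1e-5)

    def test_dimension_mismatch_raises(self, two_class_params):
        with pytest.raises(ValueError):
            class_posterior([1.0, 2.0], two_class_params)

    def test_zero_weight_pixel_never_nan(self):
        p = GammaPoissonParams.create(W=[[1.0, 0.0], [0.5, 0.5]],
                                      alpha=[2.0, 2.0], beta=[1.0, 1.0])
        s = class_posterior([2, 3], p)
        assert np.all(np.isfinite(s))
        assert s[1] > s[0]  # class 1 cannot explain energy in dimension 2

    @given(st.lists(st.integers(0, 40), min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_posterior_on_simplex(self, counts):
        p = GammaPoissonParams.create(
            W=[[1, 2, 3, 4, 5], [5, 4, 3, 2, 1], [1, 1, 1, 1, 1.0]],
            alpha=[2.0, 4.0, 8.0], beta=[1.0, 0.5, 0.25])
        s = class_posterior(np.array(counts, dtype=float), p)
        assert abs(s.sum() - 1.0) < 1e-12
        assert np.all(s >= 0)

    def test_finite_at_extreme_brightness(self, two_class_params):
        y = np.full(5, 2e5)  # yhat = 1e6
        post = joint_posterior(y, two_class_params)
        assert np.all(np.isfinite(post.s))
        assert np.isfinite(post.z_mean)


class TestIntensityEstimate:
    def test_single_class_posterior_mean(self):
        p = GammaPoissonParams(W=[[1.0]], alpha=[2.0], beta=[1.0])
        assert posterior_mean_intensity([4], p) == pytest.approx(3.0)

    def test_one_hot_limit(self):
        # extreme shape evidence makes the mixture collapse onto one class
        p = GammaPoissonParams.create(W=[[1.0, 1e-12], [1e-12, 1.0]],
                                      alpha=[2.0, 5.0], beta=[1.0, 1.0])
        val = posterior_mean_intensity([7, 0], p)
        assert val == pytest.approx((2.0 + 7.0) / 2.0, rel=1e-6)


class TestLogMarginal:
    def test_collapses_to_nb_for_one_dimension(self):
        p = GammaPoissonParams(W=[[1.0]], alpha=[3.0], beta=[0.7])
        for k in (0, 2, 17):
            got = log_marginal_likelihood(np.array([[k]]), p)
            assert got == pytest.approx(nb_log_pmf(k, 3.0, 0.7), abs=1e-12)

    def test_invariant_under_class_relabeling(self, rng):
        W = rng.dirichlet(np.ones(4), size=3)
        p = GammaPoissonParams(W=W, alpha=[2.0, 4.0, 6.0], beta=[1.0, 0.5, 0.3],
                               prior=[0.5, 0.3, 0.2])
        perm = [2, 0, 1]
        p2 = GammaPoissonParams(W=W[perm], alpha=p.alpha[perm],
                                beta=p.beta[perm], prior=p.prior[perm])
        d = sample_dataset(p, 50, seed=5)
        assert log_marginal_likelihood(d, p) == pytest.approx(
            log_marginal_likelihood(d, p2), abs=1e-9)

    def test_sampling_inference_consistency(self, rect_params, rect_data):
        # the true class assignment collects more posterior mass than any
        # relabeling of classes
        S = class_posterior_batch(rect_data.Y, rect_params)
        true_mass = np.mean(S[np.arange(rect_data.n), rect_data.true_c - 1])
        from itertools import permutations
        for perm in permutations(range(3)):
            if perm == (0, 1, 2):
                continue
            mass = np.mean(S[np.arange(rect_data.n),
                             np.asarray(perm)[rect_data.true_c - 1]])
            assert true_mass > mass


class TestDatasetContainer:
    def test_brightness_is_row_sum(self, rng):
        Y = rng.poisson(3.0, size=(10, 4))
        d = Dataset(Y=Y)
        np.testing.assert_allclose(d.brightness, Y.sum(axis=1))

    def test_misaligned_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            Dataset(Y=rng.poisson(3.0, size=(10, 4)), labels=np.ones(9, dtype=int))
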