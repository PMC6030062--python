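"""Synthetic generators and preprocessing transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcircuit import (
    DEFAULT_V,
    PreprocConfig,
    TrimConfig,
    batch_em,
    brighten_class_dependent,
    brighten_preserving,
    build_sentence,
    make_rectangle_classes,
    make_synthetic_digits,
    make_synthetic_logatomes,
    normalize_shape_only,
    sample_dataset,
    to_counts,
    trim_spectrogram,
)
from _oracles import align_params_to_truth


class TestRectangleClasses:
    def test_box_indicator_normalized(self):
        p = make_rectangle_classes(1, 5, [2], seed=0)
        W = p.W[0].reshape(5, 5)
        on = W[W > 1e-6]
        assert len(on) == 4
        np.testing.assert_allclose(on, 0.25)

    def test_rows_sum_to_one(self):
        p = make_rectangle_classes(3, 6, [2, 3, 4], seed=1)
        np.testing.assert_allclose(p.W.sum(axis=1), 1.0, atol=1e-12)

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError):
            make_rectangle_classes(1, 4, [5], seed=0)

    def test_em_recovers_box_supports(self, rect_params, rect_data):
        em, _ = batch_em(rect_data, 3, n_iter=100, seed=0)
        perm = align_params_to_truth(em.lam, rect_params.lam)
        for c in range(3):
            true_support = rect_params.W[c] > 1e-6
            est = em.W[perm[c]]
            assert np.all(est[true_support] > 0.01)
            assert np.all(est[~true_support] < 0.01)


class TestShapeNormalization:
    def test_uniform_image_analytic(self):
        cfg = PreprocConfig(A=8.0, D=4)
        out = normalize_shape_only(np.ones(4), cfg)
        np.testing.assert_allclose(out, 2.0)
        assert out.sum() == pytest.approx(8.0)

    def test_standard_constants_sum(self, rng):
        cfg = PreprocConfig(A=500.0, D=400)
        raw = rng.uniform(0, 1, size=400)
        assert normalize_shape_only(raw, cfg).sum() == pytest.approx(500.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        cfg = PreprocConfig(A=500.0, D=400)
        raw = rng.uniform(0, 1, size=400)
        np.testing.assert_allclose(normalize_shape_only(raw, cfg),
                                   normalize_shape_only(37.5 * raw, cfg), atol=1e-9)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_shape_only(np.zeros(400), PreprocConfig())

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_mass_and_floor_invariants(self, seed):
        rng = np.random.default_rng(seed)
        cfg = PreprocConfig(A=500.0, D=400)
        raw = rng.uniform(0, 1, size=400) * rng.uniform(0.1, 100)
        out = normalize_shape_only(raw, cfg)
        assert out.sum() == pytest.approx(500.0, abs=1e-8)
        assert np.all(out >= 1.0)


class TestBrightening:
    def test_brightness_factors(self):
        cfg = PreprocConfig(A=8.0, D=4)
        raw = np.array([[25.0] * 4, [75.0] * 4])
        out = brighten_preserving(raw, cfg)
        # f = [0.5, 1.5]; foreground mass (A-D)*f on top of the unit background
        np.testing.assert_allclose(out.sum(axis=1), [4 + 4 * 0.5, 4 + 4 * 1.5])

    def test_background_floor_preserved(self, rng):
        cfg = PreprocConfig(A=450.0, D=400)
        raw = rng.uniform(0, 1, size=(20, 400))
        assert np.all(brighten_preserving(raw, cfg) >= 1.0 - 1e-12)

    def test_rank_order_of_brightness_conserved(self, rng):
        cfg = PreprocConfig(A=450.0, D=400)
        raw = rng.uniform(0, 1, size=(30, 400))
        out = brighten_preserving(raw, cfg)
        assert np.array_equal(np.argsort(raw.sum(axis=1)), np.argsort(out.sum(axis=1)))

    def test_single_image_batch_allowed(self, rng):
        cfg = PreprocConfig(A=450.0, D=400)
        raw = rng.uniform(0.1, 1, size=(1, 400))
        out = brighten_preserving(raw, cfg)
        assert out.sum() == pytest.approx(450.0, abs=1e-9)  # f = 1

    def test_class_dependent_pixel_arithmetic(self):
        # a pixel with normalized value 3, f = 1, v = 2.3 maps to (3-1)(1+2.3)+1
        cfg = PreprocConfig(A=8.0, D=4, v=np.array([2.3]))
        raw = np.array([[2.0, 1.0, 1.0, 0.0]])  # y_SA = [3, 2, 2, 1]
        out = brighten_class_dependent(raw, np.array([1]), cfg)
        assert out[0, 0] == pytest.approx((3 - 1) * (1 + 2.3) + 1)
        assert out[0, 3] == pytest.approx(1.0)  # background pixel stays 1

    def test_balanced_batch_mean_brightness(self, rng):
        # mean total = D + (A-D) * (mean f + mean v) = 400 + 50*(1+5.01)
        cfg = PreprocConfig(A=450.0, D=400)
        raw, labels = make_synthetic_digits(200, 10, 20, seed=0)
        out = brighten_class_dependent(raw, labels, cfg)
        assert out.sum(axis=1).mean() == pytest.approx(700.5, rel=0.01)

    def test_label_out_of_range(self, rng):
        cfg = PreprocConfig(A=450.0, D=400)
        raw = rng.uniform(0.1, 1, size=(2, 400))
        with pytest.raises(ValueError):
            brighten_class_dependent(raw, np.array([1, 11]), cfg)


class TestTrimming:
    def test_concentrated_energy_kept(self):
        spec = np.zeros((4, 400))
        spec[:, 200] = 1.0
        res = trim_spectrogram(spec, TrimConfig(n_mel=4))
        assert res.kept
        assert res.data.shape == (4, 101)
        assert res.energy_fraction == pytest.approx(1.0)

    def test_edge_utterance_discarded(self):
        spec = np.zeros((4, 400))
        spec[:, 30] = 1.0
        res = trim_spectrogram(spec, TrimConfig(n_mel=4))
        assert not res.kept
        assert res.reason == "edge"

    def test_diffuse_energy_discarded(self):
        spec = np.ones((4, 400))
        res = trim_spectrogram(spec, TrimConfig(n_mel=4))
        assert not res.kept
        assert res.reason == "energy"
        assert res.energy_fraction == pytest.approx(101 / 400)

    def test_short_recording_uses_all_columns(self):
        spec = np.zeros((4, 15))
        spec[:, 7] = 1.0
        res = trim_spectrogram(spec, TrimConfig(n_mel=4, half_width=3))
        assert res.kept
        assert res.data.shape == (4, 7)

    def test_com_tie_rounds_to_earlier_column(self):
        # energy split evenly between columns 100 and 101 -> COM 100.5 -> 100
        spec = np.zeros((2, 400))
        spec[:, 100] = spec[:, 101] = 1.0
        res = trim_spectrogram(spec, TrimConfig(n_mel=2, n_top_bins=2))
        assert res.kept
        np.testing.assert_allclose(res.data[:, 50], 1.0)  # column 100 centered


class TestLogatomes:
    def test_near_deterministic_intensity_limit(self):
        # at huge Gamma shape the intensity is effectively fixed, so the only
        # remaining brightness spread is the Poisson counting noise
        # (variance ~ mean); the default shape leaves a much wider spread
        trim = TrimConfig(n_mel=8, half_width=5)
        tight, _ = make_synthetic_logatomes(2, 200, seed=0, cfg=trim, alpha=1e6)
        loose, _ = make_synthetic_logatomes(2, 200, seed=0, cfg=trim, alpha=30.0)
        for c in (1, 2):
            b = tight.brightness[tight.true_c == c]
            fano = b.var() / b.mean()
            assert fano < 1.5  # Poisson-limited
            bl = loose.brightness[loose.true_c == c]
            assert bl.var() / bl.mean() > 5.0  # Gamma-dominated

    def test_class_mean_brightness_matches_excitability(self):
        trim = TrimConfig(n_mel=8, half_width=5)
        data, params = make_synthetic_logatomes(4, 125, seed=1, cfg=trim)
        for c in range(4):
            b = data.brightness[data.true_c == c + 1]
            assert b.mean() == pytest.approx(params.lam[c], rel=0.02)

    def test_end_to_end_circuit_recovery(self):
        from gpcircuit import LearningConfig, train
        from gpcircuit.circuit import responsibilities
        from _oracles import best_permutation_match
        trim = TrimConfig(n_mel=16, half_width=10)
        data, params = make_synthetic_logatomes(4, 60, seed=1, cfg=trim)
        cfg = LearningConfig(eps_W=5e-5, eps_lambda=1e-2, eps_V=1e-2,
                             epochs=20, seed=0,
                             init_mode="mean_plus_poisson_noise",
                             lambda_init="brightness_quantiles")
        state, _ = train(data, 4, cfg)
        hard = responsibilities(data.Y, state).argmax(axis=1)
        acc, _ = best_permutation_match(hard, data.true_c, 4)
        assert acc >= 0.9


@pytest.fixture(scope="module")
def utterance_pool():
    trim = TrimConfig(n_mel=8, half_width=5)
    data, _ = make_synthetic_logatomes(4, 10, seed=2, cfg=trim)
    return data


class TestSentenceAssembly:
    def test_class_coverage_constraint(self, utterance_pool):
        s = build_sentence(utterance_pool, 10, seed=0)
        counts = np.bincount(s.true_c, minlength=5)[1:]
        assert counts.sum() == 10
        assert np.all(counts >= 2)

    def test_reproducible(self, utterance_pool):
        s1 = build_sentence(utterance_pool, 10, seed=5)
        s2 = build_sentence(utterance_pool, 10, seed=5)
        np.testing.assert_array_equal(s1.Y, s2.Y)

    def test_exact_pigeonhole(self, utterance_pool):
        s = build_sentence(utterance_pool, 8, seed=0)
        counts = np.bincount(s.true_c, minlength=5)[1:]
        np.testing.assert_array_equal(counts, [2, 2, 2, 2])

    def test_unsatisfiable_constraint_rejected(self, utterance_pool):
        with pytest.raises(ValueError):
            build_sentence(utterance_pool, 7, seed=0)


class TestCounts:
    def test_rounding_and_gain(self):
        out = to_counts(np.array([[0.4, 1.6], [2.5, 0.0]]), gain=2.0)
        np.testing.assert_array_equal(out, [[1, 3], [5, 0]])
        assert np.issubdtype(out.dtype, np.integer)
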