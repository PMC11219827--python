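"""Augmentation operators (noise, shift, combination) and recipe arithmetic."""

import numpy as np
import pytest

import ramandx as rx
from ramandx.augment import BookkeepingError, ConstraintError
from ramandx.core import ParameterError


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


class TestNoise:
    def test_zero_level_is_identity(self, rng):
        x = rng.standard_normal(100)
        out = rx.add_noise(x, rx.NoiseSpec(0.0, 1.0), rng)
        np.testing.assert_array_equal(out, x)

    def test_uniform_bound_and_support(self, rng):
        """k=5, I_max=1: |delta| <= 0.05 and the band is actually filled."""
        x = np.zeros(100_000)
        out = rx.add_noise(x, rx.NoiseSpec(5.0, 1.0), rng)
        assert np.max(np.abs(out)) <= 0.05
        assert np.max(np.abs(out)) >= 0.049

    def test_extended_test_maximum_level(self, rng):
        x = np.zeros(50_000)
        out = rx.add_noise(x, rx.NoiseSpec(12.5, 2.0), rng)
        assert np.max(np.abs(out)) <= 0.125 * 2.0
        assert np.max(np.abs(out)) >= 0.9 * 0.125 * 2.0

    def test_zero_mean(self, rng):
        n = 1_000_000
        amp = 0.05
        out = rx.add_noise(np.zeros(n), rx.NoiseSpec(5.0, 1.0), rng)
        assert abs(out.mean()) < 3 * amp / np.sqrt(3 * n)

    def test_negative_level_rejected(self):
        with pytest.raises(ParameterError):
            rx.NoiseSpec(-1.0, 1.0)

    def test_reference_is_global_training_maximum(self, axis):
        X = np.ones((4, axis.n_points))
        X[2, 100] = 7.5
        ds = rx.LabeledSpectrumSet(axis, X, [0, 0, 1, 1])
        assert rx.training_i_max(ds) == 7.5


class TestShift:
    def test_zero_shift_identity(self):
        x = np.random.default_rng(0).standard_normal(50)
        np.testing.assert_array_equal(rx.shift_spectrum(x, rx.ShiftSpec(0)), x)

    def test_impulse_translation(self):
        x = np.zeros(619)
        x[300] = 1.0
        out = rx.shift_spectrum(x, rx.ShiftSpec(2))
        assert out[302] == 1.0
        assert out.sum() == 1.0

    def test_edge_replication(self):
        x = np.arange(10.0)
        out = rx.shift_spectrum(x, rx.ShiftSpec(3))
        np.testing.assert_array_equal(out[:4], [0, 0, 0, 0])
        out = rx.shift_spectrum(x, rx.ShiftSpec(-3))
        np.testing.assert_array_equal(out[-4:], [9, 9, 9, 9])

    def test_forward_backward_composition(self):
        x = np.random.default_rng(1).standard_normal(80)
        back = rx.shift_spectrum(rx.shift_spectrum(x, rx.ShiftSpec(3)), rx.ShiftSpec(-3))
        np.testing.assert_allclose(back[3:-3], x[3:-3])

    def test_too_large_shift_rejected(self):
        with pytest.raises(ParameterError):
            rx.shift_spectrum(np.ones(10), rx.ShiftSpec(10))


class TestCombine:
    def test_endpoint_ratios(self, rng):
        x1 = rng.standard_normal(30)
        x2 = rng.standard_normal(30)
        np.testing.assert_array_equal(
            rx.combine_spectra(x1, x2, 1, 1, rx.CombineSpec(r=1.0)), x1
        )
        np.testing.assert_array_equal(
            rx.combine_spectra(x1, x2, 1, 1, rx.CombineSpec(r=0.0)), x2
        )

    def test_self_combination_fixed_point(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_allclose(
            rx.combine_spectra(x, x, 0, 0, rx.CombineSpec(r=0.5)), x
        )

    def test_cross_class_rejected(self, rng):
        with pytest.raises(ConstraintError):
            rx.combine_spectra(np.ones(5), np.ones(5), 0, 1, rx.CombineSpec(r=0.5))


def _train_set(n0, n1, axis, seed=0):
    rng = np.random.default_rng(seed)
    X = np.abs(rng.standard_normal((n0 + n1, axis.n_points))) + 0.5
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    return rx.LabeledSpectrumSet(axis, X, y)


class TestRecipeBookkeeping:
    def test_default_recipe_arithmetic(self):
        recipe = rx.AugmentationRecipe()
        assert recipe.expected_count(512) == 14_608

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(), 14_608),
            (dict(include_originals=False), 14_096),
            (dict(gan_count_per_class=0), 4_608),
            (dict(gan_count_per_class=0, include_originals=False), 4_096),
        ],
    )
    def test_published_count_variants(self, kwargs, expected):
        assert rx.AugmentationRecipe(**kwargs).expected_count(512) == expected

    def test_build_counts_and_provenance(self, axis):
        train = _train_set(274, 238, axis)
        recipe = rx.AugmentationRecipe(gan_count_per_class=100)
        gan = rx.LabeledSpectrumSet(
            axis,
            np.ones((200, axis.n_points)),
            np.array([0] * 100 + [1] * 100),
            provenance=np.full(200, "gan", dtype=object),
        )
        out = rx.build_augmented_training_set(train, recipe, gan, seed=0)
        assert out.n == recipe.expected_count(512) == 4_808
        tags, counts = np.unique(out.provenance.astype(str), return_counts=True)
        got = dict(zip(tags, counts))
        assert got == {
            "original": 512, "noise": 512, "shift": 512 * 6, "combo": 512, "gan": 200
        }

    def test_per_class_arithmetic_preserved(self, axis):
        train = _train_set(30, 20, axis)
        recipe = rx.AugmentationRecipe(gan_count_per_class=10)
        gan = rx.LabeledSpectrumSet(
            axis, np.ones((20, axis.n_points)), np.array([0] * 10 + [1] * 10),
            provenance=np.full(20, "gan", dtype=object),
        )
        out = rx.build_augmented_training_set(train, recipe, gan, seed=1)
        # per class: originals + noise + 6 shifts + combos (proportional) + gan
        n0, n1 = out.class_counts()
        assert n0 == 30 * 8 + 30 + 10
        assert n1 == 20 * 8 + 20 + 10

    def test_identity_recipe_returns_input(self, axis):
        train = _train_set(5, 5, axis)
        recipe = rx.AugmentationRecipe(
            noise_copies_per_spectrum=0, shift_set=(), combo_copies=0,
            gan_count_per_class=0,
        )
        out = rx.build_augmented_training_set(train, recipe, None, seed=0)
        assert out.n == train.n
        np.testing.assert_array_equal(out.spectra, train.spectra)

    def test_gan_count_mismatch_rejected(self, axis):
        train = _train_set(5, 5, axis)
        recipe = rx.AugmentationRecipe(gan_count_per_class=10)
        bad = rx.LabeledSpectrumSet(
            axis, np.ones((10, axis.n_points)), np.array([0] * 4 + [1] * 6),
            provenance=np.full(10, "gan", dtype=object),
        )
        with pytest.raises(BookkeepingError):
            rx.build_augmented_training_set(train, recipe, bad, seed=0)

    def test_missing_gan_set_rejected(self, axis):
        train = _train_set(5, 5, axis)
        with pytest.raises(BookkeepingError):
            rx.build_augmented_training_set(
                train, rx.AugmentationRecipe(gan_count_per_class=5), None
            )
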