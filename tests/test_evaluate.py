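"""AUC computation, paired Wilcoxon comparison, extended grids and the
repetition harness."""

import numpy as np
import pytest

import ramandx as rx
from ramandx import evaluate
from ramandx.evaluate import DegenerateTestError, Model, UndefinedAUCError


def pair_counting_auc(scores, labels):
    """Independent brute-force oracle: fraction of (positive, negative)
    pairs ordered correctly, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert rx.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert rx.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert rx.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            rx.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        """Trapezoidal ROC area equals Mann-Whitney pair counting exactly
        on 200 random instances (with ties)."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert rx.roc_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        a = np.linspace(0.8, 0.9, 10)
        with pytest.raises(DegenerateTestError):
            rx.paired_wilcoxon(a, a.copy())

    def test_uniform_shift_is_significant(self):
        rng = np.random.default_rng(1)
        a = 0.85 + 0.02 * rng.standard_normal(56)
        b = a + 0.02
        stat, p = rx.paired_wilcoxon(b, a)
        assert p < 0.001

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        a = 0.8 + 0.03 * rng.standard_normal(20)
        b = a + 0.01 * rng.standard_normal(20)
        _, p_ab = rx.paired_wilcoxon(a, b)
        _, p_ba = rx.paired_wilcoxon(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_short_vectors_rejected(self):
        with pytest.raises(Exception):
            rx.paired_wilcoxon([1, 2, 3], [2, 3, 4])


class TestExtendedGrid:
    def test_identity_cell_is_untouched(self, small_clean_cohort):
        grid = rx.ExtendedTestGrid(noise_levels=(0.0,), shifts=(0,))
        cells = rx.build_extended_test(small_clean_cohort, grid, 1.0, seed=0)
        assert list(cells) == [(0.0, 0)]
        assert cells[(0.0, 0)] is small_clean_cohort

    def test_noise_cell_bound(self, small_clean_cohort):
        i_max = rx.training_i_max(small_clean_cohort)
        grid = rx.ExtendedTestGrid(noise_levels=(0.0, 12.5), shifts=(0,))
        cells = rx.build_extended_test(small_clean_cohort, grid, i_max, seed=0)
        delta = cells[(12.5, 0)].spectra - small_clean_cohort.spectra
        assert np.max(np.abs(delta)) <= 0.125 * i_max

    def test_opposite_shifts_differ(self, small_clean_cohort):
        grid = rx.ExtendedTestGrid(noise_levels=(0.0,), shifts=(-3, 3))
        cells = rx.build_extended_test(small_clean_cohort, grid, 1.0, seed=0)
        assert not np.allclose(cells[(0.0, 3)].spectra, cells[(0.0, -3)].spectra)

    def test_shift_cells_are_noiseless_translations(self, small_clean_cohort):
        grid = rx.ExtendedTestGrid(noise_levels=(0.0,), shifts=(2,))
        cells = rx.build_extended_test(small_clean_cohort, grid, 1.0, seed=0)
        np.testing.assert_array_equal(
            cells[(0.0, 2)].spectra[:, 5:],
            small_clean_cohort.spectra[:, 3:-2],
        )


def constant_scorer(value=0.5):
    return Model(
        "const",
        fit=lambda train, val, seed: None,
        score=lambda state, ds: np.full(ds.n, value),
    )


def mean_intensity_scorer():
    """Cheap deterministic model: score = correlation with the training
    cancer-minus-benign mean difference."""

    def fit(train, val, seed):
        d = train.spectra[train.labels == 1].mean(0) - train.spectra[
            train.labels == 0
        ].mean(0)
        return d

    return Model("meandiff", fit=fit, score=lambda d, ds: ds.spectra @ d)


class TestHarness:
    def test_constant_scorer_gives_half_everywhere(self, small_clean_cohort):
        res = rx.run_repetitions(small_clean_cohort, [constant_scorer()], R=2)
        for subset in ("train", "val", "test"):
            np.testing.assert_allclose(res.auc["const"][subset], 0.5)

    def test_split_sizes_for_clinical_cohort_shape(self):
        cfg = rx.SyntheticCohortConfig(seed=8)
        cohort = rx.generate_cohort(cfg)
        res = rx.run_repetitions(cohort, [constant_scorer()], R=2, base_seed=3)
        assert res.split_sizes == [(512, 73, 146)] * 2

    def test_deterministic_under_base_seed(self, small_clean_cohort):
        m = mean_intensity_scorer()
        a = rx.run_repetitions(small_clean_cohort, [m], R=3, base_seed=7)
        b = rx.run_repetitions(small_clean_cohort, [m], R=3, base_seed=7)
        for subset in ("train", "val", "test"):
            np.testing.assert_array_equal(
                a.auc["meandiff"][subset], b.auc["meandiff"][subset]
            )

    def test_model_failure_recorded_not_fatal(self, small_clean_cohort):
        def broken_fit(train, val, seed):
            raise RuntimeError("deliberate")

        broken = Model("broken", fit=broken_fit, score=lambda s, d: None)
        res = rx.run_repetitions(
            small_clean_cohort, [broken, constant_scorer()], R=2
        )
        assert np.all(np.isnan(res.auc["broken"]["test"]))
        assert len(res.errors) == 2
        np.testing.assert_allclose(res.auc["const"]["test"], 0.5)

    def test_summary_mean_equals_arithmetic_mean(self, small_clean_cohort):
        m = mean_intensity_scorer()
        res = rx.run_repetitions(small_clean_cohort, [m], R=4, base_seed=1)
        df = res.summary()
        row = df[(df.model == "meandiff") & (df.subset == "test")].iloc[0]
        assert row.mean_auc == pytest.approx(np.mean(res.auc["meandiff"]["test"]))

    def test_extended_grid_zero_cell_matches_original_test_auc(
        self, small_clean_cohort
    ):
        m = mean_intensity_scorer()
        grid = rx.ExtendedTestGrid(noise_levels=(0.0, 5.0), shifts=(-2, 2))
        res = rx.run_repetitions(
            small_clean_cohort, [m], R=2, base_seed=2, grid=grid
        )
        np.testing.assert_allclose(
            res.extended["meandiff"][(0.0, 0)], res.auc["meandiff"]["test"]
        )
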