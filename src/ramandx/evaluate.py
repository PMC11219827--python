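"""ROC/AUC evaluation harness: repeated stratified splits, train-only
augmentation, extended (corrupted) test grids and paired model comparison.

Each repetition draws a fresh stratified 70/10/20 split of the cohort,
optionally expands the *training* portion with an augmentation recipe
(validation and test are never touched), fits every model on the identical
data, and records train/validation/test ROC AUCs.  AUC is the
Mann-Whitney probability that a random cancer case outscores a random
benign case (ties counted one half), computed as the trapezoidal area
under the empirical ROC curve.

The extended test grid corrupts the original test set with uniform noise
at level ``k`` percent of the training I_max, or with ``m``-pixel shifts
(without noise), probing robustness to degraded spectral quality.
Corrupted spectra are deliberately not re-normalized: the corruption
models instrument degradation downstream of preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import augment, baselines, cnn1d, gan1d
from .core import LabeledSpectrumSet, ParameterError, RamanDXError, stratified_split


class UndefinedAUCError(RamanDXError):
    """AUC requested with a single class present."""


class DegenerateTestError(RamanDXError):
    """Paired test on identical vectors (all differences zero)."""


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC (Mann-Whitney pair-ordering probability, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def paired_wilcoxon(auc_a: np.ndarray, auc_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on per-repetition differences.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 informative pairs, the continuity-corrected normal
    approximation above that.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size != b.size or a.size < 6:
        raise ParameterError("need equal-length paired vectors of length >= 6")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


@dataclass
class Model:
    """fit/score contract shared by the CNN and the chemometric baselines."""

    name: str
    fit: Callable[[LabeledSpectrumSet, LabeledSpectrumSet, int], object]
    score: Callable[[object, LabeledSpectrumSet], np.ndarray]


def cnn_model(cfg: cnn1d.CNNConfig | None = None) -> Model:
    base = cfg or cnn1d.CNNConfig()

    def fit(train, val, seed):
        import dataclasses

        run_cfg = dataclasses.replace(base, seed=seed)
        state, _ = cnn1d.train_cnn(train, val, run_cfg)
        return state

    return Model("1d-cnn", fit, cnn1d.predict_scores)


def baseline_model(method: str, cfg: baselines.BaselineConfig | None = None) -> Model:
    def fit(train, val, seed):
        return baselines.fit_baseline(method, train, val, cfg)

    return Model(method, fit, baselines.score_baseline)


def default_models(
    include: tuple[str, ...] = ("1d-cnn", "plsda", "pclda", "svm", "lr"),
    cnn_cfg: cnn1d.CNNConfig | None = None,
    baseline_cfg: baselines.BaselineConfig | None = None,
) -> list[Model]:
    out = []
    for name in include:
        if name == "1d-cnn":
            out.append(cnn_model(cnn_cfg))
        elif name in baselines.METHODS:
            out.append(baseline_model(name, baseline_cfg))
        else:
            raise ParameterError(f"unknown model {name!r}")
    return out


# ---------------------------------------------------------------------------
# extended test grid
# ---------------------------------------------------------------------------


@dataclass
class ExtendedTestGrid:
    """Noise levels (percent of training I_max) and pixel shifts probed."""

    noise_levels: tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 7.5, 10.0, 12.5)
    shifts: tuple[int, ...] = tuple(range(-6, 7))

    def cells(self) -> list[tuple[float, int]]:
        """(noise %, shift px) cells: one axis varies at a time, (0,0) first."""
        out = [(0.0, 0)]
        out += [(k, 0) for k in self.noise_levels if k != 0]
        out += [(0.0, m) for m in self.shifts if m != 0]
        return out


def build_extended_test(
    test: LabeledSpectrumSet,
    grid: ExtendedTestGrid,
    i_max: float,
    seed: int = 0,
) -> dict[tuple[float, int], LabeledSpectrumSet]:
    """Corrupted copies of the test set, one per grid cell.

    Noise cells add uniform noise at level ``k`` (relative to the training
    set's ``i_max``); shift cells translate by ``m`` pixels without noise;
    cell (0, 0) is the untouched test set.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[float, int], LabeledSpectrumSet] = {}
    for k, m in grid.cells():
        if k == 0 and m == 0:
            out[(k, m)] = test
        elif m == 0:
            spec = augment.NoiseSpec(k, i_max)
            out[(k, m)] = test.with_spectra(augment.add_noise(test.spectra, spec, rng))
        else:
            out[(k, m)] = test.with_spectra(
                augment.shift_spectrum(test.spectra, augment.ShiftSpec(m))
            )
    return out


# ---------------------------------------------------------------------------
# repetition harness
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """Per-repetition AUCs (and optional extended-grid surfaces) per model."""

    model_names: list[str]
    seeds: list[int]
    #: auc[model][subset] -> array of length R (NaN where a model failed)
    auc: dict[str, dict[str, np.ndarray]]
    #: extended[model][(noise, shift)] -> array of length R
    extended: dict[str, dict[tuple[float, int], np.ndarray]] = field(
        default_factory=dict
    )
    errors: list[str] = field(default_factory=list)
    split_sizes: list[tuple[int, int, int]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean +- SD per model and subset, mirroring a results table."""
        rows = []
        for name in self.model_names:
            for subset in ("train", "val", "test"):
                v = self.auc[name][subset]
                rows.append(
                    {
                        "model": name,
                        "subset": subset,
                        "mean_auc": float(np.nanmean(v)),
                        "sd_auc": float(np.nanstd(v, ddof=1)) if v.size > 1 else 0.0,
                        "n_reps": int(np.sum(np.isfinite(v))),
                    }
                )
        return pd.DataFrame(rows)

    def extended_summary(self) -> pd.DataFrame:
        rows = []
        for name, cells in self.extended.items():
            for (k, m), v in cells.items():
                rows.append(
                    {
                        "model": name,
                        "noise_percent": k,
                        "shift_px": m,
                        "mean_auc": float(np.nanmean(v)),
                    }
                )
        return pd.DataFrame(rows)


def run_repetitions(
    cohort: LabeledSpectrumSet,
    models: list[Model],
    recipe: augment.AugmentationRecipe | None = None,
    R: int = 56,
    base_seed: int = 0,
    gan_config: gan1d.GANConfig | None = None,
    grid: ExtendedTestGrid | None = None,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
) -> EvaluationResult:
    """Repeat split -> (augment) -> fit -> score ``R`` times.

    Repetition ``r`` uses split seed ``base_seed + r``; every model sees
    the identical split (and identical augmented training set).  When the
    recipe requests GAN spectra, a conditional GAN is trained on the
    repetition's training set with ``gan_config`` and sampled to the
    recipe's count.  Model failures are recorded per cell as NaN without
    aborting the harness.
    """
    cohort.require_both_classes()
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ParameterError("model names must be unique")
    result = EvaluationResult(
        names,
        [base_seed + r for r in range(R)],
        {n: {s: np.full(R, np.nan) for s in ("train", "val", "test")} for n in names},
        {n: {} for n in names} if grid is not None else {},
    )
    if grid is not None:
        for n in names:
            result.extended[n] = {c: np.full(R, np.nan) for c in grid.cells()}
    for r in range(R):
        seed = base_seed + r
        scheme = stratified_split(cohort, fractions, seed=seed)
        train, val, test = scheme.apply(cohort)
        result.split_sizes.append(scheme.sizes())
        i_max = augment.training_i_max(train)
        fit_train = train
        if recipe is not None:
            gan_set = None
            if recipe.gan_count_per_class > 0:
                if gan_config is None:
                    raise ParameterError(
                        "recipe requests GAN spectra: pass gan_config"
                    )
                import dataclasses

                g_cfg = dataclasses.replace(gan_config, seed=seed)
                g_state = gan1d.train_gan(train, g_cfg)
                gan_set = gan1d.synthesize_spectra(
                    g_state, recipe.gan_count_per_class, seed=seed
                )
            fit_train = augment.build_augmented_training_set(
                train, recipe, gan_set, seed=seed
            )
        cells = (
            build_extended_test(test, grid, i_max, seed=seed)
            if grid is not None
            else {}
        )
        for model in models:
            try:
                state = model.fit(fit_train, val, seed)
                for subset, ds in (("train", fit_train), ("val", val), ("test", test)):
                    result.auc[model.name][subset][r] = roc_auc(
                        model.score(state, ds), ds.labels
                    )
                for cell, ds in cells.items():
                    result.extended[model.name][cell][r] = roc_auc(
                        model.score(state, ds), ds.labels
                    )
            except Exception as exc:  # noqa: BLE001 - harness must survive
                result.errors.append(f"rep {r} model {model.name}: {exc}")
    return result
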