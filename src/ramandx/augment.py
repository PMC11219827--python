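"""Closed-form training-set augmentation operators and recipe bookkeeping.

Three label-preserving operators expand a training set (and only the
training set; validation and test data are never augmented):

* additive uniform noise ``S'(v) = S(v) + N(v)`` with
  ``N(v) = 2 (rand() - 0.5) * k/100 * I_max``, where ``I_max`` is the
  maximum intensity over the *full training set*, not per spectrum;
* pixel shifting ``S'(v_i) = S(v_{i +- m}) + N(v)``, vacated edge samples
  filled by replicating the terminal value;
* within-class convex combination ``S'(v) = r S1(v) + (1-r) S2(v) + N(v)``
  with ``r ~ U(0, 1)``; spectra from different classes are never combined.

:class:`AugmentationRecipe` bundles the operator parameters and the count
arithmetic: the default recipe (one 5% noise copy, shifts of +-1..3 pixels
with 5% noise, one combination per training spectrum with 5% noise, and
5000 GAN spectra per class) expands 512 training spectra into 14,608.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabeledSpectrumSet, ParameterError, RamanDXError


class ConstraintError(RamanDXError):
    """Cross-class spectrum combination attempted."""


class BookkeepingError(RamanDXError):
    """Augmented-set counts do not match the recipe arithmetic."""


@dataclass
class NoiseSpec:
    """Uniform-noise level ``k`` (percent) relative to ``reference_intensity``."""

    level_percent: float
    reference_intensity: float

    def __post_init__(self) -> None:
        if self.level_percent < 0:
            raise ParameterError("noise level must be >= 0")
        if self.reference_intensity <= 0:
            raise ParameterError("reference intensity must be positive")

    @property
    def amplitude(self) -> float:
        return self.level_percent / 100.0 * self.reference_intensity


@dataclass
class ShiftSpec:
    """Signed pixel shift ``m``."""

    m: int


@dataclass
class CombineSpec:
    """Mixing ratio ``r``; drawn uniformly on [0, 1] when ``None``."""

    r: float | None = None
    same_class_only: bool = True

    def __post_init__(self) -> None:
        if self.r is not None and not 0.0 <= self.r <= 1.0:
            raise ParameterError("mixing ratio r must be in [0, 1]")


def training_i_max(train: LabeledSpectrumSet) -> float:
    """Global maximum intensity of the pre-augmentation training set."""
    return float(train.spectra.max())


def add_noise(
    x: np.ndarray, spec: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. uniform noise on [-a, +a], a = k/100 * I_max, per sample."""
    x = np.asarray(x, dtype=float)
    if spec.level_percent == 0:
        return x.copy()
    return x + 2.0 * (rng.random(x.shape) - 0.5) * spec.amplitude


def shift_spectrum(
    x: np.ndarray,
    spec: ShiftSpec,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Translate by ``m`` pixels (edge replication), then optionally add noise.

    Positive ``m`` moves spectral content toward higher pixel indices:
    ``out[i] = in[i - m]``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    m = int(spec.m)
    if abs(m) >= n:
        raise ParameterError(f"|shift| {abs(m)} must be < spectrum length {n}")
    out = np.empty_like(x)
    if m > 0:
        out[..., m:] = x[..., :-m]
        out[..., :m] = x[..., :1]
    elif m < 0:
        out[..., :m] = x[..., -m:]
        out[..., m:] = x[..., -1:]
    else:
        out[...] = x
    if noise is not None and noise.level_percent > 0:
        if rng is None:
            raise ParameterError("rng required when noise is requested")
        out = add_noise(out, noise, rng)
    return out


def combine_spectra(
    x1: np.ndarray,
    x2: np.ndarray,
    label1: int,
    label2: int,
    spec: CombineSpec,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convex combination of two same-class spectra plus optional noise."""
    if spec.same_class_only and label1 != label2:
        raise ConstraintError("refusing to combine spectra across classes")
    r = spec.r
    if r is None:
        if rng is None:
            raise ParameterError("rng required to draw the mixing ratio")
        r = float(rng.random())
    out = r * np.asarray(x1, dtype=float) + (1.0 - r) * np.asarray(x2, dtype=float)
    if noise is not None and noise.level_percent > 0:
        if rng is None:
            raise ParameterError("rng required when noise is requested")
        out = add_noise(out, noise, rng)
    return out


@dataclass
class AugmentationRecipe:
    """Counts and noise levels of the full augmentation pipeline.

    ``combo_copies=None`` means "as many combinations as training
    spectra".  Expected output size for ``n`` training spectra is
    ``n*include_originals + n*noise_copies + n*len(shift_set)
    + combo_copies + 2*gan_count_per_class``.
    """

    noise_level_percent: float = 5.0
    noise_copies_per_spectrum: int = 1
    shift_set: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
    combo_copies: int | None = None
    gan_count_per_class: int = 5000
    include_originals: bool = True
    #: 5% noise is also applied to shifted and combined spectra
    derived_noise_percent: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_copies_per_spectrum < 0:
            raise ParameterError("noise_copies_per_spectrum must be >= 0")
        if self.gan_count_per_class < 0:
            raise ParameterError("gan_count_per_class must be >= 0")
        if self.combo_copies is not None and self.combo_copies < 0:
            raise ParameterError("combo_copies must be >= 0")

    def expected_count(self, n_train: int) -> int:
        combos = n_train if self.combo_copies is None else self.combo_copies
        return (
            n_train * int(self.include_originals)
            + n_train * self.noise_copies_per_spectrum
            + n_train * len(self.shift_set)
            + combos
            + 2 * self.gan_count_per_class
        )


def _combo_allocation(counts: list[int], total: int) -> list[int]:
    """Largest-remainder allocation of ``total`` combos across classes."""
    n = sum(counts)
    if n == 0 or total == 0:
        return [0] * len(counts)
    exact = [total * c / n for c in counts]
    alloc = [int(np.floor(e)) for e in exact]
    rem = total - sum(alloc)
    order = np.argsort([a - e for a, e in zip(alloc, exact)])
    for i in range(rem):
        alloc[order[i]] += 1
    return alloc


def build_augmented_training_set(
    train: LabeledSpectrumSet,
    recipe: AugmentationRecipe,
    gan_spectra: LabeledSpectrumSet | None = None,
    seed: int = 0,
) -> LabeledSpectrumSet:
    """Expand a training set according to ``recipe``.

    ``gan_spectra`` must hold exactly ``recipe.gan_count_per_class``
    spectra of each class (pass ``None`` when the recipe requests none).
    The output carries per-row provenance tags; the total count matches
    ``recipe.expected_count(train.n)`` exactly.
    """
    rng = np.random.default_rng(seed)
    i_max = training_i_max(train)
    noise = NoiseSpec(recipe.noise_level_percent, i_max)
    derived_noise = NoiseSpec(recipe.derived_noise_percent, i_max)
    parts = []
    if recipe.include_originals:
        parts.append(train)

    def tagged(X: np.ndarray, y: np.ndarray, ids: np.ndarray, tag: str):
        return LabeledSpectrumSet(
            train.axis, X, y, ids, np.full(y.size, tag, dtype=object)
        )

    for _ in range(recipe.noise_copies_per_spectrum):
        parts.append(
            tagged(
                add_noise(train.spectra, noise, rng),
                train.labels,
                train.lesion_ids,
                "noise",
            )
        )
    for m in recipe.shift_set:
        parts.append(
            tagged(
                shift_spectrum(train.spectra, ShiftSpec(m), derived_noise, rng),
                train.labels,
                train.lesion_ids,
                "shift",
            )
        )
    combos = train.n if recipe.combo_copies is None else recipe.combo_copies
    if combos:
        counts = [int(np.sum(train.labels == c)) for c in (0, 1)]
        X_parts, y_parts = [], []
        for cls, n_cls in zip((0, 1), _combo_allocation(counts, combos)):
            if n_cls == 0:
                continue
            members = np.flatnonzero(train.labels == cls)
            if members.size < 1:
                raise BookkeepingError(
                    f"cannot draw combinations for empty class {cls}"
                )
            i1 = rng.choice(members, size=n_cls)
            i2 = rng.choice(members, size=n_cls)
            r = rng.random((n_cls, 1))
            X = r * train.spectra[i1] + (1.0 - r) * train.spectra[i2]
            X = add_noise(X, derived_noise, rng)
            X_parts.append(X)
            y_parts.append(np.full(n_cls, cls, dtype=int))
        y = np.concatenate(y_parts)
        parts.append(
            tagged(
                np.vstack(X_parts),
                y,
                np.array([f"combo-{i:05d}" for i in range(y.size)]),
                "combo",
            )
        )
    if recipe.gan_count_per_class:
        if gan_spectra is None:
            raise BookkeepingError(
                "recipe requests GAN spectra but none were provided"
            )
        n0, n1 = gan_spectra.class_counts()
        if n0 != recipe.gan_count_per_class or n1 != recipe.gan_count_per_class:
            raise BookkeepingError(
                f"GAN set has {n0}/{n1} spectra per class, recipe wants "
                f"{recipe.gan_count_per_class} of each"
            )
        parts.append(gan_spectra)
    if not parts:
        return train.subset(np.array([], dtype=int))
    out = LabeledSpectrumSet.concatenate(parts)
    expected = recipe.expected_count(train.n)
    if out.n != expected:
        raise BookkeepingError(f"augmented count {out.n} != expected {expected}")
    return out
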