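"""Shared domain types and delimited-text I/O for labeled Raman spectra.

The package works on spectra sampled on a common wavenumber grid.  The
default grid has 619 samples spanning 500-1800 cm^-1 (inclusive), i.e. a
spacing of 1300/618 ~ 2.103 cm^-1 per pixel; "pixel" throughout the
package means one step of this grid.  Lesion labels are binary with the
positive class (1) meaning cancerous or precancerous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_POINTS = 619
WAVENUMBER_MIN = 500.0
WAVENUMBER_MAX = 1800.0

#: Allowed per-spectrum provenance tags.
PROVENANCE_TAGS = ("original", "noise", "shift", "combo", "gan")


class RamanDXError(Exception):
    """Base class for all package errors."""


class AxisError(RamanDXError):
    """Wavenumber axis violates the uniform-grid invariants."""


class FormatError(RamanDXError):
    """Delimited spectrum table is malformed."""


class LabelError(RamanDXError):
    """Labels are not binary 0/1."""


class SplitError(RamanDXError):
    """Stratified split preconditions violated."""


class ParameterError(RamanDXError):
    """Invalid parameter value."""


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform wavenumber grid shared by a set of spectra.

    Parameters
    ----------
    wavenumbers
        Strictly increasing, uniformly spaced wavenumbers in cm^-1.
    """

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        if w.ndim != 1 or w.size < 2:
            raise AxisError("axis needs at least two wavenumbers")
        d = np.diff(w)
        if np.any(d <= 0):
            raise AxisError("wavenumbers must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise AxisError("wavenumber spacing must be uniform")

    @classmethod
    def default(cls) -> "SpectralAxis":
        """The 619-point grid covering 500-1800 cm^-1."""
        return cls(np.linspace(WAVENUMBER_MIN, WAVENUMBER_MAX, DEFAULT_N_POINTS))

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def spacing(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def range_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def __eq__(self, other: object) -> bool:  # frozen dataclass w/ array field
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavenumbers.shape == other.wavenumbers.shape and bool(
            np.allclose(self.wavenumbers, other.wavenumbers, rtol=1e-12)
        )


@dataclass
class Spectrum:
    """A single intensity vector on a :class:`SpectralAxis`."""

    axis: SpectralAxis
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size != self.axis.n_points:
            raise FormatError(
                f"spectrum length {x.size} != axis length {self.axis.n_points}"
            )
        if not np.all(np.isfinite(x)):
            raise FormatError("spectrum contains non-finite samples")
        self.intensities = x

    def area(self, lo: float = WAVENUMBER_MIN, hi: float = WAVENUMBER_MAX) -> float:
        """Trapezoidal area under the curve between ``lo`` and ``hi`` cm^-1."""
        m = self.axis.range_mask(lo, hi)
        return float(np.trapezoid(self.intensities[m], self.axis.wavenumbers[m]))


@dataclass
class LabeledSpectrumSet:
    """Matrix of spectra with binary lesion labels and provenance tags.

    ``labels`` use 1 for cancer/precancer and 0 for benign.  ``provenance``
    records how each row was obtained (original measurement or one of the
    augmentation operators).
    """

    axis: SpectralAxis
    spectra: np.ndarray
    labels: np.ndarray
    lesion_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        y = np.asarray(self.labels, dtype=int).ravel()
        if X.shape[0] == 0:
            X = X.reshape(0, self.axis.n_points)
        if X.shape[1] != self.axis.n_points:
            raise FormatError(
                f"spectra have {X.shape[1]} columns, axis has {self.axis.n_points}"
            )
        if y.size != X.shape[0]:
            raise FormatError("labels and spectra row counts differ")
        if y.size and not np.isin(y, (0, 1)).all():
            raise LabelError("labels must be binary 0/1")
        if X.size and not np.all(np.isfinite(X)):
            raise FormatError("spectra contain non-finite samples")
        if self.lesion_ids is None:
            self.lesion_ids = np.array([f"lesion-{i:05d}" for i in range(y.size)])
        else:
            self.lesion_ids = np.asarray(self.lesion_ids, dtype=str).ravel()
        if self.provenance is None:
            self.provenance = np.full(y.size, "original", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object).ravel()
        if self.lesion_ids.size != y.size or self.provenance.size != y.size:
            raise FormatError("lesion_ids/provenance length mismatch")
        bad = set(self.provenance) - set(PROVENANCE_TAGS)
        if bad:
            raise FormatError(f"unknown provenance tags: {sorted(bad)}")
        self.spectra = X
        self.labels = y

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.labels.size)

    def class_counts(self) -> tuple[int, int]:
        """(n_benign, n_cancer)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def has_both_classes(self) -> bool:
        return len(np.unique(self.labels)) == 2

    def require_both_classes(self) -> None:
        if not self.has_both_classes():
            raise LabelError("both classes are required for training")

    # -- construction helpers -------------------------------------------
    def subset(self, idx: np.ndarray | list[int]) -> "LabeledSpectrumSet":
        idx = np.asarray(idx, dtype=int)
        return LabeledSpectrumSet(
            self.axis,
            self.spectra[idx],
            self.labels[idx],
            self.lesion_ids[idx],
            self.provenance[idx],
        )

    def with_spectra(self, X: np.ndarray) -> "LabeledSpectrumSet":
        """Same labels/ids/provenance, new intensity matrix."""
        return LabeledSpectrumSet(
            self.axis, X, self.labels, self.lesion_ids, self.provenance
        )

    @staticmethod
    def concatenate(parts: list["LabeledSpectrumSet"]) -> "LabeledSpectrumSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        axis = parts[0].axis
        for p in parts[1:]:
            if p.axis != axis:
                raise AxisError("cannot concatenate sets on different axes")
        return LabeledSpectrumSet(
            axis,
            np.vstack([p.spectra for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.lesion_ids for p in parts]),
            np.concatenate([p.provenance for p in parts]),
        )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_META_COLS = ("label", "lesion_id", "provenance")


def _sep_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def write_spectrum_table(dataset: LabeledSpectrumSet, path: str) -> str:
    """Write a labeled spectrum set to delimited text.

    Header row holds the wavenumbers followed by ``label``, ``lesion_id``
    and ``provenance``; each data row is one spectrum.  Values round-trip
    through :func:`read_spectrum_table` at full precision.
    """
    cols = [repr(float(w)) for w in dataset.axis.wavenumbers] + list(_META_COLS)
    df = pd.DataFrame(dataset.spectra, columns=cols[: dataset.axis.n_points])
    df["label"] = dataset.labels
    df["lesion_id"] = dataset.lesion_ids
    df["provenance"] = dataset.provenance
    df.to_csv(path, sep=_sep_for(path), index=False)
    return str(path)


def read_spectrum_table(path: str) -> LabeledSpectrumSet:
    """Read a labeled spectrum set written by :func:`write_spectrum_table`.

    Raises
    ------
    FormatError
        If the header/rows are inconsistent or wavenumbers are unparsable.
    AxisError
        If the wavenumber header violates the uniform-axis invariants.
    LabelError
        If the label column is not binary.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse spectrum table {path}: {exc}") from exc
    meta = [c for c in _META_COLS if c in df.columns]
    if "label" not in meta:
        raise FormatError("spectrum table lacks a 'label' column")
    wn_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from exc
    axis = SpectralAxis(wavenumbers)
    labels = df["label"].to_numpy()
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise LabelError("label column must contain only 0/1")
    return LabeledSpectrumSet(
        axis,
        df[wn_cols].to_numpy(dtype=float),
        labels.astype(int),
        df["lesion_id"].to_numpy() if "lesion_id" in df else None,
        df["provenance"].to_numpy() if "provenance" in df else None,
    )


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitScheme:
    """Index lists of one stratified train/validation/test split."""

    fractions: tuple[float, float, float]
    seed: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        idx = np.concatenate([self.train, self.val, self.test])
        if len(set(idx.tolist())) != idx.size:
            raise SplitError("split index lists overlap")

    def sizes(self) -> tuple[int, int, int]:
        return self.train.size, self.val.size, self.test.size

    def apply(
        self, dataset: LabeledSpectrumSet
    ) -> tuple[LabeledSpectrumSet, LabeledSpectrumSet, LabeledSpectrumSet]:
        return (
            dataset.subset(self.train),
            dataset.subset(self.val),
            dataset.subset(self.test),
        )


def stratified_split(
    dataset: LabeledSpectrumSet,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> SplitScheme:
    """Random stratified split into train/validation/test.

    Per class with ``n_c`` members, the training set receives
    ``round(f_train * n_c)`` cases and the validation set
    ``round(f_val * n_c)`` (round half up); the test set takes the
    remainder.  For the 340-cancer / 391-benign cohort at 70/10/20 this
    yields 512/73/146 cases.  Assignment is random but deterministic for a
    given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in (0, 1):
        members = np.flatnonzero(dataset.labels == cls)
        if members.size < 3:
            raise SplitError(
                f"class {cls} has {members.size} members; need at least 3"
            )
        rng.shuffle(members)
        n_tr = _round_half_up(fractions[0] * members.size)
        n_va = _round_half_up(fractions[1] * members.size)
        if n_tr + n_va > members.size:
            raise SplitError("fractions leave no room for a test set")
        train.append(members[:n_tr])
        val.append(members[n_tr : n_tr + n_va])
        test.append(members[n_tr + n_va :])
    return SplitScheme(
        tuple(fractions),
        seed,
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )
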