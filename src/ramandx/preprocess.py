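"""Raw-spectrum conditioning.

Raman spectra of tissue ride on a broad autofluorescence background that is
orders of magnitude smoother than the Raman bands.  The standard
conditioning chain applied here is

1. 5-point box-car smoothing (truncated windows at the edges),
2. iterative fifth-order modified-polyfit baseline removal, and
3. normalization to unit area under the curve over 500-1800 cm^-1,

in that order.  The modified-polyfit loop repeatedly fits a low-order
polynomial and clips the spectrum to the fit from above, so the polynomial
relaxes underneath the peaks onto the fluorescence baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .core import (
    LabeledSpectrumSet,
    ParameterError,
    RamanDXError,
    SpectralAxis,
    WAVENUMBER_MAX,
    WAVENUMBER_MIN,
)


class NormalizationError(RamanDXError):
    """Area under the curve is not positive."""


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning chain.

    boxcar_width : odd window width in pixels (default 5).
    poly_order : polynomial order for baseline fitting (default 5).
    poly_max_iter : iteration cap of the modified-polyfit loop.
    poly_tol : relative L2 change of the fitted baseline below which the
        loop is considered converged.
    normalize_range : wavenumber range (cm^-1) of the unit-area constraint.
    normalize : whether model inputs are area-normalized at the end.
    """

    boxcar_width: int = 5
    poly_order: int = 5
    poly_max_iter: int = 500
    poly_tol: float = 1e-4
    normalize_range: tuple[float, float] = (WAVENUMBER_MIN, WAVENUMBER_MAX)
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.boxcar_width < 1 or self.boxcar_width % 2 == 0:
            raise ParameterError("boxcar_width must be odd and >= 1")
        if self.poly_order < 1:
            raise ParameterError("poly_order must be >= 1")


def boxcar_smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    """Moving-average filter with truncated windows at the edges.

    Each output sample is the mean of the ``width``-point window centred on
    it; near the edges the window shrinks to the available samples, so the
    operator remains a true local mean everywhere.
    """
    if width < 1 or width % 2 == 0:
        raise ParameterError("box-car width must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    if width > x.shape[-1]:
        raise ParameterError("box-car width exceeds spectrum length")
    kernel = np.ones(width)
    sums = convolve1d(x, kernel, axis=-1, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(x.shape[-1]), kernel, mode="constant", cval=0.0)
    return sums / counts


def _fit_baselines(
    Y: np.ndarray, t: np.ndarray, order: int, max_iter: int, tol: float
) -> np.ndarray:
    """Iterative modified polyfit; returns the per-row baseline estimate."""
    V = np.polynomial.polynomial.polyvander(t, order)
    pinv = np.linalg.pinv(V)  # fixed design matrix: factor once
    work = Y.copy()
    fit = work @ pinv.T @ V.T  # == (V @ (pinv @ work.T)).T
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = work @ pinv.T @ V.T
        denom = np.linalg.norm(fit, axis=-1)
        denom = np.where(denom > 0, denom, 1.0)
        delta = np.linalg.norm(new_fit - fit, axis=-1) / denom
        fit = new_fit
        if np.all(delta < tol):
            break
    else:
        warnings.warn(
            "baseline fit did not converge within poly_max_iter iterations",
            RuntimeWarning,
            stacklevel=3,
        )
    return fit


def remove_fluorescence(
    x: np.ndarray, axis: SpectralAxis, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Subtract the iteratively fitted polynomial fluorescence baseline.

    A polynomial of order ``cfg.poly_order`` is fitted to the spectrum;
    samples above the fit are replaced by the fitted values and the fit is
    repeated until it changes by less than ``cfg.poly_tol`` (relative L2)
    or ``cfg.poly_max_iter`` is reached.  The final fit is subtracted from
    the input.  Broad baselines are removed to near zero while peak shapes
    are preserved.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Y = np.atleast_2d(x)
    # map wavenumbers to [-1, 1] for a well-conditioned Vandermonde basis
    w = axis.wavenumbers
    t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    fit = _fit_baselines(Y, t, cfg.poly_order, cfg.poly_max_iter, cfg.poly_tol)
    out = Y - fit
    return out[0] if single else out


def normalize_area(
    x: np.ndarray,
    axis: SpectralAxis,
    rng: tuple[float, float] = (WAVENUMBER_MIN, WAVENUMBER_MAX),
) -> np.ndarray:
    """Scale spectra so the trapezoidal area over ``rng`` equals one."""
    x = np.asarray(x, dtype=float)
    m = axis.range_mask(*rng)
    area = np.trapezoid(x[..., m], axis.wavenumbers[m], axis=-1)
    if np.any(area <= 0):
        raise NormalizationError("area under the curve must be positive")
    return x / np.expand_dims(np.asarray(area), -1) if x.ndim > 1 else x / area


def preprocess_set(
    dataset: LabeledSpectrumSet, cfg: PreprocessConfig | None = None
) -> LabeledSpectrumSet:
    """Apply smoothing, baseline removal and (optionally) normalization."""
    cfg = cfg or PreprocessConfig()
    X = boxcar_smooth(dataset.spectra, cfg.boxcar_width)
    X = remove_fluorescence(X, dataset.axis, cfg)
    if cfg.normalize:
        X = normalize_area(X, dataset.axis, cfg.normalize_range)
    return dataset.with_spectra(X)
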