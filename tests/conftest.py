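import numpy as np
import pytest

import ramandx as rx


@pytest.fixture(scope="session")
def axis():
    return rx.SpectralAxis.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A quickly generated raw cohort with both classes (60 lesions)."""
    cfg = rx.SyntheticCohortConfig(n_cancer=28, n_benign=32, seed=42)
    return rx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_clean_cohort(small_cohort):
    return rx.preprocess_set(small_cohort)


def toy_peak_set(n_per_class=60, separation=2.0, noise=0.1, seed=0, n_points=619):
    """Tiny linearly separable two-class spectra: one Gaussian bump whose
    amplitude differs between classes."""
    rng = np.random.default_rng(seed)
    axis = rx.SpectralAxis(np.linspace(500, 1800, n_points))
    t = np.linspace(-1, 1, n_points)
    bump = np.exp(-((t + 0.2) ** 2) / 0.02)
    X, y = [], []
    for cls, amp in ((0, 1.0), (1, separation)):
        amps = amp + 0.05 * rng.standard_normal(n_per_class)
        X.append(amps[:, None] * bump[None, :] + noise * rng.standard_normal((n_per_class, n_points)))
        y.append(np.full(n_per_class, cls))
    return rx.LabeledSpectrumSet(axis, np.vstack(X), np.concatenate(y))
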