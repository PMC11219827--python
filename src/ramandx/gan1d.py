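"""Conditional one-dimensional GAN for class-labeled Raman spectrum synthesis.

The generator upsamples a 4-sample latent vector to a 619-sample spectrum
through five transposed-convolution stages; the discriminator mirrors it
with five convolution stages down to a single real/fake logit:

======================  =========================================
generator stage sizes   4 -> 6 -> 25 -> 77 -> 309 -> 619
discriminator sizes     619 -> 309 -> 77 -> 25 -> 6 -> 1
======================  =========================================

Stage lengths follow ``o = (i-1)s - 2p + k`` (transposed convolution) and
``o = (i + 2p - k)/s + 1`` (convolution).  Channel widths are multiples
(8, 4, 2, 1) of a base width (64 at full scale).  Class conditioning
enters both networks as constant input channels (one-hot for the
generator latent, a +-1 channel for the discriminator), the standard
conditional-GAN pattern for 1-D signals.

Training uses the non-saturating binary cross-entropy adversarial loss
with Adam (learning rate 2e-4, decay factors 0.5 / 0.999, mini-batch
256).  Spectra are standardized internally (per-wavenumber mean, global
scale) before adversarial training and de-standardized on synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import LabeledSpectrumSet, RamanDXError, SpectralAxis

#: Table-driven stage parameters: (kernel, stride, padding) per layer.
GENERATOR_STAGES = ((3, 1, 0), (7, 4, 1), (7, 3, 1), (7, 4, 1), (5, 2, 1))
DISCRIMINATOR_STAGES = ((5, 2, 1), (7, 4, 1), (7, 3, 1), (7, 4, 1), (6, 1, 0))
#: Channel-width multipliers of the base width for stages 1..4 (stage 5 = 1).
WIDTH_MULTIPLIERS = (8, 4, 2, 1)


class ArchitectureError(RamanDXError):
    """Layer-size chain does not reproduce the required output size."""


class TrainingError(RamanDXError):
    """Adversarial optimization diverged."""


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional stage with its exact size arithmetic."""

    kind: str  # "transposed_conv" | "conv"
    input_size: int
    kernel_size: int
    n_kernels: int
    stride: int
    padding: int
    output_size: int

    def __post_init__(self) -> None:
        if self.kind == "transposed_conv":
            o = transposed_conv_output_size(
                self.input_size, self.stride, self.padding, self.kernel_size
            )
        elif self.kind == "conv":
            o = conv_output_size(
                self.input_size, self.stride, self.padding, self.kernel_size
            )
        else:
            raise ArchitectureError(f"unknown layer kind {self.kind!r}")
        if o != self.output_size:
            raise ArchitectureError(
                f"{self.kind} layer: formula gives {o}, spec says {self.output_size}"
            )


def transposed_conv_output_size(i: int, s: int, p: int, k: int) -> int:
    """Transposed-convolution output length ``o = (i-1)s - 2p + k``."""
    try:
        return nn.transposed_conv_output_size(i, s, p, k)
    except ValueError as exc:
        raise ArchitectureError(str(exc)) from exc


def conv_output_size(i: int, s: int, p: int, k: int) -> int:
    """Convolution output length ``o = (i + 2p - k)/s + 1`` (exact division)."""
    try:
        return nn.conv_output_size(i, s, p, k)
    except ValueError as exc:
        raise ArchitectureError(str(exc)) from exc


@dataclass
class GANConfig:
    """Architecture and optimizer settings of the conditional 1D-GAN.

    ``base_width`` scales every stage's channel count; 64 is the
    full-scale width, smaller values give cheap desk-scale models with
    identical stage lengths.  ``epochs=25000`` is the full-scale training
    schedule; the default here is a desk-scale 500.
    """

    latent_length: int = 4
    spectrum_length: int = 619
    base_width: int = 64
    n_classes: int = 2
    minibatch: int = 256
    learning_rate: float = 2e-4
    gradient_decay: float = 0.5
    squared_gradient_decay: float = 0.999
    leaky_slope: float = 0.2
    #: score real spectra with wrong labels as fakes (matching-aware
    #: conditional discriminator); makes conditioning emerge quickly
    matching_aware: bool = True
    epochs: int = 500
    seed: int = 0

    @classmethod
    def paper_scale(cls, **kw) -> "GANConfig":
        kw.setdefault("epochs", 25000)
        kw.setdefault("base_width", 64)
        return cls(**kw)

    def generator_layer_specs(self) -> list[LayerSpec]:
        """Chain the transposed-conv formula through all five stages."""
        widths = [m * self.base_width for m in WIDTH_MULTIPLIERS] + [1]
        size = self.latent_length
        specs = []
        for (k, s, p), w in zip(GENERATOR_STAGES, widths):
            out = transposed_conv_output_size(size, s, p, k)
            specs.append(LayerSpec("transposed_conv", size, k, w, s, p, out))
            size = out
        if size != self.spectrum_length:
            raise ArchitectureError(
                f"generator chain ends at {size}, expected {self.spectrum_length}"
            )
        return specs

    def discriminator_layer_specs(self) -> list[LayerSpec]:
        """Chain the conv formula through all five stages down to size 1."""
        widths = [m * self.base_width for m in WIDTH_MULTIPLIERS] + [1]
        size = self.spectrum_length
        specs = []
        for (k, s, p), w in zip(DISCRIMINATOR_STAGES, widths):
            out = conv_output_size(size, s, p, k)
            specs.append(LayerSpec("conv", size, k, w, s, p, out))
            size = out
        if size != 1:
            raise ArchitectureError(f"discriminator chain ends at {size}, expected 1")
        return specs


def build_generator(
    cfg: GANConfig, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, list[LayerSpec]]:
    """Five transposed-conv stages; BN+ReLU after stages 1-4, linear output.

    Input: ``(n, 1 + n_classes, latent_length)`` — one latent channel plus
    one-hot class channels.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    specs = cfg.generator_layer_specs()
    layers: list[nn.Layer] = []
    in_ch = 1 + cfg.n_classes
    for i, spec in enumerate(specs):
        layers.append(
            nn.ConvTranspose1d(
                in_ch, spec.n_kernels, spec.kernel_size, spec.stride, spec.padding, rng
            )
        )
        if i < len(specs) - 1:
            layers.append(nn.BatchNorm1d(spec.n_kernels))
            layers.append(nn.ReLU())
        in_ch = spec.n_kernels
    return nn.Sequential(layers), specs


def build_discriminator(
    cfg: GANConfig, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, list[LayerSpec]]:
    """Five conv stages; LeakyReLU after stages 1-4 (no batch norm).

    Input: ``(n, 2, spectrum_length)`` — the spectrum plus a constant
    class channel (+1 cancer / -1 benign).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    specs = cfg.discriminator_layer_specs()
    layers: list[nn.Layer] = []
    in_ch = 2
    for i, spec in enumerate(specs):
        layers.append(
            nn.Conv1d(
                in_ch, spec.n_kernels, spec.kernel_size, spec.stride, spec.padding, rng
            )
        )
        if i < len(specs) - 1:
            layers.append(nn.LeakyReLU(cfg.leaky_slope))
        in_ch = spec.n_kernels
    return nn.Sequential(layers), specs


@dataclass
class GANState:
    """Trained generator/discriminator with the input standardization."""

    cfg: GANConfig
    axis: SpectralAxis
    generator: nn.Sequential
    discriminator: nn.Sequential
    mean_spectrum: np.ndarray
    scale: float
    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)


def _latent_input(
    z: np.ndarray, labels: np.ndarray, n_classes: int
) -> np.ndarray:
    n, L = z.shape
    x = np.zeros((n, 1 + n_classes, L), dtype=nn.DTYPE)
    x[:, 0, :] = z
    x[np.arange(n), 1 + labels, :] = 1.0
    return x


def _cond_spectrum(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n, L = x.shape
    out = np.empty((n, 2, L), dtype=nn.DTYPE)
    out[:, 0, :] = x
    out[:, 1, :] = (2.0 * labels - 1.0)[:, None]
    return out


def train_gan(train: LabeledSpectrumSet, cfg: GANConfig) -> GANState:
    """Adversarial training of the conditional 1D-GAN.

    Both networks are optimized with Adam using ``cfg.gradient_decay`` and
    ``cfg.squared_gradient_decay`` as the moment-decay factors.  The
    per-epoch mean losses of both networks are recorded; divergence
    (non-finite loss) aborts with the epoch index.
    """
    train.require_both_classes()
    if train.axis.n_points != cfg.spectrum_length:
        raise ArchitectureError(
            f"training spectra have {train.axis.n_points} samples, "
            f"config expects {cfg.spectrum_length}"
        )
    rng = np.random.default_rng(cfg.seed)
    G, _ = build_generator(cfg, rng)
    D, _ = build_discriminator(cfg, rng)
    mu = train.spectra.mean(axis=0)
    scale = float((train.spectra - mu).std()) or 1.0
    Xs = ((train.spectra - mu) / scale).astype(nn.DTYPE)
    y = train.labels
    opt_g = nn.Adam(
        G.params(), cfg.learning_rate, cfg.gradient_decay, cfg.squared_gradient_decay
    )
    opt_d = nn.Adam(
        D.params(), cfg.learning_rate, cfg.gradient_decay, cfg.squared_gradient_decay
    )
    state = GANState(cfg, train.axis, G, D, mu, scale)
    n = train.n
    batch = min(cfg.minibatch, n)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - batch + 1, batch):
            idx = order[start : start + batch]
            real, labels = Xs[idx], y[idx]
            b = idx.size
            z = rng.standard_normal((b, cfg.latent_length))
            fake = G.forward(_latent_input(z, labels, cfg.n_classes))

            # discriminator step: real+correct label -> 1, generated -> 0,
            # and (matching-aware) real+wrong label -> 0 at half weight.
            # The wrong-label negatives are what give the label input a
            # gradient before the generator's samples are otherwise
            # convincing.
            logit_real = D.forward(_cond_spectrum(real, labels)).reshape(-1)
            loss_r, g_r = nn.bce_with_logits(logit_real, np.ones(b))
            D.backward(g_r.reshape(-1, 1, 1))
            acc_grads = [g.copy() for _, g in D.params()]
            logit_fake = D.forward(_cond_spectrum(fake[:, 0, :], labels)).reshape(-1)
            loss_f, g_f = nn.bce_with_logits(logit_fake, np.zeros(b))
            D.backward(g_f.reshape(-1, 1, 1))
            loss_d = loss_r + loss_f
            if cfg.matching_aware:
                for acc, (_, g) in zip(acc_grads, D.params()):
                    acc += g
                logit_wrong = D.forward(_cond_spectrum(real, 1 - labels)).reshape(-1)
                loss_m, g_m = nn.bce_with_logits(
                    logit_wrong, np.zeros(b), np.full(b, 0.5)
                )
                D.backward(g_m.reshape(-1, 1, 1))
                loss_d += loss_m
            for acc, (_, g) in zip(acc_grads, D.params()):
                g += acc
            opt_d.step()
            d_losses.append(loss_d)

            # generator step (non-saturating): the same fake batch is
            # re-scored through the updated discriminator; G's cached
            # activations from its single forward pass are still valid
            logit = D.forward(_cond_spectrum(fake[:, 0, :], labels)).reshape(-1)
            loss_g, gl = nn.bce_with_logits(logit, np.ones(idx.size))
            g_spec = D.backward(gl.reshape(-1, 1, 1))[:, :1, :]
            gfake = np.zeros_like(fake)
            gfake[:, :1, :] = g_spec
            G.backward(gfake)
            opt_g.step()
            g_losses.append(loss_g)
        state.discriminator_loss.append(float(np.mean(d_losses)))
        state.generator_loss.append(float(np.mean(g_losses)))
        if not np.isfinite(state.discriminator_loss[-1]) or not np.isfinite(
            state.generator_loss[-1]
        ):
            raise TrainingError(f"non-finite adversarial loss at epoch {epoch}")
    return state


def synthesize_spectra(
    state: GANState, n_per_class: int, seed: int = 0
) -> LabeledSpectrumSet:
    """Generate ``n_per_class`` spectra per class (provenance ``gan``)."""
    cfg = state.cfg
    labels = np.concatenate(
        [np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    )
    n = labels.size
    X = np.empty((n, cfg.spectrum_length))
    rng = np.random.default_rng(seed)
    for start in range(0, n, 512):
        idx = slice(start, min(start + 512, n))
        z = rng.standard_normal((len(range(*idx.indices(n))), cfg.latent_length))
        out = state.generator.forward(
            _latent_input(z, labels[idx], cfg.n_classes), train=False
        )
        X[idx] = out[:, 0, :] * state.scale + state.mean_spectrum
    ids = np.array([f"gan-{i:05d}" for i in range(n)])
    return LabeledSpectrumSet(
        state.axis, X, labels, ids, np.full(n, "gan", dtype=object)
    )


def discriminator_real_fake_accuracy(
    state: GANState, real: LabeledSpectrumSet, seed: int = 0
) -> float:
    """Accuracy of the trained discriminator on held-out real vs fresh fakes."""
    fake = synthesize_spectra(state, max(1, real.n // 2), seed=seed)
    Xr = (real.spectra - state.mean_spectrum) / state.scale
    Xf = (fake.spectra - state.mean_spectrum) / state.scale
    lr = state.discriminator.forward(
        _cond_spectrum(Xr.astype(nn.DTYPE), real.labels), train=False
    ).reshape(-1)
    lf = state.discriminator.forward(
        _cond_spectrum(Xf.astype(nn.DTYPE), fake.labels), train=False
    ).reshape(-1)
    correct = np.sum(lr > 0) + np.sum(lf <= 0)
    return float(correct / (lr.size + lf.size))
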