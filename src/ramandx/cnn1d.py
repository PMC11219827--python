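"""1D-CNN Raman spectral classifier with early stopping.

The network is the 21-layer architecture counted over the enumeration
input, 4 x (convolution, batch norm, ReLU, average pooling), two fully
connected layers (256 then 2), softmax, output.  Convolutions use kernel
size 3, stride 1 and 'same' padding so each stage preserves length; each
average-pooling stage (size 2, stride 2, no padding) maps length ``L`` to
``floor((L-2)/2) + 1``.  For a 619-sample spectrum the post-pool lengths
are 309, 154, 77 and 38, giving a flattened width of 38*128 = 4864.

Training uses Adam with an initial learning rate of 0.001 dropped by a
factor of 0.9 every 2 epochs.  Validation accuracy (on the full
validation set) is evaluated every iteration; training stops when it has
not exceeded its running best for ``early_stop_patience`` consecutive
iterations, and the last iteration's weights are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import LabeledSpectrumSet, ParameterError, RamanDXError


class TrainingError(RamanDXError):
    """Loss became non-finite during optimization."""


@dataclass
class CNNConfig:
    """Architecture and optimization settings of the 1D-CNN.

    ``minibatch=None`` selects the size by the training-set scale: 256 for
    an original-sized training set, 1024 once it has been augmented past
    1000 cases.  ``early_stop_patience`` counts *iterations* without a new
    best validation accuracy.
    """

    conv_channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 3
    fc_size: int = 256
    n_classes: int = 2
    pool_size: int = 2
    pool_stride: int = 2
    minibatch: int | None = None
    initial_lr: float = 1e-3
    lr_drop_factor: float = 0.9
    lr_drop_period: int = 2
    max_epochs: int = 100
    early_stop_patience: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    restore_best: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 4:
            raise ParameterError("the classifier uses exactly 4 conv stages")
        if self.kernel_size % 2 == 0:
            raise ParameterError("'same' padding requires an odd kernel size")

    def batch_for(self, n_train: int) -> int:
        if self.minibatch is not None:
            return min(self.minibatch, n_train)
        return min(1024 if n_train > 1000 else 256, n_train)


def pool_chain(input_length: int, n_stages: int = 4, size: int = 2, stride: int = 2) -> list[int]:
    """Post-pool lengths after each conv/pool stage (conv preserves length)."""
    lengths = []
    L = input_length
    for _ in range(n_stages):
        L = (L - size) // stride + 1
        if L < 1:
            raise ParameterError(f"input length {input_length} too short for pooling")
        lengths.append(L)
    return lengths


def layer_count(cfg: CNNConfig | None = None) -> int:
    """Layers under the enumeration convention (input + 4x4 + 2 fc + softmax + output)."""
    cfg = cfg or CNNConfig()
    return 1 + 4 * len(cfg.conv_channels) + 2 + 1 + 1


def build_cnn(
    cfg: CNNConfig, input_length: int, rng: np.random.Generator | None = None
) -> tuple[nn.Sequential, list[int]]:
    """Assemble the network; returns it with the post-pool length chain."""
    if input_length < 16:
        raise ParameterError("input length must be at least 16")
    rng = rng or np.random.default_rng(cfg.seed)
    lengths = pool_chain(input_length, 4, cfg.pool_size, cfg.pool_stride)
    pad = (cfg.kernel_size - 1) // 2
    layers: list[nn.Layer] = []
    in_ch = 1
    for ch in cfg.conv_channels:
        layers.append(nn.Conv1d(in_ch, ch, cfg.kernel_size, 1, pad, rng))
        layers.append(nn.BatchNorm1d(ch))
        layers.append(nn.ReLU())
        layers.append(nn.AvgPool1d(cfg.pool_size, cfg.pool_stride))
        in_ch = ch
    layers.append(nn.Flatten())
    layers.append(nn.Dense(lengths[-1] * cfg.conv_channels[-1], cfg.fc_size, rng))
    layers.append(nn.Dense(cfg.fc_size, cfg.n_classes, rng))
    return nn.Sequential(layers), lengths


def learning_rate_at(cfg: CNNConfig, epoch: int) -> float:
    """``initial_lr * drop_factor ** floor(epoch / drop_period)`` (0-based)."""
    return cfg.initial_lr * cfg.lr_drop_factor ** (epoch // cfg.lr_drop_period)


def iteration_budget(n_train: int, batch: int, max_epochs: int) -> tuple[int, int]:
    """(iterations per epoch, maximum iterations); partial batches dropped."""
    per_epoch = max(1, n_train // batch)
    return per_epoch, per_epoch * max_epochs


@dataclass
class TrainingTrace:
    """Per-iteration accuracy/loss curves and the stopping bookkeeping."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_iteration: int = 0
    best_iteration: int = 0


@dataclass
class CNNState:
    net: nn.Sequential
    cfg: CNNConfig
    input_length: int
    mean_spectrum: np.ndarray
    scale: float


def _standardize(X: np.ndarray, mu: np.ndarray, scale: float) -> np.ndarray:
    return ((X - mu) / scale).astype(nn.DTYPE)[:, None, :]


def _eval_batch(net: nn.Sequential, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = net.forward(X, train=False)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float(np.mean(logits.argmax(axis=1) == y))
    return acc, loss


def train_cnn(
    train: LabeledSpectrumSet, val: LabeledSpectrumSet, cfg: CNNConfig
) -> tuple[CNNState, TrainingTrace]:
    """Mini-batch Adam training with per-iteration validation monitoring."""
    train.require_both_classes()
    rng = np.random.default_rng(cfg.seed)
    net, _ = build_cnn(cfg, train.axis.n_points, rng)
    mu = train.spectra.mean(axis=0)
    scale = float((train.spectra - mu).std()) or 1.0
    Xtr = _standardize(train.spectra, mu, scale)
    ytr = train.labels
    Xva = _standardize(val.spectra, mu, scale)
    yva = val.labels
    batch = cfg.batch_for(train.n)
    per_epoch, max_iters = iteration_budget(train.n, batch, cfg.max_epochs)
    opt = nn.Adam(net.params(), cfg.initial_lr, cfg.beta1, cfg.beta2)
    trace = TrainingTrace()
    best_val, best_iter = -np.inf, 0
    best_params = None
    iteration = 0
    stop = False
    for epoch in range(cfg.max_epochs):
        opt.lr = learning_rate_at(cfg, epoch)
        order = rng.permutation(train.n)
        for b in range(per_epoch):
            idx = order[b * batch : (b + 1) * batch]
            logits = net.forward(Xtr[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at iteration {iteration}")
            net.backward(grad)
            opt.step()
            iteration += 1
            trace.train_loss.append(loss)
            trace.train_accuracy.append(
                float(np.mean(logits.argmax(axis=1) == ytr[idx]))
            )
            va_acc, va_loss = _eval_batch(net, Xva, yva)
            trace.val_accuracy.append(va_acc)
            trace.val_loss.append(va_loss)
            if va_acc > best_val:
                best_val, best_iter = va_acc, iteration
                if cfg.restore_best:
                    best_params = [p.copy() for p, _ in net.params()]
            if iteration - best_iter >= cfg.early_stop_patience:
                stop = True
                break
        if stop:
            break
    trace.stop_iteration = iteration
    trace.best_iteration = best_iter
    if cfg.restore_best and best_params is not None:
        for (p, _), saved in zip(net.params(), best_params):
            p[...] = saved
    return CNNState(net, cfg, train.axis.n_points, mu, scale), trace


def predict_scores(state: CNNState, dataset: LabeledSpectrumSet) -> np.ndarray:
    """Softmax probability of the cancer class, per spectrum."""
    if dataset.axis.n_points != state.input_length:
        raise ParameterError(
            f"input length {dataset.axis.n_points} != model length {state.input_length}"
        )
    X = _standardize(dataset.spectra, state.mean_spectrum, state.scale)
    scores = np.empty(dataset.n)
    for start in range(0, dataset.n, 1024):
        sl = slice(start, min(start + 1024, dataset.n))
        logits = state.net.forward(X[sl], train=False)
        scores[sl] = nn.softmax(logits)[:, 1]
    return scores
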