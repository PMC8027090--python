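"""A small one-dimensional CNN, implemented from scratch with explicit backprop.

Architecture I1-C2-C3-F4-O5: a 1 x N input (the CSP feature vector, or a
flattened time-frequency tensor), two valid-mode 1-D convolutional layers
with ReLU, a tanh fully connected layer with inverted dropout, and a
2-class softmax head trained on the sum-of-squared-errors between the
softmax output and the one-hot target.  Gradients for every layer are
derived and coded by hand (the finite-difference check in the test suite is
the contract), and parameters are updated by plain mini-batch gradient
descent with an exponentially interpolated learning-rate schedule.

Pooling layers (max and average, with their distinct error-routing rules)
are provided but not used by the default architecture: with inputs as short
as N = 4 there is nothing to downsample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ConvSpec:
    n_kernels: int
    kernel_length: int


@dataclass(frozen=True)
class CNNArchitecture:
    """Shape description of the I1-C2-C3-F4-O5 network."""

    input_length: int
    conv_layers: tuple[ConvSpec, ...] = (ConvSpec(8, 2), ConvSpec(16, 2))
    dense_width: int = 32
    n_classes: int = 2

    def __post_init__(self) -> None:
        convs = tuple(
            c if isinstance(c, ConvSpec) else ConvSpec(*c) for c in self.conv_layers
        )
        object.__setattr__(self, "conv_layers", convs)
        if self.n_classes != 2:
            raise ValueError("this network is a binary classifier (n_classes = 2)")
        if self.input_length < 1 or self.dense_width < 1:
            raise ValueError("input_length and dense_width must be >= 1")
        length = self.input_length
        for spec in convs:
            if spec.n_kernels < 1 or spec.kernel_length < 1:
                raise ValueError("kernel counts and lengths must be >= 1")
            length = length - spec.kernel_length + 1
            if length < 1:
                raise ValueError(
                    f"kernel of length {spec.kernel_length} leaves no valid output"
                )

    @property
    def conv_output_lengths(self) -> tuple[int, ...]:
        lengths, length = [], self.input_length
        for spec in self.conv_layers:
            length = length - spec.kernel_length + 1
            lengths.append(length)
        return tuple(lengths)

    @property
    def flat_dim(self) -> int:
        if not self.conv_layers:
            return self.input_length
        return self.conv_layers[-1].n_kernels * self.conv_output_lengths[-1]


@dataclass
class CNNParameters:
    """All weights and biases of the network.

    ``conv_kernels[l]`` has shape (n_kernels, in_depth, kernel_length) and
    ``conv_biases[l]`` shape (n_kernels,); dense parameters follow the
    ``y = x W + b`` convention.
    """

    conv_kernels: list[np.ndarray]
    conv_biases: list[np.ndarray]
    dense_w: np.ndarray  # [flat_dim x dense_width]
    dense_b: np.ndarray  # [dense_width]
    out_w: np.ndarray  # [dense_width x n_classes]
    out_b: np.ndarray  # [n_classes]

    def copy(self) -> "CNNParameters":
        return CNNParameters(
            conv_kernels=[k.copy() for k in self.conv_kernels],
            conv_biases=[b.copy() for b in self.conv_biases],
            dense_w=self.dense_w.copy(), dense_b=self.dense_b.copy(),
            out_w=self.out_w.copy(), out_b=self.out_b.copy(),
        )

    def flatten(self) -> np.ndarray:
        parts = [a.ravel() for a in self._arrays()]
        return np.concatenate(parts)

    def _arrays(self) -> list[np.ndarray]:
        return [*self.conv_kernels, *self.conv_biases,
                self.dense_w, self.dense_b, self.out_w, self.out_b]


# GradientSet mirrors CNNParameters shape-for-shape.
GradientSet = CNNParameters


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer hyperparameters: batch 64, 150 epochs, lr 0.02 -> 0.0002
    with decay speed 1000, dropout 0.5 at the dense layer."""

    batch_size: int = 64
    epochs: int = 150
    lr_start: float = 0.02
    lr_end: float = 0.0002
    decay_speed: float = 1000.0
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_end < self.lr_start:
            raise ValueError("require 0 < lr_end < lr_start")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1 or self.decay_speed <= 0:
            raise ValueError("batch_size, epochs and decay_speed must be positive")


@dataclass
class ForwardTrace:
    """Everything the backward pass needs from one forward pass."""

    x: np.ndarray  # [B x depth x length] network input
    conv_nets: list[np.ndarray]
    conv_acts: list[np.ndarray]
    flat: np.ndarray
    dense_net: np.ndarray
    dense_act: np.ndarray
    dropout_mask: np.ndarray | None
    dropout_rate: float
    dense_out: np.ndarray  # post-dropout activations feeding O5
    out_net: np.ndarray
    probs: np.ndarray


_INIT_BOUND = 0.3
_INIT_BIAS = 0.1
_DENSE_INIT_SD = 0.1


def _truncated_normal(rng: np.random.Generator, shape: tuple[int, ...],
                      sd: float, bound: float) -> np.ndarray:
    """Normal(0, sd) resampled until every entry lies in [-bound, bound]."""
    x = rng.normal(0.0, sd, size=shape)
    bad = np.abs(x) > bound
    while np.any(bad):
        x[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(x) > bound
    return x


def init_parameters(arch: CNNArchitecture, seed: int) -> CNNParameters:
    """Initialize: conv kernels ~ Uniform(-0.3, 0.3), dense weights
    ~ Normal(0, 0.1) truncated to the same interval, all biases = 0.1."""
    rng = np.random.default_rng(seed)
    kernels, biases = [], []
    depth = 1
    for spec in arch.conv_layers:
        kernels.append(rng.uniform(-_INIT_BOUND, _INIT_BOUND,
                                   size=(spec.n_kernels, depth, spec.kernel_length)))
        biases.append(np.full(spec.n_kernels, _INIT_BIAS))
        depth = spec.n_kernels
    dense_w = _truncated_normal(rng, (arch.flat_dim, arch.dense_width),
                                _DENSE_INIT_SD, _INIT_BOUND)
    out_w = _truncated_normal(rng, (arch.dense_width, arch.n_classes),
                              _DENSE_INIT_SD, _INIT_BOUND)
    return CNNParameters(
        conv_kernels=kernels, conv_biases=biases,
        dense_w=dense_w, dense_b=np.full(arch.dense_width, _INIT_BIAS),
        out_w=out_w, out_b=np.full(arch.n_classes, _INIT_BIAS),
    )


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def conv_forward(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray,
                 activation: str = "relu") -> tuple[np.ndarray, np.ndarray]:
    """Valid-mode 1-D cross-correlation summed over input depth, plus bias.

    ``x`` is [B x D x L] (a [D x L] input is auto-batched); kernels are
    [I x D x K].  Returns (activations, pre-activations), both [B x I x L-K+1].
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    n_k, depth, k_len = kernels.shape
    if x.shape[1] != depth:
        raise ValueError(f"input depth {x.shape[1]} != kernel depth {depth}")
    if x.shape[2] < k_len:
        raise ValueError("input shorter than the kernel")
    windows = sliding_window_view(x, k_len, axis=2)  # [B x D x Lo x K]
    net = np.einsum("bdlk,idk->bil", windows, kernels) + bias[None, :, None]
    act = relu(net) if activation == "relu" else net
    if squeeze:
        return act[0], net[0]
    return act, net


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  activation: str = "tanh") -> np.ndarray:
    """Fully connected layer ``f(x W + b)`` with tanh or softmax activation."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} != weight rows {w.shape[0]}")
    net = x @ w + b
    if activation == "tanh":
        return np.tanh(net)
    if activation == "softmax":
        return softmax(net)
    raise ValueError(f"unknown activation {activation!r}")


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - np.max(scores, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sse_loss(y: np.ndarray, r: np.ndarray) -> float:
    """Sum of squared errors between predicted probabilities and one-hot
    targets; for a batch, the mean of per-sample sums."""
    y, r = np.asarray(y, float), np.asarray(r, float)
    if y.shape != r.shape:
        raise ValueError("prediction and target shapes differ")
    per_sample = np.sum((y - r) ** 2, axis=-1)
    return float(np.mean(per_sample))


def dropout_mask(shape: tuple[int, ...], rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """0/1 keep-mask with keep probability ``1 - rate`` (inverted dropout:
    callers scale kept activations by 1/(1-rate))."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate).astype(float)


def forward(params: CNNParameters, arch: CNNArchitecture, features: np.ndarray,
            *, training: bool = False, dropout_rate: float = 0.0,
            rng: np.random.Generator | None = None) -> ForwardTrace:
    """Full forward pass.  Dropout is applied at the dense layer only, and
    only when ``training`` is true."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != arch.input_length:
        raise ValueError(f"feature length {x.shape[1]} != N = {arch.input_length}")
    act = x[:, None, :]  # depth-1 input
    x_in = act
    conv_nets, conv_acts = [], []
    for kernels, bias in zip(params.conv_kernels, params.conv_biases):
        act, net = conv_forward(act, kernels, bias)
        conv_nets.append(net)
        conv_acts.append(act)
    flat = act.reshape(act.shape[0], -1)
    dense_net = flat @ params.dense_w + params.dense_b
    dense_act = np.tanh(dense_net)
    mask = None
    dense_out = dense_act
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = dropout_mask(dense_act.shape, dropout_rate, rng)
        dense_out = dense_act * mask / (1.0 - dropout_rate)
    out_net = dense_out @ params.out_w + params.out_b
    probs = softmax(out_net)
    return ForwardTrace(
        x=x_in, conv_nets=conv_nets, conv_acts=conv_acts, flat=flat,
        dense_net=dense_net, dense_act=dense_act, dropout_mask=mask,
        dropout_rate=dropout_rate, dense_out=dense_out, out_net=out_net,
        probs=probs,
    )


def backward(trace: ForwardTrace, params: CNNParameters, arch: CNNArchitecture,
             targets: np.ndarray) -> GradientSet:
    """Backpropagate the SSE-of-softmax loss; returns gradients of the
    batch-mean loss, shape-for-shape with ``params``.

    Convolutional error terms are the full correlation of the next layer's
    deltas with the flipped kernels, gated by the ReLU derivative; kernel
    gradients correlate each layer's input with its deltas, and bias
    gradients sum the deltas (weight sharing).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    probs = trace.probs
    if targets.shape != probs.shape:
        raise ValueError("targets must match the output shape")
    batch = probs.shape[0]

    # d(mean SSE)/d(probs), then through the softmax Jacobian.
    g = 2.0 * (probs - targets) / batch
    delta_out = probs * (g - np.sum(probs * g, axis=1, keepdims=True))

    grad_out_w = trace.dense_out.T @ delta_out
    grad_out_b = delta_out.sum(axis=0)

    d_dense_out = delta_out @ params.out_w.T
    if trace.dropout_mask is not None:
        d_dense_out = d_dense_out * trace.dropout_mask / (1.0 - trace.dropout_rate)
    delta_dense = d_dense_out * (1.0 - trace.dense_act ** 2)
    grad_dense_w = trace.flat.T @ delta_dense
    grad_dense_b = delta_dense.sum(axis=0)

    d_act = (delta_dense @ params.dense_w.T).reshape(trace.conv_acts[-1].shape) \
        if params.conv_kernels else None
    grad_kernels: list[np.ndarray] = [None] * len(params.conv_kernels)
    grad_biases: list[np.ndarray] = [None] * len(params.conv_biases)
    for layer in reversed(range(len(params.conv_kernels))):
        delta = d_act * (trace.conv_nets[layer] > 0)  # ReLU derivative
        inp = trace.x if layer == 0 else trace.conv_acts[layer - 1]
        k_len = params.conv_kernels[layer].shape[2]
        windows = sliding_window_view(inp, k_len, axis=2)
        grad_kernels[layer] = np.einsum("bdlk,bil->idk", windows, delta)
        grad_biases[layer] = delta.sum(axis=(0, 2))
        if layer > 0:
            pad = np.pad(delta, ((0, 0), (0, 0), (k_len - 1, k_len - 1)))
            pwin = sliding_window_view(pad, k_len, axis=2)
            flipped = params.conv_kernels[layer][:, :, ::-1]
            d_act = np.einsum("bilk,idk->bdl", pwin, flipped)
    return GradientSet(
        conv_kernels=grad_kernels, conv_biases=grad_biases,
        dense_w=grad_dense_w, dense_b=grad_dense_b,
        out_w=grad_out_w, out_b=grad_out_b,
    )


@dataclass(frozen=True)
class PoolTrace:
    mode: str
    width: int
    input_shape: tuple[int, ...]
    argmax: np.ndarray | None  # index within each window (max mode)


def pool_forward(x: np.ndarray, width: int,
                 mode: str = "max") -> tuple[np.ndarray, PoolTrace]:
    """Non-overlapping 1-D pooling along the last axis (length must divide)."""
    if mode not in ("max", "average"):
        raise ValueError("mode must be 'max' or 'average'")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] % width != 0:
        raise ValueError("pooling width must divide the input length")
    windows = x.reshape(*x.shape[:-1], x.shape[-1] // width, width)
    if mode == "max":
        out = windows.max(axis=-1)
        arg = windows.argmax(axis=-1)  # ties -> lowest index
    else:
        out = windows.mean(axis=-1)
        arg = None
    return out, PoolTrace(mode=mode, width=width, input_shape=x.shape, argmax=arg)


def pool_backward(delta_next: np.ndarray, mode: str, trace: PoolTrace) -> np.ndarray:
    """Route pooled-layer deltas back to the pre-pooling layer.

    Max pooling passes each delta intact to the position that won the
    forward max (other positions get 0); average pooling spreads each delta
    evenly over its window.
    """
    if mode != trace.mode:
        raise ValueError(f"mode {mode!r} does not match the trace ({trace.mode!r})")
    delta_next = np.asarray(delta_next, dtype=float)
    width = trace.width
    if mode == "average":
        return np.repeat(delta_next / width, width, axis=-1).reshape(trace.input_shape)
    out = np.zeros(delta_next.shape + (width,))
    np.put_along_axis(out, trace.argmax[..., None], delta_next[..., None], axis=-1)
    return out.reshape(trace.input_shape)


def lr_at(iteration: int, config: TrainingConfig) -> float:
    """Exponentially interpolated learning rate:
    ``lr_end + (lr_start - lr_end) * exp(-i / decay_speed)``."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    return config.lr_end + (config.lr_start - config.lr_end) * float(
        np.exp(-iteration / config.decay_speed)
    )


def sgd_step(params: CNNParameters, grads: GradientSet, eta: float) -> CNNParameters:
    """One gradient-descent update ``w <- w - eta * dE/dw`` for every parameter."""
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    return CNNParameters(
        conv_kernels=[k - eta * g for k, g in zip(params.conv_kernels, grads.conv_kernels)],
        conv_biases=[b - eta * g for b, g in zip(params.conv_biases, grads.conv_biases)],
        dense_w=params.dense_w - eta * grads.dense_w,
        dense_b=params.dense_b - eta * grads.dense_b,
        out_w=params.out_w - eta * grads.out_w,
        out_b=params.out_b - eta * grads.out_b,
    )


def predict(params: CNNParameters, arch: CNNArchitecture,
            features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic forward pass; labels by argmax (ties -> class 0).

    Returns (labels, probabilities); scalars for a single feature vector.
    """
    single = np.asarray(features).ndim == 1
    trace = forward(params, arch, features)
    labels = np.argmax(trace.probs, axis=1)
    if single:
        return int(labels[0]), trace.probs[0]
    return labels, trace.probs


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[np.asarray(labels, dtype=int)]
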