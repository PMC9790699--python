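"""U-Net tensor prediction: averaged DWI stacks -> six tensor components.

The network maps a repetition-averaged, [0, 1]-normalized diffusion-weighted
stack (13 channels with a b150 shell, 7 without) to the six unique components
of the diffusion tensor on the network scale (components divided by a fixed
factor of 500).

Architecture (image-to-image regression):

* each encoder level: two (3x3 convolution -> batch norm -> leaky ReLU)
  blocks followed by 2x2 max pooling;
* a two-block bottleneck at the deepest resolution;
* each decoder level: a stride-2 up-convolution whose output is concatenated
  with the matching encoder features (long skip), then batch norm + leaky
  ReLU, then two convolution blocks;
* a final 1x1 convolution with linear activation.

Training uses a mean-absolute-error (L1) loss over all output pixels and an
Adam optimizer (lr 1e-4, beta1 0.9, beta2 0.999, batch size 8); weights are
checkpointed only when the validation loss improves.

The network is implemented directly on NumPy arrays (im2col + GEMM for the
convolutions), which keeps the whole pipeline deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .io import TensorField
from .preprocess import (
    average_repetitions,
    denormalize_tensor,
    normalize_input,
    normalize_tensor,
    subset_breath_holds,
)

logger = logging.getLogger(__name__)


@dataclass
class UNetConfig:
    """Architecture and optimization hyperparameters.

    ``levels`` counts encoder/decoder (pooling) levels; the clinical-scale
    network uses 6 levels on 128x128 inputs, the desk-scale default used in
    the tests is 3 levels on 64x64 inputs with 16 top-level filters (doubling
    per level).
    """

    levels: int = 3
    base_filters: int = 16
    in_channels: int = 13
    out_channels: int = 6
    leaky_slope: float = 0.01
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 50
    tensor_norm_factor: float = 500.0
    mask_loss: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.in_channels not in (13, 7):
            logger.info("nonstandard in_channels=%d", self.in_channels)
        if self.out_channels != 6:
            raise ValueError("the tensor has six unique components; out_channels must be 6")


# ---------------------------------------------------------------------------
# layers (NumPy, with explicit backward passes)
# ---------------------------------------------------------------------------


class Param:
    """A learnable array with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding im2col on channels-last input: (N, H, W, C) -> (N*H*W, 9*C)."""
    N, H, W, C = x.shape
    xp = np.zeros((N, H + 2, W + 2, C), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    s = xp.strides
    windows = as_strided(
        xp,
        shape=(N, H, W, 3, 3, C),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
    )
    return np.ascontiguousarray(windows).reshape(N * H * W, 9 * C)


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding (channels-last)."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        std = np.sqrt(2.0 / (cin * 9))
        self.w = Param(rng.normal(0.0, std, (3, 3, cin, cout)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        col = _im2col3(x)
        out = col @ self.w.value.reshape(9 * C, self.cout) + self.b.value
        self._cache = (col, (N, H, W, C))
        return out.reshape(N, H, W, self.cout)

    def backward(self, dy):
        col, (N, H, W, C) = self._cache
        dyr = dy.reshape(-1, self.cout)
        self.b.grad += dyr.sum(axis=0)
        self.w.grad += (col.T @ dyr).reshape(self.w.value.shape)
        # input gradient = convolution of dy with the flipped, transposed kernel
        wflip = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)
        dcol = _im2col3(dy)
        dx = dcol @ np.ascontiguousarray(wflip).reshape(9 * self.cout, C)
        return dx.reshape(N, H, W, C)


class Conv1x1:
    """1x1 convolution with linear activation (the output head).

    The default init is deliberately small: the regression targets are
    normalized tensor components of magnitude well below 1, and a small
    head keeps the early optimization focused on them rather than on
    unwinding large random outputs.
    """

    def __init__(self, cin, cout, rng, dtype=np.float32, std=0.01):
        self.w = Param(rng.normal(0.0, std, (cin, cout)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        x2 = self._x.reshape(-1, self.cin)
        dyr = dy.reshape(-1, self.cout)
        self.w.grad += x2.T @ dyr
        self.b.grad += dyr.sum(axis=0)
        return (dyr @ self.w.value.T).reshape(self._x.shape)


class BatchNorm2d:
    """Batch normalization over (batch, height, width), channels-last."""

    def __init__(self, c, dtype=np.float32, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd) if train else None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, invstd = self._cache
        n = dy.shape[0] * dy.shape[1] * dy.shape[2]
        sum_dy = dy.sum(axis=(0, 1, 2))
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 1, 2))
        self.gamma.grad += sum_dy_xhat
        self.beta.grad += sum_dy
        g = self.gamma.value * invstd
        return g * (dy - sum_dy / n - xhat * (sum_dy_xhat / n))


class LeakyReLU:
    def __init__(self, slope=0.01):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2:
    """2x2 max pooling, stride 2 (channels-last); gradient split over ties."""

    def params(self):
        return []

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        xr = x.reshape(N, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4))
        self._cache = (mask, cnt, (N, H, W, C))
        return out

    def backward(self, dy):
        mask, cnt, (N, H, W, C) = self._cache
        spread = (dy / cnt)[:, :, None, :, None, :]
        return (mask * spread).reshape(N, H, W, C)


class UpConv2:
    """2x2 transposed convolution with stride 2 (non-overlapping, channels-last)."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        std = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, std, (cin, 2, 2, cout)).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        self._x2 = x.reshape(-1, C)
        self._hw = (N, H, W)
        out = self._x2 @ self.w.value.reshape(C, 4 * self.cout)
        out = out.reshape(N, H, W, 2, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(out).reshape(N, 2 * H, 2 * W, self.cout) + self.b.value

    def backward(self, dy):
        N, H, W = self._hw
        dyr = dy.reshape(N, H, 2, W, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        dyr = np.ascontiguousarray(dyr).reshape(-1, 4 * self.cout)
        self.w.grad += (self._x2.T @ dyr).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return (dyr @ self.w.value.reshape(self.cin, 4 * self.cout).T).reshape(
            N, H, W, self.cin
        )


def _conv_block(cin, cout, rng, slope, dtype):
    return [Conv3x3(cin, cout, rng, dtype), BatchNorm2d(cout, dtype), LeakyReLU(slope)]


class UNet:
    """Encoder/decoder CNN with long skip connections (see module docstring)."""

    def __init__(self, config: UNetConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        L, f0 = config.levels, config.base_filters
        slope = config.leaky_slope
        filters = [f0 * 2**l for l in range(L + 1)]

        self.encoder = []  # per level: list of blocks (pool applied separately)
        self.pools = []
        cin = config.in_channels
        for l in range(L):
            blocks = _conv_block(cin, filters[l], rng, slope, dtype) + _conv_block(
                filters[l], filters[l], rng, slope, dtype
            )
            self.encoder.append(blocks)
            self.pools.append(MaxPool2())
            cin = filters[l]
        self.bottleneck = _conv_block(cin, filters[L], rng, slope, dtype) + _conv_block(
            filters[L], filters[L], rng, slope, dtype
        )

        self.decoder = []  # per level: (upconv, post-concat blocks)
        cin = filters[L]
        for l in range(L - 1, -1, -1):
            up = UpConv2(cin, filters[l], rng, dtype)
            post = (
                [BatchNorm2d(2 * filters[l], dtype), LeakyReLU(slope)]
                + _conv_block(2 * filters[l], filters[l], rng, slope, dtype)
                + _conv_block(filters[l], filters[l], rng, slope, dtype)
            )
            self.decoder.append((up, post))
            cin = filters[l]
        self.head = Conv1x1(filters[0], config.out_channels, rng, dtype)
        self.input_hw: tuple[int, int] | None = None  # fixed on first training batch
        self.n_skip_connections = L

    # -- bookkeeping --------------------------------------------------------
    def _layers(self):
        for blocks in self.encoder:
            yield from blocks
        yield from self.pools
        yield from self.bottleneck
        for up, post in self.decoder:
            yield up
            yield from post
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def get_state(self):
        state = [p.value.copy() for p in self.params()]
        bn_state = [
            (l.running_mean.copy(), l.running_var.copy())
            for l in self._layers()
            if isinstance(l, BatchNorm2d)
        ]
        return state, bn_state

    def set_state(self, state):
        values, bn_state = state
        for p, v in zip(self.params(), values):
            p.value = v.copy()
        bns = [l for l in self._layers() if isinstance(l, BatchNorm2d)]
        for l, (m, v) in zip(bns, bn_state):
            l.running_mean = m.copy()
            l.running_var = v.copy()

    # -- forward/backward ---------------------------------------------------
    def _check_input(self, x):
        N, C, H, W = x.shape
        if C != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {C}"
            )
        d = 2**self.config.levels
        if H % d or W % d:
            raise ValueError(f"spatial size {H}x{W} not divisible by 2^levels = {d}")

    def forward(self, x, train=True):
        """Forward pass; input and output are (N, channels, H, W).

        Internally the network runs channels-last for GEMM-friendly layouts.
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._check_input(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        skips = []
        for blocks, pool in zip(self.encoder, self.pools):
            for layer in blocks:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for (up, post), skip in zip(self.decoder, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([x, skip], axis=-1)
            for layer in post:
                x = layer.forward(x, train)
        out = self.head.forward(x, train)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy):
        dy = np.ascontiguousarray(np.asarray(dy, self.dtype).transpose(0, 2, 3, 1))
        dy = self.head.backward(dy)
        # walk the decoder from the output back toward the bottleneck
        # (the decoder list is ordered deep -> shallow)
        dskips = [None] * len(self.decoder)
        for k in range(len(self.decoder) - 1, -1, -1):
            up, post = self.decoder[k]
            for layer in reversed(post):
                dy = layer.backward(dy)
            c_up = up.cout
            dup, dskip = dy[..., :c_up], dy[..., c_up:]
            dskips[k] = dskip
            dy = up.backward(np.ascontiguousarray(dup))
        for layer in reversed(self.bottleneck):
            dy = layer.backward(dy)
        for k in range(len(self.encoder) - 1, -1, -1):
            dy = self.pools[k].backward(dy)
            dy = dy + dskips[len(self.decoder) - 1 - k]
            for layer in reversed(self.encoder[k]):
                dy = layer.backward(dy)
        return np.ascontiguousarray(dy.transpose(0, 3, 1, 2))

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def predict_stack(self, x):
        """Inference on one (C, H, W) stack with frozen batch-norm statistics."""
        return self.forward(x[None], train=False)[0]


def build_unet(config: UNetConfig) -> UNet:
    """Construct the network for the given configuration."""
    return UNet(config)


# ---------------------------------------------------------------------------
# optimizer, loss, training
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value = p.value - self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def l1_loss(pred, target, weight=None):
    """Mean absolute error with its gradient.

    With ``weight`` (a broadcastable 0/1 mask), the mean runs over the
    weighted pixels only: the loss is then restricted to the myocardium,
    where the tensor targets are defined. Without it, all pixels count.
    """
    diff = pred - target
    if weight is None:
        return float(np.abs(diff).mean()), np.sign(diff) / diff.size
    w = np.broadcast_to(weight, diff.shape)
    n = w.sum()
    return float((np.abs(diff) * w).sum() / n), np.sign(diff) * (w / n)


@dataclass
class TrainResult:
    model: UNet
    history: dict = field(default_factory=dict)


def train(model: UNet, train_pairs, val_pairs, config: UNetConfig) -> TrainResult:
    """Train with L1 loss and Adam; checkpoint on validation improvement.

    ``train_pairs``/``val_pairs`` are ``(inputs, targets)`` arrays of shape
    ``(M, in_channels, H, W)`` and ``(M, 6, H, W)`` on the normalized scales
    (inputs in [0, 1], targets divided by the tensor normalization factor,
    zero outside the mask), optionally followed by a per-sample loss mask of
    shape ``(M, 1, H, W)`` (used when ``config.mask_loss`` is set; the loss
    then runs over myocardial pixels only). The returned history has one
    train/val loss per epoch; the model ends at the checkpoint with the
    lowest validation loss.
    """
    X, Y, W = _unpack_pairs(train_pairs, model.dtype)
    Xv, Yv, Wv = _unpack_pairs(val_pairs, model.dtype)
    if not config.mask_loss:
        W = Wv = None
    if len(Xv) == 0:
        raise ValueError("empty validation set")
    for arr in (X, Xv):
        if arr.shape[1] != config.in_channels:
            raise ValueError(
                f"input has {arr.shape[1]} channels, config expects {config.in_channels}"
            )
    model.input_hw = tuple(X.shape[2:])
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params(), config.learning_rate, config.beta1, config.beta2)
    history = {"train": [], "val": [], "checkpoint_epochs": []}
    best_val = np.inf
    best_state = model.get_state()
    n = len(X)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            pred = model.forward(X[idx], train=True)
            loss, dpred = l1_loss(pred, Y[idx], None if W is None else W[idx])
            model.zero_grad()
            model.backward(dpred.astype(model.dtype))
            opt.step()
            losses.append(loss)
        val_loss = evaluate_loss(model, Xv, Yv, bs, Wv)
        history["train"].append(float(np.mean(losses)))
        history["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            history["checkpoint_epochs"].append(epoch)
        logger.debug("epoch %d: train %.4f val %.4f", epoch, history["train"][-1], val_loss)
    model.set_state(best_state)
    history["best_val"] = best_val
    return TrainResult(model=model, history=history)


def _unpack_pairs(pairs, dtype):
    pairs = tuple(pairs)
    if len(pairs) == 2:
        X, Y = (np.asarray(a, dtype=dtype) for a in pairs)
        return X, Y, None
    X, Y, W = (np.asarray(a, dtype=dtype) for a in pairs)
    return X, Y, W


def evaluate_loss(model: UNet, X, Y, batch_size=8, W=None) -> float:
    """Mean L1 loss over a dataset with frozen batch-norm statistics."""
    total, count = 0.0, 0
    for start in range(0, len(X), batch_size):
        sl = slice(start, start + batch_size)
        pred = model.forward(X[sl], train=False)
        diff = np.abs(pred - Y[sl])
        if W is None:
            total += float(diff.sum())
            count += diff.size
        else:
            w = np.broadcast_to(W[sl], diff.shape)
            total += float((diff * w).sum())
            count += int(w.sum())
    return total / count


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: UNet, path) -> None:
    """Serialize weights, batch-norm statistics and the config to ``.npz``."""
    from dataclasses import asdict

    values, bn_state = model.get_state()
    arrays = {f"param_{i}": v for i, v in enumerate(values)}
    for i, (m, v) in enumerate(bn_state):
        arrays[f"bn_mean_{i}"] = m
        arrays[f"bn_var_{i}"] = v
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    arrays["input_hw"] = np.array(model.input_hw if model.input_hw else (0, 0))
    np.savez(path, **arrays)


def load_model(path) -> UNet:
    """Inverse of :func:`save_model`."""
    data = np.load(path, allow_pickle=False)
    config = UNetConfig(**json.loads(str(data["config_json"])))
    model = UNet(config)
    n_params = len(model.params())
    values = [data[f"param_{i}"] for i in range(n_params)]
    n_bn = sum(1 for l in model._layers() if isinstance(l, BatchNorm2d))
    bn_state = [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)]
    model.set_state((values, bn_state))
    hw = tuple(int(x) for x in data["input_hw"])
    model.input_hw = hw if hw != (0, 0) else None
    return model


# ---------------------------------------------------------------------------
# end-to-end prediction
# ---------------------------------------------------------------------------


def make_pair(dataset, target_field, scheme: str, config: UNetConfig):
    """Build one (normalized input stack, normalized tensor target) pair."""
    sub = subset_breath_holds(dataset, scheme)
    avg = average_repetitions(sub)
    x = normalize_input(avg.channels, dataset.mask)
    y = np.where(dataset.mask[..., None], target_field.components, 0.0)
    y = normalize_tensor(np.transpose(y, (2, 0, 1)), factor=config.tensor_norm_factor)
    return x, y


def predict(model: UNet, dataset, scheme: str) -> TensorField:
    """Subset -> average -> normalize -> forward -> denormalize -> mask.

    The output tensor field is zero outside the myocardial mask and directly
    consumable by the parameter-map derivation. Raises if the spatial size
    differs from the size the model was trained on.
    """
    sub = subset_breath_holds(dataset, scheme)
    avg = average_repetitions(sub)
    x = normalize_input(avg.channels, dataset.mask)
    if model.input_hw is not None and tuple(x.shape[1:]) != model.input_hw:
        raise ValueError(
            f"spatial size {x.shape[1:]} differs from training size {model.input_hw}"
        )
    y = model.predict_stack(x.astype(model.dtype))
    comps = denormalize_tensor(
        np.transpose(np.asarray(y, float), (1, 2, 0)),
        factor=model.config.tensor_norm_factor,
    )
    comps[~dataset.mask] = 0.0
    return TensorField(components=comps, mask=dataset.mask)
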