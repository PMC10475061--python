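"""Optic-disc localizer: an attention-gated, recurrent-residual U-Net built
from depthwise-separable convolutions, trained with Dice loss.

The building blocks exist in two forms: pure-numpy functional ops on
(channel, row, col) feature maps, used directly in tests against scalar-loop
oracles, and autograd layer modules composed into the trainable model.
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import ContractError, DataError
from .nn import tensor as T
from .phantom import LabeledImage

EPS_DICE = 1e-6


# ---------------------------------------------------------------------------
# functional building blocks (numpy in, numpy out)
# ---------------------------------------------------------------------------


def depthwise_separable_conv(x: np.ndarray, depthwise_kernels: np.ndarray,
                             pointwise_weights: np.ndarray,
                             bias: np.ndarray | None = None) -> np.ndarray:
    """Per-channel spatial convolution then 1x1 channel mixing.

    x: (C, H, W); depthwise_kernels: (C, k, k); pointwise_weights: (C_out, C).
    Same padding, stride 1.
    """
    x = np.asarray(x, dtype=np.float64)
    dk = np.asarray(depthwise_kernels, dtype=np.float64)
    pw = np.asarray(pointwise_weights, dtype=np.float64)
    if x.ndim != 3:
        raise ContractError(f"expected (C,H,W) input, got shape {x.shape}")
    if dk.ndim != 3 or dk.shape[0] != x.shape[0]:
        raise ContractError(
            f"need one depthwise kernel per channel: input {x.shape[0]} "
            f"channels, kernels {dk.shape}")
    if pw.ndim != 2 or pw.shape[1] != x.shape[0]:
        raise ContractError(
            f"pointwise weights {pw.shape} incompatible with {x.shape[0]} channels")
    xt = T.Tensor(x[None])
    y = T.depthwise_conv2d(xt, T.Tensor(dk))
    out = T.conv2d(y, T.Tensor(pw[:, :, None, None]),
                   None if bias is None else T.Tensor(bias))
    return out.data[0]


def separable_conv_param_count(c_in: int, c_out: int, k: int,
                               bias: bool = False) -> int:
    """Weights in a depthwise-separable conv: C_in*k^2 + C_in*C_out (+ C_out)."""
    n = c_in * k * k + c_in * c_out
    return n + (c_out if bias else 0)


def full_conv_param_count(c_in: int, c_out: int, k: int, bias: bool = False) -> int:
    n = c_in * c_out * k * k
    return n + (c_out if bias else 0)


@dataclass
class AttentionGateParams:
    """1x1 projections for additive attention over a skip connection."""

    W_u: np.ndarray    # (C_int, C_u)
    W_g: np.ndarray    # (C_int, C_g)
    b_g: np.ndarray    # (C_int,)
    psi: np.ndarray    # (C_int,)
    b_psi: float

    def validate(self) -> None:
        if self.W_u.shape[0] != self.W_g.shape[0]:
            raise ContractError("W_u and W_g must project to a common channel count")
        if self.psi.ndim != 1 or self.psi.shape[0] != self.W_u.shape[0]:
            raise ContractError("psi must map the intermediate channels to 1")


def attention_gate(u: np.ndarray, g: np.ndarray,
                   params: AttentionGateParams) -> np.ndarray:
    """alpha = sigmoid(psi . relu(W_u u + W_g g + b_g) + b_psi); out = alpha * u.

    u: (C_u, H, W) skip features; g: (C_g, H', W') gating signal, upsampled
    by integer factor if coarser than u.
    """
    u = np.asarray(u, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    params.validate()
    if g.shape[1:] != u.shape[1:]:
        fh, rh = divmod(u.shape[1], g.shape[1])
        fw, rw = divmod(u.shape[2], g.shape[2])
        if rh or rw or fh != fw:
            raise ContractError(
                f"cannot align gate {g.shape[1:]} to skip {u.shape[1:]}")
        g = g.repeat(fh, axis=1).repeat(fw, axis=2)
    z = (np.einsum("iu,uhw->ihw", params.W_u, u)
         + np.einsum("ig,ghw->ihw", params.W_g, g)
         + params.b_g[:, None, None])
    z = np.maximum(z, 0.0)
    q = np.einsum("i,ihw->hw", params.psi, z) + params.b_psi
    alpha = 1.0 / (1.0 + np.exp(-q))
    return alpha[None] * u


def recurrent_residual_block(x: np.ndarray, params: dict, t: int) -> np.ndarray:
    """z0 = g(x); z_s = g(x + z_{s-1}); out = proj(x) + z_t.

    g is a shared-weight depthwise-separable conv + ReLU. `params` holds
    "depthwise" (C,k,k), "pointwise" (C,C), optional "bias" (C,) and
    optional "proj" (C,C) for the 1x1 residual projection (identity if
    absent).
    """
    if t < 0:
        raise ContractError("recurrence step count must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    pw = np.asarray(params["pointwise"], dtype=np.float64)
    if t >= 1 and pw.shape[0] != pw.shape[1]:
        raise ContractError("recurrence requires a channel-preserving conv")

    def g(v):
        return np.maximum(depthwise_separable_conv(
            v, params["depthwise"], pw, params.get("bias")), 0.0)

    z = g(x)
    for _ in range(t):
        z = g(x + z)
    proj = params.get("proj")
    res = x if proj is None else np.einsum("oc,chw->ohw", proj, x)
    return res + z


def dice_loss(pred, target, eps: float = EPS_DICE):
    """1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    Accepts numpy arrays (returns float) or an autograd Tensor prediction
    (returns a Tensor for backprop). Reduces over all axes.
    """
    if isinstance(pred, T.Tensor):
        tgt = T.Tensor(np.asarray(target, dtype=pred.data.dtype))
        if pred.shape != tgt.shape:
            raise ContractError(f"shape mismatch: {pred.shape} vs {tgt.shape}")
        inter = T.tsum(T.mul(pred, tgt))
        denom = T.tsum(pred) + T.tsum(tgt)
        num = T.mul(inter, T.Tensor(2.0)) + T.Tensor(eps)
        return T.Tensor(1.0) - T.mul(num, T.power(denom + T.Tensor(eps), -1.0))
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ContractError(f"shape mismatch: {pred.shape} vs {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def soft_dice(pred, target, eps: float = EPS_DICE) -> float:
    return 1.0 - dice_loss(np.asarray(pred), np.asarray(target), eps)


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------


@dataclass
class LocalizerConfig:
    depth: int = 4
    base_filters: int = 16
    recurrence_steps: int = 1
    input_size: int = 128
    in_channels: int = 1
    learning_rate: float = 0.003
    batch_size: int = 6
    epochs: int = 100
    optimizer: str = "rmsprop"
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ContractError("depth must be >= 2")
        if self.recurrence_steps < 0:
            raise ContractError("recurrence_steps must be >= 0")
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be positive")
        if self.input_size % (2 ** (self.depth - 1)):
            raise ContractError(
                f"input_size {self.input_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LocalizerConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


class _SepConvBNRelu(nn.Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = nn.DepthwiseSeparableConv2d(cin, cout, 3, rng)
        self.bn = nn.BatchNorm(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class RecurrentResidualLayer(nn.Module):
    """Entry separable conv to the target width, then a shared-weight
    recurrent separable conv, wrapped in a residual addition."""

    def __init__(self, cin: int, cout: int, t: int, rng: np.random.Generator):
        super().__init__()
        self.t = t
        self.entry = _SepConvBNRelu(cin, cout, rng)
        self.recur = _SepConvBNRelu(cout, cout, rng)
        self.proj = (nn.Conv2d(cin, cout, 1, rng) if cin != cout else None)

    def forward(self, x):
        xe = self.entry(x)
        z = self.recur(xe)
        for _ in range(self.t):
            z = self.recur(xe + z)
        res = x if self.proj is None else self.proj(x)
        return res + z


class AttentionGateLayer(nn.Module):
    def __init__(self, c_skip: int, c_gate: int, rng: np.random.Generator):
        super().__init__()
        c_int = max(c_skip // 2, 1)
        self.w_u = nn.Conv2d(c_skip, c_int, 1, rng, bias=False)
        self.w_g = nn.Conv2d(c_gate, c_int, 1, rng, bias=True)
        self.psi = nn.Conv2d(c_int, 1, 1, rng, bias=True)

    def forward(self, u, g):
        z = nn.relu(self.w_u(u) + self.w_g(g))
        alpha = nn.sigmoid(self.psi(z))
        return T.mul(alpha, u)


class LocalizerModel(nn.Module):
    """Encoder-decoder with attention-gated skips and a sigmoid head."""

    def __init__(self, config: LocalizerConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, f, t = config.depth, config.base_filters, config.recurrence_steps
        widths = [f * 2 ** i for i in range(d)]
        enc = nn.ModuleList()
        cin = config.in_channels
        for w in widths:
            enc.append(RecurrentResidualLayer(cin, w, t, rng))
            cin = w
        self.encoder = enc
        ups, gates, dec = nn.ModuleList(), nn.ModuleList(), nn.ModuleList()
        for i in range(d - 2, -1, -1):
            ups.append(nn.Conv2d(widths[i + 1], widths[i], 1, rng))
            gates.append(AttentionGateLayer(widths[i], widths[i], rng))
            dec.append(RecurrentResidualLayer(2 * widths[i], widths[i], t, rng))
        self.upconvs = ups
        self.gates = gates
        self.decoder = dec
        self.head = nn.Conv2d(widths[0], 1, 1, rng)

    def forward(self, x: T.Tensor) -> T.Tensor:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ContractError(
                f"expected (N,{self.config.in_channels},H,W) input, got {x.shape}")
        skips = []
        h = x
        for i, block in enumerate(self.encoder):
            h = block(h)
            if i < len(self.encoder) - 1:
                skips.append(h)
                h = T.maxpool2d(h, 2)
        for up, gate, block, skip in zip(self.upconvs, self.gates,
                                         self.decoder, reversed(skips)):
            h = up(T.upsample_nearest2d(h, 2))
            gated = gate(skip, h)
            h = block(T.concat([gated, h], axis=1))
        return T.sigmoid(self.head(h))

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_localizer(config: LocalizerConfig) -> LocalizerModel:
    return LocalizerModel(config)


def split_75_20_5(n: int, rng: np.random.Generator):
    """Seeded-shuffle 75/20/5 split; floor rounding, remainder to training."""
    idx = rng.permutation(n)
    n_val = int(np.floor(0.20 * n))
    n_test = int(np.floor(0.05 * n))
    n_train = n - n_val - n_test
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def _stack_batch(data: list[LabeledImage], idx) -> tuple[np.ndarray, np.ndarray]:
    dt = T.get_default_dtype()
    x = np.stack([data[i].frame for i in idx])[:, None].astype(dt)
    y = np.stack([data[i].mask for i in idx]).astype(dt)[:, None]
    return x, y


def _batch_dice_loss(model, x, y):
    """Mean per-sample soft Dice loss over a batch (vectorized)."""
    pred = model(T.Tensor(x))
    tgt = T.Tensor(np.asarray(y, dtype=pred.data.dtype))
    axes = (1, 2, 3)
    inter = T.tsum(T.mul(pred, tgt), axis=axes)
    denom = T.tsum(pred, axis=axes) + T.tsum(tgt, axis=axes)
    num = T.mul(inter, T.Tensor(2.0)) + T.Tensor(EPS_DICE)
    frac = T.mul(num, T.power(denom + T.Tensor(EPS_DICE), -1.0))
    return T.Tensor(1.0) - T.tmean(frac)


def train_localizer(data: list[LabeledImage], config: LocalizerConfig,
                    verbose: bool = False, dtype=np.float32):
    """Train with RMSprop on Dice loss; returns (best model, history).

    Training runs in float32 by default for speed; pass float64 for exact
    cross-run comparisons against double-precision graphs.
    """
    with T.default_dtype(dtype):
        return _train_localizer(data, config, verbose)


def _train_localizer(data: list[LabeledImage], config: LocalizerConfig,
                     verbose: bool):
    config.validate()
    n = len(data)
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx, test_idx = split_75_20_5(n, rng)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise DataError(f"dataset of {n} images leaves an empty split partition")
    if len(train_idx) < config.batch_size:
        raise DataError(
            f"{len(train_idx)} training samples < batch size {config.batch_size}")
    model = build_localizer(config)
    opt = nn.optim.make(config.optimizer, model.parameters(), config.learning_rate)
    xv, yv = _stack_batch(data, val_idx)
    history = {"train_loss": [], "val_loss": [],
               "split": {"train": train_idx.tolist(), "val": val_idx.tolist(),
                         "test": test_idx.tolist()}}
    best = (np.inf, None)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_idx[j] for j in order[start:start + config.batch_size]]
            x, y = _stack_batch(data, batch)
            loss = _batch_dice_loss(model, x, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        model.eval()
        val_pred = model(T.Tensor(xv)).data
        val_loss = float(np.mean([dice_loss(val_pred[i], yv[i])
                                  for i in range(len(val_idx))]))
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_dict()))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: "
                  f"train {history['train_loss'][-1]:.4f} val {val_loss:.4f}")
    if best[1] is not None:
        model.load_state_dict(best[1])
    history["best_epoch"] = int(np.argmin(history["val_loss"]))
    model.eval()
    return model, history


def predict_probabilities(model: LocalizerModel, frame: np.ndarray) -> np.ndarray:
    """Forward pass at model resolution; probabilities at original size."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:
        from .io import rgb_to_gray
        frame = rgb_to_gray(frame)
    if frame.ndim != 2:
        raise ContractError(f"expected a 2-D frame, got shape {frame.shape}")
    size = model.config.input_size
    orig_shape = frame.shape
    if frame.shape != (size, size):
        frame = resize(frame, (size, size), order=1, anti_aliasing=False,
                       preserve_range=True)
    model.eval()
    probs = model(T.Tensor(frame[None, None])).data[0, 0]
    if orig_shape != (size, size):
        probs = resize(probs, orig_shape, order=0, anti_aliasing=False,
                       preserve_range=True)
    return probs


def predict_mask(model: LocalizerModel, frame: np.ndarray) -> np.ndarray:
    """Binary disc mask at the frame's own resolution (threshold p >= 0.5)."""
    return (predict_probabilities(model, frame) >= 0.5).astype(np.uint8)


def save_localizer(path, model: LocalizerModel) -> None:
    from .io import save_checkpoint
    save_checkpoint(path, model.state_dict(),
                    {"kind": "localizer", "config": model.config.to_dict()})


def load_localizer(path) -> LocalizerModel:
    from .io import load_checkpoint
    state, config = load_checkpoint(path)
    model = build_localizer(LocalizerConfig.from_dict(config.get("config", {})))
    model.load_state_dict(state)
    model.eval()
    return model
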