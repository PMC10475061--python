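"""SVP video classifiers: 3D Inception, 3D Dense-ResNet, 3D ResNet, LRCN and
ConvLSTM, all consuming the same 30x64x64x1 grayscale clip and emitting a
2-class softmax ("present" is class 1).

The ConvLSTM cell update, per time step:

    f = sigmoid(W_xf*x + W_hf*H + W_cf.C + b_f)
    i = sigmoid(W_xi*x + W_hi*H + W_ci.C + b_i)
    g = tanh   (W_xg*x + W_hg*H + b_g)
    C' = f.C + i.g
    o = sigmoid(W_xo*x + W_ho*H + W_co.C' + b_o)    # peephole on the NEW cell
    H' = o.tanh(C')

where * is a same-padded convolution and . an elementwise product. The
output-gate peephole reads the updated cell state by default; set
``peephole_on_previous`` for the conventional variant.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .errors import ContractError, DataError
from .nn import tensor as T
from .phantom import ABSENT, PRESENT

ARCHITECTURES = ("inception3d", "dense_resnet3d", "resnet3d", "lrcn", "convlstm")

#: per-architecture default learning rates (tuned for full-scale training)
DEFAULT_LEARNING_RATES = {
    "inception3d": 0.0003,
    "dense_resnet3d": 0.0028,
    "resnet3d": 0.002,
    "lrcn": 0.0029,
    "convlstm": 0.004,
}

INPUT_SHAPE = (30, 64, 64, 1)


# ---------------------------------------------------------------------------
# functional ConvLSTM cell (numpy in, numpy out)
# ---------------------------------------------------------------------------


@dataclass
class ConvLSTMState:
    """Hidden and cell state, both (channels, rows, cols)."""

    H: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, channels: int, height: int, width: int) -> "ConvLSTMState":
        return cls(H=np.zeros((channels, height, width)),
                   C=np.zeros((channels, height, width)))


@dataclass
class ConvLSTMWeights:
    """Kernels, elementwise peephole weights and biases of one cell.

    Input kernels W_x? have shape (C_h, C_x, k, k); state kernels W_h? are
    (C_h, C_h, k, k); peepholes W_c? broadcast against the (C_h, H, W) cell
    state; biases are (C_h,).
    """

    W_xf: np.ndarray
    W_hf: np.ndarray
    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xg: np.ndarray
    W_hg: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    W_cf: np.ndarray
    W_ci: np.ndarray
    W_co: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_g: np.ndarray
    b_o: np.ndarray

    @classmethod
    def zeros(cls, c_x: int, c_h: int, k: int = 3,
              spatial: tuple[int, int] = (1, 1)) -> "ConvLSTMWeights":
        kx = lambda: np.zeros((c_h, c_x, k, k))
        kh = lambda: np.zeros((c_h, c_h, k, k))
        pe = lambda: np.zeros((c_h,) + tuple(spatial))
        bi = lambda: np.zeros(c_h)
        return cls(W_xf=kx(), W_hf=kh(), W_xi=kx(), W_hi=kh(),
                   W_xg=kx(), W_hg=kh(), W_xo=kx(), W_ho=kh(),
                   W_cf=pe(), W_ci=pe(), W_co=pe(),
                   b_f=bi(), b_i=bi(), b_g=bi(), b_o=bi())

    @classmethod
    def random(cls, c_x: int, c_h: int, k: int, spatial: tuple[int, int],
               rng: np.random.Generator, scale: float = 0.1) -> "ConvLSTMWeights":
        w = cls.zeros(c_x, c_h, k, spatial)
        for name in ("W_xf", "W_hf", "W_xi", "W_hi", "W_xg", "W_hg",
                     "W_xo", "W_ho", "W_cf", "W_ci", "W_co"):
            arr = getattr(w, name)
            setattr(w, name, rng.normal(0, scale, arr.shape))
        return w


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(C_in,H,W) x (C_out,C_in,k,k) -> (C_out,H,W), same padding."""
    return T.conv2d(T.Tensor(np.asarray(x, dtype=np.float64)[None]),
                    T.Tensor(np.asarray(w, dtype=np.float64))).data[0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def convlstm_step(x_t: np.ndarray, state: ConvLSTMState, w: ConvLSTMWeights,
                  peephole_on_previous: bool = False) -> ConvLSTMState:
    """One ConvLSTM cell update on a single (C, H, W) input frame."""
    x_t = np.asarray(x_t, dtype=np.float64)
    H, C = state.H, state.C
    if x_t.shape[1:] != H.shape[1:]:
        raise ContractError(
            f"input spatial {x_t.shape[1:]} != state spatial {H.shape[1:]}")
    b = lambda v: v[:, None, None]
    f = _sigmoid(_conv_same(x_t, w.W_xf) + _conv_same(H, w.W_hf)
                 + w.W_cf * C + b(w.b_f))
    i = _sigmoid(_conv_same(x_t, w.W_xi) + _conv_same(H, w.W_hi)
                 + w.W_ci * C + b(w.b_i))
    g = np.tanh(_conv_same(x_t, w.W_xg) + _conv_same(H, w.W_hg) + b(w.b_g))
    c_new = f * C + i * g
    peep = C if peephole_on_previous else c_new
    o = _sigmoid(_conv_same(x_t, w.W_xo) + _conv_same(H, w.W_ho)
                 + w.W_co * peep + b(w.b_o))
    h_new = o * np.tanh(c_new)
    return ConvLSTMState(H=h_new, C=c_new)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    architecture: str = "convlstm"
    preset: str = "small"            # "small" (desk scale) or "full"
    batch_size: int = 30
    epochs: int = 100
    learning_rate: float | None = None   # None -> per-architecture default
    optimizer: str = "adam"
    dropout: float = 0.5
    peephole_on_previous: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ContractError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}")
        if self.preset not in ("small", "full"):
            raise ContractError(f"unknown preset {self.preset!r}")
        if self.batch_size < 1:
            raise ContractError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ContractError("learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ContractError("dropout must be in [0, 1)")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return DEFAULT_LEARNING_RATES[self.architecture]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SvpPrediction:
    label: str
    probability: float   # P(present)

    def __post_init__(self):
        expected = PRESENT if self.probability >= 0.5 else ABSENT
        if self.label != expected:
            raise ContractError("label inconsistent with probability >= 0.5 rule")


def _check_clip_contract(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 4:
        x = x[None]
    if x.ndim != 5 or x.shape[1:] != INPUT_SHAPE:
        raise ContractError(
            f"classifier input must be (N,)+{INPUT_SHAPE}, got {x.shape}")
    return x


# ---------------------------------------------------------------------------
# shared sub-modules
# ---------------------------------------------------------------------------


class _Conv3dBNRelu(nn.Module):
    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, k, rng)
        self.bn = nn.BatchNorm(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _Residual3dBlock(nn.Module):
    """Two 3x3x3 conv+BN stages with an additive skip (1x1x1-projected when
    the channel count changes)."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = nn.Conv3d(cin, cout, 3, rng)
        self.bn1 = nn.BatchNorm(cout)
        self.conv2 = nn.Conv3d(cout, cout, 3, rng)
        self.bn2 = nn.BatchNorm(cout)
        self.proj = nn.Conv3d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        skip = x if self.proj is None else self.proj(x)
        return nn.relu(skip + h)


def _to_ncdhw(x: T.Tensor) -> T.Tensor:
    # (N, T, H, W, 1) -> (N, 1, T, H, W), centered to [-1, 1]
    y = T.transpose(x, (0, 4, 1, 2, 3))
    return T.mul(y - T.Tensor(0.5), T.Tensor(2.0))


def _global_avg_pool(x: T.Tensor) -> T.Tensor:
    return T.tmean(x, axis=(2, 3, 4))


def _flatten(x: T.Tensor) -> T.Tensor:
    n = x.shape[0]
    return T.reshape(x, (n, int(np.prod(x.shape[1:]))))


# ---------------------------------------------------------------------------
# the five architectures
# ---------------------------------------------------------------------------


class ConvLSTMLayer(nn.Module):
    """Trainable batched ConvLSTM over a (N, T, C, H, W) sequence."""

    def __init__(self, c_in: int, c_hidden: int, k: int,
                 spatial: tuple[int, int], rng: np.random.Generator,
                 peephole_on_previous: bool = False):
        super().__init__()
        self.c_hidden = c_hidden
        self.spatial = spatial
        self.peephole_on_previous = peephole_on_previous
        dt = T.get_default_dtype()
        def conv(cin):
            # 4 gates stacked: f, i, g, o
            w = rng.normal(0, np.sqrt(2.0 / (cin * k * k)),
                           (4 * c_hidden, cin, k, k))
            return T.Tensor(w.astype(dt), requires_grad=True)
        self.w_x = conv(c_in)
        self.w_h = conv(c_hidden)
        self.bias = T.Tensor(np.zeros(4 * c_hidden, dtype=dt), requires_grad=True)
        peep = lambda: T.Tensor(
            rng.normal(0, 0.1, (c_hidden,) + spatial).astype(dt),
            requires_grad=True)
        self.w_cf = peep()
        self.w_ci = peep()
        self.w_co = peep()

    def forward(self, x: T.Tensor) -> T.Tensor:
        n, t = x.shape[0], x.shape[1]
        ch, (hh, ww) = self.c_hidden, self.spatial
        dt = x.data.dtype
        h = T.Tensor(np.zeros((n, ch, hh, ww), dtype=dt))
        c = T.Tensor(np.zeros((n, ch, hh, ww), dtype=dt))
        outputs = []
        bias = T.reshape(self.bias, (1, 4 * ch, 1, 1))
        for step in range(t):
            xt = x[:, step]
            z = T.conv2d(xt, self.w_x) + T.conv2d(h, self.w_h) + bias
            zf = z[:, 0 * ch:1 * ch]
            zi = z[:, 1 * ch:2 * ch]
            zg = z[:, 2 * ch:3 * ch]
            zo = z[:, 3 * ch:4 * ch]
            f = T.sigmoid(zf + T.mul(self.w_cf, c))
            i = T.sigmoid(zi + T.mul(self.w_ci, c))
            g = T.tanh(zg)
            c_new = T.mul(f, c) + T.mul(i, g)
            peep = c if self.peephole_on_previous else c_new
            o = T.sigmoid(zo + T.mul(self.w_co, peep))
            h = T.mul(o, T.tanh(c_new))
            c = c_new
            outputs.append(h)
        return T.stack(outputs, axis=2)   # (N, C_h, T, H, W)


class ConvLSTMClassifier(nn.Module):
    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        small = cfg.preset == "small"
        self.pool_in = 4 if small else 2          # fixed spatial downsample
        s = 64 // self.pool_in
        widths = [8] if small else [16, 16]
        self.cells = nn.ModuleList()
        self.bns = nn.ModuleList()
        cin, side = 1, s
        for w in widths:
            self.cells.append(ConvLSTMLayer(cin, w, 3, (side, side), rng,
                                            cfg.peephole_on_previous))
            self.bns.append(nn.BatchNorm(w))
            cin, side = w, side // 2              # (1,2,2) pool after each
        self.dropout = nn.Dropout(cfg.dropout, rng)
        n_feat = widths[-1] * 30 * side * side
        self.dense = nn.Dense(n_feat, 2, rng)

    def forward(self, x: T.Tensor) -> T.Tensor:
        x = _to_ncdhw(x)                           # (N,1,T,H,W)
        n, _, t, hh, ww = x.shape
        flat = T.reshape(T.transpose(x, (0, 2, 1, 3, 4)), (n * t, 1, hh, ww))
        flat = T.avgpool2d(flat, self.pool_in)
        seq = T.reshape(flat, (n, t, 1, hh // self.pool_in, ww // self.pool_in))
        h = seq
        for cell, bn in zip(self.cells, self.bns):
            h = cell(h)                            # (N,C,T,H,W)
            h = bn(T.maxpool3d(h, (1, 2, 2)))
            h = T.transpose(h, (0, 2, 1, 3, 4))    # back to (N,T,C,H,W)
        h = T.transpose(h, (0, 2, 1, 3, 4))
        return self.dense(self.dropout(_flatten(h)))


class Inception3dModule(nn.Module):
    """Parallel 1x1x1 / 3x3x3 / 5x5x5 / pooled-projection branches,
    channel-concatenated."""

    def __init__(self, cin, b1, b3, b5, bp, rng):
        super().__init__()
        self.branch1 = _Conv3dBNRelu(cin, b1, 1, rng)
        self.branch3_reduce = _Conv3dBNRelu(cin, b3, 1, rng)
        self.branch3 = _Conv3dBNRelu(b3, b3, 3, rng)
        self.branch5_reduce = _Conv3dBNRelu(cin, b5, 1, rng)
        self.branch5 = _Conv3dBNRelu(b5, b5, 5, rng)
        self.branch_pool = _Conv3dBNRelu(cin, bp, 1, rng)
        self.out_channels = b1 + b3 + b5 + bp

    def forward(self, x):
        y1 = self.branch1(x)
        y3 = self.branch3(self.branch3_reduce(x))
        y5 = self.branch5(self.branch5_reduce(x))
        yp = self.branch_pool(T.avgpool_same3d(x, 3))
        return T.concat([y1, y3, y5, yp], axis=1)


class Inception3dClassifier(nn.Module):
    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        small = cfg.preset == "small"
        self.pool_in = (1, 4, 4) if small else (1, 2, 2)
        stem_w = 8 if small else 16
        self.stem = _Conv3dBNRelu(1, stem_w, 3, rng)
        widths = [(4, 4, 2, 2)] if small else [(8, 8, 4, 4), (8, 8, 4, 4)]
        self.modules_3d = nn.ModuleList()
        cin = stem_w
        for b in widths:
            mod = Inception3dModule(cin, *b, rng)
            self.modules_3d.append(mod)
            cin = mod.out_channels
        self.dropout = nn.Dropout(cfg.dropout, rng)
        # after stem pool (2,2,2) and final (3,2,2) pool
        d, s = 15 // 3, (64 // self.pool_in[1]) // 2 // 2
        self.dense = nn.Dense(cin * d * s * s, 2, rng)

    def forward(self, x):
        x = _to_ncdhw(x)
        x = T.avgpool3d(x, self.pool_in)
        h = T.maxpool3d(self.stem(x), (2, 2, 2))
        for mod in self.modules_3d:
            h = mod(h)
        h = T.maxpool3d(h, (3, 2, 2))
        return self.dense(self.dropout(_flatten(h)))


class ResNet3dClassifier(nn.Module):
    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        small = cfg.preset == "small"
        self.pool_in = (1, 4, 4) if small else (1, 2, 2)
        w = 8 if small else 16
        self.stem = nn.Conv3d(1, w, 3, rng)
        self.stem_bn = nn.BatchNorm(w)
        blocks = 1 if small else 2
        self.blocks = nn.ModuleList(
            [_Residual3dBlock(w, w, rng) for _ in range(blocks)])
        self.dense = nn.Dense(w, 2, rng)

    def forward(self, x):
        x = _to_ncdhw(x)
        x = T.avgpool3d(x, self.pool_in)
        h = nn.relu(self.stem_bn(T.maxpool3d(self.stem(x), (2, 2, 2))))
        for block in self.blocks:
            h = block(h)
        return self.dense(_global_avg_pool(h))


class DenseResNet3dClassifier(nn.Module):
    """Dense block whose units are residual blocks: unit k consumes the
    concatenation of the stem output and every previous unit's output."""

    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        small = cfg.preset == "small"
        self.pool_in = (1, 4, 4) if small else (1, 2, 2)
        w = 8 if small else 16
        n_units = 2 if small else 3
        self.stem = nn.Conv3d(1, w, 3, rng)
        self.stem_bn = nn.BatchNorm(w)
        self.unit_in_channels = [w * (k + 1) for k in range(n_units)]
        self.units = nn.ModuleList(
            [_Residual3dBlock(cin, w, rng) for cin in self.unit_in_channels])
        self.out_channels = w * (n_units + 1)
        self.dense = nn.Dense(self.out_channels, 2, rng)

    def forward(self, x):
        x = _to_ncdhw(x)
        x = T.avgpool3d(x, self.pool_in)
        h = nn.relu(self.stem_bn(T.maxpool3d(self.stem(x), (2, 2, 2))))
        feats = [h]
        for unit in self.units:
            h_in = feats[0] if len(feats) == 1 else T.concat(feats, axis=1)
            feats.append(unit(h_in))
        merged = T.concat(feats, axis=1)
        return self.dense(_global_avg_pool(merged))


class LRCNClassifier(nn.Module):
    """Shared-weight per-frame 2-D conv feature extractor feeding an LSTM."""

    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        small = cfg.preset == "small"
        self.pool_in = 2 if small else 1
        w = 8 if small else 16
        side = 64 // self.pool_in
        self.conv1 = nn.Conv2d(1, w, 3, rng)
        self.conv2 = nn.Conv2d(w, w, 3, rng)
        self.dropout = nn.Dropout(cfg.dropout, rng)
        feat = w * (side // 4) ** 2
        self.lstm = nn.LSTMCell(feat, 32, rng)
        self.dense = nn.Dense(32, 2, rng)
        self._feat = feat

    def frame_features(self, frames: T.Tensor) -> T.Tensor:
        """(M, 1, H, W) -> (M, feat); applied with shared weights per frame."""
        h = frames
        if self.pool_in > 1:
            h = T.avgpool2d(h, self.pool_in)
        h = T.maxpool2d(nn.relu(self.conv1(h)), 2)
        h = self.dropout(h)
        h = T.maxpool2d(nn.relu(self.conv2(h)), 2)
        return _flatten(h)

    def forward(self, x):
        x = _to_ncdhw(x)                           # (N,1,T,H,W)
        n, _, t, hh, ww = x.shape
        frames = T.reshape(T.transpose(x, (0, 2, 1, 3, 4)), (n * t, 1, hh, ww))
        feats = T.reshape(self.frame_features(frames), (n, t, self._feat))
        dt = x.data.dtype
        h = T.Tensor(np.zeros((n, 32), dtype=dt))
        c = T.Tensor(np.zeros((n, 32), dtype=dt))
        for step in range(t):
            h, c = self.lstm(feats[:, step], h, c)
        return self.dense(h)


_BUILDERS = {
    "convlstm": ConvLSTMClassifier,
    "inception3d": Inception3dClassifier,
    "resnet3d": ResNet3dClassifier,
    "dense_resnet3d": DenseResNet3dClassifier,
    "lrcn": LRCNClassifier,
}


def build_classifier(cfg: ClassifierConfig) -> nn.Module:
    cfg.validate()
    with T.default_dtype(np.float32):
        model = _BUILDERS[cfg.architecture](cfg)
    model.config = cfg
    return model


def build_convlstm_classifier(cfg: ClassifierConfig) -> nn.Module:
    return build_classifier(ClassifierConfig.from_dict(
        {**cfg.to_dict(), "architecture": "convlstm"}))


def build_inception3d(cfg: ClassifierConfig) -> nn.Module:
    return build_classifier(ClassifierConfig.from_dict(
        {**cfg.to_dict(), "architecture": "inception3d"}))


def build_resnet3d(cfg: ClassifierConfig) -> nn.Module:
    return build_classifier(ClassifierConfig.from_dict(
        {**cfg.to_dict(), "architecture": "resnet3d"}))


def build_dense_resnet3d(cfg: ClassifierConfig) -> nn.Module:
    return build_classifier(ClassifierConfig.from_dict(
        {**cfg.to_dict(), "architecture": "dense_resnet3d"}))


def build_lrcn(cfg: ClassifierConfig) -> nn.Module:
    return build_classifier(ClassifierConfig.from_dict(
        {**cfg.to_dict(), "architecture": "lrcn"}))


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


def labels_to_ints(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if lab in (PRESENT, 1, True):
            out.append(1)
        elif lab in (ABSENT, 0, False):
            out.append(0)
        else:
            raise ContractError(f"unknown label {lab!r}")
    return np.array(out, dtype=np.intp)


def train_classifier(model: nn.Module, clips: np.ndarray, labels,
                     cfg: ClassifierConfig, verbose: bool = False):
    """Adam (by default) on softmax cross-entropy; returns (model, history)."""
    cfg.validate()
    x_all = _check_clip_contract(np.asarray(clips))
    y_all = labels_to_ints(labels)
    if len(y_all) != x_all.shape[0]:
        raise ContractError("clip count and label count differ")
    if x_all.shape[0] < cfg.batch_size:
        raise DataError(
            f"{x_all.shape[0]} samples < batch size {cfg.batch_size}")
    if len(np.unique(y_all)) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    with T.default_dtype(np.float32):
        x_all = x_all.astype(np.float32)
        rng = np.random.default_rng(cfg.seed)
        opt = nn.optim.make(cfg.optimizer, model.parameters(), cfg.lr)
        history = {"loss": [], "accuracy": []}
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(x_all.shape[0])
            losses, n_correct = [], 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = model(T.Tensor(x_all[idx]))
                loss = T.softmax_cross_entropy(logits, y_all[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                n_correct += int((logits.data.argmax(axis=1) == y_all[idx]).sum())
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(n_correct / len(order))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}: "
                      f"loss {history['loss'][-1]:.4f} "
                      f"acc {history['accuracy'][-1]:.3f}")
    model.eval()
    return model, history


def predict_proba(model: nn.Module, clips: np.ndarray) -> np.ndarray:
    """P(present) for a batch of clips (or a single clip)."""
    x = _check_clip_contract(np.asarray(clips)).astype(np.float32)
    model.eval()
    probs = []
    for start in range(0, x.shape[0], 32):
        logits = model(T.Tensor(x[start:start + 32]))
        probs.append(T.softmax(logits.data)[:, 1])
    return np.concatenate(probs)


def predict_svp(model: nn.Module, clip: np.ndarray) -> SvpPrediction:
    clip = np.asarray(clip)
    if clip.ndim != 4:
        raise ContractError(
            f"predict_svp expects one {INPUT_SHAPE} clip, got shape {clip.shape}")
    p = float(predict_proba(model, clip)[0])
    return SvpPrediction(label=PRESENT if p >= 0.5 else ABSENT, probability=p)


def save_classifier(path, model: nn.Module) -> None:
    from .io import save_checkpoint
    save_checkpoint(path, model.state_dict(),
                    {"kind": "classifier", "config": model.config.to_dict()})


def load_classifier(path) -> nn.Module:
    from .io import load_checkpoint
    state, config = load_checkpoint(path)
    model = build_classifier(ClassifierConfig.from_dict(config.get("config", {})))
    model.load_state_dict(state)
    model.eval()
    return model
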