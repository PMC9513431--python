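"""Genome-parameterised CNN classifier for 8 x T EEG epochs.

The architecture is fixed apart from five integer hyperparameters — the
kernel counts of three 3x3 convolutional layers (k1, k2, k3 in [1, 20]) and
the widths of the first two fully connected layers (n1, n2 in [1, 512]):

    input (1, 8, T)
    -> conv 3x3, k1, stride 1, same padding -> batch norm -> ReLU
    -> conv 3x3, k2, same padding           -> batch norm -> ReLU
    -> conv 3x3, k3, same padding           -> ReLU
    -> max pool 2x2
    -> flatten -> FC n1 -> ReLU -> dropout
    -> FC n2 -> ReLU
    -> FC 4 -> softmax

Training uses mini-batches of 16, learning rate 1e-3, categorical
cross-entropy, and Adam by default.  Everything is plain numpy (float32
internally) with hand-written backpropagation, seeded and reproducible.
Epochs are z-scored per channel before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fexbci.synthdata import EpochSet, N_CLASSES

__all__ = [
    "HyperparamGenome", "TrainConfig", "ModelSpec", "TrainedModel",
    "FIXED_COMPARISON_GENOME", "build_model_spec", "count_parameters",
    "train_model", "predict_proba",
]

GENE_BOUNDS = {"k1": (1, 20), "k2": (1, 20), "k3": (1, 20),
               "n1": (1, 512), "n2": (1, 512)}


@dataclass(frozen=True)
class HyperparamGenome:
    """The five integers the genetic algorithm searches."""

    k1: int
    k2: int
    k3: int
    n1: int
    n2: int

    def __post_init__(self):
        for name, (lo, hi) in GENE_BOUNDS.items():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"gene {name} must be an integer, got {v!r}")
            if not lo <= v <= hi:
                raise ValueError(f"gene {name}={v} outside [{lo}, {hi}]")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (int(self.k1), int(self.k2), int(self.k3), int(self.n1), int(self.n2))


#: the fixed-hyperparameter comparison network: 3 kernels per conv layer,
#: 64- and 32-unit fully connected layers
FIXED_COMPARISON_GENOME = HyperparamGenome(3, 3, 3, 64, 32)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 1e-3
    epochs: int = 100
    dropout_rate: float = 0.5
    optimizer: str = "adam"
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be adam|sgd, got {self.optimizer}")


@dataclass(frozen=True)
class ModelSpec:
    genome: HyperparamGenome
    input_shape: tuple[int, int] = (8, 4000)
    n_classes: int = N_CLASSES

    def __post_init__(self):
        H, T = self.input_shape
        if H < 2 or T < 4 or T % 2 != 0 or H % 2 != 0:
            raise ValueError(f"input shape {self.input_shape} not poolable 2x2")

    @property
    def flatten_dim(self) -> int:
        H, T = self.input_shape
        return self.genome.k3 * (H // 2) * (T // 2)

    def layer_plan(self) -> list[str]:
        g = self.genome
        return [
            f"conv3x3[{g.k1}]", "batchnorm", "relu",
            f"conv3x3[{g.k2}]", "batchnorm", "relu",
            f"conv3x3[{g.k3}]", "relu",
            "maxpool2x2", "flatten",
            f"fc[{g.n1}]", "relu", "dropout",
            f"fc[{g.n2}]", "relu",
            f"fc[{self.n_classes}]", "softmax",
        ]


def build_model_spec(genome: HyperparamGenome,
                     input_shape: tuple[int, int] = (8, 4000)) -> ModelSpec:
    """Deterministic layer plan for a genome; rejects out-of-range genes."""
    if not isinstance(genome, HyperparamGenome):
        genome = HyperparamGenome(*genome)
    return ModelSpec(genome=genome, input_shape=input_shape)


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count.

    With F = k3 * (H/2) * (T/2) the flattened width after pooling:

        conv1: 9*k1 + k1        bn1: 2*k1
        conv2: 9*k1*k2 + k2     bn2: 2*k2
        conv3: 9*k2*k3 + k3
        fc1:   F*n1 + n1
        fc2:   n1*n2 + n2
        fc3:   n2*4 + 4

    Batch-norm running statistics are buffers, not trainable parameters.
    """
    g = spec.genome
    F = spec.flatten_dim
    total = (9 * g.k1 + g.k1 + 2 * g.k1
             + 9 * g.k1 * g.k2 + g.k2 + 2 * g.k2
             + 9 * g.k2 * g.k3 + g.k3
             + F * g.n1 + g.n1
             + g.n1 * g.n2 + g.n2
             + g.n2 * spec.n_classes + spec.n_classes)
    return int(total)


# ---------------------------------------------------------------------------
# numpy layers

def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution; x (B,Cin,H,T), W (k,Cin,3,3) -> (B,k,H,T)."""
    B, Cin, H, T = x.shape
    k = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((B, H, T, k), dtype=x.dtype)
    for dy in range(3):
        for dx in range(3):
            out += np.tensordot(xp[:, :, dy:dy + H, dx:dx + T], W[:, :, dy, dx],
                                axes=([1], [1]))
    out += b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _conv2d_backward(dout, x, W):
    B, Cin, H, T = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    d = dout.transpose(0, 2, 3, 1)  # (B,H,T,k)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy:dy + H, dx:dx + T]
            dW[:, :, dy, dx] = np.tensordot(d, patch, axes=([0, 1, 2], [0, 2, 3]))
            dxp[:, :, dy:dy + H, dx:dx + T] += np.tensordot(
                d, W[:, :, dy, dx], axes=([3], [0])).transpose(0, 3, 1, 2)
    db = d.sum(axis=(0, 1, 2))
    return dxp[:, :, 1:-1, 1:-1], dW, db


class _BatchNorm:
    """Spatial batch norm over (B,H,T) per feature map."""

    def __init__(self, k, dtype=np.float32, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(k, dtype=dtype)
        self.beta = np.zeros(k, dtype=dtype)
        self.rmean = np.zeros(k, dtype=dtype)
        self.rvar = np.ones(k, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.rmean = self.momentum * self.rmean + (1 - self.momentum) * mean
            self.rvar = self.momentum * self.rvar + (1 - self.momentum) * var
        else:
            mean, var = self.rmean, self.rvar
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._cache
        N = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (inv[None, :, None, None] / N) * (
            N * dxhat
            - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None])
        return dx, dgamma, dbeta


def _maxpool(x):
    """2x2/2 max pool on (B,k,H,T); returns pooled, argmax index cache."""
    B, k, H, T = x.shape
    xr = x.reshape(B, k, H // 2, 2, T // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xr.reshape(B, k, H // 2, T // 2, 4)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout, idx, in_shape):
    B, k, H, T = in_shape
    dxw = np.zeros((B, k, H // 2, T // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxw, idx[..., None], dout[..., None], axis=-1)
    dx = dxw.reshape(B, k, H // 2, T // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(B, k, H, T)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """Parameter container + forward/backward passes for one ModelSpec."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 dtype=np.float32):
        g = spec.genome
        self.spec = spec
        self.dtype = dtype

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

        F = spec.flatten_dim
        self.params = {
            "W1": he((g.k1, 1, 3, 3), 9), "b1": np.zeros(g.k1, dtype),
            "W2": he((g.k2, g.k1, 3, 3), 9 * g.k1), "b2": np.zeros(g.k2, dtype),
            "W3": he((g.k3, g.k2, 3, 3), 9 * g.k2), "b3": np.zeros(g.k3, dtype),
            "Wf1": he((F, g.n1), F), "bf1": np.zeros(g.n1, dtype),
            "Wf2": he((g.n1, g.n2), g.n1), "bf2": np.zeros(g.n2, dtype),
            "Wf3": he((g.n2, spec.n_classes), g.n2),
            "bf3": np.zeros(spec.n_classes, dtype),
        }
        self.bn1 = _BatchNorm(g.k1, dtype)
        self.bn2 = _BatchNorm(g.k2, dtype)

    def forward(self, x, training=False, dropout_rate=0.0, rng=None):
        p = self.params
        c = {}
        c["x"] = x
        a1 = _conv2d(x, p["W1"], p["b1"])
        h1 = self.bn1.forward(a1, training)
        r1 = np.maximum(h1, 0)
        c["r1_mask"], c["r1"] = h1 > 0, r1
        a2 = _conv2d(r1, p["W2"], p["b2"])
        h2 = self.bn2.forward(a2, training)
        r2 = np.maximum(h2, 0)
        c["r2_mask"], c["r2"] = h2 > 0, r2
        a3 = _conv2d(r2, p["W3"], p["b3"])
        r3 = np.maximum(a3, 0)
        c["r3_mask"], c["r3"] = a3 > 0, r3
        pooled, idx = _maxpool(r3)
        c["pool_idx"], c["pool_in_shape"] = idx, r3.shape
        flat = pooled.reshape(x.shape[0], -1)
        c["flat"] = flat
        z1 = flat @ p["Wf1"] + p["bf1"]
        f1 = np.maximum(z1, 0)
        c["f1_mask"] = z1 > 0
        if training and dropout_rate > 0:
            keep = (rng.random(f1.shape) >= dropout_rate).astype(self.dtype)
            f1 = f1 * keep / (1.0 - dropout_rate)
            c["drop_mask"] = keep / (1.0 - dropout_rate)
        else:
            c["drop_mask"] = None
        c["f1"] = f1
        z2 = f1 @ p["Wf2"] + p["bf2"]
        f2 = np.maximum(z2, 0)
        c["f2_mask"], c["f2"] = z2 > 0, f2
        logits = f2 @ p["Wf3"] + p["bf3"]
        c["probs"] = _softmax(logits)
        self._cache = c
        return c["probs"]

    def backward(self, y_onehot):
        """Cross-entropy gradient through the cached forward pass."""
        p, c = self.params, self._cache
        B = y_onehot.shape[0]
        grads = {}
        dz = (c["probs"] - y_onehot) / B
        grads["Wf3"] = c["f2"].T @ dz
        grads["bf3"] = dz.sum(axis=0)
        df2 = dz @ p["Wf3"].T
        df2 *= c["f2_mask"]
        grads["Wf2"] = c["f1"].T @ df2
        grads["bf2"] = df2.sum(axis=0)
        df1 = df2 @ p["Wf2"].T
        if c["drop_mask"] is not None:
            df1 *= c["drop_mask"]
        df1 *= c["f1_mask"]
        grads["Wf1"] = c["flat"].T @ df1
        grads["bf1"] = df1.sum(axis=0)
        dflat = df1 @ p["Wf1"].T
        B_, k3 = c["pool_in_shape"][0], c["pool_in_shape"][1]
        H2, T2 = c["pool_in_shape"][2] // 2, c["pool_in_shape"][3] // 2
        dpool = dflat.reshape(B_, k3, H2, T2)
        dr3 = _maxpool_backward(dpool, c["pool_idx"], c["pool_in_shape"])
        dr3 *= c["r3_mask"]
        dr2, grads["W3"], grads["b3"] = _conv2d_backward(dr3, c["r2"], p["W3"])
        dr2 *= c["r2_mask"]
        dh2, grads["g2"], grads["be2"] = self.bn2.backward(dr2)
        dr1, grads["W2"], grads["b2"] = _conv2d_backward(dh2, c["r1"], p["W2"])
        dr1 *= c["r1_mask"]
        dh1, grads["g1"], grads["be1"] = self.bn1.backward(dr1)
        _, grads["W1"], grads["b1"] = _conv2d_backward(dh1, c["x"], p["W1"])
        return grads

    def trainables(self):
        items = dict(self.params)
        items["g1"], items["be1"] = self.bn1.gamma, self.bn1.beta
        items["g2"], items["be2"] = self.bn2.gamma, self.bn2.beta
        return items


class _Adam:
    def __init__(self, keys, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, trainables, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            trainables[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, keys, lr):
        self.lr = lr

    def step(self, trainables, grads):
        for k, g in grads.items():
            trainables[k] -= self.lr * g


@dataclass
class TrainedModel:
    """A fitted network plus its per-epoch loss/accuracy history."""

    spec: ModelSpec
    cfg: TrainConfig
    network: _Network
    history: pd.DataFrame = field(repr=False)

    def predict_proba(self, epochs: EpochSet) -> np.ndarray:
        return predict_proba(self, epochs)

    def predict(self, epochs: EpochSet) -> np.ndarray:
        return self.predict_proba(epochs).argmax(axis=1)


def _prepare(epochs: EpochSet, spec: ModelSpec, dtype=np.float32) -> np.ndarray:
    """Per-epoch z-scoring over all channels jointly, shaped (n, 1, H, T).

    Normalising each epoch as a whole removes inter-epoch gain drift while
    preserving the relative power between channels, which carries the
    class-discriminative topography (per-channel scaling would erase it).
    """
    H, T = spec.input_shape
    if epochs.data.shape[1:] != (H, T):
        raise ValueError(
            f"epoch shape {epochs.data.shape[1:]} does not match model input {(H, T)}")
    x = epochs.data.astype(dtype)
    mean = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return ((x - mean) / sd)[:, None, :, :]


def train_model(spec: ModelSpec, train: EpochSet, valid: EpochSet | None,
                cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Mini-batch training with the fixed protocol (batch 16, lr 1e-3,
    cross-entropy); returns the model with its loss history.

    Raises if any of the four classes is absent from the training set or if
    the loss turns non-finite (with the offending batch in the message).
    """
    present = set(np.unique(train.labels).tolist())
    missing = set(range(spec.n_classes)) - present
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training set")

    rng = np.random.default_rng(cfg.seed)
    net = _Network(spec, rng)
    opt_cls = _Adam if cfg.optimizer == "adam" else _SGD
    opt = opt_cls(list(net.trainables().keys()), cfg.learning_rate)

    X = _prepare(train, spec)
    y = train.labels
    Y = np.eye(spec.n_classes, dtype=net.dtype)[y]
    Xv = _prepare(valid, spec) if valid is not None else None

    n = X.shape[0]
    rows = []
    for ep in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            bi = order[start:start + cfg.batch_size]
            probs = net.forward(X[bi], training=True,
                                dropout_rate=cfg.dropout_rate, rng=rng)
            eps = 1e-12
            loss = -np.log(probs[np.arange(len(bi)), y[bi]] + eps).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {ep}, batch starting {start}")
            losses.append(float(loss))
            correct += int((probs.argmax(axis=1) == y[bi]).sum())
            grads = net.backward(Y[bi])
            opt.step(net.trainables(), grads)
        row = {"epoch": ep, "train_loss": float(np.mean(losses)),
               "train_acc": correct / n}
        if Xv is not None:
            vp = _predict_batched(net, Xv)
            vl = -np.log(vp[np.arange(len(valid.labels)), valid.labels] + 1e-12).mean()
            row["val_loss"] = float(vl)
            row["val_acc"] = float((vp.argmax(axis=1) == valid.labels).mean())
        rows.append(row)
    return TrainedModel(spec=spec, cfg=cfg, network=net,
                        history=pd.DataFrame(rows))


def _predict_batched(net: _Network, X: np.ndarray, batch: int = 64) -> np.ndarray:
    out = np.empty((X.shape[0], net.spec.n_classes), dtype=np.float64)
    for start in range(0, X.shape[0], batch):
        out[start:start + batch] = net.forward(X[start:start + batch],
                                               training=False)
    return out


def predict_proba(model: TrainedModel, epochs: EpochSet) -> np.ndarray:
    """Class probabilities (n, 4); inference mode, dropout disabled.

    Rows are renormalised in float64 so each sums to 1 within 1e-6.
    """
    X = _prepare(epochs, model.spec)
    probs = _predict_batched(model.network, X)
    return probs / probs.sum(axis=1, keepdims=True)
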