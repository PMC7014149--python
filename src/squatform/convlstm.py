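"""Deep-learning branch: a CNN-LSTM on raw repetition matrices.

The network consumes a repetition as an R x 40 image (R = 6 rows per
sensor, placements stacked row-wise for multi-sensor input) and emits a
probability distribution over the six squat forms:

    conv(3x3, 8, stride 1, same, ReLU)  -> maxpool(1x2) -> dropout
    conv(3x3, 16, stride 1, same, ReLU) -> maxpool(1x2) -> dropout
    conv(3x3, 32, stride 1, same, ReLU) -> maxpool(1x2) -> dropout
    reshape to a 5-step sequence of (R*32)-dim vectors (time-major)
    LSTM(64), final hidden state -> dropout
    dense(128, ReLU) -> dropout -> dense(6) -> softmax

Pooling acts on the time axis only (1x2): three 2x2 poolings are
impossible on a 6-row input, so the 40 time points are halved three
times to 5 LSTM steps while the sensor-axis rows are preserved.
Channels double per conv layer from 8 to 32.  Training minimizes mean
cross-entropy with Adam (learning rate 0.001); inputs are standardized
per axis row using training-set statistics stored with the model.

Everything is plain NumPy with hand-derived backpropagation (im2col
convolutions, BPTT through the 5-step LSTM), which keeps the branch
dependency-free and bit-reproducible under a fixed seed.  For
regularization, three identical networks are trained with different
weight initializations and input orderings; predictions average the
three softmax distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid

from .core import FORM_ORDER, PLACEMENT_ORDER, SensorPlacement
from .segment import Repetition

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Network",
    "EnsembleModel",
    "build_network",
    "train_network",
    "train_ensemble",
    "predict_network",
    "predict_ensemble",
    "stack_dataset",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``input_rows`` is 6 per placement; ``input_cols`` must be divisible
    by 8 (the time axis is halved by each of the three poolings).
    ``dropout_rate`` applies after every pooling, after the LSTM state,
    and after the hidden dense layer.  With five dropout sites the
    survival of a signal path is rate-compounded — five sites at 0.1
    retain 0.9^5 ~ 0.59 of paths, comparable to one classic 0.5 dense
    dropout — so the per-site default is 0.1; 0.5 at every site leaves
    the network unable to fit even its training data.
    """

    input_rows: int = 6
    input_cols: int = 40
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    lstm_cells: int = 64
    dense_width: int = 128
    n_classes: int = 6
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3 or any(
            b != 2 * a for a, b in zip(self.conv_channels, self.conv_channels[1:])
        ):
            raise ValueError("conv_channels must double across three layers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults: Adam, lr 0.001, 500 epochs)."""

    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# Layers (forward + backward).

def _conv_forward(x, W, b):
    B, C, R, T = x.shape
    O = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,R,T,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * R * T, C * 9
    )
    out = cols @ W.reshape(O, -1).T + b
    out = out.reshape(B, R, T, O).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, W)


def _conv_backward(dout, cache):
    cols, xshape, W = cache
    B, C, R, T = xshape
    O = W.shape[0]
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, O)
    dW = (dmat.T @ cols).reshape(W.shape)
    db = dmat.sum(axis=0)
    dcols = (dmat @ W.reshape(O, -1)).reshape(B, R, T, C, 3, 3)
    dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B,C,R,T,3,3)
    dxp = np.zeros((B, C, R + 2, T + 2), dtype=dout.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + R, j : j + T] += dcols[:, :, :, :, i, j]
    return dxp[:, :, 1 : R + 1, 1 : T + 1], dW, db


def _pool_forward(x):
    B, C, R, T = x.shape
    x2 = x.reshape(B, C, R, T // 2, 2)
    a, b = x2[..., 0], x2[..., 1]
    first = a >= b  # ties take the earlier sample
    return np.where(first, a, b), (first, x.shape)


def _pool_backward(dout, cache):
    first, xshape = cache
    B, C, R, T = xshape
    dx2 = np.zeros((B, C, R, T // 2, 2), dtype=dout.dtype)
    dx2[..., 0] = np.where(first, dout, 0)
    dx2[..., 1] = np.where(first, 0, dout)
    return dx2.reshape(B, C, R, T)


def _dropout_forward(x, rate, rng, train):
    if not train or rate == 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * mask, mask


def _lstm_forward(x, Wx, Wh, b):
    """x: (B, S, D).  Returns final hidden state and BPTT cache."""
    B, S, D = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    steps = []
    for t in range(S):
        xt = x[:, t]
        a = xt @ Wx + h @ Wh + b
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        steps.append((xt, h_prev, c_prev, i, f, g, o, c))
    return h, (steps, Wx, Wh, x.shape)


def _lstm_backward(dh_last, cache):
    steps, Wx, Wh, xshape = cache
    B, S, D = xshape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=Wx.dtype)
    dx = np.zeros(xshape, dtype=Wx.dtype)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for t in reversed(range(S)):
        xt, h_prev, c_prev, i, f, g, o, c = steps[t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di, df, dg = dc * g, dc * c_prev, dc * i
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += xt.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dx[:, t] = da @ Wx.T
        dh = da @ Wh.T
        dc = dc * f
    return dx, dWx, dWh, db


# ---------------------------------------------------------------------------
# Network.

class Network:
    """A seeded CNN-LSTM with explicit parameters and gradients."""

    def __init__(self, spec: NetworkSpec, rng_seed: int = 0):
        if spec.input_cols % 8 != 0:
            raise ValueError(
                "input_cols must be divisible by 8 (three time-axis halvings)"
            )
        self.spec = spec
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        R, H = spec.input_rows, spec.lstm_cells
        lstm_in = R * spec.conv_channels[-1]
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for li, c_out in enumerate(spec.conv_channels, start=1):
            p[f"convW{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / (c_in * 9)), (c_out, c_in, 3, 3)
            )
            p[f"convb{li}"] = np.zeros(c_out)
            c_in = c_out
        lim = np.sqrt(6.0 / (lstm_in + H))
        p["lstmWx"] = rng.uniform(-lim, lim, (lstm_in, 4 * H))
        lim = np.sqrt(6.0 / (2 * H))
        p["lstmWh"] = rng.uniform(-lim, lim, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        p["lstmb"] = b
        p["denseW1"] = rng.normal(0.0, np.sqrt(2.0 / H), (H, spec.dense_width))
        p["denseb1"] = np.zeros(spec.dense_width)
        lim = np.sqrt(6.0 / (spec.dense_width + spec.n_classes))
        p["denseW2"] = rng.uniform(
            -lim, lim, (spec.dense_width, spec.n_classes)
        )
        p["denseb2"] = np.zeros(spec.n_classes)
        self.params = {k: v.astype(_DTYPE) for k, v in p.items()}
        # Per-row standardization constants, set at training time.
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    # -- forward ----------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.spec.input_rows, self.spec.input_cols):
            raise ValueError(
                f"input shape {x.shape[1:]} != "
                f"({self.spec.input_rows}, {self.spec.input_cols})"
            )
        return x

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return x
        return (x - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        """Softmax probabilities (B, n_classes) and a backprop cache."""
        p = self.params
        rate = self.spec.dropout_rate
        h = x[:, None]  # (B, 1, R, T)
        caches = []
        for li in range(1, 4):
            z, cc = _conv_forward(h, p[f"convW{li}"], p[f"convb{li}"])
            relu_mask = z > 0
            z = z * relu_mask
            z, pc = _pool_forward(z)
            z, dm = _dropout_forward(z, rate, rng, train)
            caches.append((cc, relu_mask, pc, dm))
            h = z
        B, C, R, S = h.shape  # S = input_cols / 8 time steps
        seq = np.ascontiguousarray(h.transpose(0, 3, 2, 1)).reshape(B, S, R * C)
        hN, lstm_cache = _lstm_forward(seq, p["lstmWx"], p["lstmWh"], p["lstmb"])
        hN, dm_l = _dropout_forward(hN, rate, rng, train)
        z1 = hN @ p["denseW1"] + p["denseb1"]
        m1 = z1 > 0
        a1 = z1 * m1
        a1d, dm_d = _dropout_forward(a1, rate, rng, train)
        logits = a1d @ p["denseW2"] + p["denseb2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (x, caches, (C, R, S), lstm_cache, dm_l, hN, m1, a1d, dm_d, probs)
        return probs, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, rng=None, train=True):
        """Mean cross-entropy and gradients for a (standardized) batch."""
        p = self.params
        probs, cache = self.forward(x, train=train, rng=rng)
        (_, caches, (C, R, S), lstm_cache, dm_l, hN, m1, a1d, dm_d, _) = cache
        B = x.shape[0]
        eps = np.finfo(_DTYPE).tiny
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["denseW2"] = a1d.T @ dlogits
        grads["denseb2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["denseW2"].T
        if dm_d is not None:
            da1 = da1 * dm_d
        dz1 = da1 * m1
        grads["denseW1"] = hN.T @ dz1
        grads["denseb1"] = dz1.sum(axis=0)
        dhN = dz1 @ p["denseW1"].T
        if dm_l is not None:
            dhN = dhN * dm_l
        dseq, dWx, dWh, db = _lstm_backward(dhN, lstm_cache)
        grads["lstmWx"], grads["lstmWh"], grads["lstmb"] = dWx, dWh, db
        dh = np.ascontiguousarray(
            dseq.reshape(B, S, R, C).transpose(0, 3, 2, 1)
        )  # (B,C,R,S)
        for li in range(3, 0, -1):
            cc, relu_mask, pc, dm = caches[li - 1]
            if dm is not None:
                dh = dh * dm
            dh = _pool_backward(dh, pc)
            dh = dh * relu_mask
            dh, dW, db_ = _conv_backward(dh, cc)
            grads[f"convW{li}"] = dW
            grads[f"convb{li}"] = db_
        return loss, grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities (standardization applied)."""
        x = self._standardize(self._check_input(x))
        probs, _ = self.forward(x, train=False)
        return probs


def build_network(spec: NetworkSpec, rng_seed: int = 0) -> Network:
    """Construct a network with seeded parameter initialization."""
    return Network(spec, rng_seed)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + eps)).astype(
                params[k].dtype
            )


def _encode_labels(labels) -> np.ndarray:
    idx = {f: i for i, f in enumerate(FORM_ORDER)}
    idx.update({f.value: i for i, f in enumerate(FORM_ORDER)})
    return np.array([idx[l] for l in labels], dtype=np.int64)


def train_network(
    net: Network,
    X: np.ndarray,
    labels,
    cfg: TrainConfig = TrainConfig(),
    record_history: bool = False,
):
    """Train in place with Adam on shuffled mini-batches.

    ``X`` is (N, R, T); ``labels`` are SquatForm values, strings, or
    integer class indices.  Standardization constants (per axis row,
    over the training set) are computed here and stored on the model.
    Returns the network (and the per-epoch loss history if requested).
    """
    X = np.asarray(X, dtype=_DTYPE)
    if X.ndim != 3 or X.shape[1:] != (net.spec.input_rows, net.spec.input_cols):
        raise ValueError(
            f"training data shape {X.shape[1:]} does not match spec "
            f"({net.spec.input_rows}, {net.spec.input_cols})"
        )
    y = (
        np.asarray(labels, dtype=np.int64)
        if np.issubdtype(np.asarray(labels).dtype, np.integer)
        else _encode_labels(labels)
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    if net.norm_mean is None:
        mu = X.mean(axis=(0, 2))
        sd = X.std(axis=(0, 2))
        sd[sd == 0] = 1.0
        net.norm_mean = mu.astype(_DTYPE)
        net.norm_std = sd.astype(_DTYPE)
    Xs = net._standardize(X)

    rng = np.random.default_rng(cfg.rng_seed)
    opt = _Adam(net.params, cfg.learning_rate)
    n = len(Xs)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            loss, grads = net.loss_and_grads(Xs[b], y[b], rng=rng, train=True)
            opt.step(net.params, grads)
            epoch_loss += loss * len(b)
        history.append(epoch_loss / n)
    return (net, history) if record_history else net


@dataclass
class EnsembleModel:
    """Three identically specified networks trained with distinct seeds."""

    members: list[Network] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError("ensemble must have exactly 3 members")
        specs = {m.spec for m in self.members}
        if len(specs) != 1:
            raise ValueError("ensemble members must share one NetworkSpec")


# ---------------------------------------------------------------------------
# Joint (vectorized) 3-member training: parameters carry a leading
# member axis M and every matmul is batched, so training the three
# ensemble members costs far less than three sequential runs while
# keeping the member semantics (distinct initializations, distinct
# input orderings) unchanged.

# Joint layers use a channels-last activation layout (M, B, R, T, C):
# the im2col matrices then reshape out of the conv output with no
# transposes, which matters on one CPU.

def _conv_forward_m(x, W, b):
    M, B, R, T, C = x.shape
    O = W.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (M,B,R,T,C,3,3)
    cols = win.reshape(M, B * R * T, C * 9)  # copies into (C,ki,kj) order
    Wmat = W.reshape(M, O, C * 9).transpose(0, 2, 1)
    out = np.matmul(cols, Wmat) + b[:, None, :]
    return out.reshape(M, B, R, T, O), (cols, x.shape, W)


def _conv_backward_m(dout, cache):
    cols, xshape, W = cache
    M, B, R, T, C = xshape
    O = W.shape[1]
    dmat = dout.reshape(M, B * R * T, O)
    dW = np.matmul(cols.transpose(0, 2, 1), dmat).transpose(0, 2, 1)
    db = dmat.sum(axis=1)
    dcols = np.matmul(dmat, W.reshape(M, O, C * 9)).reshape(
        M, B, R, T, C, 3, 3
    )
    dxp = np.zeros((M, B, R + 2, T + 2, C), dtype=dout.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + R, j : j + T, :] += dcols[..., i, j]
    return dxp[:, :, 1 : R + 1, 1 : T + 1, :], dW.reshape(W.shape), db


def _pool_forward_m(x):
    M, B, R, T, C = x.shape
    x2 = x.reshape(M, B, R, T // 2, 2, C)
    a, b = x2[:, :, :, :, 0], x2[:, :, :, :, 1]
    first = a >= b  # ties take the earlier sample
    return np.where(first, a, b), (first, x.shape)


def _pool_backward_m(dout, cache):
    first, xshape = cache
    M, B, R, T, C = xshape
    dx2 = np.zeros((M, B, R, T // 2, 2, C), dtype=dout.dtype)
    dx2[:, :, :, :, 0] = np.where(first, dout, 0)
    dx2[:, :, :, :, 1] = np.where(first, 0, dout)
    return dx2.reshape(M, B, R, T, C)


def _lstm_forward_m(x, Wx, Wh, b):
    M, B, S, D = x.shape
    H = Wh.shape[1]
    h = np.zeros((M, B, H), dtype=x.dtype)
    c = np.zeros((M, B, H), dtype=x.dtype)
    steps = []
    for t in range(S):
        xt = x[:, :, t]
        a = np.matmul(xt, Wx) + np.matmul(h, Wh) + b[:, None, :]
        i = sigmoid(a[..., :H])
        f = sigmoid(a[..., H : 2 * H])
        g = np.tanh(a[..., 2 * H : 3 * H])
        o = sigmoid(a[..., 3 * H :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        steps.append((xt, h_prev, c_prev, i, f, g, o, c))
    return h, (steps, Wx, Wh, x.shape)


def _lstm_backward_m(dh_last, cache):
    steps, Wx, Wh, xshape = cache
    M, B, S, D = xshape
    H = Wh.shape[1]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros((M, 4 * H), dtype=Wx.dtype)
    dx = np.zeros(xshape, dtype=Wx.dtype)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for t in reversed(range(S)):
        xt, h_prev, c_prev, i, f, g, o, c = steps[t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di, df, dg = dc * g, dc * c_prev, dc * i
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=-1,
        )
        dWx += np.matmul(xt.transpose(0, 2, 1), da)
        dWh += np.matmul(h_prev.transpose(0, 2, 1), da)
        db += da.sum(axis=1)
        dx[:, :, t] = np.matmul(da, Wx.transpose(0, 2, 1))
        dh = np.matmul(da, Wh.transpose(0, 2, 1))
        dc = dc * f
    return dx, dWx, dWh, db


def _joint_loss_and_grads(params, spec, x, y, rng, train=True):
    """Cross-entropy and gradients for 3 members at once.

    x is (M, B, rows, cols) — each member sees its own mini-batch —
    and y is (M, B) integer labels.
    """
    M, B = x.shape[:2]
    rate = spec.dropout_rate

    def dropout(z):
        if not train or rate == 0.0:
            return z, None
        mask = (rng.random(z.shape) >= rate).astype(z.dtype) / (1.0 - rate)
        return z * mask, mask

    h = x[..., None]  # (M,B,R,T,1) channels-last
    caches = []
    for li in range(1, 4):
        z, cc = _conv_forward_m(h, params[f"convW{li}"], params[f"convb{li}"])
        relu_mask = z > 0
        z = z * relu_mask
        z, pc = _pool_forward_m(z)
        z, dm = dropout(z)
        caches.append((cc, relu_mask, pc, dm))
        h = z
    Mx, Bx, R, S, C = h.shape
    seq = np.ascontiguousarray(h.transpose(0, 1, 3, 2, 4)).reshape(
        M, B, S, R * C
    )
    hN, lstm_cache = _lstm_forward_m(
        seq, params["lstmWx"], params["lstmWh"], params["lstmb"]
    )
    hN, dm_l = dropout(hN)
    z1 = np.matmul(hN, params["denseW1"]) + params["denseb1"][:, None, :]
    m1 = z1 > 0
    a1 = z1 * m1
    a1d, dm_d = dropout(a1)
    logits = np.matmul(a1d, params["denseW2"]) + params["denseb2"][:, None, :]
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=-1, keepdims=True)

    eps = np.finfo(_DTYPE).tiny
    mm = np.arange(M)[:, None]
    bb = np.arange(B)[None, :]
    losses = -np.log(probs[mm, bb, y] + eps).mean(axis=1)

    grads = {}
    dlogits = probs.copy()
    dlogits[mm, bb, y] -= 1.0
    dlogits /= B
    grads["denseW2"] = np.matmul(a1d.transpose(0, 2, 1), dlogits)
    grads["denseb2"] = dlogits.sum(axis=1)
    da1 = np.matmul(dlogits, params["denseW2"].transpose(0, 2, 1))
    if dm_d is not None:
        da1 = da1 * dm_d
    dz1 = da1 * m1
    grads["denseW1"] = np.matmul(hN.transpose(0, 2, 1), dz1)
    grads["denseb1"] = dz1.sum(axis=1)
    dhN = np.matmul(dz1, params["denseW1"].transpose(0, 2, 1))
    if dm_l is not None:
        dhN = dhN * dm_l
    dseq, dWx, dWh, db = _lstm_backward_m(dhN, lstm_cache)
    grads["lstmWx"], grads["lstmWh"], grads["lstmb"] = dWx, dWh, db
    dh = dseq.reshape(M, B, S, R, C).transpose(0, 1, 3, 2, 4)
    for li in range(3, 0, -1):
        cc, relu_mask, pc, dm = caches[li - 1]
        if dm is not None:
            dh = dh * dm
        dh = _pool_backward_m(dh, pc)
        dh = dh * relu_mask
        dh, dW, db_ = _conv_backward_m(dh, cc)
        grads[f"convW{li}"] = dW
        grads[f"convb{li}"] = db_
    return losses, grads


def train_ensemble(
    spec: NetworkSpec, X: np.ndarray, labels, cfg: TrainConfig = TrainConfig()
) -> EnsembleModel:
    """Train the 3-member ensemble (seeds seed, seed+1, seed+2).

    Each member gets its own weight initialization and its own
    mini-batch shuffling of the same training data; the three are
    optimized jointly through batched linear algebra (see the
    member-axis layer functions above), which is substantially faster
    than three sequential runs on one CPU.
    """
    X = np.asarray(X, dtype=_DTYPE)
    if X.ndim != 3 or X.shape[1:] != (spec.input_rows, spec.input_cols):
        raise ValueError(
            f"training data shape {X.shape[1:]} does not match spec "
            f"({spec.input_rows}, {spec.input_cols})"
        )
    y = (
        np.asarray(labels, dtype=np.int64)
        if np.issubdtype(np.asarray(labels).dtype, np.integer)
        else _encode_labels(labels)
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")

    members = [build_network(spec, rng_seed=cfg.rng_seed + k) for k in range(3)]
    mu = X.mean(axis=(0, 2)).astype(_DTYPE)
    sd = X.std(axis=(0, 2))
    sd[sd == 0] = 1.0
    sd = sd.astype(_DTYPE)
    for net in members:
        net.norm_mean, net.norm_std = mu, sd
    Xs = (X - mu[None, :, None]) / sd[None, :, None]

    params = {
        k: np.stack([net.params[k] for net in members])
        for k in members[0].params
    }
    order_rngs = [
        np.random.default_rng(cfg.rng_seed + 100 + k) for k in range(3)
    ]
    drop_rng = np.random.default_rng(cfg.rng_seed + 200)
    opt = _Adam(params, cfg.learning_rate)
    n = len(Xs)
    for _ in range(cfg.epochs):
        orders = np.stack([r.permutation(n) for r in order_rngs])
        for s in range(0, n, cfg.batch_size):
            idx = orders[:, s : s + cfg.batch_size]
            _, grads = _joint_loss_and_grads(
                params, spec, Xs[idx], y[idx], rng=drop_rng, train=True
            )
            opt.step(params, grads)
    for k, net in enumerate(members):
        net.params = {name: np.ascontiguousarray(v[k]) for name, v in params.items()}
    return EnsembleModel(members=members)


def predict_network(net: Network, x: np.ndarray) -> np.ndarray:
    """Single-network class probabilities (rows sum to 1)."""
    return net.predict_proba(x)


def predict_ensemble(model: EnsembleModel, x: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the members' softmax outputs."""
    probs = [m.predict_proba(x) for m in model.members]
    return np.mean(probs, axis=0)


def stack_dataset(
    reps: list[Repetition], placements: list[SensorPlacement] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack repetitions into (N, 6*k, 40) inputs + integer labels.

    Placements are stacked row-wise in the fixed site order; labels are
    indices into :data:`squatform.core.FORM_ORDER`.
    """
    if placements is None:
        placements = [p for p in PLACEMENT_ORDER if p in reps[0].matrices]
    else:
        placements = [p for p in PLACEMENT_ORDER if p in placements]
    X = np.stack([rep.stacked(placements) for rep in reps]).astype(_DTYPE)
    y = _encode_labels([rep.form for rep in reps])
    return X, y
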