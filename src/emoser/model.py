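"""Residual CNN + Bi-LSTM + attention emotion classifier.

Architecture, for a t x f x c input tensor (c = 3 feature channels):

1. a 1x1 convolution expands the channel dimension to ``conv_channels``;
2. ``n_blocks`` residual blocks, each two same-padded 3x3 convolutions
   with a skip connection from the block input added before the final
   ReLU, followed by 2 (time) x 4 (frequency) max-pooling;
3. the remaining t' x f' x C map is unrolled along time into a sequence
   of f'*C-dimensional vectors and encoded by a bidirectional LSTM with
   peephole-style gates (the forget/input gates see the previous cell
   state, the output gate the current one) and ``lstm_hidden`` units per
   direction, concatenated to 2*lstm_hidden per step;
4. attention pooling: each step gets score sigmoid(w . h_t + b), the
   scores are softmax-normalized into weights alpha_t, and the pooled
   representation is r = sum_t alpha_t h_t.  Because the sigmoid maps to
   (0, 1), max(alpha)/min(alpha) < e for any input; a conventional
   tanh-score variant is available via ``attention_score="tanh"``;
5. a two-layer fully connected head (ReLU between) with a softmax output.

Training minimizes mean categorical cross-entropy with Adam.  Everything
is plain float64 numpy with hand-written backpropagation; mini-batches
are handled by per-clip gradient accumulation, so variable-length clips
need no padding or masking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .features import LogMelFeature

__all__ = [
    "ModelConfig", "TrainConfig", "TrainState", "Prediction", "EmotionModel",
    "ShapeError", "lstm_step", "bilstm_forward", "attention_pool",
    "softmax", "cross_entropy", "train",
]


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the configured network."""


class DegenerateClassError(ValueError):
    """A class is absent from the training data."""


# ---------------------------------------------------------------------------
# configs


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults follow the architecture as published: 128 convolution
    kernels, three residual blocks, 2x4 pooling, 128 LSTM units per
    direction.  ``fc_hidden`` (width of the hidden classifier layer) and
    the attention score nonlinearity are configurable because the
    original description leaves them open.
    """

    n_classes: int = 7
    n_mels: int = 64
    in_channels: int = 3
    conv_channels: int = 128
    n_blocks: int = 3
    pool_time: int = 2
    pool_freq: int = 4
    lstm_hidden: int = 128
    fc_hidden: int = 64
    attention_score: str = "sigmoid"  # "tanh" = conventional variant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.attention_score not in ("sigmoid", "tanh"):
            raise ValueError("attention_score must be 'sigmoid' or 'tanh'")

    @property
    def freq_out(self) -> int:
        """Mel-axis size after all poolings (must stay >= 1)."""
        f = self.n_mels
        for _ in range(self.n_blocks):
            f //= self.pool_freq
        return f

    @property
    def seq_width(self) -> int:
        """Per-step input width of the Bi-LSTM."""
        return self.freq_out * self.conv_channels

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_classes", "n_mels", "in_channels", "conv_channels", "n_blocks",
            "pool_time", "pool_freq", "lstm_hidden", "fc_hidden",
            "attention_score", "seed")}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    patience: int | None = None  # early stopping on validation UAR

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "epochs", "batch_size", "lr", "beta1", "beta2", "eps", "seed",
            "patience")}


@dataclass
class TrainState:
    """Per-run bookkeeping: epoch counter, loss history, seed, hypers."""

    epoch: int = 0
    loss_history: list = field(default_factory=list)
    val_uar_history: list = field(default_factory=list)
    seed: int = 0
    hyper: dict = field(default_factory=dict)


@dataclass
class Prediction:
    probs: np.ndarray
    label: int
    attention_weights: np.ndarray


# ---------------------------------------------------------------------------
# stateless numerics


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cross_entropy(probs: np.ndarray, targets: np.ndarray,
                  floor: float = 1e-12) -> float:
    """Mean categorical cross-entropy; zero probabilities are floored."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if probs.shape != targets.shape:
        raise ValueError("probs and targets must have the same shape")
    return float(-(targets * np.log(np.clip(probs, floor, 1.0))).sum()
                 / probs.shape[0])


# ---------------------------------------------------------------------------
# layers (forward returns a cache consumed by the matching backward)


def _conv2d_forward(x, W, b):
    kh, kw, cin, cout = W.shape
    t, f, _ = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(0, 1))
    cols = win.transpose(0, 1, 3, 4, 2).reshape(t * f, kh * kw * cin)
    wmat = W.reshape(kh * kw * cin, cout)
    out = (cols @ wmat + b).reshape(t, f, cout)
    return out, (cols, x.shape, W.shape)


def _conv2d_backward(dout, cache, W):
    cols, xshape, wshape = cache
    kh, kw, cin, cout = wshape
    t, f, _ = xshape
    ph, pw = kh // 2, kw // 2
    dmat = dout.reshape(t * f, cout)
    dW = (cols.T @ dmat).reshape(wshape)
    db = dmat.sum(axis=0)
    dcols = (dmat @ W.reshape(kh * kw * cin, cout).T)
    dcols = dcols.reshape(t, f, kh, kw, cin)
    dxp = np.zeros((t + 2 * ph, f + 2 * pw, cin))
    for i in range(kh):
        for j in range(kw):
            dxp[i:i + t, j:j + f] += dcols[:, :, i, j, :]
    dx = dxp[ph:ph + t, pw:pw + f]
    return dx, dW, db


def _maxpool_forward(x, pt, pf):
    t, f, c = x.shape
    if t < pt or f < pf:
        raise ShapeError(f"cannot {pt}x{pf}-pool a {t}x{f} map")
    t2, f2 = t // pt, f // pf
    xc = x[:t2 * pt, :f2 * pf]
    r = xc.reshape(t2, pt, f2, pf, c)
    out = r.max(axis=(1, 3))
    mask = (r == out[:, None, :, None, :])
    nmax = mask.sum(axis=(1, 3), keepdims=True)
    return out, (mask, nmax, x.shape, pt, pf)


def _maxpool_backward(dout, cache):
    mask, nmax, xshape, pt, pf = cache
    t, f, c = xshape
    t2, f2 = t // pt, f // pf
    dr = mask * (dout[:, None, :, None, :] / nmax)
    dx = np.zeros(xshape)
    dx[:t2 * pt, :f2 * pf] = dr.reshape(t2 * pt, f2 * pf, c)
    return dx


def _residual_block_forward(x, p, pt, pf):
    a1, c1 = _conv2d_forward(x, p["W1"], p["b1"])
    r1 = np.maximum(a1, 0.0)
    a2, c2 = _conv2d_forward(r1, p["W2"], p["b2"])
    s = a2 + x  # skip connection
    r2 = np.maximum(s, 0.0)
    out, cp = _maxpool_forward(r2, pt, pf)
    return out, (c1, a1, c2, s, cp)


def _residual_block_backward(dout, cache, p):
    c1, a1, c2, s, cp = cache
    ds = _maxpool_backward(dout, cp) * (s > 0)
    dr1, dW2, db2 = _conv2d_backward(ds, c2, p["W2"])
    da1 = dr1 * (a1 > 0)
    dx, dW1, db1 = _conv2d_backward(da1, c1, p["W1"])
    dx += ds  # skip path
    return dx, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


_GATES = ("f", "i", "c", "o")


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: dict) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step with peephole-style gates.

        f_t = sig(Wcf c_{t-1} + Whf h_{t-1} + Wxf x_t + bf)
        i_t = sig(Wci c_{t-1} + Whi h_{t-1} + Wxi x_t + bi)
        c_t = f_t c_{t-1} + i_t tanh(Whc h_{t-1} + Wxc x_t + bc)
        o_t = sig(Wco c_t   + Who h_{t-1} + Wxo x_t + bo)
        h_t = o_t tanh(c_t)
    """
    h, c, _ = _lstm_step_cached(x_t, h_prev, c_prev, params)
    return h, c


def _lstm_step_cached(x_t, h_prev, c_prev, p):
    f = _sigmoid(c_prev @ p["Wcf"] + h_prev @ p["Whf"] + x_t @ p["Wxf"] + p["bf"])
    i = _sigmoid(c_prev @ p["Wci"] + h_prev @ p["Whi"] + x_t @ p["Wxi"] + p["bi"])
    g = np.tanh(h_prev @ p["Whc"] + x_t @ p["Wxc"] + p["bc"])
    c = f * c_prev + i * g
    o = _sigmoid(c @ p["Wco"] + h_prev @ p["Who"] + x_t @ p["Wxo"] + p["bo"])
    tc = np.tanh(c)
    h = o * tc
    return h, c, (x_t, h_prev, c_prev, f, i, g, c, o, tc)


def _lstm_forward(xs, p):
    T = xs.shape[0]
    H = p["bf"].shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    hs = np.empty((T, H))
    caches = []
    for t in range(T):
        h, c, cache = _lstm_step_cached(xs[t], h, c, p)
        hs[t] = h
        caches.append(cache)
    return hs, caches


def _lstm_backward(dhs, caches, p):
    T = len(caches)
    D = p["Wxf"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dxs = np.empty((T, D))
    dh_carry = np.zeros_like(dhs[0])
    dc_carry = np.zeros_like(dhs[0])
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, f, i, g, c, o, tc = caches[t]
        dh = dhs[t] + dh_carry
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_carry
        dao = do * o * (1.0 - o)
        dc = dc + dao @ p["Wco"].T  # output gate peeps at current cell
        grads["Wco"] += np.outer(c, dao)
        grads["Who"] += np.outer(h_prev, dao)
        grads["Wxo"] += np.outer(x_t, dao)
        grads["bo"] += dao
        dh_prev = dao @ p["Who"].T
        dx = dao @ p["Wxo"].T
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_prev = dc * f
        daf = df * f * (1.0 - f)
        dai = di * i * (1.0 - i)
        dag = dg * (1.0 - g * g)
        grads["Wcf"] += np.outer(c_prev, daf)
        grads["Whf"] += np.outer(h_prev, daf)
        grads["Wxf"] += np.outer(x_t, daf)
        grads["bf"] += daf
        grads["Wci"] += np.outer(c_prev, dai)
        grads["Whi"] += np.outer(h_prev, dai)
        grads["Wxi"] += np.outer(x_t, dai)
        grads["bi"] += dai
        grads["Whc"] += np.outer(h_prev, dag)
        grads["Wxc"] += np.outer(x_t, dag)
        grads["bc"] += dag
        dc_prev += daf @ p["Wcf"].T + dai @ p["Wci"].T
        dh_prev += (daf @ p["Whf"].T + dai @ p["Whi"].T + dag @ p["Whc"].T)
        dx += daf @ p["Wxf"].T + dai @ p["Wxi"].T + dag @ p["Wxc"].T
        dxs[t] = dx
        dh_carry, dc_carry = dh_prev, dc_prev
    return dxs, grads


def bilstm_forward(xs: np.ndarray, params_fwd: dict,
                   params_bwd: dict) -> np.ndarray:
    """Bidirectional encoding; per-step output is [h_fwd_t, h_bwd_t].

    With 128 hidden units per direction the per-step width is 256.
    """
    xs = np.asarray(xs, dtype=np.float64)
    if xs.ndim != 2 or xs.shape[0] == 0:
        raise ValueError("expected a non-empty [T][D] sequence")
    hs_f, _ = _lstm_forward(xs, params_fwd)
    hs_b, _ = _lstm_forward(xs[::-1], params_bwd)
    return np.concatenate([hs_f, hs_b[::-1]], axis=1)


def attention_pool(hs: np.ndarray, w: np.ndarray, b: float,
                   variant: str = "sigmoid") -> tuple[np.ndarray, np.ndarray]:
    """Softmax-of-score pooling; returns (r, alpha)."""
    r, alphas, _ = _attention_forward(np.asarray(hs, dtype=np.float64),
                                      w, b, variant)
    return r, alphas


def _attention_forward(hs, w, b, variant):
    if hs.ndim != 2 or hs.shape[0] == 0:
        raise ValueError("expected a non-empty [T][D] sequence")
    a = hs @ w + float(b)
    s = _sigmoid(a) if variant == "sigmoid" else np.tanh(a)
    alphas = softmax(s)
    r = alphas @ hs
    return r, alphas, (hs, a, s, alphas)


def _attention_backward(dr, cache, w, variant):
    hs, a, s, alphas = cache
    dhs = np.outer(alphas, dr)
    dalpha = hs @ dr
    dscore = alphas * (dalpha - float(alphas @ dalpha))
    if variant == "sigmoid":
        da = dscore * s * (1.0 - s)
    else:
        da = dscore * (1.0 - s * s)
    dw = hs.T @ da
    db = float(da.sum())
    dhs += np.outer(da, w)
    return dhs, dw, db


# ---------------------------------------------------------------------------
# parameter tree utilities


def _tree_iter(tree, path=()):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from _tree_iter(tree[k], path + (k,))
    elif isinstance(tree, list):
        for idx, v in enumerate(tree):
            yield from _tree_iter(v, path + (idx,))
    else:
        yield path, tree


def _tree_get(tree, path):
    for k in path:
        tree = tree[k]
    return tree


def _tree_set(tree, path, value):
    for k in path[:-1]:
        tree = tree[k]
    tree[path[-1]] = value


def _tree_zeros_like(tree):
    if isinstance(tree, dict):
        return {k: _tree_zeros_like(v) for k, v in tree.items()}
    if isinstance(tree, list):
        return [_tree_zeros_like(v) for v in tree]
    return np.zeros_like(tree)


def _tree_add_(acc, other):
    for path, leaf in _tree_iter(other):
        _tree_get(acc, path[:-1])[path[-1]] = _tree_get(acc, path) + leaf


def _tree_scale_(tree, s):
    for path, leaf in _tree_iter(tree):
        _tree_set(tree, path, leaf * s)


class Adam:
    """Standard Adam over a nested parameter tree."""

    def __init__(self, params, cfg: TrainConfig):
        self.cfg = cfg
        self.m = _tree_zeros_like(params)
        self.v = _tree_zeros_like(params)
        self.t = 0

    def step(self, params, grads) -> None:
        c = self.cfg
        self.t += 1
        bias1 = 1.0 - c.beta1 ** self.t
        bias2 = 1.0 - c.beta2 ** self.t
        for path, g in _tree_iter(grads):
            m = c.beta1 * _tree_get(self.m, path) + (1 - c.beta1) * g
            v = c.beta2 * _tree_get(self.v, path) + (1 - c.beta2) * g * g
            _tree_set(self.m, path, m)
            _tree_set(self.v, path, v)
            upd = c.lr * (m / bias1) / (np.sqrt(v / bias2) + c.eps)
            _tree_set(params, path, _tree_get(params, path) - upd)


# ---------------------------------------------------------------------------
# the model


def _glorot(rng, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def _init_lstm(rng, d_in, h):
    p = {}
    for gate in _GATES:
        if gate != "c":
            p[f"Wc{gate}"] = _glorot(rng, (h, h), h, h)
        p[f"Wh{gate}"] = _glorot(rng, (h, h), h, h)
        p[f"Wx{gate}"] = _glorot(rng, (d_in, h), d_in, h)
        p[f"b{gate}"] = np.zeros(h)
    p["bf"] = np.ones(h)  # forget-gate bias 1: remember by default
    return p


class EmotionModel:
    """The trained (or freshly initialized) network; see module docstring."""

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        if config.freq_out < 1:
            raise ShapeError(
                f"n_mels={config.n_mels} collapses to zero after "
                f"{config.n_blocks} poolings by {config.pool_freq}")
        self.params = params if params is not None else self._init_params()

    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        C = cfg.conv_channels
        p: dict = {
            "expand": {
                "W": _glorot(rng, (1, 1, cfg.in_channels, C),
                             cfg.in_channels, C),
                "b": np.zeros(C),
            },
            "blocks": [
                {
                    "W1": _glorot(rng, (3, 3, C, C), 9 * C, C),
                    "b1": np.zeros(C),
                    "W2": _glorot(rng, (3, 3, C, C), 9 * C, C),
                    "b2": np.zeros(C),
                }
                for _ in range(cfg.n_blocks)
            ],
            "lstm_fwd": _init_lstm(rng, cfg.seq_width, cfg.lstm_hidden),
            "lstm_bwd": _init_lstm(rng, cfg.seq_width, cfg.lstm_hidden),
            "attn": {
                "w": _glorot(rng, (2 * cfg.lstm_hidden,),
                             2 * cfg.lstm_hidden, 1),
                "b": np.zeros(()),
            },
            "fc1": {
                "W": _glorot(rng, (2 * cfg.lstm_hidden, cfg.fc_hidden),
                             2 * cfg.lstm_hidden, cfg.fc_hidden),
                "b": np.zeros(cfg.fc_hidden),
            },
            "fc2": {
                "W": _glorot(rng, (cfg.fc_hidden, cfg.n_classes),
                             cfg.fc_hidden, cfg.n_classes),
                "b": np.zeros(cfg.n_classes),
            },
        }
        return p

    # -- forward ----------------------------------------------------------

    def rescnn_forward(self, values: np.ndarray) -> np.ndarray:
        """Convolutional front: returns the [T'][f'*C] frame-step sequence."""
        seq, _ = self._conv_forward(np.asarray(values, dtype=np.float64))
        return seq

    def _conv_forward(self, v):
        cfg = self.config
        if v.ndim != 3 or v.shape[2] != cfg.in_channels:
            raise ShapeError(
                f"expected [t][f][{cfg.in_channels}] input, got {v.shape}")
        caches = {}
        x, caches["expand"] = _conv2d_forward(
            v, self.params["expand"]["W"], self.params["expand"]["b"])
        bcaches = []
        for bp in self.params["blocks"]:
            x, c = _residual_block_forward(x, bp, cfg.pool_time, cfg.pool_freq)
            bcaches.append(c)
        caches["blocks"] = bcaches
        t2, f2, C = x.shape
        caches["conv_out_shape"] = (t2, f2, C)
        return x.reshape(t2, f2 * C), caches

    def _forward(self, v):
        p = self.params
        cfg = self.config
        seq, caches = self._conv_forward(v)
        hs_f, cf = _lstm_forward(seq, p["lstm_fwd"])
        hs_b, cb = _lstm_forward(seq[::-1], p["lstm_bwd"])
        hs = np.concatenate([hs_f, hs_b[::-1]], axis=1)
        r, alphas, ca = _attention_forward(
            hs, p["attn"]["w"], p["attn"]["b"], cfg.attention_score)
        z1 = r @ p["fc1"]["W"] + p["fc1"]["b"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ p["fc2"]["W"] + p["fc2"]["b"]
        probs = softmax(logits)
        caches.update(seq=seq, lstm_f=cf, lstm_b=cb, attn=ca, r=r,
                      z1=z1, a1=a1, alphas=alphas)
        return probs, alphas, caches

    def predict(self, feat: LogMelFeature | np.ndarray) -> Prediction:
        v = feat.values if isinstance(feat, LogMelFeature) else feat
        probs, alphas, _ = self._forward(np.asarray(v, dtype=np.float64))
        # ties broken toward the lowest class index (np.argmax convention)
        return Prediction(probs=probs, label=int(np.argmax(probs)),
                          attention_weights=alphas)

    def classify(self, r: np.ndarray) -> np.ndarray:
        """Apply only the two-layer softmax head to a pooled vector."""
        p = self.params
        a1 = np.maximum(r @ p["fc1"]["W"] + p["fc1"]["b"], 0.0)
        return softmax(a1 @ p["fc2"]["W"] + p["fc2"]["b"])

    # -- backward ---------------------------------------------------------

    def _backward(self, dlogits, caches):
        p = self.params
        cfg = self.config
        grads: dict = {}
        a1 = caches["a1"]
        grads["fc2"] = {"W": np.outer(a1, dlogits), "b": dlogits.copy()}
        da1 = p["fc2"]["W"] @ dlogits
        dz1 = da1 * (caches["z1"] > 0)
        grads["fc1"] = {"W": np.outer(caches["r"], dz1), "b": dz1.copy()}
        dr = p["fc1"]["W"] @ dz1
        dhs, dw, db = _attention_backward(dr, caches["attn"], p["attn"]["w"],
                                          cfg.attention_score)
        grads["attn"] = {"w": dw, "b": np.asarray(db)}
        H = cfg.lstm_hidden
        dxs_f, g_f = _lstm_backward(dhs[:, :H], caches["lstm_f"],
                                    p["lstm_fwd"])
        dxs_b, g_b = _lstm_backward(dhs[::-1, H:], caches["lstm_b"],
                                    p["lstm_bwd"])
        grads["lstm_fwd"] = g_f
        grads["lstm_bwd"] = g_b
        dseq = dxs_f + dxs_b[::-1]
        t2, f2, C = caches["conv_out_shape"]
        dx = dseq.reshape(t2, f2, C)
        bgrads = []
        for bp, bc in zip(reversed(self.params["blocks"]),
                          reversed(caches["blocks"])):
            dx, bg = _residual_block_backward(dx, bc, bp)
            bgrads.append(bg)
        grads["blocks"] = list(reversed(bgrads))
        _, dWe, dbe = _conv2d_backward(dx, caches["expand"],
                                       p["expand"]["W"])
        grads["expand"] = {"W": dWe, "b": dbe}
        return grads

    def loss_and_grads(self, values_list, labels) -> tuple[float, dict]:
        """Mean cross-entropy and its gradient over a mini-batch of clips."""
        n = len(values_list)
        n_classes = self.config.n_classes
        total_grads = _tree_zeros_like(self.params)
        loss = 0.0
        for v, y in zip(values_list, labels):
            probs, _, caches = self._forward(v)
            loss += -np.log(max(probs[y], 1e-12))
            dlogits = probs.copy()
            dlogits[y] -= 1.0
            _tree_add_(total_grads, self._backward(dlogits / n, caches))
        return loss / n, total_grads

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: JSON config header + npz parameter blob."""
        path = Path(path)
        path.with_suffix(".json").write_text(
            json.dumps(self.config.to_dict(), indent=1))
        flat = {"/".join(map(str, p)): leaf
                for p, leaf in _tree_iter(self.params)}
        np.savez(path.with_suffix(".npz"), **flat)

    @classmethod
    def load(cls, path: str | Path) -> "EmotionModel":
        path = Path(path)
        config = ModelConfig.from_dict(
            json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as blob:
            for p, _ in list(_tree_iter(model.params)):
                _tree_set(model.params, p, blob["/".join(map(str, p))])
        return model


# ---------------------------------------------------------------------------
# training


def _uar_quick(model, values_list, labels, n_classes):
    correct = np.zeros(n_classes)
    seen = np.zeros(n_classes)
    for v, y in zip(values_list, labels):
        seen[y] += 1
        if model.predict(v).label == y:
            correct[y] += 1
    present = seen > 0
    return float((correct[present] / seen[present]).mean())


def train(features, labels, model_cfg: ModelConfig,
          train_cfg: TrainConfig | None = None,
          val_features=None, val_labels=None,
          strict_classes: bool = False) -> tuple[EmotionModel, TrainState]:
    """Mini-batch Adam training.

    ``features`` is a sequence of [t][f][c] arrays or LogMelFeature;
    ``labels`` integer class ids in [0, n_classes).  Deterministic given
    ``train_cfg.seed``.  If a validation set and ``patience`` are given,
    training stops when validation UAR has not improved for ``patience``
    epochs and the best parameters are restored.
    """
    if train_cfg is None:
        train_cfg = TrainConfig()
    values = [f.values if isinstance(f, LogMelFeature) else
              np.asarray(f, dtype=np.float64) for f in features]
    labels = np.asarray(labels, dtype=int)
    present = set(labels.tolist())
    missing = set(range(model_cfg.n_classes)) - present
    if missing:
        msg = f"classes absent from training data: {sorted(missing)}"
        if strict_classes:
            raise DegenerateClassError(msg)
        warnings.warn(msg)
    if len(present) < 2:
        raise DegenerateClassError("need at least 2 classes present to train")

    model = EmotionModel(model_cfg)
    opt = Adam(model.params, train_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    state = TrainState(seed=train_cfg.seed, hyper=train_cfg.to_dict())

    best_uar, best_params, since_best = -1.0, None, 0
    n = len(values)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            loss, grads = model.loss_and_grads(
                [values[i] for i in idx], labels[idx])
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        state.epoch = epoch + 1
        state.loss_history.append(float(epoch_loss / n))
        if val_features is not None and train_cfg.patience is not None:
            vals = [f.values if isinstance(f, LogMelFeature) else
                    np.asarray(f, dtype=np.float64) for f in val_features]
            uar = _uar_quick(model, vals, np.asarray(val_labels, dtype=int),
                             model_cfg.n_classes)
            state.val_uar_history.append(uar)
            if uar > best_uar:
                best_uar, since_best = uar, 0
                best_params = _tree_zeros_like(model.params)
                for p, leaf in _tree_iter(model.params):
                    _tree_set(best_params, p, leaf.copy())
            else:
                since_best += 1
                if since_best >= train_cfg.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model, state
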