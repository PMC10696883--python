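"""Numpy implementation of the conv + bidirectional-LSTM binding network.

Forward/backward passes are written out explicitly and verified against
central finite differences in the test suite. The architecture is

    one-hot (L x 4)
      -> [1-D convolution (ReLU) -> max pool -> dropout]   (optional)
      -> LSTM over the feature sequence (optionally bidirectional,
         final hidden state(s) taken)
      -> dense (ReLU, dropout, per-unit max-norm constraint)
      -> single logistic output unit

trained with Adam on binary cross-entropy. Everything is float64 and driven
by explicit ``numpy.random.Generator`` streams, so runs are bit-reproducible
from a seed on any platform.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from crnn_tfbs.errors import ConfigError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class CRNNetwork:
    """Parameter store plus forward/backward passes.

    ``config`` is a :class:`crnn_tfbs.crnn.ModelConfig`; only its
    architectural and seed fields are read here.
    """

    VERSION = "crnn-tfbs-network-v1"

    def __init__(self, config) -> None:
        cfg = config
        if cfg.use_conv and cfg.kernel_len > cfg.input_length:
            raise ConfigError(
                f"kernel_len {cfg.kernel_len} exceeds input_length {cfg.input_length}"
            )
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}

        if cfg.use_conv:
            p["Wc"] = _glorot(rng, (cfg.kernel_len * 4, cfg.conv_kernels))
            p["bc"] = np.zeros(cfg.conv_kernels)
            t_conv = cfg.input_length - cfg.kernel_len + 1
            self.n_steps = max(t_conv // cfg.pool_size, 1)
            rnn_in = cfg.conv_kernels
        else:
            self.n_steps = cfg.input_length
            rnn_in = 4
        self.rnn_in = rnn_in

        H = cfg.rnn_units
        for d in self._directions():
            p[f"Wx_{d}"] = _glorot(rng, (rnn_in, 4 * H))
            p[f"Wh_{d}"] = _glorot(rng, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias at 1: remember by default
            p[f"b_{d}"] = b

        feat = H * (2 if cfg.bidirectional else 1)
        p["W1"] = _glorot(rng, (feat, cfg.dense_units))
        p["b1"] = np.zeros(cfg.dense_units)
        p["W2"] = _glorot(rng, (cfg.dense_units, 1))
        p["b2"] = np.zeros(1)
        self.params = p

    def _directions(self) -> list[str]:
        return ["fwd", "bwd"] if self.config.bidirectional else ["fwd"]

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict[str, Any]]:
        """Probabilities for a batch ``X`` of shape (B, L, 4), plus cache."""
        cfg = self.config
        p = self.params
        cache: dict[str, Any] = {"train": train}

        if cfg.use_conv:
            k = cfg.kernel_len
            t_conv = X.shape[1] - k + 1
            windows = np.lib.stride_tricks.sliding_window_view(X, (k, 4), axis=(1, 2))
            x_col = windows.reshape(X.shape[0], t_conv, k * 4)
            z = x_col @ p["Wc"] + p["bc"]
            a = np.maximum(z, 0.0)
            t_pool = t_conv // cfg.pool_size
            a_trim = a[:, : t_pool * cfg.pool_size].reshape(
                X.shape[0], t_pool, cfg.pool_size, cfg.conv_kernels
            )
            pool_arg = a_trim.argmax(axis=2)
            pooled = np.take_along_axis(a_trim, pool_arg[:, :, None, :], axis=2)[
                :, :, 0, :
            ]
            if train and cfg.conv_dropout > 0:
                mask = (rng.random(pooled.shape) >= cfg.conv_dropout) / (
                    1.0 - cfg.conv_dropout
                )
                pooled = pooled * mask
                cache["conv_drop_mask"] = mask
            cache.update(x_col=x_col, z=z, t_conv=t_conv, pool_arg=pool_arg)
            feats = pooled
        else:
            feats = X
        cache["feats"] = feats

        h_parts = []
        for d in self._directions():
            seq = feats if d == "fwd" else feats[:, ::-1]
            h_last, steps = self._lstm_forward(
                seq, p[f"Wx_{d}"], p[f"Wh_{d}"], p[f"b_{d}"]
            )
            cache[f"lstm_{d}"] = steps
            h_parts.append(h_last)
        h_cat = np.concatenate(h_parts, axis=1)
        cache["h_cat"] = h_cat

        z1 = h_cat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        if train and cfg.dense_dropout > 0:
            mask1 = (rng.random(a1.shape) >= cfg.dense_dropout) / (
                1.0 - cfg.dense_dropout
            )
            a1 = a1 * mask1
            cache["dense_drop_mask"] = mask1
        cache.update(z1=z1, a1=a1)

        logits = (a1 @ p["W2"] + p["b2"]).ravel()
        prob = _sigmoid(logits)
        cache["prob"] = prob
        return prob, cache

    @staticmethod
    def _lstm_forward(X, Wx, Wh, b):
        B, T, _ = X.shape
        H = Wh.shape[0]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x_t = X[:, t]
            g = x_t @ Wx + h @ Wh + b
            i = _sigmoid(g[:, :H])
            f = _sigmoid(g[:, H : 2 * H])
            gg = np.tanh(g[:, 2 * H : 3 * H])
            o = _sigmoid(g[:, 3 * H :])
            c_new = f * c + i * gg
            tc = np.tanh(c_new)
            steps.append((x_t, h, c, i, f, gg, o, tc))
            h = o * tc
            c = c_new
        return h, steps

    # -- loss --------------------------------------------------------------

    @staticmethod
    def loss(prob: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        p = np.clip(prob, eps, 1.0 - eps)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict[str, Any], y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        cfg = self.config
        p = self.params
        g: dict[str, np.ndarray] = {}
        B = y.shape[0]

        dlogits = ((cache["prob"] - y) / B)[:, None]
        g["W2"] = cache["a1"].T @ dlogits
        g["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["W2"].T
        if "dense_drop_mask" in cache:
            da1 = da1 * cache["dense_drop_mask"]
        dz1 = da1 * (cache["z1"] > 0)
        g["W1"] = cache["h_cat"].T @ dz1
        g["b1"] = dz1.sum(axis=0)
        dh_cat = dz1 @ p["W1"].T

        H = cfg.rnn_units
        dfeats = np.zeros_like(cache["feats"])
        for di, d in enumerate(self._directions()):
            dh_last = dh_cat[:, di * H : (di + 1) * H]
            dX_dir, dWx, dWh, db = self._lstm_backward(
                dh_last, cache[f"lstm_{d}"], p[f"Wx_{d}"], p[f"Wh_{d}"]
            )
            g[f"Wx_{d}"] = dWx
            g[f"Wh_{d}"] = dWh
            g[f"b_{d}"] = db
            dfeats += dX_dir if d == "fwd" else dX_dir[:, ::-1]

        if cfg.use_conv:
            if "conv_drop_mask" in cache:
                dfeats = dfeats * cache["conv_drop_mask"]
            # un-pool: route gradient to each window's argmax position
            B_, t_pool, K = dfeats.shape
            da_trim = np.zeros((B_, t_pool, cfg.pool_size, K))
            np.put_along_axis(
                da_trim, cache["pool_arg"][:, :, None, :], dfeats[:, :, None, :], axis=2
            )
            da = np.zeros((B_, cache["t_conv"], K))
            da[:, : t_pool * cfg.pool_size] = da_trim.reshape(
                B_, t_pool * cfg.pool_size, K
            )
            dz = da * (cache["z"] > 0)
            g["Wc"] = cache["x_col"].reshape(-1, cfg.kernel_len * 4).T @ dz.reshape(
                -1, cfg.conv_kernels
            )
            g["bc"] = dz.sum(axis=(0, 1))
        return g

    @staticmethod
    def _lstm_backward(dh_last, steps, Wx, Wh):
        T = len(steps)
        B = dh_last.shape[0]
        H = Wh.shape[0]
        D = Wx.shape[0]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros((B, T, D))
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, gg, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dgg = dc * i
            d_pre = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dgg * (1.0 - gg * gg),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ d_pre
            dWh += h_prev.T @ d_pre
            db += d_pre.sum(axis=0)
            dX[:, t] = d_pre @ Wx.T
            dh = d_pre @ Wh.T
            dc = dc * f
        return dX, dWx, dWh, db

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Deterministic (dropout-free) probabilities, batch-size invariant."""
        out = np.empty(X.shape[0])
        for lo in range(0, X.shape[0], batch_size):
            prob, _ = self.forward(X[lo : lo + batch_size], train=False)
            out[lo : lo + batch_size] = prob
        return out


class Adam:
    """Adaptive-moment-estimation optimizer over a parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, grad in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * grad
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * grad * grad
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def apply_max_norm(params: dict[str, np.ndarray], max_norm: float) -> None:
    """Clip each dense unit's incoming weight-vector L2 norm to ``max_norm``."""
    for key in ("W1", "W2"):
        W = params[key]
        norms = np.sqrt((W * W).sum(axis=0, keepdims=True))
        factor = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
        W *= factor
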