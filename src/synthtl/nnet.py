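"""Minimal numpy neural-network stack for small sequence forecasters.

Implements exactly what the forecasting module needs: four feature
extractor ("body") types — LSTM, GRU, 1-D CNN and dense — plus a
two-layer perceptron head, mean-squared-error loss, Adam, and
reverse-mode gradients written by hand.  Everything is plain float64
numpy, single-threaded and bitwise deterministic for a fixed seed, which
makes frozen-parameter contracts and paired-seed comparisons exact.

Parameters live in a flat ``dict[str, ndarray]`` with ``body.*`` /
``head.*`` name prefixes so training can freeze the body wholesale.
Gradients returned by ``backward`` are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

Params = Dict[str, np.ndarray]


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Bodies: map (B, T, n_in) -> (B, feature_dim)
# ---------------------------------------------------------------------------

class _Body:
    feature_dim: int

    def init_params(self, rng: np.random.Generator) -> Params:
        raise NotImplementedError

    def forward(self, x: np.ndarray, p: Params):
        raise NotImplementedError

    def backward(self, dfeat: np.ndarray, cache, p: Params) -> Params:
        raise NotImplementedError


class DenseBody(_Body):
    """Flatten the window and apply one ReLU dense layer."""

    def __init__(self, input_len: int, n_in: int, units: int = 64):
        self.input_len, self.n_in, self.units = input_len, n_in, units
        self.feature_dim = units

    def init_params(self, rng):
        d = self.input_len * self.n_in
        return {"body.W": _glorot(rng, (d, self.units)),
                "body.b": np.zeros(self.units)}

    def forward(self, x, p):
        flat = x.reshape(x.shape[0], -1)
        z = flat @ p["body.W"] + p["body.b"]
        h = np.maximum(z, 0.0)
        return h, (x.shape, flat, z)

    def backward(self, dfeat, cache, p):
        shape, flat, z = cache
        dz = dfeat * (z > 0)
        return {"body.W": flat.T @ dz, "body.b": dz.sum(axis=0)}


class CNNBody(_Body):
    """Two 1-D convolutions (same padding, ReLU) + global average pooling."""

    def __init__(self, input_len: int, n_in: int, channels: int = 32,
                 kernel: int = 3):
        self.input_len, self.n_in = input_len, n_in
        self.channels, self.kernel = channels, kernel
        self.feature_dim = channels

    def init_params(self, rng):
        k, c, n = self.kernel, self.channels, self.n_in
        return {"body.W1": _glorot(rng, (k * n, c)).reshape(k, n, c),
                "body.b1": np.zeros(c),
                "body.W2": _glorot(rng, (k * c, c)).reshape(k, c, c),
                "body.b2": np.zeros(c)}

    @staticmethod
    def _conv(x, w, b):
        # x: (B,T,Cin), w: (k,Cin,Cout); zero 'same' padding
        k = w.shape[0]
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        t_len = x.shape[1]
        out = np.tensordot(xp[:, 0:t_len, :], w[0], axes=([2], [0]))
        for d in range(1, k):
            out += np.tensordot(xp[:, d:d + t_len, :], w[d], axes=([2], [0]))
        return out + b, xp

    @staticmethod
    def _conv_backward(dout, xp, w, t_len):
        k = w.shape[0]
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for d in range(k):
            seg = xp[:, d:d + t_len, :]
            dw[d] = np.tensordot(seg, dout, axes=([0, 1], [0, 1]))
            dxp[:, d:d + t_len, :] += np.tensordot(dout, w[d], axes=([2], [1]))
        db = dout.sum(axis=(0, 1))
        pad = k // 2
        dx = dxp[:, pad:pad + t_len, :]
        return dx, dw, db

    def forward(self, x, p):
        z1, xp1 = self._conv(x, p["body.W1"], p["body.b1"])
        h1 = np.maximum(z1, 0.0)
        z2, xp2 = self._conv(h1, p["body.W2"], p["body.b2"])
        h2 = np.maximum(z2, 0.0)
        feat = h2.mean(axis=1)
        return feat, (x, xp1, z1, xp2, z2)

    def backward(self, dfeat, cache, p):
        x, xp1, z1, xp2, z2 = cache
        t_len = x.shape[1]
        dh2 = np.repeat(dfeat[:, None, :], t_len, axis=1) / t_len
        dz2 = dh2 * (z2 > 0)
        dh1, dw2, db2 = self._conv_backward(dz2, xp2, p["body.W2"], t_len)
        dz1 = dh1 * (z1 > 0)
        _, dw1, db1 = self._conv_backward(dz1, xp1, p["body.W1"], t_len)
        return {"body.W1": dw1, "body.b1": db1, "body.W2": dw2, "body.b2": db2}


class LSTMBody(_Body):
    """Single-layer LSTM; the feature is the last hidden state."""

    def __init__(self, n_in: int, units: int = 64):
        self.n_in, self.units = n_in, units
        self.feature_dim = units

    def init_params(self, rng):
        n, h = self.n_in, self.units
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias
        return {"body.Wx": _glorot(rng, (n, 4 * h)),
                "body.Wh": _glorot(rng, (h, 4 * h)),
                "body.b": b}

    def forward(self, x, p):
        B, T, _ = x.shape
        h_dim = self.units
        h = np.zeros((B, h_dim))
        c = np.zeros((B, h_dim))
        caches = []
        for t in range(T):
            a = x[:, t, :] @ p["body.Wx"] + h @ p["body.Wh"] + p["body.b"]
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim:2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            caches.append((x[:, t, :], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h, caches

    def backward(self, dfeat, caches, p):
        h_dim = self.units
        dWx = np.zeros_like(p["body.Wx"])
        dWh = np.zeros_like(p["body.Wh"])
        db = np.zeros_like(p["body.b"])
        dh = dfeat
        dc = np.zeros_like(dfeat)
        for xt, h_prev, c_prev, i, f, g, o, c_new, tc in reversed(caches):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc = dc * f
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += xt.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dh = da @ p["body.Wh"].T
        return {"body.Wx": dWx, "body.Wh": dWh, "body.b": db}


class GRUBody(_Body):
    """Single-layer GRU; the feature is the last hidden state.

    Candidate uses the reset gate on the hidden state before the
    recurrent matmul: n = tanh(x Wn + (r*h) Un + bn).
    """

    def __init__(self, n_in: int, units: int = 64):
        self.n_in, self.units = n_in, units
        self.feature_dim = units

    def init_params(self, rng):
        n, h = self.n_in, self.units
        return {"body.Wx": _glorot(rng, (n, 3 * h)),
                "body.Wh": _glorot(rng, (h, 3 * h)),
                "body.b": np.zeros(3 * h)}

    def forward(self, x, p):
        B, T, _ = x.shape
        hd = self.units
        h = np.zeros((B, hd))
        caches = []
        for t in range(T):
            xt = x[:, t, :]
            ax = xt @ p["body.Wx"] + p["body.b"]
            ah = h @ p["body.Wh"]
            z = _sigmoid(ax[:, :hd] + ah[:, :hd])
            r = _sigmoid(ax[:, hd:2 * hd] + ah[:, hd:2 * hd])
            rh = r * h
            an = ax[:, 2 * hd:] + rh @ p["body.Wh"][:, 2 * hd:]
            n = np.tanh(an)
            h_new = (1 - z) * n + z * h
            caches.append((xt, h, z, r, rh, n, ah))
            h = h_new
        return h, caches

    def backward(self, dfeat, caches, p):
        hd = self.units
        Wh = p["body.Wh"]
        dWx = np.zeros_like(p["body.Wx"])
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(p["body.b"])
        dh = dfeat
        for xt, h_prev, z, r, rh, n, ah in reversed(caches):
            dz = dh * (h_prev - n)
            dn = dh * (1 - z)
            dh_prev = dh * z
            dan = dn * (1 - n ** 2)
            drh = dan @ Wh[:, 2 * hd:].T
            dWh[:, 2 * hd:] += rh.T @ dan
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            da_zr = np.concatenate([daz, dar], axis=1)
            dWh[:, :2 * hd] += h_prev.T @ da_zr
            dh_prev += da_zr @ Wh[:, :2 * hd].T
            da_x = np.concatenate([daz, dar, dan], axis=1)
            dWx += xt.T @ da_x
            db += da_x.sum(axis=0)
            dh = dh_prev
        return {"body.Wx": dWx, "body.Wh": dWh, "body.b": db}


# ---------------------------------------------------------------------------
# Head: two-layer perceptron mapping features to the forecast
# ---------------------------------------------------------------------------

class Head:
    """Two parameterised layers: ReLU hidden layer + linear output."""

    def __init__(self, feature_dim: int, hidden: int, out_dim: int):
        self.feature_dim, self.hidden, self.out_dim = feature_dim, hidden, out_dim

    def init_params(self, rng: np.random.Generator) -> Params:
        return {"head.W1": _glorot(rng, (self.feature_dim, self.hidden)),
                "head.b1": np.zeros(self.hidden),
                "head.W2": _glorot(rng, (self.hidden, self.out_dim)),
                "head.b2": np.zeros(self.out_dim)}

    def forward(self, feat: np.ndarray, p: Params):
        z1 = feat @ p["head.W1"] + p["head.b1"]
        h1 = np.maximum(z1, 0.0)
        out = h1 @ p["head.W2"] + p["head.b2"]
        return out, (feat, z1, h1)

    def backward(self, dout: np.ndarray, cache, p: Params):
        feat, z1, h1 = cache
        grads = {"head.W2": h1.T @ dout, "head.b2": dout.sum(axis=0)}
        dh1 = dout @ p["head.W2"].T
        dz1 = dh1 * (z1 > 0)
        grads["head.W1"] = feat.T @ dz1
        grads["head.b1"] = dz1.sum(axis=0)
        dfeat = dz1 @ p["head.W1"].T
        return dfeat, grads


# ---------------------------------------------------------------------------
# Network = body + head, MSE loss, Adam
# ---------------------------------------------------------------------------

def make_body(architecture: str, input_len: int, n_in: int,
              hyper: Dict) -> _Body:
    arch = architecture.upper()
    if arch == "DNN":
        return DenseBody(input_len, n_in, hyper.get("dense_units", 64))
    if arch == "CNN":
        return CNNBody(input_len, n_in, hyper.get("cnn_channels", 32),
                       hyper.get("cnn_kernel", 3))
    if arch == "LSTM":
        return LSTMBody(n_in, hyper.get("recurrent_units", 64))
    if arch == "GRU":
        return GRUBody(n_in, hyper.get("recurrent_units", 64))
    raise ValueError(f"unknown architecture {architecture!r}; "
                     f"known: LSTM, GRU, CNN, DNN")


class Network:
    """Body + two-layer head with hand-written reverse-mode gradients."""

    def __init__(self, body: _Body, head: Head):
        self.body = body
        self.head = head

    def init_params(self, seed: int) -> Params:
        rng = np.random.default_rng(seed)
        p = self.body.init_params(rng)
        p.update(self.head.init_params(rng))
        return p

    def forward(self, x: np.ndarray, p: Params) -> np.ndarray:
        feat, _ = self.body.forward(x, p)
        out, _ = self.head.forward(feat, p)
        return out

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       p: Params) -> Tuple[float, Params]:
        """Mean-squared-error loss over all output cells and its gradients."""
        feat, bcache = self.body.forward(x, p)
        out, hcache = self.head.forward(feat, p)
        diff = out - y
        loss = float(np.mean(diff ** 2))
        dout = (2.0 / diff.size) * diff
        dfeat, grads = self.head.backward(dout, hcache, p)
        grads.update(self.body.backward(dfeat, bcache, p))
        return loss, grads

    def loss(self, x: np.ndarray, y: np.ndarray, p: Params) -> float:
        out = self.forward(x, p)
        return float(np.mean((out - y) ** 2))


class Adam:
    """Adam over a parameter dict, restricted to ``trainable`` keys."""

    def __init__(self, params: Params, trainable: set, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.trainable = set(trainable)
        self.m = {k: np.zeros_like(v) for k, v in params.items() if k in self.trainable}
        self.v = {k: np.zeros_like(v) for k, v in params.items() if k in self.trainable}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k in self.trainable:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            params[k] = params[k] - self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps)
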