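"""Minimal feed-forward/backprop engine in numpy (float32).

Implements exactly the layer set the EE architectures need — valid 1D
convolution, 1D max pooling (kernel 3, stride 1), LSTM with full
backpropagation through time, dense, ReLU, dropout — plus Adam.  Layouts
are channels-last: sequence tensors are (batch, length, channels).

Everything is deterministic given the numpy Generator passed to
``Regressor.forward`` (dropout masks) and the initialization seed; on a
fixed platform with a fixed BLAS, training runs are bit-reproducible.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

try:  # numba accelerates the LSTM recurrence; a numpy path covers its absence
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco

F32 = np.float32


@_njit(cache=False, fastmath=True)
def _lstm_fwd_kernel(xp, Wh, b, I, F, G, O, C, TC, Hs):  # pragma: no cover - jit
    """Time-major LSTM recurrence. xp: (T,B,4H) pre-projected inputs."""
    T, B, H4 = xp.shape
    h = H4 // 4
    ht = np.zeros((B, h), dtype=np.float32)
    ct = np.zeros((B, h), dtype=np.float32)
    for t in range(T):
        a = np.dot(ht, Wh)
        for n in range(B):
            for j in range(h):
                i_ = 1.0 / (1.0 + np.exp(-(a[n, j] + xp[t, n, j] + b[j])))
                f_ = 1.0 / (1.0 + np.exp(-(a[n, h + j] + xp[t, n, h + j] + b[h + j])))
                g_ = np.tanh(a[n, 2 * h + j] + xp[t, n, 2 * h + j] + b[2 * h + j])
                o_ = 1.0 / (1.0 + np.exp(-(a[n, 3 * h + j] + xp[t, n, 3 * h + j] + b[3 * h + j])))
                c_ = f_ * ct[n, j] + i_ * g_
                tc_ = np.tanh(c_)
                ct[n, j] = c_
                ht[n, j] = o_ * tc_
                I[t, n, j] = i_
                F[t, n, j] = f_
                G[t, n, j] = g_
                O[t, n, j] = o_
                C[t, n, j] = c_
                TC[t, n, j] = tc_
                Hs[t, n, j] = o_ * tc_


@_njit(cache=False, fastmath=True)
def _lstm_bwd_kernel(dout, WhT, I, F, G, O, C, TC, dA):  # pragma: no cover - jit
    """Gate gradients + hidden-state recurrence, time-major; fills dA (T,B,4H)."""
    T, B, h = dout.shape
    dh = np.zeros((B, h), dtype=np.float32)
    dc = np.zeros((B, h), dtype=np.float32)
    for t in range(T - 1, -1, -1):
        dat = dA[t]
        for n in range(B):
            for j in range(h):
                dhv = dh[n, j] + dout[t, n, j]
                tc = TC[t, n, j]
                o = O[t, n, j]
                i = I[t, n, j]
                f = F[t, n, j]
                g = G[t, n, j]
                do = dhv * tc
                dcv = dc[n, j] + dhv * o * (1.0 - tc * tc)
                cp = C[t - 1, n, j] if t > 0 else 0.0
                dc[n, j] = dcv * f
                dat[n, j] = dcv * g * i * (1.0 - i)
                dat[n, h + j] = dcv * cp * f * (1.0 - f)
                dat[n, 2 * h + j] = dcv * i * (1.0 - g * g)
                dat[n, 3 * h + j] = do * o * (1.0 - o)
        dh = np.dot(dat, WhT)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.negative(x, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


class Layer:
    """Base: trainable arrays in ``params``, matching grads in ``grads``."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    #: parameter keys subject to L2 regularization (kernels, not biases)
    weight_keys: Tuple[str, ...] = ()

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: Tuple[int, ...]) -> Tuple[int, ...]:
        """Per-sample output shape given per-sample input shape."""
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    weight_keys = ("W",)

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params = {"W": _glorot(rng, d_in, d_out, (d_in, d_out)),
                       "b": np.zeros(d_out, dtype=F32)}

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T

    def out_shape(self, in_shape):
        return (self.d_out,)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)

    def out_shape(self, in_shape):
        return in_shape


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def out_shape(self, in_shape):
        return in_shape


class Conv1d(Layer):
    """Valid (no padding) 1D convolution, stride 1, channels-last."""

    weight_keys = ("W",)

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.params = {"W": _glorot(rng, fan_in, fan_out, (kernel * c_in, c_out)),
                       "b": np.zeros(c_out, dtype=F32)}

    def forward(self, x, train, rng):
        b, L, c = x.shape
        lo = L - self.k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)  # (B, Lo, C, k)
        self._cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(b * lo, self.k * c)
        self._in_shape = x.shape
        y = self._cols @ self.params["W"] + self.params["b"]
        return y.reshape(b, lo, self.c_out)

    def backward(self, dout):
        b, lo, _ = dout.shape
        dflat = dout.reshape(b * lo, self.c_out)
        self.grads = {"W": self._cols.T @ dflat, "b": dflat.sum(axis=0)}
        dcols = (dflat @ self.params["W"].T).reshape(b, lo, self.k, self.c_in)
        dx = np.zeros(self._in_shape, dtype=F32)
        for tap in range(self.k):
            dx[:, tap:tap + lo, :] += dcols[:, :, tap, :]
        return dx

    def out_shape(self, in_shape):
        L, _ = in_shape
        return (L - self.k + 1, self.c_out)


class MaxPool1d(Layer):
    """1D max pooling, kernel 3 by default, stride 1, per channel."""

    def __init__(self, kernel: int = 3) -> None:
        super().__init__()
        self.k = kernel

    def forward(self, x, train, rng):
        lo = x.shape[1] - self.k + 1
        y = x[:, :lo, :].copy()
        arg = np.zeros(y.shape, dtype=np.int8)
        for tap in range(1, self.k):
            cand = x[:, tap:tap + lo, :]
            better = cand > y  # strict: ties keep the earliest tap
            np.copyto(y, cand, where=better)
            arg[better] = tap
        self._arg = arg
        self._in_shape = x.shape
        return y

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=F32)
        lo = dout.shape[1]
        for tap in range(self.k):
            dx[:, tap:tap + lo, :] += dout * (self._arg == tap)
        return dx

    def out_shape(self, in_shape):
        L, c = in_shape
        return (L - self.k + 1, c)


class LSTM(Layer):
    """Single LSTM layer returning the full hidden sequence (B, T, H).

    Gate order i, f, g, o; forget-gate bias initialized to 1.  Backward is
    full BPTT; input projections are batched over all time steps into one
    GEMM, only the recurrent part loops.
    """

    weight_keys = ("Wx", "Wh")

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.h = d_in, hidden
        b = np.zeros(4 * hidden, dtype=F32)
        b[hidden:2 * hidden] = 1.0
        self.params = {
            "Wx": _glorot(rng, d_in, 4 * hidden, (d_in, 4 * hidden)),
            "Wh": _glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)),
            "b": b,
        }

    def forward(self, x, train, rng):
        b, T, d = x.shape
        h = self.h
        x = np.ascontiguousarray(x, dtype=F32)
        # time-major internal layout so every per-step slice is contiguous
        x_tm = np.ascontiguousarray(x.transpose(1, 0, 2))  # (T, B, D)
        self._x_tm = x_tm
        xp = np.ascontiguousarray(
            (x_tm.reshape(T * b, d) @ self.params["Wx"]).reshape(T, b, 4 * h)
        )
        Wh = self.params["Wh"]
        bias = self.params["b"]

        I = np.empty((T, b, h), dtype=F32)
        Fg = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        TC = np.empty_like(I)
        Hs = np.empty_like(I)

        if _HAVE_NUMBA:
            _lstm_fwd_kernel(xp, Wh, bias, I, Fg, G, O, C, TC, Hs)
        else:
            ht = np.zeros((b, h), dtype=F32)
            ct = np.zeros((b, h), dtype=F32)
            for t in range(T):
                a = xp[t] + ht @ Wh + bias
                i = _sigmoid(a[:, :h]); f = _sigmoid(a[:, h:2 * h])
                g = np.tanh(a[:, 2 * h:3 * h]); o = _sigmoid(a[:, 3 * h:])
                ct = f * ct + i * g
                tc = np.tanh(ct)
                ht = o * tc
                I[t] = i; Fg[t] = f; G[t] = g; O[t] = o
                C[t] = ct; TC[t] = tc; Hs[t] = ht
        self._cache = (I, Fg, G, O, C, TC, Hs)
        return np.ascontiguousarray(Hs.transpose(1, 0, 2))

    def backward(self, dout):
        I, Fg, G, O, C, TC, Hs = self._cache
        b, T, h = dout.shape
        Wh = self.params["Wh"]
        dout_tm = np.ascontiguousarray(dout.transpose(1, 0, 2), dtype=F32)
        dA = np.empty((T, b, 4 * h), dtype=F32)

        if _HAVE_NUMBA:
            _lstm_bwd_kernel(dout_tm, np.ascontiguousarray(Wh.T), I, Fg, G, O, C, TC, dA)
        else:
            dh = np.zeros((b, h), dtype=F32)
            dc = np.zeros((b, h), dtype=F32)
            for t in range(T - 1, -1, -1):
                dhv = dh + dout_tm[t]
                tc = TC[t]; o = O[t]; i = I[t]; f = Fg[t]; g = G[t]
                do = dhv * tc
                dcv = dc + dhv * o * (1.0 - tc * tc)
                cp = C[t - 1] if t > 0 else np.zeros_like(dcv)
                dc = dcv * f
                dat = dA[t]
                dat[:, :h] = dcv * g * i * (1.0 - i)
                dat[:, h:2 * h] = dcv * cp * f * (1.0 - f)
                dat[:, 2 * h:3 * h] = dcv * i * (1.0 - g * g)
                dat[:, 3 * h:] = do * o * (1.0 - o)
                dh = dat @ Wh.T

        # recurrent-weight gradient as one GEMM over hidden states shifted by one
        h_prev = np.empty_like(Hs)
        h_prev[0] = 0.0
        h_prev[1:] = Hs[:-1]
        dA_flat = dA.reshape(T * b, 4 * h)
        self.grads = {
            "Wx": self._x_tm.reshape(T * b, self.d_in).T @ dA_flat,
            "Wh": h_prev.reshape(T * b, h).T @ dA_flat,
            "b": dA_flat.sum(axis=0),
        }
        dx_tm = (dA_flat @ self.params["Wx"].T).reshape(T, b, self.d_in)
        return np.ascontiguousarray(dx_tm.transpose(1, 0, 2))

    def out_shape(self, in_shape):
        L, _ = in_shape
        return (L, self.h)


class Regressor:
    """Sequence (or flat) regressor with subject-feature concatenation.

    Forward pipeline: ``seq_layers`` over (B, L, C) -> flatten ->
    ``flatten_dropout`` (optional) -> concatenate the scaled subject
    features -> ``post_layers`` ending in a 1-unit dense head.
    """

    def __init__(self, seq_layers: List[Layer], post_layers: List[Layer],
                 flatten_dropout: Optional[Dropout] = None) -> None:
        self.seq_layers = seq_layers
        self.post_layers = post_layers
        self.flatten_dropout = flatten_dropout

    @property
    def layers(self) -> List[Layer]:
        out = list(self.seq_layers)
        if self.flatten_dropout is not None:
            out.append(self.flatten_dropout)
        out.extend(self.post_layers)
        return out

    def forward(self, x: np.ndarray, feats: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        z = np.ascontiguousarray(x, dtype=F32)
        for layer in self.seq_layers:
            z = layer.forward(z, train, rng)
        self._seq_out_shape = z.shape
        z = z.reshape(z.shape[0], -1)
        if self.flatten_dropout is not None:
            z = self.flatten_dropout.forward(z, train, rng)
        self._n_flat = z.shape[1]
        feats = np.ascontiguousarray(feats, dtype=F32)
        if feats.ndim != 2 or feats.shape[0] != z.shape[0]:
            raise ValueError("subject features must be (batch, n_features)")
        z = np.concatenate([z, feats], axis=1)
        self._n_concat = z.shape[1]
        for layer in self.post_layers:
            z = layer.forward(z, train, rng)
        if z.shape[1] != 1:
            raise ValueError("head must emit one scalar per sample")
        return z[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = np.ascontiguousarray(dpred, dtype=F32)[:, None]
        for layer in reversed(self.post_layers):
            d = layer.backward(d)
        d = d[:, :self._n_flat]  # subject-feature inputs take no gradient
        if self.flatten_dropout is not None:
            d = self.flatten_dropout.backward(d)
        d = d.reshape(self._seq_out_shape)
        for layer in reversed(self.seq_layers):
            d = layer.backward(d)

    # -- parameter plumbing --------------------------------------------------

    def named_params(self):
        for li, layer in enumerate(self.layers):
            for key, arr in layer.params.items():
                yield f"layer{li}.{key}", layer, key, arr

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_arrays(self) -> Dict[str, np.ndarray]:
        return {name: arr for name, _, _, arr in self.named_params()}

    def load_state_arrays(self, state: Dict[str, np.ndarray]) -> None:
        for name, layer, key, arr in self.named_params():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            layer.params[key] = state[name].astype(F32)


class Adam:
    """Adam with per-step learning rate supplied by the caller."""

    def __init__(self, net: Regressor, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, _, _, arr in net.named_params()}
        self.v = {name: np.zeros_like(arr) for name, _, _, arr in net.named_params()}

    def step(self, lr: float, l2_coeff: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, layer, key, arr in self.net.named_params():
            g = layer.grads[key].astype(F32)
            if l2_coeff > 0.0 and key in layer.weight_keys:
                g = g + F32(2.0 * l2_coeff) * arr
            m = self.m[name]; v = self.v[name]
            m *= b1; m += (1.0 - b1) * g
            v *= b2; v += (1.0 - b2) * g * g
            arr -= F32(lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
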