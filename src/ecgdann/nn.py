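"""Small deterministic neural-network engine on numpy.

Implements exactly the layer set the beat classifier needs — unpadded
1-D convolution, max pooling, batch normalization, inverted dropout,
fully connected layers — with explicit backward passes, so every
gradient is inspectable and the alternating update scheme can freeze
parameter groups precisely.  All randomness (initialization, dropout)
flows from explicit ``numpy.random.Generator`` streams, making training
bit-reproducible on one machine.
"""

from __future__ import annotations

import hashlib

import numpy as np

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco

#: Parameter/activation dtype: single precision keeps the big conv GEMMs
#: and their im2col buffers memory-efficient; all ops preserve it.
DTYPE = np.float32

__all__ = [
    "Layer", "Conv1d", "MaxPool1d", "ReLU", "Dropout", "Flatten", "Linear",
    "BatchNorm", "Reshape1d", "ReLUMaxPool2", "Sequential", "SGD",
    "softmax", "sigmoid", "collect_params", "param_hash",
    "get_state", "set_state", "derive_seed",
]


def derive_seed(seed: int, name: str) -> int:
    """Fan a master seed out to a named stream (stable across runs)."""
    h = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little") % (2**31)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: ``params``/``grads`` are parallel dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Arrays to persist (parameters plus any running statistics)."""
        return dict(self.params)

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        for k, v in st.items():
            self.params[k][...] = v


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                     fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# --- numba kernels for the memory-bound hot paths -----------------------
# Single-pass fused implementations of operations that numpy can only
# express as several full-array traversals.  Each has a numpy fallback.

@_njit(fastmath=True, cache=False)
def _nb_conv_c1_fwd(x2, W2, b, y):
    # x2 (B, L); W2 (k, O); y (B, Lo, O)
    B, L = x2.shape
    k, O = W2.shape
    Lo = L - k + 1
    for bi in range(B):
        for l in range(Lo):
            for o in range(O):
                acc = b[o]
                for j in range(k):
                    acc += x2[bi, l + j] * W2[j, o]
                y[bi, l, o] = acc


@_njit(fastmath=True, cache=False)
def _nb_conv_c1_bwd(x2, W2, g, dW2, dx2):
    # g (B, Lo, O); accumulates dW2 (k, O) and dx2 (B, L) in one pass
    B, L = x2.shape
    k, O = W2.shape
    Lo = L - k + 1
    for bi in range(B):
        for l in range(Lo):
            for o in range(O):
                gv = g[bi, l, o]
                for j in range(k):
                    dW2[j, o] += x2[bi, l + j] * gv
                    dx2[bi, l + j] += W2[j, o] * gv


@_njit(fastmath=True, cache=False)
def _nb_relu_maxpool2_fwd(x, y, sel):
    # x (B, L, C) -> y (B, Lo, C); sel: 0/1 = winning tap, 2 = clipped to 0
    B, L, C = x.shape
    Lo = y.shape[1]
    for bi in range(B):
        for l in range(Lo):
            for c in range(C):
                a = x[bi, 2 * l, c]
                b2 = x[bi, 2 * l + 1, c]
                if b2 > a:
                    m, s = b2, 1
                else:
                    m, s = a, 0
                if m > 0.0:
                    y[bi, l, c] = m
                    sel[bi, l, c] = s
                else:
                    y[bi, l, c] = 0.0
                    sel[bi, l, c] = 2


@_njit(fastmath=True, cache=False)
def _nb_relu_maxpool2_bwd(g, sel, dx):
    B, Lo, C = g.shape
    for bi in range(B):
        for l in range(Lo):
            for c in range(C):
                s = sel[bi, l, c]
                if s != 2:
                    dx[bi, 2 * l + s, c] = g[bi, l, c]


@_njit(fastmath=True, cache=False)
def _nb_bn3_stats(x, mean, var):
    B, L, C = x.shape
    m = B * L
    for c in range(C):
        mean[c] = 0.0
        var[c] = 0.0
    for bi in range(B):
        for l in range(L):
            for c in range(C):
                mean[c] += x[bi, l, c]
    for c in range(C):
        mean[c] /= m
    for bi in range(B):
        for l in range(L):
            for c in range(C):
                d = x[bi, l, c] - mean[c]
                var[c] += d * d
    for c in range(C):
        var[c] /= m


@_njit(fastmath=True, cache=False)
def _nb_bn3_norm(x, mean, ivstd, gamma, beta, xhat, y):
    B, L, C = x.shape
    for bi in range(B):
        for l in range(L):
            for c in range(C):
                h = (x[bi, l, c] - mean[c]) * ivstd[c]
                xhat[bi, l, c] = h
                y[bi, l, c] = gamma[c] * h + beta[c]


@_njit(fastmath=True, cache=False)
def _nb_bn3_bwd(g, xhat, gamma, ivstd, dgamma, dbeta, dx):
    B, L, C = g.shape
    m = B * L
    for c in range(C):
        dgamma[c] = 0.0
        dbeta[c] = 0.0
    for bi in range(B):
        for l in range(L):
            for c in range(C):
                dgamma[c] += g[bi, l, c] * xhat[bi, l, c]
                dbeta[c] += g[bi, l, c]
    for bi in range(B):
        for l in range(L):
            for c in range(C):
                dxhat = g[bi, l, c] * gamma[c]
                dx[bi, l, c] = (ivstd[c] / m) * (
                    m * dxhat - dbeta[c] * gamma[c]
                    - xhat[bi, l, c] * dgamma[c] * gamma[c]
                )


class Conv1d(Layer):
    """Unpadded stride-1 1-D convolution, channels-last:
    (B, L, C_in) -> (B, L-k+1, C_out).

    Realized as k accumulated GEMMs ``y += x[:, j:j+Lo, :] @ W[j]`` — on a
    channels-last layout each slice is BLAS-friendly without an im2col
    copy, which is what makes the long discriminator inputs affordable.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        self.params["W"] = _kaiming_uniform(rng, (kernel, c_in, c_out), fan_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        k = self.kernel
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        Lo = L - k + 1
        W = self.params["W"]
        self._x = x
        if C == 1:
            x2 = np.ascontiguousarray(x[:, :, 0])
            self._x2 = x2
            if _HAVE_NUMBA:
                y = np.empty((B, Lo, self.c_out), dtype=x.dtype)
                _nb_conv_c1_fwd(x2, W[:, 0, :], self.params["b"], y)
                return y
            win = np.lib.stride_tricks.sliding_window_view(x2, k, axis=1)
            col = np.ascontiguousarray(win).reshape(B * Lo, k)
            self._col = col
            y = col @ W[:, 0, :] + self.params["b"]
            return y.reshape(B, Lo, self.c_out)
        y = x[:, 0:Lo, :] @ W[0]
        for j in range(1, k):
            y += x[:, j : j + Lo, :] @ W[j]
        y += self.params["b"]
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, k = self._x, self.kernel
        B, L, C = x.shape
        Lo = L - k + 1
        W = self.params["W"]
        dW = np.empty_like(W)
        dx = np.zeros_like(x)
        if C == 1:
            if _HAVE_NUMBA:
                dW2 = np.zeros((k, self.c_out), dtype=g.dtype)
                dx2 = np.zeros((B, L), dtype=g.dtype)
                _nb_conv_c1_bwd(self._x2, W[:, 0, :], np.ascontiguousarray(g),
                                dW2, dx2)
                dW[:, 0, :] = dW2
                dx[:, :, 0] = dx2
            else:
                g2 = g.reshape(B * Lo, self.c_out)
                dW[:, 0, :] = self._col.T @ g2
                dcol = (g2 @ W[:, 0, :].T).reshape(B, Lo, k)
                for j in range(k):
                    dx[:, j : j + Lo, 0] += dcol[:, :, j]
        else:
            for j in range(k):
                xs = x[:, j : j + Lo, :]
                dW[j] = np.matmul(xs.transpose(0, 2, 1), g).sum(axis=0)
                dx[:, j : j + Lo, :] += g @ W[j].T
        self.grads["W"] = dW
        self.grads["b"] = g.sum(axis=(0, 1))
        return dx


class MaxPool1d(Layer):
    """Max pooling over the time axis of a channels-last (B, L, C) input:
    L -> floor((L - k) / s) + 1."""

    def __init__(self, kernel: int = 2, stride: int = 2) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        B, L, C = x.shape
        k, s = self.kernel, self.stride
        Lo = (L - k) // s + 1
        if k == 2 and s == 2:
            # dominant case: pairwise comparison, no argmax/scatter machinery
            x0, x1 = x[:, 0 : 2 * Lo : 2, :], x[:, 1 : 2 * Lo : 2, :]
            self._take1 = x1 > x0  # ties keep the earlier sample
            return np.where(self._take1, x1, x0)
        self._take1 = None
        if s == k:
            win = np.ascontiguousarray(x[:, : Lo * k, :]).reshape(B, Lo, k, C)
        else:
            win = np.lib.stride_tricks.sliding_window_view(
                x, k, axis=1
            )[:, ::s].transpose(0, 1, 3, 2)  # (B, Lo, k, C)
        self._idx = win.argmax(axis=2)
        return np.take_along_axis(win, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, Lout, C = g.shape
        k, s = self.kernel, self.stride
        dx = np.zeros(self._in_shape, dtype=g.dtype)
        if self._take1 is not None:
            dx[:, 0 : 2 * Lout : 2, :] = np.where(self._take1, 0.0, g)
            dx[:, 1 : 2 * Lout : 2, :] = np.where(self._take1, g, 0.0)
        elif s == k:
            dwin = np.zeros((B, Lout, k, C), dtype=g.dtype)
            np.put_along_axis(dwin, self._idx[:, :, None, :], g[:, :, None, :], axis=2)
            dx[:, : Lout * k, :] = dwin.reshape(B, Lout * k, C)
        else:  # overlapping windows may collide -> scatter-add
            pos = (np.arange(Lout) * s)[None, :, None] + self._idx
            bi = np.arange(B)[:, None, None]
            ci = np.arange(C)[None, None, :]
            np.add.at(dx, (bi, pos, ci), g)
        return dx


class ReLUMaxPool2(Layer):
    """Fused ReLU followed by MaxPool(kernel 2, stride 2).

    The two operations commute exactly (ReLU is monotone), so the fused
    result and gradient match the separate layers; fusing them turns
    four full-array traversals into one.  ``sel`` records, per output,
    which of the two pooled taps won (0/1) or 2 when the maximum was
    clipped to zero (no gradient flows).
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        B, L, C = x.shape
        Lo = (L - 2) // 2 + 1
        if _HAVE_NUMBA:
            x = np.ascontiguousarray(x)
            y = np.empty((B, Lo, C), dtype=x.dtype)
            sel = np.empty((B, Lo, C), dtype=np.int8)
            _nb_relu_maxpool2_fwd(x, y, sel)
            self._sel = sel
            return y
        x0, x1 = x[:, 0 : 2 * Lo, :][:, ::2], x[:, 1 : 2 * Lo, :][:, ::2]
        take1 = x1 > x0
        m = np.where(take1, x1, x0)
        self._sel = np.where(m <= 0, np.int8(2), take1.astype(np.int8))
        return np.maximum(m, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=g.dtype)
        if _HAVE_NUMBA:
            _nb_relu_maxpool2_bwd(np.ascontiguousarray(g), self._sel, dx)
            return dx
        Lo = g.shape[1]
        sel = self._sel
        dx[:, 0 : 2 * Lo : 2, :] = np.where(sel == 0, g, 0.0)
        dx[:, 1 : 2 * Lo : 2, :] = np.where(sel == 1, g, 0.0)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        np.multiply(g, self._mask, out=g)  # upstream gradient is never reused
        return g


class Dropout(Layer):
    """Inverted dropout with a private RNG stream (bit-reproducible)."""

    def __init__(self, rate: float, seed: int) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Reshape1d(Layer):
    """(B, F) -> (B, F, 1): view a flat feature vector as a 1-channel signal."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x[:, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g[:, :, 0]


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _kaiming_uniform(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalization per trailing-axis component.

    Handles both fully connected activations (B, F) and channels-last
    conv maps (B, L, C): statistics are taken over every axis except the
    last.  Running statistics (momentum 0.1) serve evaluation mode.
    """

    def __init__(self, n: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n, dtype=DTYPE)
        self.params["beta"] = np.zeros(n, dtype=DTYPE)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._m_count = int(np.prod(x.shape[:-1]))
        self._train = train
        use_nb = _HAVE_NUMBA and x.ndim == 3
        if train:
            if use_nb:
                x = np.ascontiguousarray(x)
                mean = np.empty(x.shape[-1], dtype=x.dtype)
                var = np.empty(x.shape[-1], dtype=x.dtype)
                _nb_bn3_stats(x, mean, var)
            else:
                ax = tuple(range(x.ndim - 1))
                mean = x.mean(axis=ax)
                var = x.var(axis=ax)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        if use_nb:
            x = np.ascontiguousarray(x)
            self._xhat = np.empty_like(x)
            y = np.empty_like(x)
            _nb_bn3_norm(x, mean.astype(x.dtype), self._ivstd,
                         self.params["gamma"].astype(x.dtype),
                         self.params["beta"].astype(x.dtype), self._xhat, y)
            return y
        self._xhat = (x - mean) * self._ivstd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        if _HAVE_NUMBA and g.ndim == 3 and self._train:
            g = np.ascontiguousarray(g)
            C = g.shape[-1]
            dgamma = np.empty(C, dtype=g.dtype)
            dbeta = np.empty(C, dtype=g.dtype)
            dx = np.empty_like(g)
            _nb_bn3_bwd(g, self._xhat, self.params["gamma"].astype(g.dtype),
                        self._ivstd, dgamma, dbeta, dx)
            self.grads["gamma"] = dgamma
            self.grads["beta"] = dbeta
            return dx
        ax = tuple(range(g.ndim - 1))
        self.grads["gamma"] = (g * self._xhat).sum(axis=ax)
        self.grads["beta"] = g.sum(axis=ax)
        dxhat = g * self.params["gamma"]
        if not self._train:
            return dxhat * self._ivstd
        m = self._m_count
        sum_dxhat = dxhat.sum(axis=ax)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=ax)
        return (self._ivstd / m) * (
            m * dxhat - sum_dxhat - self._xhat * sum_dxhat_xhat
        )

    def state(self) -> dict[str, np.ndarray]:
        st = dict(self.params)
        st["running_mean"] = self.running_mean
        st["running_var"] = self.running_var
        return st

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        self.params["gamma"][...] = st["gamma"]
        self.params["beta"][...] = st["beta"]
        self.running_mean[...] = st["running_mean"]
        self.running_var[...] = st["running_var"]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.children = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.children:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.children):
            g = layer.backward(g)
        return g


def _iter_layers(net: Layer):
    """Depth-first leaves of a layer tree (containers expose ``children``)."""
    children = getattr(net, "children", None)
    if children:
        for child in children:
            yield from _iter_layers(child)
    else:
        yield net


def collect_params(*nets: Layer) -> list[tuple[Layer, str]]:
    """Flat list of (layer, parameter-name) across one or more networks."""
    out = []
    for net in nets:
        for layer in _iter_layers(net):
            for name in layer.params:
                out.append((layer, name))
    return out


def param_hash(*nets: Layer) -> str:
    """Digest of every parameter array — used to assert frozen groups."""
    h = hashlib.blake2b(digest_size=16)
    for layer, name in collect_params(*nets):
        h.update(np.ascontiguousarray(layer.params[name]).tobytes())
    return h.hexdigest()


def get_state(*nets: Layer) -> dict[str, np.ndarray]:
    st = {}
    for i, net in enumerate(nets):
        for j, layer in enumerate(_iter_layers(net)):
            for k, v in layer.state().items():
                st[f"{i}.{j}.{k}"] = v.copy()
    return st


def set_state(st: dict[str, np.ndarray], *nets: Layer) -> None:
    for i, net in enumerate(nets):
        for j, layer in enumerate(_iter_layers(net)):
            keys = layer.state().keys()
            layer.load_state({k: st[f"{i}.{j}.{k}"] for k in keys})


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float,
                 momentum: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(layer.params[name]) for layer, name in params]

    def step(self) -> None:
        for (layer, name), vel in zip(self.params, self._vel):
            g = layer.grads[name]
            if self.momentum:
                vel *= self.momentum
                vel += g
                g = vel
            layer.params[name] -= self.lr * g
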