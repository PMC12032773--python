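"""Compact convolutional EEG decoder implemented on NumPy.

The architecture follows the compact-CNN design for raw EEG: a temporal
convolution bank (F1 kernels, ~0.5 s), a depthwise spatial convolution across
all electrodes (multiplier D, max-norm constrained), and a separable
(depthwise temporal + pointwise) convolution to F2 maps; each block is
batch-normalized, ELU-activated, average-pooled and dropout-regularized,
ending in a dense softmax over the two classes.  Training is Adam on softmax
cross-entropy with deterministic seeding.  Convolutions run in the Fourier
domain, with hand-derived adjoints for the backward pass.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len

from .config import CNNConfig

_EPS = 1e-5


# ---------------------------------------------------------------------------
# FFT 1-D same-size cross-correlation and its adjoints (odd kernel lengths)
# ---------------------------------------------------------------------------

def corr1d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """y[..., t] = sum_k w[..., k] * x[..., t - p + k], p = (K-1)//2."""
    K = w.shape[-1]
    T = x.shape[-1]
    p = (K - 1) // 2
    L = next_fast_len(T + K)
    y = np.fft.irfft(np.fft.rfft(x, L) * np.fft.rfft(w[..., ::-1], L), L)
    return y[..., K - 1 - p:K - 1 - p + T]


def corr1d_same_grad_x(g: np.ndarray, w: np.ndarray, T: int) -> np.ndarray:
    K = w.shape[-1]
    p = (K - 1) // 2
    L = next_fast_len(T + K)
    dx = np.fft.irfft(np.fft.rfft(g, L) * np.fft.rfft(w, L), L)
    return dx[..., p:p + T]


def corr1d_same_grad_w(x: np.ndarray, g: np.ndarray, K: int) -> np.ndarray:
    """dw[..., k] = sum_t x[..., t + k - p] * g[..., t] (lags via circular corr)."""
    T = x.shape[-1]
    p = (K - 1) // 2
    L = next_fast_len(T + K)
    c = np.fft.irfft(np.fft.rfft(x, L) * np.conj(np.fft.rfft(g, L)), L)
    lags = (np.arange(K) - p) % L
    return c[..., lags]


# ---------------------------------------------------------------------------
# small layer helpers (train-time caches kept in plain dicts)
# ---------------------------------------------------------------------------

def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(y, g):
    return np.where(y > 0, g, g * (y + 1.0))


def _avgpool(x, p):
    T = x.shape[-1] // p * p
    return x[..., :T].reshape(*x.shape[:-1], T // p, p).mean(-1)


def _avgpool_grad(g, p, T):
    up = np.repeat(g, p, axis=-1) / p
    if up.shape[-1] < T:
        up = np.concatenate([up, np.zeros((*up.shape[:-1], T - up.shape[-1]), up.dtype)], -1)
    return up


class _BatchNorm:
    """Batch normalization over all axes except the given feature axis."""

    def __init__(self, n_feat: int, axis: int):
        self.gamma = np.ones(n_feat)
        self.beta = np.zeros(n_feat)
        self.run_mean = np.zeros(n_feat)
        self.run_var = np.ones(n_feat)
        self.axis = axis
        self.momentum = 0.9
        self.cache = None

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[self.axis] = x.shape[self.axis]
        return shape

    def forward(self, x, train: bool):
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        if train:
            self.cache = (xhat, inv, axes, sh)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, g):
        xhat, inv, axes, sh = self.cache
        m = np.prod([xhat.shape[i] for i in axes])
        self.d_gamma = (g * xhat).sum(axis=axes)
        self.d_beta = g.sum(axis=axes)
        gx = g * self.gamma.reshape(sh)
        dx = (inv.reshape(sh) / m) * (
            m * gx
            - gx.sum(axis=axes).reshape(sh)
            - xhat * (gx * xhat).sum(axis=axes).reshape(sh)
        )
        return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


class CompactCNN:
    """Forward/backward of the three-block compact CNN (binary softmax head)."""

    def __init__(self, cfg: CNNConfig, n_channels: int, n_times: int, seed: int = 0):
        self.cfg = cfg
        self.C, self.T = n_channels, n_times
        rng = np.random.default_rng(seed)
        F1, D, F2 = cfg.f1, cfg.depth_multiplier, cfg.f2
        K1, K2 = cfg.temporal_kernel, cfg.separable_kernel
        if K1 % 2 == 0 or K2 % 2 == 0:
            raise ValueError("kernel lengths must be odd")
        self.M = F1 * D
        self.T1 = n_times // cfg.pool1
        self.T2 = self.T1 // cfg.pool2
        glorot = lambda *s: rng.normal(0.0, np.sqrt(2.0 / (s[0] + s[-1])), size=s)
        self.params = {
            "w_temp": glorot(F1, K1) / np.sqrt(K1),
            "w_spat": glorot(F1 * D, n_channels).reshape(F1, D, n_channels),
            "w_sep": glorot(self.M, K2) / np.sqrt(K2),
            "w_point": glorot(F2, self.M),
            "w_dense": glorot(2, F2 * self.T2),
            "b_dense": np.zeros(2),
        }
        self.bn1 = _BatchNorm(F1, axis=1)
        self.bn2 = _BatchNorm(self.M, axis=1)
        self.bn3 = _BatchNorm(F2, axis=1)

    @property
    def n_parameters(self) -> int:
        n = sum(p.size for p in self.params.values())
        for bn in (self.bn1, self.bn2, self.bn3):
            n += bn.gamma.size + bn.beta.size
        return n

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        cfg = self.cfg
        cache = {"x": x}
        # block 1: temporal conv bank -> BN -> depthwise spatial -> BN -> ELU -> pool -> drop
        h1 = corr1d_same(x[:, None, :, :], self.params["w_temp"][None, :, None, :])
        h1 = self.bn1.forward(h1, train)
        cache["h1"] = h1
        h2 = np.einsum("nfct,fdc->nfdt", h1, self.params["w_spat"])
        h2 = h2.reshape(x.shape[0], self.M, -1)
        h2 = self.bn2.forward(h2, train)
        a2 = _elu(h2)
        p2 = _avgpool(a2, cfg.pool1)
        cache["a2"], cache["len_a2"] = a2, a2.shape[-1]
        if train:
            mask2 = (rng.random(p2.shape) >= cfg.dropout) / (1 - cfg.dropout)
            p2 = p2 * mask2
            cache["mask2"] = mask2
        cache["p2"] = p2
        # block 2: separable conv -> BN -> ELU -> pool -> drop
        h3 = corr1d_same(p2, self.params["w_sep"][None, :, :])
        cache["h3_in"] = p2
        h4 = np.einsum("nmt,gm->ngt", h3, self.params["w_point"])
        cache["h3"] = h3
        h4 = self.bn3.forward(h4, train)
        a4 = _elu(h4)
        p4 = _avgpool(a4, cfg.pool2)
        cache["a4"], cache["len_a4"] = a4, a4.shape[-1]
        if train:
            mask4 = (rng.random(p4.shape) >= cfg.dropout) / (1 - cfg.dropout)
            p4 = p4 * mask4
            cache["mask4"] = mask4
        flat = p4.reshape(x.shape[0], -1)
        cache["flat"] = flat
        logits = flat @ self.params["w_dense"].T + self.params["b_dense"]
        return logits, cache

    def backward(self, cache, g_logits):
        cfg = self.cfg
        grads = {}
        grads["w_dense"] = g_logits.T @ cache["flat"]
        grads["b_dense"] = g_logits.sum(0)
        g = (g_logits @ self.params["w_dense"]).reshape(
            -1, self.cfg.f2, self.T2
        )
        if "mask4" in cache:
            g = g * cache["mask4"]
        g = _avgpool_grad(g, cfg.pool2, cache["len_a4"])
        g = _elu_grad(cache["a4"], g)
        g = self.bn3.backward(g)
        grads["w_point"] = np.einsum("ngt,nmt->gm", g, cache["h3"])
        g = np.einsum("ngt,gm->nmt", g, self.params["w_point"])
        grads["w_sep"] = corr1d_same_grad_w(cache["h3_in"], g, cfg.separable_kernel).sum(0)
        g = corr1d_same_grad_x(g, self.params["w_sep"][None, :, :], cache["h3_in"].shape[-1])
        if "mask2" in cache:
            g = g * cache["mask2"]
        g = _avgpool_grad(g, cfg.pool1, cache["len_a2"])
        g = _elu_grad(cache["a2"], g)
        g = self.bn2.backward(g)
        g = g.reshape(g.shape[0], cfg.f1, cfg.depth_multiplier, -1)
        grads["w_spat"] = np.einsum("nfdt,nfct->fdc", g, cache["h1"])
        g = np.einsum("nfdt,fdc->nfct", g, self.params["w_spat"])
        g = self.bn1.backward(g)
        grads["w_temp"] = corr1d_same_grad_w(
            cache["x"][:, None, :, :], g, cfg.temporal_kernel
        ).sum(axis=(0, 2))
        for bn, name in ((self.bn1, "bn1"), (self.bn2, "bn2"), (self.bn3, "bn3")):
            grads[f"{name}_gamma"] = bn.d_gamma
            grads[f"{name}_beta"] = bn.d_beta
        return grads


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CompactCNNDecoder:
    """fit/predict wrapper with Adam training, deterministic under the seed."""

    def __init__(self, cfg: CNNConfig | None = None, n_channels: int | None = None,
                 n_times: int | None = None, seed: int = 0):
        self.cfg = cfg or CNNConfig()
        self.seed = seed
        self.n_channels = n_channels
        self.n_times = n_times
        self.net: CompactCNN | None = None

    def _build(self, X):
        self.net = CompactCNN(self.cfg, X.shape[1], X.shape[2], seed=self.seed)
        self._bn_params = {}
        for name, bn in (("bn1", self.net.bn1), ("bn2", self.net.bn2), ("bn3", self.net.bn3)):
            self._bn_params[f"{name}_gamma"] = bn.gamma
            self._bn_params[f"{name}_beta"] = bn.beta

    def _standardize(self, X, fit=False):
        if fit:
            self._mu = X.mean(axis=(0, 2), keepdims=True)
            self._sd = X.std(axis=(0, 2), keepdims=True) + 1e-12
        return ((X - self._mu) / self._sd).astype(np.float64)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary decoder")
        yi = (np.asarray(y) == self.classes_[1]).astype(int)
        X = self._standardize(X, fit=True)
        self._build(X)
        rng = np.random.default_rng(self.seed + 1)
        all_params = {**self.net.params, **self._bn_params}
        opt = _Adam(all_params, self.cfg.lr)
        n = X.shape[0]
        bs = min(self.cfg.batch_size, n)
        for ep in range(self.cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if idx.size < 2:
                    continue
                logits, cache = self.net.forward(X[idx], train=True, rng=rng)
                prob = _softmax(logits)
                if not np.all(np.isfinite(prob)):
                    raise FloatingPointError("non-finite loss during CNN training")
                g = (prob - np.eye(2)[yi[idx]]) / idx.size
                grads = self.net.backward(cache, g)
                opt.step(all_params, grads)
                # max-norm constraint on the spatial filters
                w = self.net.params["w_spat"]
                norm = np.linalg.norm(w, axis=2, keepdims=True)
                np.multiply(w, np.minimum(1.0, self.cfg.max_norm / np.maximum(norm, 1e-12)),
                            out=w)
        return self

    def predict_proba(self, X):
        X = self._standardize(np.asarray(X, dtype=np.float64))
        out = []
        for start in range(0, X.shape[0], 256):
            logits, _ = self.net.forward(X[start:start + 256], train=False)
            out.append(_softmax(logits))
        return np.concatenate(out)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]
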