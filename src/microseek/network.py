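"""A compact numpy convolutional network for 3-class read-origin scoring.

Architecture: conv(64 filters, width 8, ReLU) -> max-pool 2 ->
conv(32, width 8, ReLU) -> global max-pool -> dense(64, ReLU) ->
dense(3, softmax), trained with cross-entropy and Adam.  Input is a one-hot
76 x 4 encoding (A, C, G, T); N never reaches the model — read
normalization resolves it first.

The forward/backward passes are written with im2col so every layer is a
dense matmul; at the fixture scales this trains in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import BASES

_BASE_LUT = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i


def one_hot(segments: list[str], length: int = 76) -> np.ndarray:
    """Encode equal-length A/C/G/T strings as (n, length, 4) float32."""
    n = len(segments)
    if n == 0:
        return np.zeros((0, length, 4), dtype=np.float32)
    flat = np.frombuffer("".join(segments).encode(), dtype=np.uint8).reshape(n, -1)
    if flat.shape[1] != length:
        raise ValueError(f"expected length-{length} segments, got {flat.shape[1]}")
    idx = _BASE_LUT[flat]
    if (idx < 0).any():
        raise ValueError("segments must contain only A/C/G/T")
    out = np.zeros((n, length, 4), dtype=np.float32)
    np.put_along_axis(out, idx[:, :, None].astype(np.int64), 1.0, axis=2)
    return out


@dataclass
class ClassifierConfig:
    input_length: int = 76
    conv1_filters: int = 64
    conv1_width: int = 8
    pool_size: int = 2
    conv2_filters: int = 32
    conv2_width: int = 8
    dense_units: int = 64
    epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    rng_seed: int = 0


def _windows(x: np.ndarray, width: int) -> np.ndarray:
    """im2col: (n, L, c) -> (n, L-width+1, width*c)."""
    v = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)  # (n, L-w+1, c, w)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(x.shape[0], -1, width * x.shape[2])


class ReadOriginNet:
    """Two convolutional layers and one fully-connected hidden layer."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        c = self.config
        rng = np.random.default_rng(c.rng_seed)

        def he(shape):
            fan_in = shape[0]
            return (rng.normal(0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)

        self.params = {
            "w1": he((c.conv1_width * 4, c.conv1_filters)),
            "b1": np.zeros(c.conv1_filters, dtype=np.float32),
            "w2": he((c.conv2_width * c.conv1_filters, c.conv2_filters)),
            "b2": np.zeros(c.conv2_filters, dtype=np.float32),
            "w3": he((c.conv2_filters, c.dense_units)),
            "b3": np.zeros(c.dense_units, dtype=np.float32),
            "w4": he((c.dense_units, 3)),
            "b4": np.zeros(3, dtype=np.float32),
        }

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        c = self.config
        p = self.params
        cols1 = _windows(x, c.conv1_width)
        z1 = cols1 @ p["w1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        # max-pool, stride = size; trailing remainder dropped
        n, l1, f1 = a1.shape
        l1c = (l1 // c.pool_size) * c.pool_size
        pooled_in = a1[:, :l1c].reshape(n, l1c // c.pool_size, c.pool_size, f1)
        pool_arg = pooled_in.argmax(axis=2)
        pooled = pooled_in.max(axis=2)
        cols2 = _windows(pooled, c.conv2_width)
        z2 = cols2 @ p["w2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        g_arg = a2.argmax(axis=1)
        g = a2.max(axis=1)
        h_pre = g @ p["w3"] + p["b3"]
        h = np.maximum(h_pre, 0.0)
        logits = h @ p["w4"] + p["b4"]
        cache = dict(x=x, cols1=cols1, z1=z1, pooled_in=pooled_in, pool_arg=pool_arg,
                     pooled=pooled, cols2=cols2, z2=z2, a2=a2, g_arg=g_arg, g=g,
                     h_pre=h_pre, h=h, l1c=l1c)
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self._forward(x[i : i + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out) if out else np.zeros((0, 3))

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        c = self.config
        p = self.params
        n = len(x)
        logits, cc = self._forward(x)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads: dict[str, np.ndarray] = {}
        grads["w4"] = cc["h"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dh = (dlogits @ p["w4"].T) * (cc["h_pre"] > 0)
        grads["w3"] = cc["g"].T @ dh
        grads["b3"] = dh.sum(axis=0)
        dg = dh @ p["w3"].T  # (n, f2)

        da2 = np.zeros_like(cc["a2"])
        np.put_along_axis(da2, cc["g_arg"][:, None, :], dg[:, None, :], axis=1)
        dz2 = da2 * (cc["z2"] > 0)
        f2_in = c.conv2_width * c.conv1_filters
        grads["w2"] = cc["cols2"].reshape(-1, f2_in).T @ dz2.reshape(-1, c.conv2_filters)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = (dz2 @ p["w2"].T).reshape(n, -1, c.conv2_width, c.conv1_filters)
        dpooled = np.zeros_like(cc["pooled"])
        for k in range(c.conv2_width):
            dpooled[:, k : k + dcols2.shape[1]] += dcols2[:, :, k, :]

        dpooled_in = np.zeros_like(cc["pooled_in"])
        np.put_along_axis(dpooled_in, cc["pool_arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        da1 = np.zeros_like(cc["z1"])
        da1[:, : cc["l1c"]] = dpooled_in.reshape(n, cc["l1c"], c.conv1_filters)
        dz1 = da1 * (cc["z1"] > 0)
        f1_in = c.conv1_width * 4
        grads["w1"] = cc["cols1"].reshape(-1, f1_in).T @ dz1.reshape(-1, c.conv1_filters)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return loss, grads

    # -- persistence -------------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=np.float32).copy() for k, v in params.items()}

    def save(self, path: str) -> None:
        meta = {f"cfg_{k}": v for k, v in vars(self.config).items()}
        np.savez(path, **self.params, **meta)

    @classmethod
    def load(cls, path: str) -> "ReadOriginNet":
        data = np.load(path)
        cfg_kwargs = {}
        for k in data.files:
            if k.startswith("cfg_"):
                v = data[k].item()
                cfg_kwargs[k[4:]] = v
        net = cls(ClassifierConfig(**cfg_kwargs))
        net.set_params({k: data[k] for k in data.files if not k.startswith("cfg_")})
        return net


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
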