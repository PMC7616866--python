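"""A compact 1-D residual convolutional network in pure numpy.

Layers keep their own parameters, Adam state and backward passes; the
network maps a (batch, 12, 4096) signal tensor through a convolutional stem
and a stack of residual blocks to a flattened penultimate feature vector
(the "embedding"), followed by a single linear classification head with one
sigmoid output per diagnosis.  Removing the head therefore exposes the
embedding unchanged.

Everything runs in float32; all initialization flows from one seeded
Generator, so training is bit-reproducible on a fixed backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ArchConfig", "TrainConfig", "ECGResNet",
           "default_arch", "desk_arch", "sharp_desk_arch", "tiny_arch",
           "ARCH_PRESETS", "resolve_arch"]


@dataclass(frozen=True)
class ArchConfig:
    """Network sizing.

    The embedding dimension is ``final filters x final temporal length``,
    where the final temporal length is the input length divided by the
    product of the per-block subsampling factors.  The default configuration
    (4096 input, x4 subsampling in each of 4 blocks, 320 final filters)
    yields 16 x 320 = 5120 features and a 6-wide head.
    """

    n_leads: int = 12
    input_len: int = 4096
    stem_filters: int = 64
    stem_kernel: int = 17
    block_filters: tuple[int, ...] = (128, 196, 256, 320)
    block_strides: tuple[int, ...] = (4, 4, 4, 4)
    block_kernel: int = 17
    n_outputs: int = 6

    def __post_init__(self) -> None:
        if len(self.block_filters) != len(self.block_strides):
            raise ValueError("block_filters and block_strides must align")
        if self.stem_kernel % 2 == 0 or self.block_kernel % 2 == 0:
            raise ValueError("kernels must be odd (symmetric padding)")
        L = self.input_len
        for s in self.block_strides:
            if L % s:
                raise ValueError(
                    f"temporal length {L} not divisible by subsampling {s}")
            L //= s

    @property
    def final_len(self) -> int:
        L = self.input_len
        for s in self.block_strides:
            L //= s
        return L

    @property
    def embedding_dim(self) -> int:
        return self.final_len * self.block_filters[-1]


def default_arch() -> ArchConfig:
    """Full-size configuration: 16 time steps x 320 filters = 5120 features."""
    return ArchConfig()


def desk_arch() -> ArchConfig:
    """CPU-trainable configuration: 16 steps x 64 filters = 1024 features."""
    return ArchConfig(stem_filters=16, stem_kernel=9,
                      block_filters=(32, 32, 48, 64))


def sharp_desk_arch() -> ArchConfig:
    """Desk configuration with a small receptive field and fine final maps.

    Two kernel-3 blocks with x2 subsampling keep 1024 time steps (10 ms
    bins) and a ~50 ms receptive field, so class-activation maps can
    resolve within-beat structure; the trade-off is weaker long-range
    context for rhythm labels than the deeper presets.
    """
    return ArchConfig(stem_filters=8, stem_kernel=3,
                      block_filters=(12, 16),
                      block_strides=(2, 2), block_kernel=3)


def tiny_arch() -> ArchConfig:
    """Minimal configuration for fast unit-level training runs."""
    return ArchConfig(stem_filters=6, stem_kernel=9,
                      block_filters=(8, 8, 8, 8), block_kernel=9)


ARCH_PRESETS = {"default": default_arch, "desk": desk_arch,
                "sharp": sharp_desk_arch, "tiny": tiny_arch}


def resolve_arch(arch: "ArchConfig | str") -> ArchConfig:
    if isinstance(arch, ArchConfig):
        return arch
    try:
        return ARCH_PRESETS[arch]()
    except KeyError:
        raise ValueError(f"unknown architecture preset {arch!r}") from None


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv1d:
    """Same-padded strided 1-D convolution via im2col + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, (c_out, c_in, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.stride = stride
        self.kernel = kernel
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pad = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        out = np.tensordot(cols, self.w, axes=([1, 3], [1, 2]))  # (B, Lout, Cout)
        out += self.b
        if train:
            self._cache = (cols, x.shape[-1])
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, L = self._cache
        self.db = dy.sum(axis=(0, 2)).astype(np.float32)
        # (Cout, Cin, K) from (B, Cout, Lout) x (B, Cin, Lout, K)
        self.dw = np.tensordot(dy, cols, axes=([0, 2], [0, 2])).astype(np.float32)
        pad = (self.kernel - 1) // 2
        B, _, Lout = dy.shape
        dxp = np.zeros((B, self.w.shape[1], L + 2 * pad), dtype=np.float32)
        pos = self.stride * np.arange(Lout)
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, Lout, Cout)
        for i in range(self.kernel):
            contrib = dyt @ self.w[:, :, i]                # (B, Lout, Cin)
            dxp[:, :, pos + i] += contrib.transpose(0, 2, 1)
        return dxp[:, :, pad:pad + L]

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm1d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.w = np.ones(c, dtype=np.float32)   # gamma
        self.b = np.zeros(c, dtype=np.float32)  # beta
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        if train:
            self._cache = (xhat, inv)
        return self.w[:, None] * xhat + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.dw = (dy * xhat).sum(axis=(0, 2)).astype(np.float32)
        self.db = dy.sum(axis=(0, 2)).astype(np.float32)
        dxhat = dy * self.w[:, None]
        dx = (inv[:, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True).transpose(0, 1, 2)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        return dx.astype(np.float32)

    def params(self):
        return [("w", self), ("b", self)]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / d_in)
        self.w = rng.normal(0.0, scale, (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.dw = (x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return dy @ self.w.T

    def params(self):
        return [("w", self), ("b", self)]


class _ResBlock:
    """conv-BN-ReLU-conv-BN with a strided 1x1 projection skip, ReLU after."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = _Conv1d(c_in, c_out, kernel, stride, rng)
        self.bn1 = _BatchNorm1d(c_out)
        self.conv2 = _Conv1d(c_out, c_out, kernel, 1, rng)
        self.bn2 = _BatchNorm1d(c_out)
        self.project = (stride != 1) or (c_in != c_out)
        if self.project:
            self.skip = _Conv1d(c_in, c_out, 1, stride, rng)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        mask1 = h > 0
        h = h * mask1
        y = self.bn2.forward(self.conv2.forward(h, train), train)
        r = self.skip.forward(x, train) if self.project else x
        out = y + r
        mask2 = out > 0
        if train:
            self._cache = (mask1, mask2)
        return out * mask2

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask1, mask2 = self._cache
        dy = dy * mask2
        dr = dy
        dh = self.conv2.backward(self.bn2.backward(dy)) * mask1
        dx = self.conv1.backward(self.bn1.backward(dh))
        if self.project:
            dx = dx + self.skip.backward(dr)
        else:
            dx = dx + dr
        return dx

    def params(self):
        out = []
        for name, layer in (("conv1", self.conv1), ("bn1", self.bn1),
                            ("conv2", self.conv2), ("bn2", self.bn2)):
            out += [(f"{name}.{p}", obj) for p, obj in layer.params()]
        if self.project:
            out += [(f"skip.{p}", obj) for p, obj in self.skip.params()]
        return out


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class ECGResNet:
    """Residual 1-D CNN: stem conv-BN-ReLU, residual blocks, linear head."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.stem = _Conv1d(arch.n_leads, arch.stem_filters,
                            arch.stem_kernel, 1, rng)
        self.stem_bn = _BatchNorm1d(arch.stem_filters)
        self.blocks: list[_ResBlock] = []
        c_in = arch.stem_filters
        for c_out, stride in zip(arch.block_filters, arch.block_strides):
            self.blocks.append(_ResBlock(c_in, c_out, arch.block_kernel,
                                         stride, rng))
            c_in = c_out
        self.head = _Dense(arch.embedding_dim, arch.n_outputs, rng)
        self._stem_mask = None

    # -- introspection ------------------------------------------------------

    @property
    def embedding_dim(self) -> int:
        """Penultimate (flattened) feature count."""
        return self.arch.embedding_dim

    @property
    def n_outputs(self) -> int:
        return self.arch.n_outputs

    # -- forward / backward -------------------------------------------------

    def _validate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.arch.n_leads, self.arch.input_len):
            raise ValueError(
                f"input must be (batch, {self.arch.n_leads}, "
                f"{self.arch.input_len}), got {x.shape}")
        return x

    def feature_maps(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Last-block activations, shape (batch, C_final, T_final)."""
        x = self._validate(x)
        h = self.stem_bn.forward(self.stem.forward(x, train), train)
        mask = h > 0
        if train:
            self._stem_mask = mask
        h = h * mask
        for blk in self.blocks:
            h = blk.forward(h, train)
        return h

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate feature vectors, shape (batch, embedding_dim)."""
        maps = self.feature_maps(x, train=False)
        return maps.reshape(maps.shape[0], -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Head logits, shape (batch, n_outputs)."""
        maps = self.feature_maps(x, train)
        emb = maps.reshape(maps.shape[0], -1)
        return self.head.forward(emb, train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward(x, train=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dlogits: np.ndarray) -> None:
        demb = self.head.backward(dlogits)
        B = demb.shape[0]
        dmaps = demb.reshape(B, self.arch.block_filters[-1], self.arch.final_len)
        for blk in reversed(self.blocks):
            dmaps = blk.backward(dmaps)
        self.stem.backward(self.stem_bn.backward(dmaps * self._stem_mask))

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[tuple[str, object, str]]:
        """Flat (qualified name, layer object, attribute) parameter list."""
        out = [("stem.w", self.stem, "w"), ("stem.b", self.stem, "b"),
               ("stem_bn.w", self.stem_bn, "w"), ("stem_bn.b", self.stem_bn, "b")]
        for i, blk in enumerate(self.blocks):
            out += [(f"block{i}.{name}", obj, name.split(".")[-1])
                    for name, obj in blk.params()]
        out += [("head.w", self.head, "w"), ("head.b", self.head, "b")]
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: getattr(obj, attr).copy()
                 for name, obj, attr in self.params()}
        for name, bn in self._batchnorms():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, obj, attr in self.params():
            setattr(obj, attr, np.asarray(state[name], dtype=np.float32))
        for name, bn in self._batchnorms():
            bn.running_mean = np.asarray(state[f"{name}.running_mean"],
                                         dtype=np.float32)
            bn.running_var = np.asarray(state[f"{name}.running_var"],
                                        dtype=np.float32)

    def _batchnorms(self):
        yield "stem_bn", self.stem_bn
        for i, blk in enumerate(self.blocks):
            yield f"block{i}.bn1", blk.bn1
            yield f"block{i}.bn2", blk.bn2

    # -- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
            label_mask: np.ndarray | None = None) -> list[float]:
        """Adam on per-label binary cross-entropy; returns per-epoch losses.

        ``label_mask`` silences the loss of single-class label columns so
        training proceeds on the remaining labels.
        """
        x = self._validate(x)
        y = np.asarray(y, dtype=np.float32)
        if label_mask is None:
            label_mask = np.ones(self.n_outputs, dtype=np.float32)
        label_mask = label_mask.astype(np.float32)
        rng = np.random.default_rng(cfg.seed)
        mom = {name: (np.zeros_like(getattr(obj, attr)),
                      np.zeros_like(getattr(obj, attr)))
               for name, obj, attr in self.params()}
        step = 0
        losses = []
        n = x.shape[0]
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                z = self.forward(xb, train=True)
                p = 1.0 / (1.0 + np.exp(-z))
                eps = 1e-7
                bce = -(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                bce = bce * label_mask
                denom = len(idx) * max(label_mask.sum(), 1.0)
                epoch_loss += float(bce.sum())
                dz = (p - yb) * label_mask / denom
                self.backward(dz.astype(np.float32))
                step += 1
                b1, b2, lr = 0.9, 0.999, cfg.learning_rate
                for name, obj, attr in self.params():
                    g = getattr(obj, "d" + attr)
                    m, v = mom[name]
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1 ** step)
                    vhat = v / (1 - b2 ** step)
                    p_arr = getattr(obj, attr)
                    p_arr -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            losses.append(epoch_loss / (n * max(label_mask.sum(), 1.0)))
        return losses

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        import dataclasses as dc
        state = self.state_dict()
        state["__arch__"] = np.frombuffer(
            json.dumps(dc.asdict(self.arch)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str) -> "ECGResNet":
        data = np.load(path)
        arch_json = json.loads(bytes(data["__arch__"]).decode())
        for key in ("block_filters", "block_strides"):
            arch_json[key] = tuple(arch_json[key])
        net = cls(ArchConfig(**arch_json))
        net.load_state_dict({k: data[k] for k in data.files if k != "__arch__"})
        return net
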