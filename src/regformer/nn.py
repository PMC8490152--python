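"""Neural-network building blocks on top of :mod:`regformer.autodiff`.

Layers follow the conventions of the sequence-to-profile model family:
activations flow as (batch, length, channels); convolutions are 'same'
padded; batch normalization runs per channel over batch and length with
momentum 0.9; attention pooling halves the length axis.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d_same, softmax


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval mode, state."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    yield (f"{prefix}{k}", v)

    def _named_modules(self, prefix=""):
        yield (prefix, self)
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")
            elif isinstance(v, dict):
                for name, item in v.items():
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def buffers(self):
        for prefix, mod in self._named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, np.ndarray):
                    yield (f"{prefix}{k}", v)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = value.copy()
        for prefix, mod in self._named_modules():
            for k, v in list(mod.__dict__.items()):
                full = f"{prefix}{k}"
                bkey = f"buffer:{full}"
                if isinstance(v, np.ndarray) and bkey in state:
                    mod.__dict__[k] = state[bkey].copy()
        return self


def _fan_in_normal(rng: np.random.Generator, shape, fan_in: int, dtype):
    return (rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dtype)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True, dtype="float32"):
        super().__init__()
        self.w = Parameter(_fan_in_normal(rng, (n_in, n_out), n_in, dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class Conv1d(Module):
    """'Same'-padded 1-D convolution over (B, L, C), as shifted matmuls per tap."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype="float32"):
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        self.w = Parameter(_fan_in_normal(rng, (kernel, c_in, c_out), kernel * c_in, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        if self.kernel == 1:
            return x @ self.w[0] + self.b
        return conv1d_same(x, self.w, self.b)


class BatchNorm1d(Module):
    """Per-channel batch norm over (batch, length); running stats with momentum 0.9."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype="float32"):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            n = x.shape[0] * x.shape[1]
            mu = x.sum(axis=(0, 1)) / n  # (C,)
            xc = x - mu
            var = xc.sqsum(axis=(0, 1)) / n  # (C,)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu.data).astype(self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var.data).astype(self.running_var.dtype)
            scale = self.gamma * ((var + self.eps) ** -0.5)
            return xc * scale + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = self.gamma * Tensor(inv)
        return x * scale + (self.beta - scale * Tensor(self.running_mean))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype="float32"):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * ((var + self.eps) ** -0.5)) + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        mask = (u < keep).astype(x.dtype)
        mask /= keep
        return x * Tensor(mask)


class AttentionPool(Module):
    """Learned softmax-weighted pooling over non-overlapping windows.

    For each output channel j the window positions i are weighted by
    softmax_i(x_i . w_j) and the channel values x_ij averaged under those
    weights.  ``w`` is initialized to twice the identity, which biases the
    operation toward max pooling; ``w = 0`` recovers average pooling.
    """

    def __init__(self, channels: int, window: int = 2, init_scale: float = 2.0, dtype="float32"):
        super().__init__()
        self.window = window
        self.w = Parameter((init_scale * np.eye(channels)).astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        W = self.window
        if L % W:
            raise ValueError(f"length {L} not divisible by pool window {W}")
        xw = x.reshape(B, L // W, W, C)
        if W == 2:
            # pairwise softmax via sigmoid of the logit difference
            x0, x1 = xw[:, :, 0, :], xw[:, :, 1, :]
            a0 = ((x0 - x1) @ self.w).sigmoid()
            return a0 * (x0 - x1) + x1
        logits = xw @ self.w  # (B, P, W, C): logits[..., i, j] = x_i . w_j
        alpha = softmax(logits, axis=2)
        return (alpha * xw).sum(axis=2)


def attention_pool(x, w) -> np.ndarray:
    """Functional single-window form: x (W, C), w (C, C) -> (C,) pooled vector.

    h_j = sum_i exp(x_i . w_j) x_ij / sum_i exp(x_i . w_j)
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(w))):
        raise ValueError("attention_pool requires finite inputs")
    logits = x @ w  # (W, C): logits[i, j] = x_i . w_j
    a = np.exp(logits - logits.max(axis=0, keepdims=True))
    a /= a.sum(axis=0, keepdims=True)
    return (a * x).sum(axis=0)
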