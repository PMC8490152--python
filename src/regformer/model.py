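"""The sequence-to-profile architecture.

A convolutional tower with learned attention pooling reduces one-hot DNA at
base-pair resolution to a sequence of bin embeddings (one per ``2^conv_blocks``
bp), a stack of transformer blocks with relative positional encodings shares
information across the full sequence, and, after cropping the unreliable
edges, organism-specific linear heads emit non-negative Poisson rates for
every output track.

Relative positional encodings follow the Transformer-XL decomposition

    logits_ij = q_i k_j^T / sqrt(K) + q_i r_{i-j}^T + u k_j^T + v r_{i-j}^T

where r_d = W_R f(d) projects a fixed bank of distance basis functions
(exponential decay, dyadic central masks, gamma densities; each in a
symmetric and a sign-asymmetric variant) into key space.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from io import BytesIO
from typing import Optional

import numpy as np
from scipy import stats as _st

from . import nn
from .autodiff import Tensor, concatenate, no_grad, rel_shift, softmax


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale configuration: 196,608-bp input, 7 pooling
    stages down to 1,536 positions of 128 bp, 11 transformer blocks with 8
    heads (key size 64, value size 192), cropping 320 bins per side to a
    896-bin output, and human/mouse heads of 5,313 and 1,643 tracks.
    """

    channels: int = 1536
    conv_blocks: int = 7
    transformer_blocks: int = 11
    heads: int = 8
    key_size: int = 64
    value_size: int = 192
    positional_features: int = 192  # total basis features; divisible by 2 * n classes
    input_length: int = 196_608
    crop_bins: int = 320
    head_widths: dict = field(default_factory=lambda: {"human": 5313, "mouse": 1643})
    stem_kernel: int = 15
    conv_kernel: int = 5
    pool_window: int = 2
    ff_expansion: int = 2
    dropout_positional: float = 0.01
    dropout_attention: float = 0.05
    dropout_ff: float = 0.2
    dropout_conv: float = 0.2
    dropout_head: float = 0.05
    dtype: str = "float32"
    seed: int = 0
    # distance scale (in pooled bins) for the positional basis functions;
    # None ties it to the sequence length seen at run time.  Pinning it lets
    # one model train on shorter sequences and run on longer ones with a
    # consistent distance code.
    positional_basis_length: Optional[int] = None
    # accept inputs of any pooling-compatible length (fully-convolutional
    # trunk + length-agnostic attention); off by default so accidental
    # length mismatches are rejected.
    variable_length: bool = False
    # normalization inside conv blocks: "batch" (running statistics,
    # momentum 0.9; the full-scale choice) or "layer" (per-position, no
    # train/eval statistics gap; preferable when training at batch size 1-2)
    conv_norm: str = "batch"
    # initialize the last projection of every residual branch (attention
    # output, feed-forward output, conv residual pointwise) to zero, so each
    # block starts as the identity and branches switch on gradually; this
    # markedly stabilizes small-data training
    zero_init_residual: bool = True

    @property
    def bin_width(self) -> int:
        return self.pool_window**self.conv_blocks

    @property
    def pooled_length(self) -> int:
        return self.input_length // self.bin_width

    @property
    def output_bins(self) -> int:
        return self.pooled_length - 2 * self.crop_bins

    @property
    def output_span_bp(self) -> int:
        return self.output_bins * self.bin_width

    def validate(self):
        if self.input_length % self.bin_width:
            raise ValueError("input_length must be divisible by pool_window**conv_blocks")
        if self.output_bins <= 0:
            raise ValueError("crop_bins removes the whole output")
        if self.positional_features % 6:
            raise ValueError("positional_features must be divisible by 2 * number of basis classes (= 6)")
        if self.channels % self.heads:
            raise ValueError("channels must be divisible by heads")
        return self

    def to_yaml(self, path):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh)).validate()


def toy_config(**overrides) -> ModelConfig:
    """A desk-scale configuration that trains in minutes on one CPU."""
    base = dict(
        channels=32,
        conv_blocks=5,
        transformer_blocks=2,
        heads=4,
        key_size=8,
        value_size=8,
        positional_features=12,
        input_length=8192,
        crop_bins=8,
        head_widths={"human": 3},
        stem_kernel=15,
        conv_kernel=5,
    )
    base.update(overrides)
    return ModelConfig(**base).validate()


# ---------------------------------------------------------------------------
# Positional basis functions


def basis_exponential(r, half_lives) -> np.ndarray:
    """f_i(r) = 2^(-r / r_half,i) for r >= 0; one column per half-life."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    hl = np.asarray(half_lives, dtype=float)
    return np.exp2(-r[..., None] / hl)


def basis_central_mask(r, thresholds) -> np.ndarray:
    """f_i(r) = 1 if r <= threshold_i else 0 (thresholds are powers of two)."""
    r = np.asarray(r, dtype=float)
    th = np.asarray(thresholds, dtype=float)
    return (r[..., None] <= th).astype(float)


def basis_gamma(r, means, sigma, normalize: bool = True) -> np.ndarray:
    """Gamma-density features peaked near each mean.

    Feature i evaluates the gamma pdf with shape mu_i^2/sigma^2 and rate
    mu_i/sigma^2 (mean mu_i, variance sigma^2).  With ``normalize`` each
    feature is rescaled by its value at the mode so its maximum is 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    mu = np.asarray(means, dtype=float)
    shape = (mu / sigma) ** 2
    rate = mu / sigma**2
    out = _st.gamma.pdf(r[..., None], a=shape, scale=1.0 / rate)
    if normalize:
        mode = np.where(shape > 1, (shape - 1) / rate, 0.0)
        peak = _st.gamma.pdf(np.maximum(mode, 1e-9), a=shape, scale=1.0 / rate)
        out = out / peak
    return out


def exponential_half_lives(n: int, seq_len: int) -> np.ndarray:
    """n half-lives placed linearly in log-space between 3 and seq_len."""
    return np.exp(np.linspace(np.log(3.0), np.log(float(seq_len)), n))


def central_mask_thresholds(n: int) -> np.ndarray:
    return 2.0 ** np.arange(1, n + 1)


def gamma_means_sigma(n: int, seq_len: int) -> tuple[np.ndarray, float]:
    means = np.linspace(seq_len / n, seq_len, n)
    sigma = seq_len / (2 * n)
    return means, sigma


def positional_features(r, total_features: int, seq_len: int) -> np.ndarray:
    """Bank of relative-distance features for signed distances ``r``.

    The budget is divided equally among three basis classes (exponential,
    central mask, gamma) and, within each class, between a symmetric f(|r|)
    and an asymmetric sign(r) * f(|r|) variant.
    """
    if total_features % 6:
        raise ValueError("total_features must be divisible by 6")
    r = np.asarray(r, dtype=float)
    n = total_features // 6  # features per class per parity
    a = np.abs(r)
    sym = np.concatenate(
        [
            basis_exponential(a, exponential_half_lives(n, seq_len)),
            basis_central_mask(a, central_mask_thresholds(n)),
            basis_gamma(a, *gamma_means_sigma(n, seq_len)),
        ],
        axis=-1,
    )
    asym = np.sign(r)[..., None] * sym
    return np.concatenate([sym, asym], axis=-1)


# ---------------------------------------------------------------------------
# Attention


class RelativeMHA(nn.Module):
    """Multi-head self-attention with relative positional encodings."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        C, H, K, V = cfg.channels, cfg.heads, cfg.key_size, cfg.value_size
        dt = cfg.dtype
        self.cfg = cfg
        self.H, self.K, self.V = H, K, V
        self.wq = nn.Dense(C, H * K, rng, bias=False, dtype=dt)
        self.wk = nn.Dense(C, H * K, rng, bias=False, dtype=dt)
        self.wv = nn.Dense(C, H * V, rng, bias=False, dtype=dt)
        self.wr = nn.Dense(cfg.positional_features, H * K, rng, bias=False, dtype=dt)
        self.u = nn.Parameter(np.zeros((H, 1, K), dtype=dt))
        self.v = nn.Parameter(np.zeros((H, 1, K), dtype=dt))
        self.out = nn.Dense(H * V, C, rng, dtype=dt)
        if cfg.zero_init_residual:
            self.out.w.data = np.zeros_like(self.out.w.data)
        self.drop_pos = nn.Dropout(cfg.dropout_positional, rng)
        self.drop_attn = nn.Dropout(cfg.dropout_attention, rng)

    def _split_heads(self, t: Tensor, width: int) -> Tensor:
        B, L, _ = t.shape
        return t.reshape(B, L, self.H, width).transpose(0, 2, 1, 3)  # (B, H, L, w)

    def __call__(self, x: Tensor, return_attention: bool = False):
        B, L, C = x.shape
        cfg = self.cfg
        q = self._split_heads(self.wq(x), self.K)
        k = self._split_heads(self.wk(x), self.K)
        v = self._split_heads(self.wv(x), self.V)

        # distance features for d = -(L-1) .. (L-1); the basis scale is the
        # configured distance budget, defaulting to the current pooled length
        basis_len = cfg.positional_basis_length or L
        d = np.arange(-(L - 1), L, dtype=float)
        feats = positional_features(d, cfg.positional_features, basis_len).astype(x.dtype)
        feats_t = self.drop_pos(Tensor(feats))
        r = self.wr(feats_t.reshape(1, 2 * L - 1, cfg.positional_features))
        r = r.reshape(2 * L - 1, self.H, self.K).transpose(1, 0, 2)  # (H, D, K)
        r_t = r.transpose(0, 2, 1)  # (H, K, D)

        scale = 1.0 / np.sqrt(self.K)
        content = (q @ k.transpose(0, 1, 3, 2)) * scale  # (B, H, L, L)
        qr = rel_shift(q @ r_t, L)  # (B, H, L, L)
        uk = self.u @ k.transpose(0, 1, 3, 2)  # (B, H, 1, L)
        vr = rel_shift((self.v @ r_t).reshape(self.H, 1, 2 * L - 1) + Tensor(np.zeros((1, L, 1), dtype=x.dtype)), L)

        logits = content + qr + uk + vr
        if not np.isfinite(logits.data.sum()):
            raise FloatingPointError("non-finite attention logits")
        attn = softmax(logits, axis=-1)
        attn_maps = attn.data.copy() if return_attention else None
        attn = self.drop_attn(attn)
        out = attn @ v  # (B, H, L, V)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, self.H * self.V)
        y = self.out(out)
        return (y, attn_maps) if return_attention else (y, None)


class TransformerBlock(nn.Module):
    """Pre-norm attention and feed-forward sublayers with residuals."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.channels
        self.ln1 = nn.LayerNorm(C, dtype=cfg.dtype)
        self.mha = RelativeMHA(cfg, rng)
        self.ln2 = nn.LayerNorm(C, dtype=cfg.dtype)
        self.ff1 = nn.Dense(C, cfg.ff_expansion * C, rng, dtype=cfg.dtype)
        self.ff2 = nn.Dense(cfg.ff_expansion * C, C, rng, dtype=cfg.dtype)
        if cfg.zero_init_residual:
            self.ff2.w.data = np.zeros_like(self.ff2.w.data)
        self.drop = nn.Dropout(cfg.dropout_ff, rng)

    def __call__(self, x: Tensor, return_attention: bool = False):
        h, attn = self.mha(self.ln1(x), return_attention=return_attention)
        x = x + self.drop(h)
        f = self.drop(self.ff2(self.drop(self.ff1(self.ln2(x))).relu()))
        return x + f, attn


class ConvBlock(nn.Module):
    """norm -> GELU -> conv, with a residual pointwise conv, then pooling."""

    def __init__(self, c_in: int, c_out: int, kernel: int, cfg: ModelConfig, rng, pre_activate: bool = True):
        super().__init__()
        norm = nn.BatchNorm1d if cfg.conv_norm == "batch" else nn.LayerNorm
        self.pre_activate = pre_activate
        self.bn1 = norm(c_in, dtype=cfg.dtype) if pre_activate else None
        self.conv = nn.Conv1d(c_in, c_out, kernel, rng, dtype=cfg.dtype)
        self.bn2 = norm(c_out, dtype=cfg.dtype)
        self.pointwise = nn.Conv1d(c_out, c_out, 1, rng, dtype=cfg.dtype)
        if cfg.zero_init_residual:
            self.pointwise.w.data = np.zeros_like(self.pointwise.w.data)
        self.drop = nn.Dropout(cfg.dropout_conv, rng)
        self.pool = nn.AttentionPool(c_out, window=cfg.pool_window, dtype=cfg.dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if self.pre_activate:
            x = self.bn1(x).gelu()
        x = self.conv(x)
        x = x + self.drop(self.pointwise(self.bn2(x).gelu()))
        return self.pool(x)


def conv_channel_schedule(cfg: ModelConfig) -> list[int]:
    """Stem at C/2; channels grow geometrically to C across the tower."""
    half = cfg.channels // 2
    n = cfg.conv_blocks - 1
    if n == 0:
        return [cfg.channels]
    return [half] + [int(round(half * 2 ** (i / n))) for i in range(1, n + 1)]


class SeqToTracksModel(nn.Module):
    """The full network: conv tower, transformer tower, crop, organism heads."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = conv_channel_schedule(cfg)
        blocks = []
        c_prev = 4
        for i, c in enumerate(chans):
            kernel = cfg.stem_kernel if i == 0 else cfg.conv_kernel
            blocks.append(ConvBlock(c_prev, c, kernel, cfg, rng, pre_activate=i > 0))
            c_prev = c
        self.conv_tower = blocks
        self.transformer = [TransformerBlock(cfg, rng) for _ in range(cfg.transformer_blocks)]
        C = cfg.channels
        self.final_bn = nn.LayerNorm(C, dtype=cfg.dtype)
        self.final_pointwise = nn.Dense(C, 2 * C, rng, dtype=cfg.dtype)
        self.final_drop = nn.Dropout(cfg.dropout_head, rng)
        self.heads = {org: nn.Dense(2 * C, w, rng, dtype=cfg.dtype) for org, w in cfg.head_widths.items()}
        self.eval()

    # -- forward ---------------------------------------------------------------

    def trunk(self, x: Tensor, return_attention: bool = False):
        """One-hot (B, L, 4) -> bin embeddings (B, pooled_length, C)."""
        if self.cfg.variable_length:
            if x.shape[1] % self.cfg.bin_width:
                raise ValueError(f"input length {x.shape[1]} not divisible by bin width {self.cfg.bin_width}")
        elif x.shape[1] != self.cfg.input_length:
            raise ValueError(f"expected input length {self.cfg.input_length}, got {x.shape[1]}")
        maps = [] if return_attention else None
        for block in self.conv_tower:
            x = block(x)
        for tb in self.transformer:
            x, attn = tb(x, return_attention=return_attention)
            if return_attention:
                maps.append(attn)
        return x, maps

    def __call__(self, x, organism: str, return_attention: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.cfg.dtype))
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        h, maps = self.trunk(x, return_attention=return_attention)
        c = self.cfg.crop_bins
        if c:
            h = h[:, c : h.shape[1] - c, :]
        h = self.final_drop(self.final_pointwise(self.final_bn(h)).gelu())
        y = self.heads[organism](h).softplus()  # non-negative Poisson rates
        if squeeze:
            y = y.reshape(*y.shape[1:])
        return (y, maps) if return_attention else y

    def predict(self, onehot: np.ndarray, organism: str) -> np.ndarray:
        """Inference convenience: (L, 4) -> (output_bins, tracks), no graph."""
        self.eval()
        with no_grad():
            return self(onehot, organism).data

    def attention_maps(self, onehot: np.ndarray, organism: str = None) -> np.ndarray:
        """(layers, heads, L, L) post-softmax attention for one sequence."""
        self.eval()
        with no_grad():
            x = Tensor(np.asarray(onehot, dtype=self.cfg.dtype)[None])
            _, maps = self.trunk(x, return_attention=True)
        return np.stack([m[0] for m in maps])

    # -- persistence -----------------------------------------------------------

    def save(self, path):
        buf = BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.cfg)))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "SeqToTracksModel":
        with zipfile.ZipFile(path) as zf:
            cfg = ModelConfig(**json.loads(zf.read("config.json")))
            with zf.open("weights.npz") as fh:
                state = dict(np.load(BytesIO(fh.read())))
        model = cls(cfg)
        model.load_state_dict(state)
        return model


def crop_output(values: np.ndarray, crop_bins: int, axis: int = -1):
    """Trim ``crop_bins`` bins from each end of the spatial axis."""
    if crop_bins == 0:
        return values
    index = [slice(None)] * np.ndim(values)
    index[axis] = slice(crop_bins, values.shape[axis] - crop_bins)
    return values[tuple(index)]
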