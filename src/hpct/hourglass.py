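"""The hourglass compression transformer (HPCT).

An autoencoder for variable-length per-residue embeddings.  The encoder
runs a transformer stack over the (normalized) L x D input, shortens the
length axis by a factor S with a learned linear downsampling (equivalent
to a stride-S, width-S convolution), lets the shortened positions
cross-attend back over the full-length sequence, and projects channels
D -> d_c = D / K.  The bottleneck is tanh (continuous) or a quantizer
(VQ-VAE / FSQ).  The decoder mirrors the encoder: channel upprojection,
linear upsampling back to length L, cross-attention of full-length queries
over the shortened positions, and a final transformer stack.

There are no skip connections across the bottleneck: the reconstruction
depends on the input only through the compressed latent c, whose size per
protein is ceil(L/S) * D/K scalars.

Masks: lengths are ragged, samples are zero-padded; a binary mask marks
valid positions.  Shortening reduces the mask with an any-valid rule
(a block is valid iff any source position is valid) and the decoder
expands it by repetition.  Padded positions never influence valid-position
outputs: encoder activations are zeroed at padded rows before blocks are
mixed, and attention gives masked keys zero weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, constant, pad_axis
from .bottleneck import (
    FSQBottleneck,
    FSQLevels,
    TanhBottleneck,
    TokenizedLatent,
    VQBottleneck,
)
from .nn import CrossAttention, Linear, Module, TransformerStack

__all__ = [
    "HourglassConfig",
    "CompressedLatent",
    "HourglassAutoencoder",
    "linear_downsample",
    "linear_upsample",
    "reduce_mask",
    "expand_mask",
    "attention_resample",
    "compression_ratio",
]


@dataclass(frozen=True)
class HourglassConfig:
    """Architecture hyperparameters.

    ``shorten_factor`` (S) compresses the length axis; ``downproj_factor``
    (K) the channel axis, giving a bottleneck width d_c = d_model / K.
    ``bottleneck_kind`` is one of {"tanh", "vq", "fsq"}; VQ uses
    ``codebook_size`` and commitment weight ``vq_beta``, FSQ uses
    ``fsq_levels`` (per-channel level counts, length d_c).
    """

    d_model: int = 1024
    n_layers_enc: int = 2
    n_layers_dec: int = 2
    n_heads: int = 4
    shorten_factor: int = 2
    downproj_factor: int = 8
    bottleneck_kind: str = "tanh"
    codebook_size: int = 256
    vq_beta: float = 0.25
    fsq_levels: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.shorten_factor < 1:
            raise ValueError("shorten_factor must be >= 1")
        if self.d_model % self.downproj_factor:
            raise ValueError(
                f"d_model={self.d_model} not divisible by downproj_factor={self.downproj_factor}"
            )
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.bottleneck_kind not in ("tanh", "vq", "fsq"):
            raise ValueError(f"unknown bottleneck_kind {self.bottleneck_kind!r}")
        if self.bottleneck_kind == "fsq":
            levels = self.fsq_levels or (8,) * self.d_c
            if len(levels) != self.d_c:
                raise ValueError(
                    f"fsq_levels must have d_c={self.d_c} entries, got {len(levels)}"
                )
            object.__setattr__(self, "fsq_levels", tuple(levels))

    @property
    def d_c(self) -> int:
        return self.d_model // self.downproj_factor


@dataclass
class CompressedLatent:
    """Bottleneck output for one batch: continuous values and, for discrete
    bottlenecks, the integer tokens."""

    values: np.ndarray                 # (B, L', d_c)
    mask: np.ndarray                   # (B, L')
    shorten_factor: int
    downproj_factor: int
    bottleneck_kind: str
    tokens: TokenizedLatent | None = None
    original_length: int | None = None


# ------------------------------------------------------ functional primitives

def linear_downsample(a: np.ndarray, s: int, w: np.ndarray) -> np.ndarray:
    """Shorten (L, D) -> (L/S, D): reshape to (L/S, S*D), multiply by W.

    ``L`` must already be padded to a multiple of S.  Equivalent to a
    1-D convolution with filter size and stride both equal to S.
    """
    a = np.asarray(a)
    l, d = a.shape[-2], a.shape[-1]
    if l % s:
        raise ValueError(f"length {l} not a multiple of shorten factor {s}; pad first")
    if w.shape != (s * d, d):
        raise ValueError(f"W must be ({s * d}, {d}), got {w.shape}")
    return a.reshape(*a.shape[:-2], l // s, s * d) @ w


def linear_upsample(a_short: np.ndarray, s: int, w: np.ndarray) -> np.ndarray:
    """Expand (L/S, D) -> (L, D): multiply by W (D, S*D), reshape back."""
    a_short = np.asarray(a_short)
    ls, d = a_short.shape[-2], a_short.shape[-1]
    if w.shape != (d, s * d):
        raise ValueError(f"W must be ({d}, {s * d}), got {w.shape}")
    out = a_short @ w
    return out.reshape(*a_short.shape[:-2], ls * s, d)


def reduce_mask(m: np.ndarray, s: int) -> np.ndarray:
    """Shorten a validity mask: block b is valid iff any of its S sources is
    (sum over the block then threshold > 0)."""
    m = np.asarray(m)
    l = m.shape[-1]
    if l % s:
        raise ValueError(f"mask length {l} not a multiple of {s}; pad first")
    blocks = m.reshape(*m.shape[:-1], l // s, s)
    return (blocks.sum(axis=-1) > 0).astype(m.dtype)


def expand_mask(m_short: np.ndarray, s: int, length: int | None = None) -> np.ndarray:
    """Inverse of :func:`reduce_mask` by repetition (then threshold > 0)."""
    out = np.repeat(np.asarray(m_short), s, axis=-1)
    if length is not None:
        out = out[..., :length]
    return (out > 0).astype(m_short.dtype)


def attention_resample(queries: np.ndarray, keys_values: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Scaled-dot-product attention of ``queries`` over ``keys_values``.

    Keys and values coincide (no learned projections at this level); masked
    key positions receive exactly zero attention weight.  Raises if every
    key is masked out.
    """
    q = np.asarray(queries, dtype=np.float64)
    kv = np.asarray(keys_values, dtype=np.float64)
    if q.shape[-1] != kv.shape[-1]:
        raise ValueError("queries and keys must share the channel dimension")
    d = q.shape[-1]
    scores = q @ kv.T / math.sqrt(d)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("attention_resample: all key positions are masked out")
        scores = np.where(mask[None, :], scores, -np.inf)
    scores = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ kv


def compression_ratio(length: int, d: int, s: int, k: int) -> float:
    """Stored scalars before / after: (L * D) / (ceil(L/S) * D/K)."""
    l_short = math.ceil(length / s)
    return (length * d) / (l_short * (d // k))


# ---------------------------------------------------------------------- model

class HourglassAutoencoder(Module):
    """End-to-end HPCT: encoder, bottleneck, decoder.  Operates on padded
    batches (B, L, D) with masks (B, L); inputs are assumed normalized."""

    def __init__(self, cfg: HourglassConfig):
        self.cfg = cfg
        d, s = cfg.d_model, cfg.shorten_factor
        rng = np.random.default_rng(cfg.seed)
        self.encoder = TransformerStack(d, cfg.n_layers_enc, cfg.n_heads, rng)
        self.w_down = Linear(s * d, d, rng, bias=False, orthogonal=True)
        self.cross_enc = CrossAttention(d, cfg.n_heads, rng)
        self.w_d = Linear(d, cfg.d_c, rng, bias=False, orthogonal=True)
        if cfg.bottleneck_kind == "tanh":
            self.bottleneck = TanhBottleneck()
        elif cfg.bottleneck_kind == "vq":
            self.bottleneck = VQBottleneck(cfg.codebook_size, cfg.d_c, rng, beta=cfg.vq_beta)
        else:
            self.bottleneck = FSQBottleneck(FSQLevels(cfg.fsq_levels))
        self.w_u = Linear(cfg.d_c, d, rng, bias=False, orthogonal=True)
        self.w_up = Linear(d, s * d, rng, bias=False, orthogonal=True)
        self.cross_dec = CrossAttention(d, cfg.n_heads, rng)
        self.decoder = TransformerStack(d, cfg.n_layers_dec, cfg.n_heads, rng)

    # ------------------------------------------------------------- encoding
    def _check_input(self, x: np.ndarray, mask: np.ndarray):
        if x.ndim != 3 or x.shape[-1] != self.cfg.d_model:
            raise ValueError(
                f"expected (B, L, {self.cfg.d_model}) input, got shape {x.shape}"
            )
        if mask.shape != x.shape[:2]:
            raise ValueError("mask shape must match (B, L)")

    def encode(self, x: np.ndarray, mask: np.ndarray):
        """Pre-bottleneck encoding: returns (a', m') with a' of shape
        (B, ceil(L/S), D) as an autograd Tensor."""
        self._check_input(x, mask)
        cfg = self.cfg
        s = cfg.shorten_factor
        b, l, d = x.shape
        a = self.encoder(constant(x), mask)
        # zero padded rows so length-blocks cannot leak pad content
        a = a * constant(mask[..., None].astype(np.float64))
        pad_n = (-l) % s
        if pad_n:
            a = pad_axis(a, 1, pad_n)
        mask_p = np.pad(mask, ((0, 0), (0, pad_n)))
        lp = l + pad_n
        a_short = a.reshape(b, lp // s, s * d) @ self.w_down.weight
        m_short = reduce_mask(mask_p, s)
        a_short = a_short + self.cross_enc(a_short, a, mask_p)
        return a_short, m_short

    def compress(self, x: np.ndarray, mask: np.ndarray) -> CompressedLatent:
        """Full compression: encode, downproject, run the bottleneck."""
        a_short, m_short = self.encode(x, mask)
        c = a_short @ self.w_d.weight
        z, tokens, _ = self.bottleneck(c, m_short)
        return CompressedLatent(
            values=z.data,
            mask=m_short,
            shorten_factor=self.cfg.shorten_factor,
            downproj_factor=self.cfg.downproj_factor,
            bottleneck_kind=self.cfg.bottleneck_kind,
            tokens=tokens,
            original_length=x.shape[1],
        )

    # ------------------------------------------------------------- decoding
    def decode(self, z, m_short: np.ndarray, length: int):
        """Reconstruct (B, length, D) from bottleneck values ``z``
        ((B, L', d_c) array or Tensor) and the shortened mask."""
        cfg = self.cfg
        s = cfg.shorten_factor
        zt = z if isinstance(z, Tensor) else constant(np.asarray(z, dtype=np.float64))
        if zt.shape[-1] != cfg.d_c:
            raise ValueError(f"latent width {zt.shape[-1]} != configured d_c {cfg.d_c}")
        a_short = zt @ self.w_u.weight
        b, ls, d = a_short.shape
        up = (a_short @ self.w_up.weight).reshape(b, ls * s, d)
        up = up[:, :length]
        m = expand_mask(m_short, s, length)
        up = up + self.cross_dec(up, a_short, m_short)
        return self.decoder(up, m), m

    def decode_latent(self, latent: CompressedLatent) -> np.ndarray:
        if latent.bottleneck_kind != self.cfg.bottleneck_kind:
            raise ValueError(
                f"latent was produced with bottleneck {latent.bottleneck_kind!r}, "
                f"model uses {self.cfg.bottleneck_kind!r}"
            )
        if (latent.shorten_factor, latent.downproj_factor) != (
            self.cfg.shorten_factor,
            self.cfg.downproj_factor,
        ):
            raise ValueError("latent S/K factors do not match model config")
        length = latent.original_length or latent.values.shape[1] * self.cfg.shorten_factor
        recon, _ = self.decode(latent.values, latent.mask, length)
        return recon.data

    # ------------------------------------------------------------- training
    def forward(self, x: np.ndarray, mask: np.ndarray):
        """Training pass.  Returns (reconstruction Tensor, bottleneck Tensor,
        tokens or None, dict of auxiliary loss Tensors)."""
        a_short, m_short = self.encode(x, mask)
        c = a_short @ self.w_d.weight
        z, tokens, aux = self.bottleneck(c, m_short)
        recon, _ = self.decode(z, m_short, x.shape[1])
        return recon, z, tokens, aux

    def __call__(self, x: np.ndarray, mask: np.ndarray):
        return self.forward(x, mask)
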