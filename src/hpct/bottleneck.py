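"""Bottleneck layers: continuous tanh, VQ-VAE, and finite scalar quantization.

The continuous bottleneck simply bounds the compressed latent to (-1, 1)
with an elementwise tanh.  The discrete bottlenecks map each bottleneck
position to an integer token:

* **VQ-VAE** — nearest-neighbour (Euclidean) assignment to a learned
  codebook of C vectors, trained with a codebook loss ||sg[h] - z||^2 and a
  commitment loss beta * ||h - sg[z]||^2; gradients cross the discrete step
  with the straight-through estimator (gradients of the quantized output
  are copied to the continuous input).  Ties break to the lowest index.
* **FSQ** — parameter-free: per channel j, tanh bounds the value to
  [-1, 1] and it is rounded onto a grid of L_j levels; the implicit
  codebook size is the product of the per-channel level counts.  Odd level
  counts use the integer grid round(floor(L/2) * tanh(z)); even counts use
  the standard half-integer offset grid.  Token indices are the mixed-radix
  encoding of the per-channel level indices (channel 0 most significant).

Codebook-health diagnostics (selection perplexity, utilization) live here
as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, constant, take
from .nn import Module

__all__ = [
    "Codebook",
    "FSQLevels",
    "TokenizedLatent",
    "tanh_bottleneck",
    "vq_quantize",
    "vq_perplexity",
    "fsq_quantize",
    "fsq_codes_to_index",
    "fsq_index_to_codes",
    "codebook_utilization",
    "TanhBottleneck",
    "VQBottleneck",
    "FSQBottleneck",
]


@dataclass
class Codebook:
    vectors: np.ndarray  # (C, d_c)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ValueError("codebook must be a non-empty (C, d_c) matrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("codebook vectors must be finite")

    @property
    def size(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class FSQLevels:
    levels: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(int(l) for l in self.levels))
        if any(l < 1 for l in self.levels):
            raise ValueError("each FSQ level count must be >= 1")

    @property
    def implicit_size(self) -> int:
        return int(np.prod(self.levels, dtype=np.int64))

    @property
    def d(self) -> int:
        return len(self.levels)


@dataclass
class TokenizedLatent:
    indices: np.ndarray  # integer array, any leading shape
    mask: np.ndarray | None = None
    codebook_size: int | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices)
        if self.codebook_size is not None:
            valid = self.indices if self.mask is None else self.indices[self.mask.astype(bool)]
            if valid.size and (valid.min() < 0 or valid.max() >= self.codebook_size):
                raise ValueError("token indices out of range for codebook size")


# ---------------------------------------------------------------- continuous

def tanh_bottleneck(c: np.ndarray) -> np.ndarray:
    """Elementwise tanh; bounds the compressed latent to (-1, 1)."""
    return np.tanh(c)


# -------------------------------------------------------------------- VQ-VAE

def vq_nearest(c: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Nearest codebook row per input row (Euclidean; ties -> lowest index)."""
    c2 = (c ** 2).sum(axis=-1, keepdims=True)
    e2 = (codebook ** 2).sum(axis=-1)
    d2 = c2 - 2.0 * c @ codebook.T + e2
    return np.argmin(d2, axis=-1)


def vq_quantize(c: np.ndarray, codebook: Codebook, beta: float = 0.25):
    """Quantize rows of ``c`` to their nearest codebook vectors.

    Returns ``(tokens, quantized, losses)`` where ``losses`` holds the
    scalar codebook loss mean||sg[c] - z||^2 and commitment loss
    beta * mean||c - sg[z]||^2 over all positions.
    """
    c = np.asarray(c, dtype=np.float64)
    idx = vq_nearest(c, codebook.vectors)
    quantized = codebook.vectors[idx]
    sq = ((c - quantized) ** 2).mean() if c.size else 0.0
    losses = {"codebook": float(sq), "commitment": float(beta * sq)}
    tokens = TokenizedLatent(indices=idx, codebook_size=codebook.size)
    return tokens, quantized, losses


def vq_perplexity(index_counts: np.ndarray) -> float:
    """exp(entropy) of the empirical code-selection distribution.

    Uniform selection over C codes gives C; a collapsed codebook gives 1.
    """
    counts = np.asarray(index_counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("vq_perplexity requires a positive total count")
    p = counts[counts > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


# ----------------------------------------------------------------------- FSQ

def _fsq_half_widths(levels: FSQLevels) -> np.ndarray:
    return (np.array(levels.levels, dtype=np.float64) - 1.0) / 2.0


def fsq_quantize(z: np.ndarray, levels: FSQLevels):
    """Bound with tanh and round each channel onto its finite grid.

    Returns ``(tokens, quantized)``: ``quantized`` holds decoder-facing
    values rescaled to [-1, 1] (grid points q / h with h = (L_j - 1)/2);
    ``tokens`` holds the mixed-radix index over per-channel level indices.
    Channels with L_j = 1 always quantize to 0.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != levels.d:
        raise ValueError(f"z has {z.shape[-1]} channels but {levels.d} level entries given")
    lv = np.array(levels.levels, dtype=np.float64)
    h = _fsq_half_widths(levels)
    offset = np.where(lv % 2 == 0, 0.5, 0.0)
    bounded = np.tanh(z)
    q = np.round(h * bounded + offset) - offset  # grid values in [-h, h]
    codes = np.rint(q + h).astype(np.int64)      # level indices in [0, L_j)
    safe_h = np.where(h == 0, 1.0, h)
    quantized = np.where(h == 0, 0.0, q / safe_h)
    index = fsq_codes_to_index(codes, levels)
    tokens = TokenizedLatent(indices=index, codebook_size=levels.implicit_size)
    return tokens, quantized


def fsq_codes_to_index(codes: np.ndarray, levels: FSQLevels) -> np.ndarray:
    """Mixed-radix encoding of per-channel level indices; channel 0 is most
    significant.  Inverse of :func:`fsq_index_to_codes`."""
    codes = np.asarray(codes)
    if codes.shape[-1] != levels.d:
        raise ValueError("code tuple width does not match level count")
    for j, lj in enumerate(levels.levels):
        cj = codes[..., j]
        if cj.size and (cj.min() < 0 or cj.max() >= lj):
            raise ValueError(f"channel {j} codes out of range [0, {lj})")
    index = np.zeros(codes.shape[:-1], dtype=np.int64)
    for j, lj in enumerate(levels.levels):
        index = index * lj + codes[..., j]
    return index


def fsq_index_to_codes(index: np.ndarray, levels: FSQLevels) -> np.ndarray:
    index = np.asarray(index)
    if index.size and (index.min() < 0 or index.max() >= levels.implicit_size):
        raise ValueError(f"index out of range [0, {levels.implicit_size})")
    out = np.zeros(index.shape + (levels.d,), dtype=np.int64)
    rem = index.astype(np.int64)
    for j in range(levels.d - 1, -1, -1):
        lj = levels.levels[j]
        out[..., j] = rem % lj
        rem = rem // lj
    return out


def fsq_grid_values(levels: FSQLevels, channel: int) -> np.ndarray:
    """The decoder-facing grid of channel ``channel`` (values in [-1, 1])."""
    lj = levels.levels[channel]
    h = (lj - 1) / 2.0
    if h == 0:
        return np.array([0.0])
    return (np.arange(lj) - h) / h


# ---------------------------------------------------------------- diagnostics

def codebook_utilization(tokens, codebook_size: int) -> float:
    """Fraction of distinct codes observed among valid positions."""
    if codebook_size < 1:
        raise ValueError("codebook_size must be >= 1")
    seen = set()
    items = tokens if isinstance(tokens, (list, tuple)) else [tokens]
    for t in items:
        idx = t.indices if isinstance(t, TokenizedLatent) else np.asarray(t)
        mask = getattr(t, "mask", None)
        if mask is not None:
            idx = idx[np.asarray(mask).astype(bool)]
        seen.update(np.unique(idx).tolist())
    return len(seen) / codebook_size


# ----------------------------------------------------- model-facing modules

class TanhBottleneck(Module):
    """Continuous bottleneck; values bounded to (-1, 1)."""

    kind = "tanh"

    def __call__(self, c: Tensor, mask: np.ndarray):
        return c.tanh(), None, {}


class VQBottleneck(Module):
    """Learned-codebook quantizer with straight-through gradients.

    The auxiliary losses are masked means over valid bottleneck positions;
    the codebook loss carries gradient to the codebook, the commitment loss
    to the encoder.
    """

    kind = "vq"

    def __init__(self, codebook_size: int, d_c: int, rng: np.random.Generator,
                 beta: float = 0.25):
        self.codebook = Parameter(rng.standard_normal((codebook_size, d_c)) * 0.5)
        self.beta = beta

    def __call__(self, c: Tensor, mask: np.ndarray):
        idx = vq_nearest(c.data, self.codebook.data)
        selected = take(self.codebook, idx)                  # grads -> codebook
        # straight-through: forward value is the code vector, gradient is identity
        quantized = c + constant(selected.data - c.data)
        w = mask[..., None].astype(np.float64)
        denom = max(w.sum() * c.shape[-1], 1.0)
        diff_cb = selected - constant(c.data)
        diff_commit = c - constant(selected.data)
        codebook_loss = (diff_cb * diff_cb * constant(w)).sum() * (1.0 / denom)
        commit_loss = (diff_commit * diff_commit * constant(w)).sum() * (self.beta / denom)
        tokens = TokenizedLatent(indices=idx, mask=mask,
                                 codebook_size=self.codebook.data.shape[0])
        return quantized, tokens, {"codebook": codebook_loss, "commitment": commit_loss}


class FSQBottleneck(Module):
    """Parameter-free quantizer; straight-through around the rounding only
    (the tanh bound is differentiated exactly)."""

    kind = "fsq"

    def __init__(self, levels: FSQLevels):
        self.levels = levels

    def __call__(self, c: Tensor, mask: np.ndarray):
        bounded = c.tanh()
        tokens, quantized = fsq_quantize(c.data, self.levels)
        tokens.mask = mask
        out = bounded + constant(quantized - bounded.data)
        return out, tokens, {}
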