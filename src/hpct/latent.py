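"""Latent-space geometry experiments: linear interpolation and token
corruption.

Interpolation is the straight segment x'(t) = t * x1 + (1 - t) * x2,
evaluated in whichever space the caller supplies (raw, normalized, or
compressed); decoding back to sequence/structure and scoring similarity to
the endpoints probes how smooth that space is.  Token corruption is the
discrete mirror: each valid token is independently replaced by a uniform
random code with some probability, and the damage is measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bottleneck import TokenizedLatent

__all__ = [
    "InterpolationTrace",
    "interpolate",
    "corrupt_tokens",
    "smoothness_curve",
]


@dataclass
class InterpolationTrace:
    ts: np.ndarray
    latents: list[np.ndarray]
    observables: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.latents) != self.ts.shape[0]:
            raise ValueError("one latent per t value required")


def interpolate(x1: np.ndarray, x2: np.ndarray, ts) -> InterpolationTrace:
    """Linear interpolation x'(t) = t * x1 + (1 - t) * x2.

    t = 1 reproduces ``x1`` exactly and t = 0 reproduces ``x2`` exactly
    (no floating error is introduced at the endpoints).
    """
    x1, x2 = np.asarray(x1, dtype=np.float64), np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    ts = np.asarray(ts, dtype=np.float64)
    if np.any((ts < 0) | (ts > 1)):
        raise ValueError("t values must lie in [0, 1]")
    latents = []
    for t in ts:
        if t == 0.0:
            latents.append(x2.copy())
        elif t == 1.0:
            latents.append(x1.copy())
        else:
            latents.append(t * x1 + (1.0 - t) * x2)
    return InterpolationTrace(ts=ts, latents=latents)


def corrupt_tokens(tokens: TokenizedLatent, rate: float, codebook_size: int,
                   seed: int = 0) -> TokenizedLatent:
    """Independently replace each valid token by a uniform random code with
    probability ``rate``.  Replacement may resample the original code, so
    the expected changed fraction is rate * (1 - 1/C).  Masked positions
    are untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    idx = np.array(tokens.indices)
    hit = rng.random(idx.shape) < rate
    if tokens.mask is not None:
        hit &= np.asarray(tokens.mask).astype(bool)
    idx[hit] = rng.integers(0, codebook_size, size=int(hit.sum()))
    return TokenizedLatent(indices=idx, mask=tokens.mask, codebook_size=codebook_size)


def smoothness_curve(trace: InterpolationTrace, similarity) -> dict:
    """Similarity of each interpolation point to both endpoints.

    ``similarity(a, b)`` is any callable on decoded observables or latents;
    it is evaluated against endpoint x1 (t = 1) and endpoint x2 (t = 0).
    Returns per-t similarity tables plus a monotonicity summary: the
    fraction of adjacent steps (in increasing t) on which similarity to the
    t = 1 endpoint does not decrease.
    """
    order = np.argsort(trace.ts)
    ts = trace.ts[order]
    pts = [trace.latents[i] for i in order]
    end_hi = trace.latents[int(np.argmax(trace.ts))]
    end_lo = trace.latents[int(np.argmin(trace.ts))]
    sim_hi = np.array([similarity(p, end_hi) for p in pts])
    sim_lo = np.array([similarity(p, end_lo) for p in pts])
    steps = np.diff(sim_hi)
    monotone_fraction = float((steps >= 0).mean()) if steps.size else 1.0
    return {
        "t": ts,
        "similarity_to_t1": sim_hi,
        "similarity_to_t0": sim_lo,
        "monotone_fraction": monotone_fraction,
    }
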