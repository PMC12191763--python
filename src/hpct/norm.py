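"""Per-channel min-max normalization and massive-activation diagnostics.

A few channels of pLM latents carry values orders of magnitude above the
median channel regardless of the input.  Global normalization would be
dominated by those channels, so calibration statistics (per-channel min and
max over a reference set of embeddings) are estimated independently for
each channel, and each channel is affinely mapped so its calibration
extrema land exactly on target bounds [c_min, c_max] (default [-1, 1]):

    x' = (x - x_min) / (x_max - x_min) * (c_max - c_min) + c_min

Values outside the calibration range map outside [c_min, c_max]; no
clipping is applied, which keeps the map invertible and information
preserving.  Channels whose calibration range is (numerically) empty are
flagged and map to ``c_min``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelStats",
    "ActivationReport",
    "estimate_channel_stats",
    "normalize",
    "denormalize",
    "activation_report",
    "zero_channels",
    "save_channel_stats",
    "load_channel_stats",
]

RANGE_EPS = 1e-12


@dataclass
class ChannelStats:
    x_min: np.ndarray
    x_max: np.ndarray
    c_min: float = -1.0
    c_max: float = 1.0
    n_samples_used: int = 0
    constant_channels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.x_min = np.asarray(self.x_min, dtype=np.float64)
        self.x_max = np.asarray(self.x_max, dtype=np.float64)
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max must have the same shape")
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min per channel")
        if not self.c_max > self.c_min:
            raise ValueError("c_max must exceed c_min")
        if self.constant_channels is None:
            self.constant_channels = (self.x_max - self.x_min) < RANGE_EPS

    @property
    def n_channels(self) -> int:
        return self.x_min.shape[0]


@dataclass
class ActivationReport:
    """Summary of activation magnitudes: channel means, top-k, and median."""

    per_channel_mean: np.ndarray
    top_k_magnitudes: list[tuple[int, float]]
    median_magnitude: float

    @property
    def top_over_median(self) -> float:
        return self.top_k_magnitudes[0][1] / self.median_magnitude


def _iter_valid(samples, masks):
    if masks is None:
        masks = [None] * len(samples)
    for x, m in zip(samples, masks):
        x = np.asarray(x)
        if m is None:
            yield x
        else:
            yield x[np.asarray(m).astype(bool)]


def estimate_channel_stats(samples, masks=None, c_min: float = -1.0,
                           c_max: float = 1.0) -> ChannelStats:
    """Elementwise per-channel extrema over all valid positions of all samples.

    ``samples`` is an iterable of (L_i, D) arrays; ``masks`` an optional
    aligned iterable of length-L_i validity vectors (padded positions are
    excluded from the statistics).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot estimate channel stats from an empty collection")
    x_min = x_max = None
    n_used = 0
    for valid in _iter_valid(samples, masks):
        if valid.shape[0] == 0:
            continue
        lo, hi = valid.min(axis=0), valid.max(axis=0)
        x_min = lo if x_min is None else np.minimum(x_min, lo)
        x_max = hi if x_max is None else np.maximum(x_max, hi)
        n_used += 1
    if x_min is None:
        raise ValueError("no valid (masked-in) positions in any sample")
    return ChannelStats(x_min=x_min, x_max=x_max, c_min=c_min, c_max=c_max,
                        n_samples_used=n_used)


def normalize(x: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Map each channel's calibration range [x_min, x_max] onto [c_min, c_max].

    Out-of-calibration values map outside the target bounds (no clipping).
    Constant channels (empty calibration range) map to ``c_min``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != stats.n_channels:
        raise ValueError(f"x has {x.shape[-1]} channels, stats expect {stats.n_channels}")
    span = stats.x_max - stats.x_min
    safe_span = np.where(stats.constant_channels, 1.0, span)
    unit = (x - stats.x_min) / safe_span
    out = unit * (stats.c_max - stats.c_min) + stats.c_min
    if stats.constant_channels.any():
        out = np.where(stats.constant_channels, stats.c_min, out)
    return out


def denormalize(x_norm: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Inverse of :func:`normalize`; undefined for constant channels."""
    x_norm = np.asarray(x_norm, dtype=np.float64)
    if x_norm.shape[-1] != stats.n_channels:
        raise ValueError(f"x has {x_norm.shape[-1]} channels, stats expect {stats.n_channels}")
    if stats.constant_channels.any():
        bad = np.flatnonzero(stats.constant_channels)
        raise ValueError(f"denormalize undefined for constant channels {bad.tolist()}")
    unit = (x_norm - stats.c_min) / (stats.c_max - stats.c_min)
    return unit * (stats.x_max - stats.x_min) + stats.x_min


def activation_report(layer_outputs, masks=None, k: int = 3) -> ActivationReport:
    """Per-channel mean activations, the k largest |mean|s, and the median |mean|.

    Mirrors the standard massive-activation diagnostic: outlier channels show
    up as top-k magnitudes far above the median.
    """
    layer_outputs = list(layer_outputs)
    if not layer_outputs:
        raise ValueError("activation_report requires at least one sample")
    rows = np.concatenate(list(_iter_valid(layer_outputs, masks)), axis=0)
    if rows.shape[0] == 0:
        raise ValueError("no valid positions")
    per_channel_mean = rows.mean(axis=0)
    mags = np.abs(per_channel_mean)
    order = np.argsort(-mags)[:k]
    top = [(int(c), float(mags[c])) for c in order]
    return ActivationReport(
        per_channel_mean=per_channel_mean,
        top_k_magnitudes=top,
        median_magnitude=float(np.median(mags)),
    )


def zero_channels(x: np.ndarray, channels) -> np.ndarray:
    """Return a copy of ``x`` with the listed channels set to zero."""
    x = np.asarray(x)
    out = x.copy()
    for c in channels:
        if not (0 <= c < x.shape[-1]):
            raise ValueError(f"channel {c} out of range [0, {x.shape[-1]})")
        out[..., c] = 0.0
    return out


def save_channel_stats(path, stats: ChannelStats) -> None:
    payload = {
        "x_min": stats.x_min.tolist(),
        "x_max": stats.x_max.tolist(),
        "c_min": stats.c_min,
        "c_max": stats.c_max,
        "n_samples_used": stats.n_samples_used,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_channel_stats(path) -> ChannelStats:
    with open(path) as fh:
        payload = json.load(fh)
    return ChannelStats(
        x_min=np.array(payload["x_min"]),
        x_max=np.array(payload["x_max"]),
        c_min=payload["c_min"],
        c_max=payload["c_max"],
        n_samples_used=payload["n_samples_used"],
    )
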