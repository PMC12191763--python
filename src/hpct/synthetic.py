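"""Seeded synthetic protein-language-model latents.

Real pLM latents that feed a folding trunk are per-residue matrices
(length L x channels D, D = 1,024 for the latent this stack targets) with
two statistical properties this generator reproduces:

* **Low intrinsic rank** — each residue's embedding row is a fixed linear
  mixture of a small number of latent factors, so the stacked-row
  covariance has at most ``intrinsic_rank`` non-trivial eigenvalues.
* **Massive activations** — a handful of fixed channels carry constant
  offsets whose mean magnitude is orders of magnitude above the median
  channel, independent of the input; by convention these default to
  channel indices [274, 641, 37].

Each residue additionally carries a token label in [0, 21) (20 amino
acids plus an unknown placeholder) that is a deterministic function of the
noiseless low-rank signal: the argmax of a fixed random D x 21 projection.
This gives sequence-decoder heads a perfectly recoverable target, an
analogue of the sequence information embedded in real latents.

Toy 3D backbones (ideal helices) are provided for exercising structure
metrics without any structure database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_embeddings",
    "gen_toy_structures",
    "helix_coords",
    "pad_and_stack",
    "LABEL_ALPHABET",
]

#: 20 amino acids + 'X' for the unknown class; index i maps to LABEL_ALPHABET[i].
LABEL_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

DEFAULT_OUTLIER_CHANNELS = (274, 641, 37)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic latent generator.

    Attributes
    ----------
    n_samples : number of proteins to generate.
    length_range : inclusive (min, max) residue counts; lengths are uniform.
    n_channels : embedding width D.
    intrinsic_rank : number of latent factors per residue.
    outlier_channels : channels receiving a constant massive-activation offset.
    outlier_scale : target ratio of an outlier channel's mean |value| to the
        median non-outlier channel's mean |value|.
    noise_sd : standard deviation of i.i.d. Gaussian measurement noise.
    seed : root seed; identical seeds give bit-identical datasets.
    with_coords : also generate toy helix backbones, one residue per row.
    """

    n_samples: int = 64
    length_range: tuple[int, int] = (32, 128)
    n_channels: int = 1024
    intrinsic_rank: int = 16
    outlier_channels: tuple[int, ...] = DEFAULT_OUTLIER_CHANNELS
    outlier_scale: float = 1000.0
    noise_sd: float = 0.05
    seed: int = 0
    with_coords: bool = False

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo < 4:
            raise ValueError(f"length_range minimum must be >= 4, got {lo}")
        if hi < lo:
            raise ValueError(f"length_range max {hi} < min {lo}")
        if self.intrinsic_rank > self.n_channels:
            raise ValueError(
                f"intrinsic_rank {self.intrinsic_rank} exceeds n_channels {self.n_channels}"
            )
        if self.intrinsic_rank < 1:
            raise ValueError("intrinsic_rank must be >= 1")
        for c in self.outlier_channels:
            if not (0 <= c < self.n_channels):
                raise ValueError(f"outlier channel {c} out of range [0, {self.n_channels})")
        if self.outlier_scale <= 0 or self.noise_sd < 0:
            raise ValueError("outlier_scale must be > 0 and noise_sd >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SyntheticDataset:
    """Ragged collection of per-residue embeddings with aligned labels.

    ``label_matrix`` (D x 21) and ``channel_offsets`` (D,) make the label
    rule reproducible from the dataset alone: for embedding row e the label
    is ``argmax((e - channel_offsets - noise) @ label_matrix)``, evaluated
    here on the noiseless signal.
    """

    embeddings: list[np.ndarray]
    masks: list[np.ndarray]
    labels: list[np.ndarray]
    coords: list[np.ndarray] | None
    config: SyntheticConfig
    label_matrix: np.ndarray = field(repr=False, default=None)
    channel_offsets: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        n = len(self.embeddings)
        if not (len(self.masks) == len(self.labels) == n):
            raise ValueError("embeddings/masks/labels must have equal sample counts")
        for e, m, l in zip(self.embeddings, self.masks, self.labels):
            if not (e.shape[0] == m.shape[0] == l.shape[0]):
                raise ValueError("per-sample lengths disagree across embeddings/masks/labels")

    def __len__(self) -> int:
        return len(self.embeddings)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e.shape[0] for e in self.embeddings])


def gen_embeddings(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a seeded dataset of low-rank latents with massive activations.

    The signal for residue t is ``z_t @ M`` with ``z_t ~ N(0, I_r)`` and a
    fixed mixing matrix ``M`` (r x D, columns scaled so per-channel signal
    variance is ~1/1).  Outlier channels then receive a constant positive
    offset calibrated on the realized data so that their mean |value|
    exceeds the median non-outlier channel's mean |value| by at least
    ``outlier_scale``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    d, r = cfg.n_channels, cfg.intrinsic_rank
    mixing = rng.standard_normal((r, d)) / np.sqrt(r)
    label_matrix = rng.standard_normal((d, 21))
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_samples)

    signals, embeddings, labels = [], [], []
    for length in lengths:
        z = rng.standard_normal((length, r))
        signal = z @ mixing
        noise = cfg.noise_sd * rng.standard_normal((length, d)) if cfg.noise_sd > 0 else 0.0
        signals.append(signal)
        embeddings.append(signal + noise)
        labels.append(np.argmax(signal @ label_matrix, axis=1))

    # Calibrate constant offsets so the outlier contract holds by construction.
    stacked = np.concatenate(embeddings, axis=0)
    mean_abs = np.abs(stacked).mean(axis=0)
    non_outlier = np.setdiff1d(np.arange(d), np.asarray(cfg.outlier_channels))
    med = np.median(mean_abs[non_outlier])
    offsets = np.zeros(d)
    for i, c in enumerate(cfg.outlier_channels):
        # small per-channel spread so outliers are distinguishable in reports
        offsets[c] = cfg.outlier_scale * med * (1.1 + 0.05 * i) + mean_abs[c]
    embeddings = [e + offsets for e in embeddings]

    masks = [np.ones(length, dtype=np.int8) for length in lengths]
    coords = None
    if cfg.with_coords:
        coords = [
            helix_coords(int(length)) + 0.1 * rng.standard_normal((int(length), 3))
            for length in lengths
        ]
    return SyntheticDataset(
        embeddings=embeddings,
        masks=masks,
        labels=labels,
        coords=coords,
        config=cfg,
        label_matrix=label_matrix,
        channel_offsets=offsets,
    )


def helix_coords(length: int, rise: float = 1.5, radius: float = 2.3,
                 turn_deg: float = 100.0) -> np.ndarray:
    """CA trace of an ideal helix: fixed rise/residue, radius and turn angle."""
    if length < 3:
        raise ValueError("helix length must be >= 3")
    t = np.arange(length)
    theta = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * t])


def gen_toy_structures(n: int, length: int, seed: int = 0,
                       rigid_copies: bool = False) -> list[np.ndarray]:
    """Toy backbones for metric tests: ideal helices under random rigid motions.

    With ``rigid_copies=True`` returns ``2n`` structures where structure
    ``n + i`` is a rigid-motion copy of structure ``i`` (same internal
    geometry, rotated and translated) — useful as ground truth for
    superposition metrics.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    rng = np.random.default_rng(seed)
    base = helix_coords(length)
    structures = []
    for _ in range(n):
        structures.append(base + rng.standard_normal(3))
    if rigid_copies:
        from scipy.spatial.transform import Rotation

        for i in range(n):
            rot = Rotation.random(rng=rng).as_matrix()
            structures.append(structures[i] @ rot.T + 10 * rng.standard_normal(3))
    return structures


def pad_and_stack(dataset: SyntheticDataset, pad_to: int | None = None):
    """Pad ragged samples with zeros into dense arrays.

    Returns ``(embeddings (N, Lmax, D), masks (N, Lmax), labels (N, Lmax))``.
    Zero is the pad value everywhere; labels at padded positions are 0 and
    must be ignored via the mask.
    """
    lengths = dataset.lengths
    lmax = int(lengths.max()) if pad_to is None else pad_to
    if lmax < lengths.max():
        raise ValueError(f"pad_to={pad_to} smaller than longest sample {lengths.max()}")
    n = len(dataset)
    d = dataset.embeddings[0].shape[1]
    emb = np.zeros((n, lmax, d))
    mask = np.zeros((n, lmax), dtype=np.int8)
    lab = np.zeros((n, lmax), dtype=np.int64)
    for i, (e, m, l) in enumerate(zip(dataset.embeddings, dataset.masks, dataset.labels)):
        li = e.shape[0]
        emb[i, :li] = e
        mask[i, :li] = m
        lab[i, :li] = l
    return emb, mask, lab
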