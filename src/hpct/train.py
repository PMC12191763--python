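"""Training loops and probe harnesses for the compression stack.

The autoencoder is trained end to end with a masked mean-squared-error
reconstruction loss (padded positions never contribute), AdamW, and a
linear warmup to a constant learning rate.  Defaults follow the settings
used for the full-scale latents: lr 8e-5 with 5,000 warmup steps for
continuous bottlenecks and lr 1e-4 with 1,000 warmup steps for discrete
ones.  Desk-scale experiments pass their own ``TrainConfig``.

Also here: the sequence-decoder head (two affine layers, hidden width
1,024, 21 output classes) that maps per-residue embeddings back to token
labels, and a linear-probe harness (mean pool -> projection to 1,024 ->
2-layer MLP) for protein-level targets on compressed latents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, constant, gelu, log_softmax
from .hourglass import HourglassAutoencoder, HourglassConfig
from .nn import AdamW, Linear, Module
from .norm import ChannelStats, estimate_channel_stats, normalize
from .synthetic import SyntheticDataset, pad_and_stack

__all__ = [
    "TrainConfig",
    "TrainedCompressor",
    "masked_mse",
    "masked_mse_tensor",
    "train_compression",
    "SequenceDecoder",
    "train_sequence_decoder",
    "LinearProbe",
    "linear_probe",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 8e-5
    warmup_steps: int = 5000
    max_steps: int = 2000
    batch_size: int = 8
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.warmup_steps < 0 or self.max_steps < 0:
            raise ValueError("warmup_steps and max_steps must be >= 0")

    @staticmethod
    def discrete_default() -> "TrainConfig":
        return TrainConfig(learning_rate=1e-4, warmup_steps=1000)


class TrainingDiverged(RuntimeError):
    pass


def masked_mse(x: np.ndarray, x_hat: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared difference over valid positions x channels only."""
    x, x_hat = np.asarray(x, dtype=np.float64), np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("masked_mse requires at least one valid position")
    diff = (x - x_hat)[m]
    return float((diff ** 2).mean())


def masked_mse_tensor(x_hat: Tensor, x: np.ndarray, mask: np.ndarray) -> Tensor:
    w = mask[..., None].astype(np.float64)
    denom = w.sum() * x.shape[-1]
    if denom == 0:
        raise ValueError("masked_mse requires at least one valid position")
    diff = x_hat - constant(x)
    return (diff * diff * constant(w)).sum() * (1.0 / denom)


@dataclass
class TrainedCompressor:
    """Checkpoint bundle: model + its config + the normalization stats the
    model was trained under (compression is self-describing)."""

    model: HourglassAutoencoder
    config: HourglassConfig
    stats: ChannelStats
    train_config: TrainConfig
    loss_trace: list[float]
    lr_trace: list[float]

    def compress_normalized(self, x_norm: np.ndarray, mask: np.ndarray):
        return self.model.compress(x_norm, mask)

    def compress_raw(self, x: np.ndarray, mask: np.ndarray):
        return self.model.compress(normalize(x, self.stats), mask)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_compression(data: SyntheticDataset, hcfg: HourglassConfig,
                      tcfg: TrainConfig, stats: ChannelStats | None = None,
                      log_every: int = 0) -> TrainedCompressor:
    """Train an HPCT autoencoder on a (synthetic) dataset.

    Channel stats are estimated on the training data unless supplied; all
    inputs are normalized before entering the model.  The loss is the
    masked reconstruction MSE plus, for VQ bottlenecks, the codebook and
    commitment terms.  Raises :class:`TrainingDiverged` on NaN loss.
    """
    if stats is None:
        stats = estimate_channel_stats(data.embeddings, data.masks)
    emb, mask, _ = pad_and_stack(data)
    emb = normalize(emb, stats)
    emb *= mask[..., None]  # keep pad positions at the zero pad value

    model = HourglassAutoencoder(hcfg)
    rng = np.random.default_rng(tcfg.seed)
    opt = AdamW(model.parameters(), lr=tcfg.learning_rate,
                warmup_steps=tcfg.warmup_steps, weight_decay=tcfg.weight_decay)
    loss_trace: list[float] = []
    lr_trace: list[float] = []
    step = 0
    while step < tcfg.max_steps:
        for idx in _batches(len(data), tcfg.batch_size, rng):
            if step >= tcfg.max_steps:
                break
            xb, mb = emb[idx], mask[idx]
            lmax = int(mb.sum(axis=1).max())
            xb, mb = xb[:, :lmax], mb[:, :lmax]
            recon, _, _, aux = model.forward(xb, mb)
            loss = masked_mse_tensor(recon, xb, mb)
            for term in aux.values():
                loss = loss + term
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDiverged(f"non-finite loss {value} at step {step}")
            lr_trace.append(opt.current_lr())
            model.zero_grad()
            loss.backward()
            opt.step()
            loss_trace.append(value)
            step += 1
            if log_every and step % log_every == 0:
                print(f"step {step}: loss {value:.6f}")
    return TrainedCompressor(model=model, config=hcfg, stats=stats,
                             train_config=tcfg, loss_trace=loss_trace,
                             lr_trace=lr_trace)


def eval_masked_mse(model: HourglassAutoencoder, emb: np.ndarray,
                    mask: np.ndarray) -> float:
    recon, _, _, _ = model.forward(emb, mask)
    return masked_mse(emb, recon.data, mask)


# ------------------------------------------------------------ sequence head

class SequenceDecoder(Module):
    """Two affine layers (hidden width 1,024 by default) mapping a per-residue
    embedding to logits over the 21 token classes (20 amino acids + 'X').

    The layers are purely affine — no hidden nonlinearity.  Token identity
    is (near-)linearly decodable from the embedding, and extra decoder
    capacity hurts held-out accuracy on this task, so the head is kept at
    the minimum that fits the factored-affine description.
    """

    N_CLASSES = 21

    def __init__(self, d_in: int, hidden: int = 1024, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, self.N_CLASSES, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits = self(constant(np.asarray(x, dtype=np.float64)))
        return np.argmax(logits.data, axis=-1)


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


def train_sequence_decoder(embeddings, labels, masks=None, hidden: int = 1024,
                           lr: float = 1e-3, steps: int = 400, batch_size: int = 256,
                           holdout_frac: float = 0.1, seed: int = 0):
    """Train the token-decoder head on per-residue (embedding, label) pairs.

    ``embeddings``/``labels``/``masks`` are aligned ragged lists; valid
    positions are pooled, split 90/10 into train/held-out (seeded), and the
    head is trained with cross-entropy.  Returns
    ``(decoder, holdout_accuracy, accuracy_trace)``.
    """
    xs, ys = [], []
    for i, (e, l) in enumerate(zip(embeddings, labels)):
        e, l = np.asarray(e), np.asarray(l)
        if l.min(initial=0) < 0 or l.max(initial=0) >= SequenceDecoder.N_CLASSES:
            raise ValueError("labels must lie in [0, 21)")
        if masks is not None:
            keep = np.asarray(masks[i]).astype(bool)
            e, l = e[keep], l[keep]
        xs.append(e)
        ys.append(l)
    x = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(x.shape[0])
    n_hold = max(1, int(round(holdout_frac * x.shape[0])))
    hold, tr = order[:n_hold], order[n_hold:]
    # standardize inputs (fixed affine map; massive-activation offsets would
    # otherwise dominate the first layer)
    mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0) + 1e-8
    xz = (x - mu) / sd

    dec = SequenceDecoder(x.shape[1], hidden=hidden, seed=seed)
    opt = AdamW(dec.parameters(), lr=lr, warmup_steps=0)
    acc_trace: list[float] = []
    for step in range(steps):
        # cosine decay: the head is small and converges fast, but the final
        # boundary precision needs a vanishing step size
        opt.base_lr = lr * 0.5 * (1.0 + np.cos(np.pi * step / max(steps, 1)))
        idx = tr[rng.integers(0, tr.shape[0], size=min(batch_size, tr.shape[0]))]
        logits = dec(constant(xz[idx]))
        loss = _cross_entropy(logits, y[idx])
        dec.zero_grad()
        loss.backward()
        opt.step()
        if (step + 1) % max(1, steps // 10) == 0:
            acc_trace.append(float((dec.predict(xz[hold]) == y[hold]).mean()))
    holdout_acc = float((dec.predict(xz[hold]) == y[hold]).mean())
    dec._standardizer = (mu, sd)  # stored so predict-time users can reuse it
    return dec, holdout_acc, acc_trace


# ------------------------------------------------------------- linear probe

class LinearProbe(Module):
    """Mean-pooled probe: projection back to 1,024 channels, then a 2-layer
    MLP to the task output."""

    def __init__(self, d_in: int, n_out: int, proj_width: int = 1024,
                 hidden: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.proj = Linear(d_in, proj_width, rng)
        self.fc1 = Linear(proj_width, hidden, rng)
        self.fc2 = Linear(hidden, n_out, rng)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(gelu(self.proj(pooled)))))


def mean_pool(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mask-weighted mean over the length axis: (B, L, d) -> (B, d)."""
    w = np.asarray(mask, dtype=np.float64)[..., None]
    denom = np.maximum(w.sum(axis=-2), 1e-12)
    return (np.asarray(values, dtype=np.float64) * w).sum(axis=-2) / denom


def linear_probe(compressed, targets, task: str = "regression", proj_width: int = 1024,
                 hidden: int = 256, lr: float = 1e-3, steps: int = 500,
                 holdout_frac: float = 0.2, seed: int = 0):
    """Fit a probe on mean-pooled compressed latents; one target per protein.

    ``compressed`` is a list of :class:`~hpct.hourglass.CompressedLatent` or
    of (values, mask) pairs.  For ``task="regression"`` returns held-out R^2
    and Spearman rho; for ``task="classification"`` held-out accuracy.
    """
    from scipy.stats import spearmanr

    pooled = []
    for item in compressed:
        values, mask = (item.values, item.mask) if hasattr(item, "values") else item
        v = np.asarray(values, dtype=np.float64)
        m = np.asarray(mask)
        if v.ndim == 3:  # batch of one
            v, m = v[0], m[0]
        pooled.append(mean_pool(v[None], m[None])[0])
    x = np.stack(pooled)
    targets = np.asarray(targets)
    if targets.shape[0] != x.shape[0]:
        raise ValueError(f"{targets.shape[0]} targets for {x.shape[0]} proteins")
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(x.shape[0])
    n_hold = max(1, int(round(holdout_frac * x.shape[0])))
    hold, tr = order[:n_hold], order[n_hold:]
    mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0) + 1e-8
    xz = (x - mu) / sd

    if task == "classification":
        n_out = int(targets.max()) + 1
        y = targets.astype(np.int64)
    else:
        n_out = 1
        ty = targets.astype(np.float64)
        t_mu, t_sd = ty[tr].mean(), ty[tr].std() + 1e-12
        y = (ty - t_mu) / t_sd

    probe = LinearProbe(x.shape[1], n_out, proj_width=proj_width, hidden=hidden, seed=seed)
    opt = AdamW(probe.parameters(), lr=lr, warmup_steps=0)
    bsz = min(64, tr.shape[0])
    for _ in range(steps):
        idx = tr[rng.integers(0, tr.shape[0], size=bsz)]
        out = probe(constant(xz[idx]))
        if task == "classification":
            loss = _cross_entropy(out, y[idx])
        else:
            diff = out.reshape(-1) - constant(y[idx])
            loss = (diff * diff).mean()
        probe.zero_grad()
        loss.backward()
        opt.step()

    out_hold = probe(constant(xz[hold])).data
    if task == "classification":
        return {"accuracy": float((np.argmax(out_hold, axis=-1) == y[hold]).mean())}
    pred = out_hold.reshape(-1)
    resid = ((pred - y[hold]) ** 2).sum()
    total = ((y[hold] - y[hold].mean()) ** 2).sum()
    r2 = float(1.0 - resid / max(total, 1e-12))
    rho = float(spearmanr(pred, y[hold]).statistic) if n_hold > 2 else float("nan")
    return {"r2": r2, "spearman": rho}
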