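"""Training loop contracts: masked loss, warmup schedule, determinism,
checkpointing, and the sequence-decoder / probe harnesses."""

import dataclasses

import numpy as np
import pytest

from hpct.hourglass import HourglassConfig
from hpct.io import load_checkpoint, save_checkpoint
from hpct.norm import estimate_channel_stats, normalize
from hpct.synthetic import SyntheticConfig, gen_embeddings, pad_and_stack
from hpct.train import (
    TrainConfig,
    eval_masked_mse,
    linear_probe,
    masked_mse,
    train_compression,
    train_sequence_decoder,
)

TINY_H = dict(d_model=32, n_layers_enc=1, n_layers_dec=1, n_heads=4,
              shorten_factor=2, downproj_factor=4)
TINY_T = dict(learning_rate=3e-3, warmup_steps=10, batch_size=4)


@pytest.fixture(scope="module")
def tiny_data():
    cfg = SyntheticConfig(n_samples=12, length_range=(8, 14), n_channels=32,
                          intrinsic_rank=4, outlier_channels=(3, 17),
                          outlier_scale=500.0, noise_sd=0.02, seed=5)
    return gen_embeddings(cfg)


# ------------------------------------------------------------------ masked mse

def test_masked_mse_zero_for_identical_inputs(rng):
    x = rng.standard_normal((2, 5, 3))
    assert masked_mse(x, x, np.ones((2, 5))) == 0.0


def test_masked_mse_constant_offset_closed_form(rng):
    x = rng.standard_normal((2, 5, 3))
    assert masked_mse(x, x + 0.3, np.ones((2, 5))) == pytest.approx(0.09)


def test_masked_mse_ignores_padded_rows(rng):
    x = rng.standard_normal((1, 6, 3))
    mask = np.array([[1, 1, 1, 1, 0, 0]])
    y = x.copy()
    y[0, 4:] += 1e6
    assert masked_mse(x, y, mask) == 0.0


def test_masked_mse_empty_mask_rejected(rng):
    x = rng.standard_normal((1, 3, 2))
    with pytest.raises(ValueError):
        masked_mse(x, x, np.zeros((1, 3)))


# -------------------------------------------------------------- training loop

def test_warmup_schedule_is_linear_then_constant(tiny_data):
    hcfg = HourglassConfig(**TINY_H, seed=0)
    tcfg = TrainConfig(**TINY_T, max_steps=25, seed=0)
    trained = train_compression(tiny_data, hcfg, tcfg)
    lrs = np.array(trained.lr_trace)
    expected = tcfg.learning_rate * np.minimum(1.0, np.arange(1, 26) / tcfg.warmup_steps)
    np.testing.assert_allclose(lrs, expected, rtol=1e-12)


def test_same_seed_gives_identical_loss_trace(tiny_data):
    hcfg = HourglassConfig(**TINY_H, seed=3)
    tcfg = TrainConfig(**TINY_T, max_steps=12, seed=3)
    a = train_compression(tiny_data, hcfg, tcfg)
    b = train_compression(tiny_data, hcfg, tcfg)
    assert a.loss_trace == b.loss_trace


def test_zero_max_steps_leaves_initialization_untouched(tiny_data):
    hcfg = HourglassConfig(**TINY_H, seed=4)
    trained = train_compression(tiny_data, hcfg, TrainConfig(**TINY_T, max_steps=0, seed=0))
    from hpct.hourglass import HourglassAutoencoder

    fresh = HourglassAutoencoder(hcfg)
    for (ka, pa), (kb, pb) in zip(
        sorted(trained.model.named_parameters()), sorted(fresh.named_parameters())
    ):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)
    assert trained.loss_trace == []


def test_loss_decreases_on_compressible_data(tiny_data):
    hcfg = HourglassConfig(**TINY_H, seed=1)
    trained = train_compression(tiny_data, hcfg, TrainConfig(**TINY_T, max_steps=150, seed=1))
    first = np.mean(trained.loss_trace[:10])
    last = np.mean(trained.loss_trace[-10:])
    assert last < 0.5 * first


def test_checkpoint_round_trip_reproduces_loss(tmp_path, tiny_data):
    hcfg = HourglassConfig(**TINY_H, seed=2)
    trained = train_compression(tiny_data, hcfg, TrainConfig(**TINY_T, max_steps=30, seed=2))
    emb, mask, _ = pad_and_stack(tiny_data)
    embn = normalize(emb, trained.stats) * mask[..., None]
    before = eval_masked_mse(trained.model, embn, mask)
    p = tmp_path / "ckpt.npz"
    save_checkpoint(p, trained)
    loaded = load_checkpoint(p)
    after = eval_masked_mse(loaded.model, embn, mask)
    assert abs(before - after) < 1e-6
    assert loaded.config == trained.config
    np.testing.assert_allclose(loaded.stats.x_min, trained.stats.x_min)


def test_vq_training_runs_and_reports_aux_losses(tiny_data):
    hcfg = HourglassConfig(**TINY_H, bottleneck_kind="vq", codebook_size=16, seed=6)
    tcfg = TrainConfig(learning_rate=1e-3, warmup_steps=10, batch_size=4,
                       max_steps=40, seed=6)
    trained = train_compression(tiny_data, hcfg, tcfg)
    assert len(trained.loss_trace) == 40
    assert np.isfinite(trained.loss_trace).all()


def test_fsq_training_runs(tiny_data):
    hcfg = HourglassConfig(**TINY_H, bottleneck_kind="fsq",
                           fsq_levels=(5,) * 8, seed=7)
    tcfg = TrainConfig(learning_rate=1e-3, warmup_steps=10, batch_size=4,
                       max_steps=30, seed=7)
    trained = train_compression(tiny_data, hcfg, tcfg)
    assert np.isfinite(trained.loss_trace).all()


# ------------------------------------------------------------- sequence head

def test_sequence_decoder_output_shape_is_l_by_21(tiny_data):
    from hpct.autograd import constant
    from hpct.train import SequenceDecoder

    dec = SequenceDecoder(32, hidden=64, seed=0)
    x = tiny_data.embeddings[0]
    logits = dec(constant(x))
    assert logits.shape == (x.shape[0], 21)


def test_sequence_decoder_chance_level_on_shuffled_labels():
    cfg = SyntheticConfig(n_samples=24, length_range=(16, 24), n_channels=32,
                          intrinsic_rank=4, outlier_channels=(3,), noise_sd=0.0, seed=9)
    ds = gen_embeddings(cfg)
    rng = np.random.default_rng(0)
    shuffled = [rng.integers(0, 21, size=l.shape[0]) for l in ds.labels]
    _, acc, _ = train_sequence_decoder(ds.embeddings, shuffled, ds.masks,
                                       hidden=64, steps=150, seed=0)
    assert abs(acc - 1 / 21) < 0.05


def test_sequence_decoder_rejects_out_of_range_labels(tiny_data):
    bad = [np.full(e.shape[0], 25) for e in tiny_data.embeddings]
    with pytest.raises(ValueError):
        train_sequence_decoder(tiny_data.embeddings, bad, tiny_data.masks)


# -------------------------------------------------------------- linear probe

def test_probe_recovers_linear_function_of_pooled_embedding():
    rng = np.random.default_rng(2)
    n, l, d = 600, 10, 8
    items, targets = [], []
    w = rng.standard_normal(d)
    for _ in range(n):
        v = rng.standard_normal((l, d))
        m = np.ones(l)
        items.append((v, m))
        targets.append(float(v.mean(axis=0) @ w))
    out = linear_probe(items, targets, task="regression", proj_width=32,
                       hidden=32, steps=1500, lr=3e-3, seed=0)
    assert out["r2"] > 0.99


def test_probe_shuffled_classification_labels_give_chance_accuracy():
    rng = np.random.default_rng(3)
    items = [(rng.standard_normal((6, 4)), np.ones(6)) for _ in range(80)]
    labels = rng.integers(0, 4, size=80)
    out = linear_probe(items, labels, task="classification", proj_width=16,
                       hidden=16, steps=200, seed=0)
    assert out["accuracy"] < 0.6  # chance is 0.25; allow small-sample wobble


def test_probe_target_count_mismatch_rejected():
    items = [(np.zeros((4, 3)), np.ones(4))]
    with pytest.raises(ValueError):
        linear_probe(items, [1.0, 2.0])
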