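"""Bottlenecks: tanh bounds, VQ nearest-neighbour semantics against a
brute-force oracle, FSQ grid/index algebra, and codebook diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpct.autograd import Parameter, constant
from hpct.bottleneck import (
    Codebook,
    FSQBottleneck,
    FSQLevels,
    TokenizedLatent,
    VQBottleneck,
    codebook_utilization,
    fsq_codes_to_index,
    fsq_grid_values,
    fsq_index_to_codes,
    fsq_quantize,
    tanh_bottleneck,
    vq_perplexity,
    vq_quantize,
)


# ----------------------------------------------------------------------- tanh

def test_tanh_bottleneck_values():
    assert tanh_bottleneck(np.array(0.0)) == 0.0
    assert abs(tanh_bottleneck(np.array(1e6)) - 1.0) < 1e-9
    assert tanh_bottleneck(np.array(0.5)) == pytest.approx(0.46211715726, abs=1e-9)
    x = np.linspace(-8, 8, 101)
    out = tanh_bottleneck(x)
    assert (out > -1).all() and (out < 1).all()


# ------------------------------------------------------------------------- VQ

def brute_force_nearest(c, codebook):
    return np.array([
        int(np.argmin([np.sum((row - e) ** 2) for e in codebook])) for row in c
    ])


def test_vq_matches_brute_force_scan_on_random_cases(rng):
    for _ in range(25):
        c_size = int(rng.integers(1, 64))
        d_c = int(rng.integers(1, 16))
        cb = Codebook(rng.standard_normal((c_size, d_c)))
        x = rng.standard_normal((40, d_c))
        tokens, quantized, _ = vq_quantize(x, cb)
        np.testing.assert_array_equal(tokens.indices, brute_force_nearest(x, cb.vectors))
        np.testing.assert_array_equal(quantized, cb.vectors[tokens.indices])


def test_vq_exact_code_has_zero_auxiliary_losses():
    cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
    tokens, quantized, losses = vq_quantize(np.array([[1.0, 1.0]]), cb)
    assert tokens.indices[0] == 1
    assert losses["codebook"] == 0.0 and losses["commitment"] == 0.0


def test_vq_nearest_and_tie_break():
    cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
    tokens, quantized, _ = vq_quantize(np.array([[0.9, 0.8]]), cb)
    assert tokens.indices[0] == 1
    np.testing.assert_array_equal(quantized[0], [1.0, 1.0])
    # equidistant input -> lowest index
    tokens, _, _ = vq_quantize(np.array([[0.5, 0.5]]), cb)
    assert tokens.indices[0] == 0


def test_vq_empty_codebook_rejected():
    with pytest.raises(ValueError):
        Codebook(np.zeros((0, 3)))


def test_vq_module_straight_through_gradient_reaches_encoder(rng):
    bn = VQBottleneck(codebook_size=4, d_c=3, rng=np.random.default_rng(0))
    c = Parameter(rng.standard_normal((1, 5, 3)))
    mask = np.ones((1, 5))
    quantized, tokens, aux = bn(c, mask)
    loss = (quantized * quantized).sum() + aux["codebook"] + aux["commitment"]
    loss.backward()
    assert c.grad is not None and np.any(c.grad != 0)
    assert bn.codebook.grad is not None and np.any(bn.codebook.grad != 0)


def test_vq_module_loss_terms_match_printed_form(rng):
    beta = 0.25
    bn = VQBottleneck(codebook_size=8, d_c=4, rng=np.random.default_rng(1), beta=beta)
    c = Parameter(rng.standard_normal((1, 6, 4)))
    mask = np.ones((1, 6))
    quantized, tokens, aux = bn(c, mask)
    sel = bn.codebook.data[tokens.indices]
    expected = ((c.data - sel) ** 2).mean()
    assert aux["codebook"].item() == pytest.approx(expected)
    assert aux["commitment"].item() == pytest.approx(beta * expected)
    # straight-through realizes the value as c + (sel - c): equal to 1 ulp
    np.testing.assert_allclose(quantized.data, sel, atol=1e-12)


# ----------------------------------------------------------------- perplexity

@pytest.mark.parametrize(
    "counts,expected",
    # [3,1] value frozen from exp(scipy.stats.entropy([3,1])) = 1.7547653...
    [(np.ones(16), 16.0), ([0, 10, 0], 1.0), ([3, 1], 1.7547653506)],
)
def test_vq_perplexity_values(counts, expected):
    assert vq_perplexity(counts) == pytest.approx(expected, rel=1e-9)


def test_vq_perplexity_zero_total_rejected():
    with pytest.raises(ValueError):
        vq_perplexity([0, 0])


# ------------------------------------------------------------------------ FSQ

def test_fsq_zero_is_a_fixed_point():
    tokens, quantized = fsq_quantize(np.zeros((3, 2)), FSQLevels((5, 5)))
    np.testing.assert_array_equal(quantized, 0.0)


def test_fsq_saturation_and_worked_rounding():
    levels = FSQLevels((5,))
    # tanh(10) ~ 1 -> top bin (integer 2 of [-2..2], decoder value 1.0)
    _, q = fsq_quantize(np.array([[10.0]]), levels)
    assert q[0, 0] == pytest.approx(1.0)
    # round(2 * tanh(0.3)) = round(0.58262) = 1 -> decoder value 0.5
    _, q = fsq_quantize(np.array([[0.3]]), levels)
    assert q[0, 0] == pytest.approx(0.5)


def test_fsq_grid_membership_and_idempotence(rng):
    levels = FSQLevels((5, 4, 3))
    z = rng.standard_normal((50, 3)) * 3
    _, q = fsq_quantize(z, levels)
    for j in range(3):
        grid = fsq_grid_values(levels, j)
        assert np.all(np.isin(np.round(q[:, j], 10), np.round(grid, 10)))
    # idempotent: grid values quantize to themselves (atanh maps back inside tanh)
    _, q2 = fsq_quantize(np.arctanh(np.clip(q, -0.999999, 0.999999)), levels)
    np.testing.assert_allclose(q2, q, atol=1e-9)


@pytest.mark.parametrize("levels", [(3, 3), (5, 4), (2, 2, 2), (7,)])
def test_fsq_code_index_bijection_exhaustive(levels):
    lv = FSQLevels(levels)
    grids = np.stack(np.meshgrid(*[np.arange(l) for l in levels], indexing="ij"), axis=-1)
    tuples = grids.reshape(-1, len(levels))
    idx = fsq_codes_to_index(tuples, lv)
    assert sorted(idx.tolist()) == list(range(lv.implicit_size))
    back = fsq_index_to_codes(idx, lv)
    np.testing.assert_array_equal(back, tuples)


def test_fsq_even_levels_reachable_through_quantizer():
    # drive the even-level offset path across its full input range
    levels = FSQLevels((5, 4))
    z = np.linspace(-4, 4, 201)
    z2 = np.stack([z, z], axis=-1)
    tokens, q = fsq_quantize(z2, levels)
    assert len(np.unique(np.rint(q[:, 0] * 2))) == 5
    assert len(np.unique(q[:, 1])) == 4
    assert tokens.indices.max() < levels.implicit_size


def test_fsq_degenerate_and_implicit_sizes():
    assert FSQLevels((1,)).implicit_size == 1
    tokens, q = fsq_quantize(np.array([[3.0]]), FSQLevels((1,)))
    assert tokens.indices[0] == 0 and q[0, 0] == 0.0
    assert FSQLevels((2,) * 8).implicit_size == 256
    with pytest.raises(ValueError):
        FSQLevels((0, 3))


def test_fsq_out_of_range_codes_rejected():
    with pytest.raises(ValueError):
        fsq_codes_to_index(np.array([[3, 0]]), FSQLevels((3, 3)))
    with pytest.raises(ValueError):
        fsq_index_to_codes(np.array([9]), FSQLevels((3, 3)))


@settings(deadline=None, max_examples=30)
@given(st.lists(st.integers(1, 6), min_size=1, max_size=4), st.integers(0, 2 ** 31 - 1))
def test_fsq_roundtrip_property(levels, seed):
    lv = FSQLevels(tuple(levels))
    rng = np.random.default_rng(seed)
    codes = np.stack([rng.integers(0, l, size=10) for l in levels], axis=-1)
    back = fsq_index_to_codes(fsq_codes_to_index(codes, lv), lv)
    np.testing.assert_array_equal(back, codes)


def test_fsq_module_straight_through_gradient(rng):
    bn = FSQBottleneck(FSQLevels((5, 5)))
    c = Parameter(rng.standard_normal((1, 4, 2)))
    out, tokens, _ = bn(c, np.ones((1, 4)))
    (out * out).sum().backward()
    assert np.any(c.grad != 0)
    assert tokens.indices.shape == (1, 4)


def test_fsq_forced_utilization_on_spanning_input():
    levels = FSQLevels((3, 3))
    rng = np.random.default_rng(3)
    z = rng.uniform(-3, 3, size=(4000, 2))
    tokens, _ = fsq_quantize(z, levels)
    assert codebook_utilization(tokens, levels.implicit_size) == 1.0


# ---------------------------------------------------------------- utilization

def test_codebook_utilization_extremes():
    full = TokenizedLatent(indices=np.arange(8), codebook_size=8)
    assert codebook_utilization(full, 8) == 1.0
    collapsed = TokenizedLatent(indices=np.zeros(100, dtype=int), codebook_size=16)
    assert codebook_utilization(collapsed, 16) == pytest.approx(1 / 16)


def test_codebook_utilization_ignores_masked_positions():
    t = TokenizedLatent(indices=np.array([0, 1, 2, 3]), mask=np.array([1, 1, 0, 0]))
    assert codebook_utilization(t, 4) == pytest.approx(2 / 4)


def test_uniform_random_tokens_cover_codebook():
    rng = np.random.default_rng(9)
    t = TokenizedLatent(indices=rng.integers(0, 16, size=10_000), codebook_size=16)
    # coupon-collector: miss probability < 16 * (15/16)^10000, astronomically small
    assert codebook_utilization(t, 16) == 1.0
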