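"""Neural-network building blocks on top of :mod:`hpct.autograd`.

Pre-norm transformer blocks with learned relative-position attention bias,
masked multi-head self/cross attention, and a decoupled-weight-decay Adam
optimizer.  All initialization is driven by an explicit ``numpy`` Generator
so models are bit-reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, constant, gelu, softmax, take

MASK_NEG = 1e9


def orthogonal_init(rng: np.random.Generator, d_in: int, d_out: int, gain: float = 1.0) -> np.ndarray:
    """Scaled-orthogonal init: orthonormal columns (or rows) times ``gain``."""
    a = rng.standard_normal((max(d_in, d_out), min(d_in, d_out)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign ambiguity for determinism
    w = q if d_in >= d_out else q.T
    return gain * w


class Module:
    """Base class; discovers parameters/submodules from instance attributes."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, orthogonal: bool = False, gain: float = 1.0):
        if orthogonal:
            w = orthogonal_init(rng, d_in, d_out, gain=gain)
        else:
            w = rng.standard_normal((d_in, d_out)) * (gain / np.sqrt(d_in))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, l, d = x.shape
    return x.reshape(b, l, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, l, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)


class SelfAttention(Module):
    """Masked multi-head self-attention with a learned relative-position bias.

    The bias is a per-head lookup over clipped relative offsets j - i in
    [-max_offset, max_offset]; this is the only positional information in
    the model.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, max_offset: int = 64):
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, bias=False)
        self.rel_bias = Parameter(np.zeros((2 * max_offset + 1, n_heads)))
        self.n_heads = n_heads
        self.max_offset = max_offset
        self._dh = d // n_heads

    def _bias(self, l: int) -> Tensor:
        idx = np.arange(l)[None, :] - np.arange(l)[:, None]
        idx = np.clip(idx, -self.max_offset, self.max_offset) + self.max_offset
        b = take(self.rel_bias, idx)            # (L, L, H)
        return b.transpose(2, 0, 1).reshape(1, self.n_heads, l, l)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b, l, d = x.shape
        q = _split_heads(self.wq(x), self.n_heads)
        k = _split_heads(self.wk(x), self.n_heads)
        v = _split_heads(self.wv(x), self.n_heads)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self._dh))
        scores = scores + self._bias(l)
        key_bias = (mask[:, None, None, :] - 1.0) * MASK_NEG
        attn = softmax(scores + constant(key_bias), axis=-1)
        return self.wo(_merge_heads(attn @ v))


class CrossAttention(Module):
    """Masked multi-head cross-attention (queries over a separate key set)."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, bias=False)
        self.n_heads = n_heads
        self._dh = d // n_heads

    def __call__(self, queries: Tensor, keys_values: Tensor, kv_mask: np.ndarray) -> Tensor:
        q = _split_heads(self.wq(queries), self.n_heads)
        k = _split_heads(self.wk(keys_values), self.n_heads)
        v = _split_heads(self.wv(keys_values), self.n_heads)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self._dh))
        key_bias = (kv_mask[:, None, None, :] - 1.0) * MASK_NEG
        attn = softmax(scores + constant(key_bias), axis=-1)
        return self.wo(_merge_heads(attn @ v))


class FeedForward(Module):
    def __init__(self, d: int, rng: np.random.Generator, expansion: int = 4):
        self.fc1 = Linear(d, expansion * d, rng)
        self.fc2 = Linear(expansion * d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-norm block: x + Attn(LN(x)), then x + FF(LN(x))."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = SelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.ff = FeedForward(d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), mask)
        return x + self.ff(self.ln2(x))


class TransformerStack(Module):
    def __init__(self, d: int, n_layers: int, n_heads: int, rng: np.random.Generator):
        self.blocks = [TransformerBlock(d, n_heads, rng) for _ in range(n_layers)]
        self.ln_out = LayerNorm(d)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        for block in self.blocks:
            x = block(x, mask)
        return self.ln_out(x)


class AdamW:
    """Adam with decoupled weight decay and linear warmup to a constant rate."""

    def __init__(self, params: list[Parameter], lr: float, warmup_steps: int = 0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.base_lr = lr
        self.warmup_steps = warmup_steps
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        # warmup applies to the *upcoming* step t+1
        s = self.t + 1
        scale = min(1.0, s / self.warmup_steps) if self.warmup_steps > 0 else 1.0
        return self.base_lr * scale

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
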