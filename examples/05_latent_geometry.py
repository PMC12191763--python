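"""Latent-space geometry: interpolation smoothness and token corruption.

Interpolates linearly between two latents and tabulates similarity to the
endpoints, then corrupts discrete tokens at increasing rates and checks
the expected damage rate * (1 - 1/C).
"""

import numpy as np

from hpct import TokenizedLatent, corrupt_tokens, interpolate, smoothness_curve

rng = np.random.default_rng(0)
x1 = rng.standard_normal((20, 8))
x2 = rng.standard_normal((20, 8))

trace = interpolate(x1, x2, np.linspace(0, 1, 6))
out = smoothness_curve(trace, lambda a, b: -float(np.linalg.norm(a - b)))
print(" t     dist->x1   dist->x2")
for t, s1, s0 in zip(out["t"], out["similarity_to_t1"], out["similarity_to_t0"]):
    print("%.1f   %8.3f   %8.3f" % (t, -s1, -s0))
print("monotone fraction toward x1: %.2f (1.0 = perfectly smooth in latent space)"
      % out["monotone_fraction"])

c = 64
tokens = TokenizedLatent(indices=rng.integers(0, c, size=5000), codebook_size=c)
print("\ncorruption  changed  expected")
for rate in (0.1, 0.5, 0.9):
    out_t = corrupt_tokens(tokens, rate, c, seed=1)
    changed = float((out_t.indices != tokens.indices).mean())
    print("   %.1f      %.3f    %.3f" % (rate, changed, rate * (1 - 1 / c)))
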