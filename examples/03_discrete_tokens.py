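"""Quantize latents into discrete tokens with VQ-VAE and FSQ bottlenecks.

Shows nearest-neighbour VQ assignment with its codebook/commitment losses
and selection perplexity, and FSQ's parameter-free grid quantization with
its implicit codebook (the product of per-channel level counts).
"""

import numpy as np

from hpct import (
    Codebook,
    FSQLevels,
    codebook_utilization,
    fsq_index_to_codes,
    fsq_quantize,
    vq_perplexity,
    vq_quantize,
)

rng = np.random.default_rng(0)

# --- VQ: learned codebook, nearest neighbour in Euclidean space
codebook = Codebook(rng.standard_normal((16, 8)))
z = rng.standard_normal((200, 8))
tokens, quantized, losses = vq_quantize(z, codebook, beta=0.25)
counts = np.bincount(tokens.indices, minlength=codebook.size)
print("VQ: %d codes, utilization %.2f, selection perplexity %.2f (max %d)"
      % (codebook.size, codebook_utilization(tokens, codebook.size),
         vq_perplexity(counts), codebook.size))
print("    codebook loss %.4f, commitment loss %.4f" % (losses["codebook"], losses["commitment"]))

# --- FSQ: no quantizer parameters; tanh-bound then round per channel
levels = FSQLevels((8, 8, 8, 8))   # implicit codebook 8^4 = 4096 codes
tokens, quantized = fsq_quantize(rng.standard_normal((2000, 4)) * 2, levels)
print("FSQ levels %s -> implicit codebook %d" % (list(levels.levels), levels.implicit_size))
print("    utilization on 2000 random positions: %.2f"
      % codebook_utilization(tokens, levels.implicit_size))
print("    token 0 decodes to per-channel bins %s"
      % fsq_index_to_codes(tokens.indices[:1], levels)[0].tolist())
# FSQ spreads mass across its grid by construction; VQ must learn to.
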