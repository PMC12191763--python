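# Methods

## Problem setting

Protein language models (pLMs) that feed a folding trunk expose a
per-residue latent `x ∈ R^{L×D}` (D = 1,024 for the latent this package
targets) that jointly encodes sequence and structure information.  Two
properties make that latent awkward to use directly:

1. **Massive activations.**  A handful of channels carry values orders of
   magnitude larger than the median channel, largely independent of the
   input sequence.  They dominate any global normalization and distort
   distance computations.
2. **Low intrinsic dimensionality.**  Far fewer than D effective degrees
   of freedom are present, so most of the storage and compute spent on the
   raw latent is wasted.

The package provides (a) per-channel min-max normalization with
diagnostics for the massive-activation pathology, (b) an hourglass
transformer autoencoder that compresses the length axis by a factor S and
the channel axis by a factor K around a continuous or discrete bottleneck,
(c) the evaluation surface (masked reconstruction error, sequence
recovery, RMSD/RMSPD/TM-score on coordinates), and (d) latent-geometry
probes (linear interpolation, token corruption).  A seeded synthetic
generator reproduces the two statistical properties above so every module
is testable without any pretrained model or structure database.

## Per-channel normalization

Calibration statistics are the elementwise per-channel extrema
`x_min, x_max ∈ R^D` over all valid positions of a reference sample set.
Each channel is mapped affinely so its calibration range lands on
`[c_min, c_max]` (default `[-1, 1]`):

    x' = (x - x_min) / (x_max - x_min) · (c_max - c_min) + c_min

Numerical choices:

* **No clipping** of out-of-calibration values at inference.  The map
  stays invertible and information-preserving; values outside the bounds
  are allowed and documented.
* **Divide guard:** channels whose calibration span is below `1e-12` are
  flagged as constant and map to `c_min`; inverting a stats object with
  constant channels raises rather than producing garbage.
* Padded positions never enter the statistics (mask contract).

## The hourglass autoencoder

Encoder: transformer stack → zero the padded rows → zero-pad L to a
multiple of S → reshape `(L, D) → (L/S, S·D)` and multiply by a learned
`W ∈ R^{S·D×D}` (linear downsampling; equivalent to a stride-S, width-S
convolution) → reduce the mask with an any-valid rule → cross-attention of
the shortened positions over the full-length sequence → channel
downprojection `W_d ∈ R^{D×D/K}`.  Decoder mirrors it: upprojection
`W_u ∈ R^{D/K×D}`, linear upsampling `(L/S, D) → (L, D)`, mask expansion by
repetition, cross-attention of full-length queries over the shortened
positions, and a final transformer stack.  There are no skip connections
across the bottleneck: the reconstruction depends on the input only
through the compressed latent, which stores `ceil(L/S) · D/K` scalars per
protein.

Bottlenecks:

* **tanh** (continuous): elementwise bound to (-1, 1).
* **VQ-VAE**: nearest-neighbour Euclidean assignment to a learned codebook
  (ties break to the lowest index, deterministically), trained with the
  codebook loss `||sg[h] - z||²` and commitment loss `β·||h - sg[z]||²`
  (β = 0.25 default) plus the masked reconstruction MSE; the discrete step
  is crossed with the straight-through estimator.  No EMA updates and no
  codebook resets: collapse, when it happens, is meant to be observable in
  the utilization/perplexity diagnostics rather than masked.
* **FSQ**: per channel j, `tanh` bounds the value and it is rounded onto a
  grid of `L_j` levels — `round(⌊L/2⌋·tanh z)` for odd `L_j`, the standard
  half-integer offset grid for even `L_j`.  Decoder-facing values are
  rescaled to [-1, 1].  The implicit codebook size is `Π L_j`; token
  indices use a mixed-radix encoding with channel 0 most significant.
  Only the rounding is straight-through; the tanh is differentiated
  exactly.

Architecture details the problem leaves open, fixed here as defaults:
pre-norm blocks, GELU feedforward with expansion 4, learned per-head
relative-position bias (clipped at ±64 offsets) as the only positional
information, scaled-orthogonal init for the four resampling/projection
matrices, all seeded from one root seed.  Layer and head counts are
configuration.  When `L % S ≠ 0` the input is zero-padded to the next
multiple and the mask extended with zeros; the loss never includes pad
positions.

## Training

Masked MSE (mean over valid positions × channels) with AdamW and a linear
warmup to a constant learning rate.  Full-scale defaults follow the
regime the latents were originally compressed under: lr 8e-5 with 5,000
warmup steps (continuous), lr 1e-4 with 1,000 warmup steps (discrete);
the post-warmup schedule is constant — the simplest consistent choice.
Auxiliary sequence-space or structure-space losses are deliberately not
implemented (they did not help in the original setting).  Train/test
splits are random per-protein with a seeded shuffle.  A NaN loss aborts
with a diagnostic.  Checkpoints bundle weights, the architecture config
and the channel stats, so compressed artifacts are self-describing.

The desk-scale study conditions used by the test suite are a 64-channel,
2+2-layer model (4 heads) on 48 rank-4 samples of length 12–24 with noise
SD 0.02, batch size 8, lr 3e-3 with 100 warmup steps — sizes chosen so a
single training run finishes in about a minute on one CPU while leaving
the qualitative behaviour (trainability below 10% of data variance;
reconstruction error non-increasing in bottleneck width over d_c ∈
{4, 8, 64}) intact.

**Sequence decoder.**  Two affine layers (hidden width 1,024, 21 output
classes: 20 amino acids plus unknown), trained with cross-entropy, inputs
standardized per channel, cosine learning-rate decay.  The layers are
purely affine with no hidden nonlinearity: token identity is
(near-)linearly decodable from the latent, and added decoder capacity
measurably hurts held-out accuracy by memorizing boundary tokens.

**Linear probe.**  Mask-weighted mean pool over valid positions, a
trainable projection back to 1,024 channels (so probes on different
compression levels have the same downstream capacity), then a 2-layer GELU
MLP; reports held-out R²/Spearman (regression) or accuracy
(classification).

## Metrics

* `rmsd(a, b, superimpose=True)` — optimal rigid-body (Kabsch)
  superposition via `scipy.spatial.transform.Rotation.align_vectors`,
  then the root-mean-square of paired distances.  Superposition needs at
  least 3 atoms.
* `rmspd(a, b)` — RMS difference of all intra-structure pairwise distances
  (i < j).  Superposition-free by construction, and blind to chirality:
  a mirror image scores 0.  This is a documented limitation, not a bug.
* `tm_score(a, b)` — `(1/L) Σ 1/(1 + (d_i/d0)²)` with
  `d0 = 1.24·(L-15)^{1/3} - 1.8`, clamped to 0.5 for L ≤ 15.  The
  score-maximizing superposition is approximated by iteratively re-fitting
  on the residues within d0 of the reference, starting from the global
  Kabsch fit; the score is always evaluated over all residues and
  normalized by the reference (target) length.  No alignment search is
  performed — reconstruction pairs share their residue correspondence.

## Synthetic data: what it emulates, and what it does not

Each residue's embedding row is `z_t M + noise` with `z_t ~ N(0, I_r)` and
a fixed mixing matrix M (rank r « D), plus a constant positive offset on
each configured outlier channel, calibrated on the realized data so the
outlier channel's mean |value| exceeds the median non-outlier channel's by
at least `outlier_scale` (default 1,000×; the offsets are additive and
position-independent, matching the input-independence of the real
pathology).  Token labels are the argmax of a fixed random D×21 projection
of the noiseless low-rank signal, excluding the offsets — including them
would make every label identical.  The rule is deterministic and linearly
recoverable, giving decoder heads a perfect-information target (an upper
bound: a perfect classifier reaches 100%).  Toy backbones are ideal
helices (rise 1.5, radius 2.3, 100°/residue) under rigid motions.

Passing tests on this generator demonstrate the mechanics of the stack —
normalization, shortening, quantization, mask hygiene, metric algebra —
under the two statistical pathologies that motivate it.  They do not
demonstrate performance on real pLM latents: real latents have richer
covariance structure, position-dependent signals, nonlinear
sequence↔embedding relationships, and structure that is genuinely harder
to compress than sequence.  Absolute reconstruction numbers here say
nothing about reconstruction of real embeddings; only the qualitative
orderings (wider bottleneck ⇒ no worse error, and so on) are expected to
transfer.  Real latents enter through the `adapter_stream` seam, which
validates shapes and otherwise treats any provider identically to the
generator.

## Known limitations

* The trainer is single-device, full-precision numpy; it is meant for
  desk-scale experiments and correctness work, not for compressing
  million-protein corpora.
* VQ codebook learning is purely loss-driven; large codebooks on small
  data will show partial utilization (visible in the diagnostics).
* TM-score's iterative superposition is an approximation of the global
  maximum; for adversarial geometries it can return a slight
  underestimate.
* The FSQ level sets appropriate for a given target codebook size are
  exposed entirely as configuration; no schedule of recommended level
  sets ships with the package.
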