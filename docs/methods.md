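# Methods

## Problem setting

Particle picking is cast as binary segmentation followed by instance
localization. A model maps a micrograph to a per-pixel particle
probability; a deterministic geometric pipeline converts the mask to
particle centers. Adaptation to a new protein uses K annotated micrographs
(K-shot; annotation cost is counted per micrograph because each micrograph
carries hundreds of particles).

## Adapter stack

The backbone is any frozen hierarchical encoder exposing, per stage *i* and
block *j*, the block input feature map of shape (H_i, W_i, D_i) and
accepting an additive pre-block modification (`cryofsl.encoder` defines the
contract and a registry). The adapter applied before block (i, j) is

    out = feat + W_shared_i · GELU( W_unshared_(i,j) · (P_emb_i(feat) + P_fft_i(hp_i)) )

with bottleneck width d_i = ⌊D_i / reduction⌋ (minimum 1). Choices that the
formulation leaves open, and how this package resolves them:

- **Bottleneck rounding.** With the full-scale widths (144, 288, 576, 1152)
  and reduction 32, stage 1 gives 144/32 = 4.5; we floor, so
  d = (4, 9, 18, 36). A config with reduction exceeding a stage width is
  rejected unless `clamp_bottleneck=True` clamps d_i to 1.
- **Shared-layer scope.** One shared up-projection per stage. A single
  global layer is dimensionally impossible when stage widths differ, so the
  per-stage reading is the only consistent one.
- **Zero initialization.** Shared up-projections (weights and biases) start
  at zero, making a fresh stack an exact residual identity: the adapted
  forward pass equals the frozen encoder's bit-for-bit semantics at init.
  This is standard adapter practice and stabilizes few-shot training.
- **Biases** are present on all adapter linear maps; the parameter cost is
  negligible and `count_trainable_params` accounts for them explicitly.
- **GELU** uses the exact erf form, not the tanh approximation, so numeric
  tests have a single well-defined reference.

### High-pass stream

The second adapter input is the micrograph filtered by a Gaussian high-pass
with transfer 1 − exp(−f²/2f_c²), f_c = `fft_cutoff_fraction` × Nyquist
(default 0.25, Nyquist = 0.5 cycles/px). The Gaussian transition avoids the
ringing of a brick-wall cutoff; the DC gain is exactly zero, so constant
background vanishes. The filter runs once at full resolution; the result is
block-average-pooled to each stage's token grid and standardized to zero
mean / unit variance per stage (an all-zero stream when the pooled map is
constant). How the stream should reach each stage's resolution is not
dictated by the formulation; average pooling was chosen as the cheapest
alias-free reduction.

## Surrogate encoder

`build_surrogate_encoder` provides a desk-scale stand-in honouring the
four-stage contract: non-overlapping `patch_stride`² patches are linearly
embedded, each block applies a frozen residual two-layer MLP per token, and
stage transitions 2×2-average-pool the grid and widen the embedding
(defaults 16/32/48/64 wide, depths 1/1/2/1, stride 4). Its parameters are
drawn once from a seed and frozen, making it a deterministic multi-scale
random-feature extractor — enough structure for the adapters and head to
learn from, with bit-exact freeze checks via a SHA-256 over parameter
bytes. External backbones (e.g. a SAM2 Hiera-large checkpoint) can be
registered by user plugins; nothing is downloaded.

## Segmentation head and training

The head projects every stage's final features to a common width (default
32), nearest-upsamples to the stage-1 grid, sums, applies GELU + a mixing
layer, and maps each token to its `patch_stride`² pixels (depth-to-space).
Fusing all four stages rather than only the last is a deliberate design
choice: at 1/32 resolution alone, a 16-px particle occupies half a token,
which cannot support per-pixel masks at desk scale. The final layer is
zero-initialized, so an untrained model predicts probability 0.5 everywhere.

Training: images are standardized per micrograph and bilinearly resized to
a square `input_size`; masks are nearest-resized (label-preserving). The
loss is mean-over-pixels BCE-with-logits with a foreground weight
`pos_weight`; in `auto` mode the weight is the background/foreground pixel
ratio of the batch, clipped to [1, 100], falling back to 1 (with a warning)
for degenerate all-one-class targets. Class-frequency weighting is the
standard reading of a "balanced" BCE for sparse particle masks; the
constant-vs-per-batch choice is exposed in config. Optimization is Adam
(β = 0.9/0.999); the full-scale protocol is batch 2, lr 1e-4, up to 4000
epochs at 1024², with no early stopping, augmentation, or scheduling.
Desk-scale runs shrink input size and epochs only. All arithmetic is
float64 numpy through an in-package reverse-mode autodiff tape, so runs
are deterministic given the seed on a fixed platform.

## Localization

Given a probability mask and an expected particle diameter *d*:

1. **Binarize** at `threshold` (strict >, default 0.5).
2. **Distance transform** (exact Euclidean).
3. **Multi-scale peaks**: local maxima of the Gaussian-smoothed distance map
   at sigmas (1, 2, 4) px, finest scale first; candidates below a distance
   floor of 0.25·(d/2) are discarded, and a greedy non-maximum suppression
   enforces `min_peak_distance_frac`·d between seeds (finer scales win
   conflicts). The seed NMS radius defaults to 0.25·d — deliberately below
   the dedup radius — because on a discrete distance map the two maxima of
   an overlapping pair at center gap 0.5·d can round to as little as
   ~0.27·d apart; duplicate suppression is owned by steps 5–6, not by
   seeding.
4. **Marker-controlled watershed** on the negated distance map restricted to
   the foreground; seeds landing on background are dropped with a warning.
5. **Geometric filter**: keep regions with area in `area_range`·π(d/2)²
   (default 0.3–3.0) and circularity 4πA/P² ≥ 0.6, with the perimeter from
   the weighted contour estimator (diagonal steps ≈ √2), since naive
   pixel-edge counting makes even ideal disks fail; circularity is capped
   at 1. Border-touching regions are kept by default (`drop_border`).
6. **Second pass** (default on): accepted regions are erased, the distance
   map is recomputed on the residual foreground, and peak detection reruns
   with the finest scale only and the distance floor halved — recovering
   closely packed particles the first pass merged.
7. **Deduplication**: candidates ordered by (pass 1 first, larger seed
   distance value, then (y, x)); a candidate within
   `min_separation_frac`·d (default 0.6) of an accepted center is dropped.
   The total order makes the output reproducible.

Particle diameter is the region's equivalent diameter; score is the mean
mask probability over the region.

## Synthetic study conditions

The generator renders soft-edged disks (1-px cosine taper — hard edges
alias and destabilize distance-map tests) of amplitude a on a zero-mean
background with additive Gaussian noise of variance a²/snr; SNR is defined
operationally as amplitude²/noise-variance since "low SNR" alone fixes no
number. The binary ground-truth mask is the exact union of hard rasterized
disks, and centers/diameters are stored exactly. Overlapping particles take
the max of their profiles. Identical specs are bit-identical; a K-shot
dataset uses seeds seed+0..K−1, so smaller K are prefixes of larger K.

Desk-scale conditions used throughout tests and the acceptance script:
128² fields with 12 particles of d = 16 px at SNR 4 and 1.5·d separation
for training/evaluation (12 is near the packing limit of a 128-px field at
that separation); 512² fields with 50 disks for the localization oracle;
K = 5 shots, 80 epochs at lr 3e-3 (Adam), batch 2. What the generator does
*not* emulate: CTF, projection structure, ice/carbon contamination,
aggregation, non-circular particles. Passing tests therefore demonstrate
the correctness of the machinery and the recoverability of low-SNR
quasi-circular particles, not performance on real micrographs.

## Evaluation and statistics

Matching is greedy nearest-first one-to-one within `match_radius` (default
0.5·d); the choice is conventional, and tests bound it against the
exhaustive optimal assignment (equal on small instances, never above it).
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, all
with 0/0 → 0. IoU rasterizes each particle set as a union of disks on the
reference grid and takes the pixel intersection/union ratio.

Method comparison, per (method, dataset, metric) against a reference:
Shapiro–Wilk on the paired differences as a normality gate (constant
samples flagged non-testable), a two-sided paired Wilcoxon signed-rank test
with the normal approximation, tie correction, zero differences dropped and
no continuity correction (empirical type-I error at N = 30 is ~0.05), the
rank-biserial effect size r = z/√N with z signed by the direction of the
rank sum, and Benjamini–Hochberg adjustment applied per metric jointly
across all method×dataset tests. Entries with fewer than five valid pairs
are flagged untestable and excluded from adjustment; identical paired
samples yield the degenerate z = 0, p = 1 rather than an error.

## Numerical and I/O choices

- Coordinates everywhere: 0-based pixel centers, x = column, y = row,
  origin top-left; STAR files carry this frame and state it in a comment
  line. Round-trips preserve coordinates to 1e-6 px.
- MRC2014 single 2D images, modes 0/1/2/6; stacks are rejected (the
  pipeline is per-micrograph). Non-finite pixels are replaced by the image
  median with a logged warning, since the FFT stream and standardization
  require finite input. Integer TIFF/PNG values are never rescaled.
- Checkpoints store only trainable arrays plus rebuild metadata; the frozen
  encoder is reconstructed from its seed.

## Known limitations

- The surrogate encoder is a random-feature tower, not a pretrained
  transformer; desk-scale results validate the adaptation machinery, not
  transfer from natural-image pretraining.
- The geometric filter assumes quasi-circular particles; heavily elongated
  or aggregated shapes will be merged or dropped.
- The Wilcoxon implementation is asymptotic; for fewer than ~10 pairs an
  exact-distribution test would be preferable.
- Training is single-process CPU float64 — deterministic and exact, but not
  intended for 1024² full-scale runs, which require an external GPU
  backbone via the encoder registry.
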