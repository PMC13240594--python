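# cryofsl

Few-shot particle picking for cryo-electron microscopy micrographs.

Single-particle cryo-EM reconstruction starts by locating the (x, y)
centers of thousands of protein projections in micrographs with extremely
low signal-to-noise. Supervised pickers need large annotated datasets and
generalize poorly to new targets; template matchers over-pick noise. This
package implements an annotation-efficient alternative: a frozen
hierarchical image encoder is adapted to a new protein with small residual
**adapter** modules trained on as few as five annotated micrographs (K-shot,
with K counted in micrographs, not particles), followed by a structured
mask-to-coordinates pipeline and STAR export for downstream refinement.

It is intended for methods developers and practitioners who want a fully
testable, CPU-scale implementation of this picking strategy: every stage —
synthetic data, adapters, training, localization, evaluation statistics —
runs end-to-end on generated micrographs with exact ground truth.

## The model

A hierarchical encoder processes the micrograph in four stages
(embedding widths D₁..D₄ = 144/288/576/1152 with 2/6/36/4 blocks at full
scale; a small built-in surrogate encoder with the same contract is used at
desk scale). The encoder stays **frozen**; before every transformer block
(i, j) the block input is modulated residually:

    feat(i,j)_adapter = W_shared · σ( W_unshared(i,j) · (P_emb feat(i,j) + P_fft hp_i) )
    feat(i,j)_final   = feat(i,j) + feat(i,j)_adapter
    feat(i,j+1)       = BLK(i,j)( feat(i,j)_final )

where σ is exact GELU, `hp_i` is a high-pass FFT-filtered copy of the
micrograph (Gaussian transfer, zero DC gain) pooled to stage *i*'s token
grid, `P_emb : D_i → d_i` and `P_fft : 1 → d_i` project into the bottleneck
d_i = ⌊D_i/32⌋, `W_unshared(i,j)` is block-specific and `W_shared : d_i → D_i`
is one up-projection per stage, **zero-initialized** so a fresh stack is an
exact identity. Only adapters and a small segmentation head train (balanced
BCE-with-logits, Adam, batch 2; full-scale protocol: 1024×1024 inputs,
lr 1e-4, up to 4000 epochs).

Predicted probability masks are converted to particles by: binarize →
Euclidean distance transform → multi-scale peak detection → marker-controlled
watershed → area/circularity filtering → a second pass on the residual
foreground for closely packed particles → deduplication.

Evaluation uses greedy one-to-one center matching (TP/FP/FN), precision,
recall, F1 and rasterized-disk IoU, with method comparison by paired
Wilcoxon signed-rank tests (rank-biserial effect size r = z/√N) and
Benjamini–Hochberg FDR adjustment per metric.

## Worked example

```python
import dataclasses
from cryofsl import (SyntheticSpec, generate_fewshot_dataset, generate_micrograph,
                     PostprocessConfig, masks_to_particles, match_particles,
                     precision_recall_f1)
from cryofsl.training import TrainConfig, build_desk_model, train_fewshot, predict_mask

spec = SyntheticSpec(image_shape=(128, 128), n_particles=12,
                     diameter_px=16.0, snr=4.0, min_separation=24.0, seed=100)
trained = train_fewshot(
    generate_fewshot_dataset(spec, K=5),
    build_desk_model(seed=0),
    TrainConfig(input_size=128, learning_rate=3e-3, max_epochs=80, seed=0))
print(f"loss {trained.loss_history[0]:.3f} -> {trained.loss_history[-1]:.3f}")

mic, _, gt = generate_micrograph(dataclasses.replace(spec, seed=500))
pred = masks_to_particles(predict_mask(trained, mic),
                          PostprocessConfig(expected_diameter_px=16.0))
p, r, f1 = precision_recall_f1(match_particles(pred, gt, 8.0))
print(f"picked {len(pred)} of {len(gt)}: precision {p:.2f} recall {r:.2f} F1 {f1:.2f}")
```

prints

```
loss 1.168 -> 0.111
picked 12 of 12: precision 1.00 recall 1.00 F1 1.00
```

i.e. the 5-shot model (5 annotated 128-px synthetic micrographs, 80 epochs,
a few CPU-seconds) recovers all 12 held-out particles with no false
positives. The same flow is available from the shell:

```bash
cryofsl synth --set synth.n_items=5 --out data/
cryofsl train --images data/ --masks data/ --config cfg.yaml --out model.npz
cryofsl pick  --model model.npz --images data/ --out picks/ --diameter 16
cryofsl evaluate --pred picks/ --gt data/ --diameter 16 --out metrics.tsv
cryofsl compare --metrics metrics.tsv --reference cryofsl --out stats.tsv
```

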