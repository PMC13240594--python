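"""Few-shot segmentation training: frozen encoder, trainable adapters + head.

The protocol follows standard few-shot particle segmentation practice:
micrographs are resized to a square model input (bilinear; masks nearest),
standardized per image, and the adapters plus a small segmentation head are
optimized with Adam against a class-balanced binary cross-entropy with
logits, while the hierarchical encoder stays frozen throughout. At the
paper-scale configuration this means input 1024x1024, batch 2, learning
rate 1e-4 and up to 4000 epochs; desk-scale runs shrink the input and epoch
count, not the procedure.

The segmentation head fuses every encoder stage at the stage-1 token grid
(per-stage linear projection + nearest upsampling), then maps each token to
its ``patch_stride^2`` output pixels. Its final layer starts at zero so an
untrained model predicts probability 0.5 everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize

from .adapters import (AdapterParams, AdapterStackConfig, AdaptedEncoder,
                       attach_adapters, build_adapter_stack)
from .autodiff import Adam, Tensor
from .datamodel import FewShotDataset, Micrograph, SegmentationMask
from .encoder import SurrogateHieraEncoder, build_surrogate_encoder

__all__ = [
    "TrainConfig",
    "SegmentationModel",
    "TrainedModel",
    "balanced_bce_with_logits",
    "compute_pos_weight",
    "train_fewshot",
    "predict_mask",
    "build_desk_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the full-scale protocol."""

    input_size: int = 1024
    batch_size: int = 2
    learning_rate: float = 1e-4
    max_epochs: int = 4000
    seed: int = 0
    pos_weight_mode: str = "auto"  # "auto" (per batch) or "fixed"
    pos_weight: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (self.learning_rate > 0):
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.pos_weight_mode not in ("auto", "fixed"):
            raise ValueError("pos_weight_mode must be 'auto' or 'fixed'")


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def compute_pos_weight(target: np.ndarray, clip: Tuple[float, float] = (1.0, 100.0)) -> float:
    """Background/foreground pixel ratio, clipped; 1 for degenerate targets."""
    t = np.asarray(target)
    n_fg = float((t > 0.5).sum())
    n_bg = float(t.size - n_fg)
    if n_fg == 0 or n_bg == 0:
        warnings.warn(
            "all-foreground or all-background target; pos_weight falls back to 1",
            stacklevel=2,
        )
        return 1.0
    return float(np.clip(n_bg / n_fg, *clip))


def balanced_bce_with_logits(
    logits: Union[Tensor, np.ndarray],
    target: np.ndarray,
    pos_weight: float = 1.0,
) -> Tensor:
    """Mean over pixels of -[pw*t*log(sigmoid(z)) + (1-t)*log(1-sigmoid(z))]."""
    target = np.asarray(target, dtype=np.float64)
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    if logits.data.shape != target.shape:
        raise ValueError(f"logits shape {logits.data.shape} != target {target.shape}")
    if not np.all(np.isin(target, (0.0, 1.0))):
        raise ValueError("target must be binary {0, 1}")
    return logits.bce_with_logits(target, pos_weight)


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

class SegmentationModel:
    """Adapted frozen encoder + trainable multi-stage segmentation head."""

    def __init__(self, encoder: SurrogateHieraEncoder, adapter_config: AdapterStackConfig,
                 head_channels: int = 32, seed: int = 0):
        self.encoder = encoder
        self.adapter_config = adapter_config
        self.adapters: AdapterParams = build_adapter_stack(adapter_config, seed=seed)
        self.adapted: AdaptedEncoder = attach_adapters(encoder, self.adapters)
        self.head_channels = int(head_channels)
        self.seed = int(seed)
        self._head: Dict[str, Tensor] = {}
        self._init_head()

    def _init_head(self) -> None:
        rng = np.random.default_rng(self.seed + 1)
        C = self.head_channels
        p2 = self.encoder.patch_stride ** 2
        for i, D in enumerate(self.encoder.stage_dims):
            self._head[f"proj{i}.W"] = Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(D), (D, C)), True, f"head.proj{i}.W")
            self._head[f"proj{i}.b"] = Tensor(np.zeros(C), True, f"head.proj{i}.b")
        self._head["mix.W"] = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(C), (C, C)), True, "head.mix.W")
        self._head["mix.b"] = Tensor(np.zeros(C), True, "head.mix.b")
        # zero-initialized output layer: untrained model predicts sigmoid(0)=0.5
        self._head["out.W"] = Tensor(np.zeros((C, p2)), True, "head.out.W")
        self._head["out.b"] = Tensor(np.zeros(p2), True, "head.out.b")

    def head_parameters(self) -> List[Tensor]:
        return [self._head[k] for k in sorted(self._head)]

    def trainable_parameters(self) -> List[Tensor]:
        return self.adapters.parameters() + self.head_parameters()

    def parameters(self) -> List[Tensor]:
        return self.encoder.parameters() + self.trainable_parameters()

    def forward_logits(self, image: np.ndarray) -> Tensor:
        """Full-resolution logits for one standardized square image."""
        stage_feats = self.adapted.forward(image)
        H = self._head
        fused: Optional[Tensor] = None
        for i, feat in enumerate(stage_feats):
            proj = feat.linear(H[f"proj{i}.W"], H[f"proj{i}.b"])
            if i > 0:
                proj = proj.upsample_nearest(2 ** i)
            fused = proj if fused is None else fused + proj
        hidden = fused.gelu().linear(H["mix.W"], H["mix.b"]).gelu()
        tokens = hidden.linear(H["out.W"], H["out.b"])
        return tokens.depth_to_space(self.encoder.patch_stride)


def build_desk_model(
    input_size: int = 128,
    stage_dims: Sequence[int] = (16, 32, 48, 64),
    stage_depths: Sequence[int] = (1, 1, 2, 1),
    patch_stride: int = 4,
    reduction: int = 4,
    head_channels: int = 32,
    seed: int = 0,
) -> SegmentationModel:
    """Desk-scale model: surrogate frozen encoder + adapters + head."""
    encoder = build_surrogate_encoder(stage_dims, stage_depths, patch_stride, seed=seed)
    config = AdapterStackConfig(
        stage_dims=tuple(stage_dims), stage_depths=tuple(stage_depths),
        reduction=reduction, clamp_bottleneck=True,
    )
    del input_size  # geometry is resolved per forward pass
    return SegmentationModel(encoder, config, head_channels=head_channels, seed=seed)


@dataclass
class TrainedModel:
    """A trained model plus its config and per-epoch loss history."""

    model: SegmentationModel
    config: TrainConfig
    loss_history: List[float] = field(default_factory=list)
    encoder_hash_before: Optional[str] = None
    encoder_hash_after: Optional[str] = None


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def _standardize(image: np.ndarray) -> np.ndarray:
    std = image.std()
    return (image - image.mean()) / (std if std > 1e-12 else 1.0)


def _prepare_pair(mic: Micrograph, mask: SegmentationMask, size: int
                  ) -> Tuple[np.ndarray, np.ndarray]:
    img = resize(_standardize(mic.pixels), (size, size), order=1,
                 anti_aliasing=False, preserve_range=True)
    tgt = resize(mask.values, (size, size), order=0,
                 anti_aliasing=False, preserve_range=True)
    return img.astype(np.float64), (tgt > 0.5).astype(np.float64)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def train_fewshot(dataset: FewShotDataset, model: SegmentationModel,
                  config: TrainConfig) -> TrainedModel:
    """Train adapters + head on K annotated micrographs; encoder frozen."""
    if len(dataset) < 1:
        raise ValueError("training dataset is empty")
    for _, mask, _ in dataset:
        if mask.kind != "binary":
            raise ValueError("training masks must be binary")
    pairs = [_prepare_pair(mic, mask, config.input_size) for mic, mask, _ in dataset]
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.trainable_parameters(), lr=config.learning_rate)
    hash_before = model.encoder.state_hash()
    history: List[float] = []
    n = len(pairs)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses: List[float] = []
        for start in range(0, n, config.batch_size):
            batch = [pairs[k] for k in order[start:start + config.batch_size]]
            if config.pos_weight_mode == "auto":
                stacked = np.concatenate([t.ravel() for _, t in batch])
                pw = compute_pos_weight(stacked)
            else:
                pw = config.pos_weight
            optimizer.zero_grad()
            loss: Optional[Tensor] = None
            for img, tgt in batch:
                item = balanced_bce_with_logits(model.forward_logits(img), tgt, pw)
                loss = item if loss is None else loss + item
            loss = loss * (1.0 / len(batch))
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    hash_after = model.encoder.state_hash()
    if hash_before != hash_after:
        raise RuntimeError("frozen encoder changed during training")
    return TrainedModel(model=model, config=config, loss_history=history,
                        encoder_hash_before=hash_before, encoder_hash_after=hash_after)


def predict_mask(trained: Union[TrainedModel, SegmentationModel],
                 micrograph: Micrograph,
                 input_size: Optional[int] = None) -> SegmentationMask:
    """Probability mask at the micrograph's native resolution."""
    if isinstance(trained, TrainedModel):
        model = trained.model
        size = input_size or trained.config.input_size
    else:
        model = trained
        if input_size is None:
            raise ValueError("input_size required when passing a bare model")
        size = input_size
    img = resize(_standardize(micrograph.pixels), (size, size), order=1,
                 anti_aliasing=False, preserve_range=True)
    logits = model.forward_logits(img).data
    prob = 1.0 / (1.0 + np.exp(-logits))
    native = resize(prob, micrograph.shape, order=1,
                    anti_aliasing=False, preserve_range=True)
    return SegmentationMask(values=np.clip(native, 0.0, 1.0), kind="probability")
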