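"""Hierarchical residual adapters over a frozen encoder.

Each transformer block's input feature map is modulated before the block
runs:

    feat_adapter = W_shared . GELU( W_unshared(i,j) . ( P_emb(feat) + P_fft(hp) ) )
    feat_final   = feat + feat_adapter

where ``hp`` is a high-pass FFT-filtered version of the input micrograph
resampled to the stage's token grid, ``P_emb`` projects the D_i-dimensional
block embedding down to the bottleneck width d_i = floor(D_i / reduction)
(minimum 1), ``P_fft`` lifts the scalar filtered intensity to d_i,
``W_unshared(i,j)`` is specific to block j of stage i, and ``W_shared`` is
one up-projection per stage. Shared up-projections start at zero so a
freshly built stack is an exact identity: the adapted forward pass equals
the frozen encoder's until training moves the shared layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Tensor
from .datamodel import Micrograph

__all__ = [
    "AdapterStackConfig",
    "AdapterParams",
    "highpass_fft_filter",
    "prepare_fft_stream",
    "adapter_forward",
    "build_adapter_stack",
    "attach_adapters",
    "AdaptedEncoder",
    "count_trainable_params",
]


@dataclass(frozen=True)
class AdapterStackConfig:
    """Stage geometry of the adapter stack.

    Defaults follow the Hiera-large stage layout: embedding widths
    144/288/576/1152 with 2/6/36/4 blocks per stage and a 1/32 bottleneck.
    ``clamp_bottleneck`` permits d_i = 1 when reduction exceeds a stage
    width; otherwise such configs are rejected.
    """

    stage_dims: Tuple[int, ...] = (144, 288, 576, 1152)
    stage_depths: Tuple[int, ...] = (2, 6, 36, 4)
    reduction: int = 32
    fft_cutoff_fraction: float = 0.25
    clamp_bottleneck: bool = False

    def __post_init__(self) -> None:
        if len(self.stage_dims) != len(self.stage_depths):
            raise ValueError("stage_dims and stage_depths must have equal length")
        if any(d <= 0 for d in self.stage_dims) or any(d <= 0 for d in self.stage_depths):
            raise ValueError("stage dims and depths must be positive")
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")
        if not (0.0 < self.fft_cutoff_fraction < 1.0):
            raise ValueError("fft_cutoff_fraction must lie in (0, 1)")
        if not self.clamp_bottleneck and any(d < self.reduction for d in self.stage_dims):
            raise ValueError(
                f"reduction {self.reduction} exceeds a stage width in "
                f"{self.stage_dims}; the bottleneck would vanish "
                "(set clamp_bottleneck=True to clamp d_i to 1)"
            )

    @property
    def n_stages(self) -> int:
        return len(self.stage_dims)

    @property
    def bottleneck_dims(self) -> Tuple[int, ...]:
        return tuple(max(1, d // self.reduction) for d in self.stage_dims)


class AdapterParams:
    """Trainable adapter parameters for every (stage, block) of the encoder."""

    def __init__(self, config: AdapterStackConfig, seed: int = 0,
                 init_scale: float = 0.02):
        self.config = config
        rng = np.random.default_rng(seed)
        self.fft_proj: List[Tuple[Tensor, Tensor]] = []
        self.emb_proj: List[Tuple[Tensor, Tensor]] = []
        self.shared_up: List[Tuple[Tensor, Tensor]] = []
        self.unshared: Dict[Tuple[int, int], Tuple[Tensor, Tensor]] = {}
        for i, (D, depth, d) in enumerate(
            zip(config.stage_dims, config.stage_depths, config.bottleneck_dims)
        ):
            self.fft_proj.append((
                Tensor(rng.normal(0.0, init_scale, (1, d)), True, f"a{i}.fft.W"),
                Tensor(np.zeros(d), True, f"a{i}.fft.b"),
            ))
            self.emb_proj.append((
                Tensor(rng.normal(0.0, init_scale, (D, d)), True, f"a{i}.emb.W"),
                Tensor(np.zeros(d), True, f"a{i}.emb.b"),
            ))
            # zero-initialized: a fresh stack is an exact residual identity
            self.shared_up.append((
                Tensor(np.zeros((d, D)), True, f"a{i}.shared.W"),
                Tensor(np.zeros(D), True, f"a{i}.shared.b"),
            ))
            for j in range(depth):
                self.unshared[(i, j)] = (
                    Tensor(rng.normal(0.0, init_scale, (d, d)), True, f"a{i}.u{j}.W"),
                    Tensor(np.zeros(d), True, f"a{i}.u{j}.b"),
                )

    @property
    def n_unshared(self) -> int:
        return len(self.unshared)

    @property
    def n_shared(self) -> int:
        return len(self.shared_up)

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for pairs in (self.fft_proj, self.emb_proj, self.shared_up):
            for W, b in pairs:
                out.extend((W, b))
        for key in sorted(self.unshared):
            out.extend(self.unshared[key])
        return out


def build_adapter_stack(config: AdapterStackConfig, seed: int = 0) -> AdapterParams:
    """Allocate one unshared layer per (stage, block) plus per-stage
    fft/embedding down-projections and a zero-initialized shared up-projection."""
    return AdapterParams(config, seed=seed)


# --------------------------------------------------------------------------
# FFT stream
# --------------------------------------------------------------------------

def highpass_fft_filter(image: np.ndarray, cutoff_fraction: float) -> np.ndarray:
    """Gaussian high-pass filter with exactly zero DC gain.

    The transfer function is ``1 - exp(-f^2 / (2 fc^2))`` on radial spatial
    frequency ``f`` (cycles/pixel), with ``fc = cutoff_fraction * Nyquist``
    and Nyquist = 0.5 cycles/pixel. The smooth Gaussian transition avoids
    the ringing a brick-wall cutoff would introduce.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("highpass_fft_filter requires finite input")
    if not (0.0 < cutoff_fraction < 1.0):
        raise ValueError("cutoff_fraction must lie in (0, 1)")
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    f2 = fy * fy + fx * fx
    fc = cutoff_fraction * 0.5
    transfer = 1.0 - np.exp(-f2 / (2.0 * fc * fc))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * transfer))


def prepare_fft_stream(
    micrograph: Union[Micrograph, np.ndarray],
    config: AdapterStackConfig,
    stage_shapes: Sequence[Tuple[int, int]],
) -> List[np.ndarray]:
    """High-pass filter once at full resolution, then average-pool to each
    stage's token grid and standardize to zero mean / unit variance."""
    pixels = micrograph.pixels if isinstance(micrograph, Micrograph) else np.asarray(micrograph)
    filtered = highpass_fft_filter(pixels, config.fft_cutoff_fraction)
    h, w = filtered.shape
    streams: List[np.ndarray] = []
    for (hi, wi) in stage_shapes:
        if hi <= 0 or wi <= 0 or h % hi or w % wi:
            raise ValueError(
                f"stage shape {(hi, wi)} does not evenly divide image {h}x{w}"
            )
        by, bx = h // hi, w // wi
        pooled = filtered.reshape(hi, by, wi, bx).mean(axis=(1, 3))
        std = pooled.std()
        if std < 1e-12:
            streams.append(np.zeros_like(pooled))
        else:
            streams.append((pooled - pooled.mean()) / std)
    return streams


# --------------------------------------------------------------------------
# forward
# --------------------------------------------------------------------------

def adapter_forward(
    feat: Union[Tensor, np.ndarray],
    fft_stage_stream: np.ndarray,
    params: AdapterParams,
    stage: int,
    block: int,
) -> Tensor:
    """Residual adapter modulation of one block input."""
    cfg = params.config
    if not (0 <= stage < cfg.n_stages):
        raise IndexError(f"stage {stage} out of range for {cfg.n_stages} stages")
    if not (0 <= block < cfg.stage_depths[stage]):
        raise IndexError(
            f"block {block} out of range for stage {stage} "
            f"(depth {cfg.stage_depths[stage]})"
        )
    if not isinstance(feat, Tensor):
        feat = Tensor(feat)
    if feat.data.ndim != 3 or feat.data.shape[-1] != cfg.stage_dims[stage]:
        raise ValueError(
            f"stage {stage} expects features (H, W, {cfg.stage_dims[stage]}), "
            f"got {feat.data.shape}"
        )
    hi, wi = feat.data.shape[:2]
    stream = np.asarray(fft_stage_stream, dtype=np.float64)
    if stream.shape != (hi, wi):
        raise ValueError(
            f"fft stream shape {stream.shape} != feature grid {(hi, wi)} "
            f"at stage {stage}"
        )
    eW, eb = params.emb_proj[stage]
    fW, fb = params.fft_proj[stage]
    uW, ub = params.unshared[(stage, block)]
    sW, sb = params.shared_up[stage]
    reduced = feat.linear(eW, eb) + Tensor(stream.reshape(hi, wi, 1)).linear(fW, fb)
    modulated = reduced.linear(uW, ub).gelu().linear(sW, sb)
    return feat + modulated


class AdaptedEncoder:
    """A frozen encoder with adapters attached before every block."""

    def __init__(self, encoder, params: AdapterParams):
        cfg = params.config
        if tuple(encoder.stage_dims) != tuple(cfg.stage_dims):
            for s, (ed, cd) in enumerate(zip(encoder.stage_dims, cfg.stage_dims)):
                if ed != cd:
                    raise ValueError(
                        f"stage {s}: encoder width {ed} != adapter config width {cd}"
                    )
            raise ValueError("encoder/adapter stage counts differ")
        if tuple(encoder.stage_depths) != tuple(cfg.stage_depths):
            raise ValueError(
                f"encoder depths {tuple(encoder.stage_depths)} != adapter "
                f"config depths {tuple(cfg.stage_depths)}"
            )
        self.encoder = encoder
        self.params = params

    def forward(self, image: np.ndarray) -> List[Tensor]:
        image = np.asarray(image, dtype=np.float64)
        stage_shapes = self.encoder.stage_shapes(image.shape)
        streams = prepare_fft_stream(image, self.params.config, stage_shapes)

        def hook(feat: Tensor, i: int, j: int) -> Tensor:
            return adapter_forward(feat, streams[i], self.params, i, j)

        return self.encoder.forward(image, block_hook=hook)

    def detach(self):
        """Return the untouched frozen encoder."""
        return self.encoder


def attach_adapters(encoder, params: AdapterParams) -> AdaptedEncoder:
    """Wrap a frozen hierarchical encoder so every block input passes through
    its adapter first; encoder weights are never modified."""
    return AdaptedEncoder(encoder, params)


def count_trainable_params(model) -> int:
    """Number of scalar parameters marked trainable in ``model``.

    Accepts anything exposing ``parameters()`` (or an iterable of such
    objects / Tensors); frozen parameters are excluded.
    """
    def tensors_of(obj):
        if isinstance(obj, Tensor):
            return [obj]
        if hasattr(obj, "parameters"):
            return list(obj.parameters())
        return [t for sub in obj for t in tensors_of(sub)]

    return int(sum(t.size for t in tensors_of(model) if t.requires_grad))
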