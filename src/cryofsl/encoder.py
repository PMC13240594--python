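"""Pluggable frozen hierarchical encoders.

The encoder contract mirrors a Hiera-style vision backbone: four sequential
stages, each a run of blocks over a token grid, with 2x spatial reduction
and a widening embedding between stages. Adapters hook in as an additive
modification of every block's input. The built-in ``surrogate`` encoder is a
small deterministic random-feature tower honouring this contract at desk
scale; external backbones (e.g. a SAM2 Hiera-large checkpoint) can be
registered through :func:`register_encoder` by user plugins.
"""

from __future__ import annotations

import hashlib
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor

__all__ = [
    "SurrogateHieraEncoder",
    "build_surrogate_encoder",
    "register_encoder",
    "get_encoder_builder",
    "ENCODER_REGISTRY",
]

# hook(feat, stage_index, block_index) -> modified feat
BlockHook = Callable[[Tensor, int, int], Tensor]


class SurrogateHieraEncoder:
    """Frozen four-stage token-grid encoder at desk scale.

    The input image is split into non-overlapping ``patch_stride`` x
    ``patch_stride`` patches that are linearly embedded into the stage-1
    width. Each block applies a frozen residual two-layer MLP per token;
    stage transitions 2x2-average-pool the token grid and project to the
    next stage width. All parameters are drawn once from ``seed`` and are
    frozen by default, so the encoder acts as a fixed multi-scale
    random-feature extractor — the role the pretrained backbone plays at
    full scale.
    """

    def __init__(self, stage_dims: Sequence[int], stage_depths: Sequence[int],
                 patch_stride: int = 4, seed: int = 0, frozen: bool = True):
        if len(stage_dims) != len(stage_depths):
            raise ValueError("stage_dims and stage_depths must have equal length")
        if any(d <= 0 for d in stage_dims) or any(d <= 0 for d in stage_depths):
            raise ValueError("stage dims and depths must be positive")
        if patch_stride < 1:
            raise ValueError("patch_stride must be >= 1")
        self.stage_dims = [int(d) for d in stage_dims]
        self.stage_depths = [int(d) for d in stage_depths]
        self.patch_stride = int(patch_stride)
        self.seed = int(seed)
        self._params: Dict[str, Tensor] = {}
        self._init_params(frozen)

    # -- parameters --------------------------------------------------------

    def _mk(self, name: str, array: np.ndarray, frozen: bool) -> Tensor:
        t = Tensor(array, requires_grad=not frozen, name=name)
        self._params[name] = t
        return t

    def _init_params(self, frozen: bool) -> None:
        rng = np.random.default_rng(self.seed)
        p2 = self.patch_stride ** 2
        d0 = self.stage_dims[0]
        self._mk("embed.W", rng.normal(0.0, 1.0 / np.sqrt(p2), (p2, d0)), frozen)
        self._mk("embed.b", np.zeros(d0), frozen)
        for i, (dim, depth) in enumerate(zip(self.stage_dims, self.stage_depths)):
            scale = 0.5 / np.sqrt(dim)
            for j in range(depth):
                self._mk(f"s{i}.b{j}.W1", rng.normal(0.0, scale, (dim, dim)), frozen)
                self._mk(f"s{i}.b{j}.b1", np.zeros(dim), frozen)
                self._mk(f"s{i}.b{j}.W2", rng.normal(0.0, scale, (dim, dim)), frozen)
                self._mk(f"s{i}.b{j}.b2", np.zeros(dim), frozen)
            if i + 1 < len(self.stage_dims):
                nxt = self.stage_dims[i + 1]
                self._mk(f"trans{i}.W",
                         rng.normal(0.0, 1.0 / np.sqrt(dim), (dim, nxt)), frozen)
                self._mk(f"trans{i}.b", np.zeros(nxt), frozen)

    def parameters(self) -> List[Tensor]:
        return list(self._params.values())

    @property
    def frozen(self) -> bool:
        return not any(p.requires_grad for p in self._params.values())

    def state_hash(self) -> str:
        """SHA-256 over all parameter bytes (bit-identity check for freezing)."""
        h = hashlib.sha256()
        for name in sorted(self._params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self._params[name].data).tobytes())
        return h.hexdigest()

    # -- geometry ----------------------------------------------------------

    def stage_shapes(self, input_hw: Tuple[int, int]) -> List[Tuple[int, int]]:
        """Token-grid shape (H_i, W_i) of every stage for a given input size."""
        h, w = input_hw
        p = self.patch_stride
        if h % p or w % p:
            raise ValueError(f"input {h}x{w} not divisible by patch_stride {p}")
        ht, wt = h // p, w // p
        shapes = []
        for i in range(len(self.stage_dims)):
            shapes.append((ht, wt))
            if i + 1 < len(self.stage_dims):
                if ht % 2 or wt % 2:
                    raise ValueError(
                        f"stage {i} grid {ht}x{wt} not divisible by 2; "
                        "choose an input size with enough factors of 2"
                    )
                ht, wt = ht // 2, wt // 2
        return shapes

    def _patchify(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape
        p = self.patch_stride
        return (
            image.reshape(h // p, p, w // p, p)
            .transpose(0, 2, 1, 3)
            .reshape(h // p, w // p, p * p)
        )

    # -- forward -----------------------------------------------------------

    def forward(self, image: np.ndarray,
                block_hook: Optional[BlockHook] = None) -> List[Tensor]:
        """Run the tower; returns the final feature map of every stage.

        ``block_hook`` receives each block's input before the block runs and
        may return a modified feature map (this is where adapters attach).
        """
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("encoder input must be a 2D image")
        self.stage_shapes(image.shape)  # validates divisibility
        P = self._params
        feat = Tensor(self._patchify(image)).linear(P["embed.W"], P["embed.b"])
        outputs: List[Tensor] = []
        for i, depth in enumerate(self.stage_depths):
            for j in range(depth):
                if block_hook is not None:
                    feat = block_hook(feat, i, j)
                hidden = feat.linear(P[f"s{i}.b{j}.W1"], P[f"s{i}.b{j}.b1"]).gelu()
                feat = feat + hidden.linear(P[f"s{i}.b{j}.W2"], P[f"s{i}.b{j}.b2"])
            outputs.append(feat)
            if i + 1 < len(self.stage_dims):
                feat = feat.avg_pool2().linear(P[f"trans{i}.W"], P[f"trans{i}.b"])
        return outputs


def build_surrogate_encoder(stage_dims: Sequence[int] = (16, 32, 48, 64),
                            stage_depths: Sequence[int] = (1, 1, 2, 1),
                            patch_stride: int = 4, seed: int = 0,
                            frozen: bool = True) -> SurrogateHieraEncoder:
    """Construct the built-in desk-scale frozen hierarchical encoder."""
    return SurrogateHieraEncoder(stage_dims, stage_depths, patch_stride,
                                 seed=seed, frozen=frozen)


ENCODER_REGISTRY: Dict[str, Callable[..., object]] = {}


def register_encoder(name: str):
    """Decorator registering an encoder builder under ``name``."""

    def deco(builder):
        ENCODER_REGISTRY[name] = builder
        return builder

    return deco


register_encoder("surrogate")(build_surrogate_encoder)


@register_encoder("sam2-hiera-large")
def _sam2_placeholder(*args, **kwargs):
    raise NotImplementedError(
        "the sam2-hiera-large backbone requires an external checkpoint and a "
        "user-supplied plugin; register a builder with "
        "cryofsl.encoder.register_encoder('sam2-hiera-large')"
    )


def get_encoder_builder(name: str):
    try:
        return ENCODER_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown encoder {name!r}; available: {sorted(ENCODER_REGISTRY)}"
        ) from None
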