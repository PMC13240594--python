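"""Core domain types for micrographs, masks and particle coordinate sets.

Coordinate convention used throughout the package: coordinates are 0-based
pixel centers with ``x`` the column index and ``y`` the row index, origin at
the top-left of the image. STAR files are written in this same frame (the
convention is recorded in a comment line of every file written).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Micrograph",
    "SegmentationMask",
    "Particle",
    "ParticleSet",
    "FewShotDataset",
]


@dataclass
class Micrograph:
    """A single 2D micrograph with optional physical pixel size.

    Parameters
    ----------
    pixels
        2D float array of raw intensities (arbitrary units). Must be finite;
        readers replace non-finite values before constructing a Micrograph.
    pixel_size
        Optional pixel size in Angstrom per pixel.
    source_path
        Path the image was loaded from, when applicable.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph pixels must be 2D, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError(f"micrograph must be at least 16x16, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph pixels must be finite; readers sanitize inputs")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.height, self.width)


@dataclass
class SegmentationMask:
    """A probability or binary map aligned to a micrograph.

    ``kind="probability"`` requires values in [0, 1]; ``kind="binary"``
    requires values in {0, 1}.
    """

    values: np.ndarray
    kind: Literal["probability", "binary"] = "probability"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("mask values must be 2D")
        if self.kind == "probability":
            if self.values.size and (self.values.min() < 0.0 or self.values.max() > 1.0):
                raise ValueError("probability mask values must lie in [0, 1]")
        elif self.kind == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError("binary mask values must lie in {0, 1}")
        else:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (int(self.values.shape[0]), int(self.values.shape[1]))

    def as_bool(self) -> np.ndarray:
        if self.kind != "binary":
            raise ValueError("as_bool requires a binary mask; use binarize() first")
        return self.values > 0.5


@dataclass(frozen=True)
class Particle:
    """One particle: center (x, y) in pixels, diameter in pixels, optional score."""

    x: float
    y: float
    diameter: float = 1.0
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError(f"particle diameter must be > 0, got {self.diameter}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"particle score must lie in [0, 1], got {self.score}")


@dataclass
class ParticleSet:
    """An ordered list of particles against a reference image shape."""

    particles: List[Particle]
    reference_shape: Tuple[int, int]
    provenance: Literal["ground_truth", "predicted"] = "predicted"

    def __post_init__(self) -> None:
        h, w = self.reference_shape
        for p in self.particles:
            if not (0.0 <= p.x < w and 0.0 <= p.y < h):
                raise ValueError(
                    f"particle ({p.x}, {p.y}) outside reference shape {self.reference_shape}"
                )

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def coordinates(self) -> np.ndarray:
        """(N, 2) array of (x, y) centers."""
        if not self.particles:
            return np.zeros((0, 2), dtype=np.float64)
        return np.array([(p.x, p.y) for p in self.particles], dtype=np.float64)

    def diameters(self) -> np.ndarray:
        return np.array([p.diameter for p in self.particles], dtype=np.float64)


@dataclass
class FewShotDataset:
    """K annotated (micrograph, binary mask, ground-truth particles) triples."""

    items: List[Tuple[Micrograph, SegmentationMask, ParticleSet]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("a few-shot dataset needs at least one annotated micrograph")
        for mic, mask, pts in self.items:
            if mask.kind != "binary":
                raise ValueError("few-shot masks must be binary")
            if mask.shape != mic.shape:
                raise ValueError(f"mask shape {mask.shape} != micrograph shape {mic.shape}")
            if pts.reference_shape != mic.shape:
                raise ValueError("particle reference shape must match its micrograph")

    @property
    def K(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)
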