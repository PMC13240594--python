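"""Synthetic low-SNR micrographs with exact ground truth.

Particles are rendered as soft-edged disks (1-pixel cosine taper) of
amplitude ``a`` on a zero-mean background, with additive Gaussian noise of
variance ``a^2 / snr``. The binary ground-truth mask is the exact union of
the hard rasterized disks (pixel center within the particle radius), and the
ParticleSet holds the exact subpixel centers and diameters used for
rendering. Identical specs produce bit-identical outputs.

This emulates the dominant difficulty of cryo-EM particle picking — faint
quasi-circular blobs at low signal-to-noise — without physics-based image
formation (no CTF, no projections, no ice/carbon artifacts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .datamodel import FewShotDataset, Micrograph, Particle, ParticleSet, SegmentationMask

__all__ = [
    "SyntheticSpec",
    "CapacityError",
    "generate_micrograph",
    "generate_overlapping_pair",
    "generate_fewshot_dataset",
]


class CapacityError(RuntimeError):
    """Raised when the requested particle count cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} particles under the "
            "separation constraint; reduce n_particles or min_separation"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic micrograph.

    snr is defined operationally as (contrast amplitude)^2 / noise variance.
    min_separation is the minimum center-to-center distance enforced during
    placement; set it below diameter_px with allow_overlap=True to force
    overlapping particles.
    """

    image_shape: Tuple[int, int] = (512, 512)
    n_particles: int = 50
    diameter_px: float = 16.0
    diameter_jitter: float = 0.0
    snr: float = 4.0
    min_separation: float = 24.0
    allow_overlap: bool = False
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.diameter_px < 3:
            raise ValueError("diameter_px must be >= 3")
        if not (self.snr > 0):
            raise ValueError("snr must be > 0")
        if not (0.0 <= self.diameter_jitter < 1.0):
            raise ValueError("diameter_jitter must lie in [0, 1)")


def _render_particle(image: np.ndarray, mask: np.ndarray, cx: float, cy: float,
                     radius: float, amplitude: float) -> None:
    """Render one soft-edged disk in place; hard disk into the mask."""
    h, w = image.shape
    r_out = radius + 1.0
    x0, x1 = max(0, int(np.floor(cx - r_out))), min(w, int(np.ceil(cx + r_out)) + 1)
    y0, y1 = max(0, int(np.floor(cy - r_out))), min(h, int(np.ceil(cy + r_out)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx, yy - cy)
    # cosine taper over the last pixel of the radius: 1 inside r-1, 0 outside r
    profile = np.clip(0.5 * (1.0 + np.cos(np.pi * (r - (radius - 1.0)))), 0.0, 1.0)
    profile[r <= radius - 1.0] = 1.0
    profile[r > radius] = 0.0
    patch = image[y0:y1, x0:x1]
    np.maximum(patch, amplitude * profile, out=patch)
    mask[y0:y1, x0:x1] |= r <= radius


def _place_centers(rng: np.random.Generator, spec: SyntheticSpec,
                   radii: np.ndarray) -> np.ndarray:
    """Rejection-sample particle centers; bounded retries."""
    h, w = spec.image_shape
    centers: List[Tuple[float, float]] = []
    max_attempts = 300 * max(spec.n_particles, 1)
    attempts = 0
    min_sep = spec.min_separation
    if not spec.allow_overlap:
        min_sep = max(min_sep, float(2.0 * radii.max(initial=0.0)))
    for k in range(spec.n_particles):
        margin = radii[k] + 1.0
        placed = False
        while attempts < max_attempts:
            attempts += 1
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            if all(np.hypot(cx - px, cy - py) >= min_sep for px, py in centers):
                centers.append((cx, cy))
                placed = True
                break
        if not placed:
            raise CapacityError(spec.n_particles, len(centers))
    return np.array(centers, dtype=np.float64).reshape(-1, 2)


def generate_micrograph(spec: SyntheticSpec) -> Tuple[Micrograph, SegmentationMask, ParticleSet]:
    """Render one synthetic micrograph with exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    diam = spec.diameter_px * (
        1.0 + spec.diameter_jitter * rng.uniform(-1.0, 1.0, size=spec.n_particles)
    )
    radii = diam / 2.0
    centers = _place_centers(rng, spec, radii)
    image = np.zeros((h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)
    for (cx, cy), radius in zip(centers, radii):
        _render_particle(image, mask, cx, cy, radius, spec.amplitude)
    noise_sigma = spec.amplitude / np.sqrt(spec.snr)
    image = image + rng.normal(0.0, noise_sigma, size=(h, w))
    particles = [
        Particle(x=float(cx), y=float(cy), diameter=float(d))
        for (cx, cy), d in zip(centers, diam)
    ]
    return (
        Micrograph(pixels=image),
        SegmentationMask(values=mask.astype(np.float64), kind="binary"),
        ParticleSet(particles=particles, reference_shape=(h, w), provenance="ground_truth"),
    )


def generate_overlapping_pair(
    diameter_px: float, center_gap: float, seed: int = 0, snr: float = 4.0
) -> Tuple[Micrograph, SegmentationMask, ParticleSet]:
    """Two overlapping disks whose masks merge into one connected component.

    The pair is placed at a random orientation about the image center;
    requires 0 < center_gap < diameter_px so the disks genuinely overlap.
    """
    if not (0.0 < center_gap < diameter_px):
        raise ValueError(
            f"center_gap must lie in (0, diameter_px); got gap={center_gap}, "
            f"diameter={diameter_px}"
        )
    rng = np.random.default_rng(seed)
    radius = diameter_px / 2.0
    side = int(np.ceil(diameter_px + center_gap)) + 16
    side = max(side, 32)
    cx0 = cy0 = (side - 1) / 2.0
    theta = rng.uniform(0.0, np.pi)
    dx, dy = 0.5 * center_gap * np.cos(theta), 0.5 * center_gap * np.sin(theta)
    centers = [(cx0 - dx, cy0 - dy), (cx0 + dx, cy0 + dy)]
    image = np.zeros((side, side), dtype=np.float64)
    mask = np.zeros((side, side), dtype=bool)
    for cx, cy in centers:
        _render_particle(image, mask, cx, cy, radius, 1.0)
    image = image + rng.normal(0.0, 1.0 / np.sqrt(snr), size=image.shape)
    particles = [Particle(x=cx, y=cy, diameter=diameter_px) for cx, cy in centers]
    return (
        Micrograph(pixels=image),
        SegmentationMask(values=mask.astype(np.float64), kind="binary"),
        ParticleSet(particles=particles, reference_shape=(side, side),
                    provenance="ground_truth"),
    )


def generate_fewshot_dataset(spec: SyntheticSpec, K: int) -> FewShotDataset:
    """K independent synthetic micrographs, drawn with seeds seed+0 .. seed+K-1."""
    if K < 1:
        raise ValueError("K must be >= 1")
    items = []
    for k in range(K):
        items.append(generate_micrograph(dataclasses.replace(spec, seed=spec.seed + k)))
    return FewShotDataset(items=items)
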