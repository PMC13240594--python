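"""Mask-to-coordinates localization.

Pipeline: binarize -> Euclidean distance transform -> multi-scale peak
detection -> marker-controlled watershed -> geometric (area + circularity)
filtering -> optional second pass on the residual foreground to recover
closely packed particles -> deduplication. All thresholds live in
:class:`PostprocessConfig` and default to values calibrated for roughly
circular particles of a known expected diameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max  # noqa: F401  (kept for users; NMS below is in-package)
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .datamodel import Micrograph, Particle, ParticleSet, SegmentationMask

logger = logging.getLogger("cryofsl")

__all__ = [
    "PostprocessConfig",
    "RegionStats",
    "LabeledRegions",
    "binarize",
    "distance_map",
    "detect_peaks_multiscale",
    "watershed_split",
    "geometric_filter",
    "dual_pass_localize",
    "masks_to_particles",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """Localization thresholds, mostly expressed relative to the expected
    particle diameter (pixels)."""

    expected_diameter_px: float
    threshold: float = 0.5
    area_range: Tuple[float, float] = (0.3, 3.0)   # fractions of pi*(d/2)^2
    min_circularity: float = 0.6
    peak_scales: Tuple[float, ...] = (1.0, 2.0, 4.0)
    # 0.25 (not 0.5): on the discrete distance map the two maxima of an
    # overlapping pair at center gap 0.5*d can sit as little as ~0.27*d
    # apart (orientation-dependent plateau rounding), so a half-diameter
    # floor suppresses the second seed; duplicate control is owned by the
    # geometric filter and the final dedup at min_separation_frac*d
    min_peak_distance_frac: float = 0.25
    min_separation_frac: float = 0.6
    dual_pass: bool = True
    drop_border: bool = False

    def __post_init__(self) -> None:
        if not (self.expected_diameter_px > 0):
            raise ValueError("expected_diameter_px must be > 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (self.area_range[0] < self.area_range[1]):
            raise ValueError("area_range must satisfy min < max")
        if any(s <= 0 for s in self.peak_scales):
            raise ValueError("all peak scales must be > 0")

    @property
    def expected_area(self) -> float:
        return float(np.pi * (self.expected_diameter_px / 2.0) ** 2)


@dataclass(frozen=True)
class RegionStats:
    label: int
    area: float
    perimeter: float
    centroid_xy: Tuple[float, float]
    equivalent_diameter: float
    circularity: float


@dataclass
class LabeledRegions:
    """Integer label map (0 = background) with per-region geometry."""

    label_map: np.ndarray
    regions: List[RegionStats]
    seed_xy: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)


# --------------------------------------------------------------------------
# elementary steps
# --------------------------------------------------------------------------

def binarize(mask: SegmentationMask, threshold: float = 0.5) -> SegmentationMask:
    """Foreground where probability is strictly greater than the threshold."""
    return SegmentationMask(values=(mask.values > threshold).astype(np.float64),
                            kind="binary")


def distance_map(binary: SegmentationMask) -> np.ndarray:
    """Euclidean distance from each foreground pixel to the nearest background."""
    if binary.kind != "binary":
        raise ValueError("distance_map requires a binary mask")
    return ndi.distance_transform_edt(binary.values > 0.5)


def _local_maxima(arr: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """(row, col) of strict-or-plateau local maxima restricted to foreground."""
    maxed = ndi.maximum_filter(arr, size=3, mode="constant", cval=-np.inf)
    cand = (arr >= maxed) & foreground
    return np.argwhere(cand)


def detect_peaks_multiscale(dist: np.ndarray,
                            config: PostprocessConfig) -> List[Tuple[int, int]]:
    """Union over smoothing scales of distance-map maxima, finest scale first.

    A candidate is kept when its raw distance value is at least
    ``0.25 * expected_radius`` (configurable via the second pass, which halves
    this floor) and it lies at least ``min_peak_distance_frac * diameter``
    from every already-accepted peak; peaks found at finer scales therefore
    take precedence over coarser ones.
    """
    return _detect_peaks(dist, config, config.peak_scales,
                         floor=0.25 * config.expected_diameter_px / 2.0)


def _detect_peaks(dist: np.ndarray, config: PostprocessConfig,
                  scales: Sequence[float], floor: float) -> List[Tuple[int, int]]:
    foreground = dist > 0
    if not foreground.any():
        return []
    min_dist = config.min_peak_distance_frac * config.expected_diameter_px
    accepted: List[Tuple[int, int]] = []
    for sigma in sorted(scales):
        smoothed = ndi.gaussian_filter(dist, sigma)
        coords = _local_maxima(smoothed, foreground)
        if coords.size == 0:
            continue
        values = smoothed[coords[:, 0], coords[:, 1]]
        # deterministic order: strongest first, then lexicographic (y, x)
        order = np.lexsort((coords[:, 1], coords[:, 0], -values))
        for idx in order:
            y, x = int(coords[idx, 0]), int(coords[idx, 1])
            if dist[y, x] < floor:
                continue
            if all(np.hypot(x - ax, y - ay) >= min_dist for ax, ay in accepted):
                accepted.append((x, y))
    return accepted


def _region_stats(label_map: np.ndarray) -> List[RegionStats]:
    stats: List[RegionStats] = []
    for rp in regionprops(label_map):
        area = float(rp.area)
        perimeter = float(rp.perimeter)
        if perimeter > 0:
            circ = min(4.0 * np.pi * area / (perimeter * perimeter), 1.0)
        else:
            circ = 1.0
        cy, cx = rp.centroid
        stats.append(RegionStats(
            label=int(rp.label), area=area, perimeter=perimeter,
            centroid_xy=(float(cx), float(cy)),
            equivalent_diameter=float(rp.equivalent_diameter_area),
            circularity=circ,
        ))
    return stats


def watershed_split(binary: SegmentationMask, seeds: Sequence[Tuple[int, int]],
                    dist: Optional[np.ndarray] = None) -> LabeledRegions:
    """Marker-controlled watershed on the negated distance map."""
    fg = binary.as_bool()
    if dist is None:
        dist = distance_map(binary)
    markers = np.zeros(fg.shape, dtype=np.int32)
    seed_xy: Dict[int, Tuple[int, int]] = {}
    label = 0
    for (x, y) in seeds:
        if not fg[y, x]:
            warnings.warn(f"seed ({x}, {y}) lies on background; dropped", stacklevel=2)
            continue
        label += 1
        markers[y, x] = label
        seed_xy[label] = (x, y)
    if label == 0:
        return LabeledRegions(label_map=np.zeros(fg.shape, dtype=np.int32), regions=[])
    label_map = watershed(-dist, markers, mask=fg).astype(np.int32)
    return LabeledRegions(label_map=label_map, regions=_region_stats(label_map),
                          seed_xy=seed_xy)


def geometric_filter(regions: LabeledRegions,
                     config: PostprocessConfig) -> LabeledRegions:
    """Keep regions plausible for a round particle of the expected diameter."""
    a0 = config.expected_area
    lo, hi = config.area_range[0] * a0, config.area_range[1] * a0
    h, w = regions.label_map.shape
    keep: List[RegionStats] = []
    for r in regions.regions:
        if not (lo <= r.area <= hi):
            continue
        if r.circularity < config.min_circularity:
            continue
        if config.drop_border:
            ys, xs = np.nonzero(regions.label_map == r.label)
            if ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1:
                continue
        keep.append(r)
    new_map = np.zeros_like(regions.label_map)
    new_regions: List[RegionStats] = []
    new_seed_xy: Dict[int, Tuple[int, int]] = {}
    for new_label, r in enumerate(keep, start=1):
        new_map[regions.label_map == r.label] = new_label
        new_regions.append(replace(r, label=new_label))
        if r.label in regions.seed_xy:
            new_seed_xy[new_label] = regions.seed_xy[r.label]
    return LabeledRegions(label_map=new_map, regions=new_regions, seed_xy=new_seed_xy)


# --------------------------------------------------------------------------
# dual-pass localization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _Candidate:
    x: float
    y: float
    diameter: float
    label: int
    pass_index: int
    dist_value: float


def _run_pass(binary: SegmentationMask, dist: np.ndarray,
              config: PostprocessConfig, scales: Sequence[float],
              floor: float, pass_index: int) -> Tuple[List[_Candidate], LabeledRegions]:
    seeds = _detect_peaks(dist, config, scales, floor)
    regions = geometric_filter(watershed_split(binary, seeds, dist), config)
    out = []
    for r in regions.regions:
        sx, sy = regions.seed_xy.get(r.label, (int(round(r.centroid_xy[0])),
                                               int(round(r.centroid_xy[1]))))
        out.append(_Candidate(
            x=r.centroid_xy[0], y=r.centroid_xy[1],
            diameter=r.equivalent_diameter, label=r.label,
            pass_index=pass_index, dist_value=float(dist[sy, sx]),
        ))
    return out, regions


def _dual_pass(binary: SegmentationMask, dist: np.ndarray,
               config: PostprocessConfig
               ) -> List[Tuple[_Candidate, np.ndarray, np.ndarray]]:
    """Accepted candidates with their region pixel indices (ys, xs)."""
    floor1 = 0.25 * config.expected_diameter_px / 2.0
    pass1, regions1 = _run_pass(binary, dist, config, config.peak_scales,
                                floor1, pass_index=0)
    candidates = list(pass1)
    region_pixels: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}
    for cand in pass1:
        region_pixels[(0, cand.label)] = np.nonzero(regions1.label_map == cand.label)
    if config.dual_pass:
        residual = binary.values.copy()
        residual[regions1.label_map > 0] = 0.0
        residual_mask = SegmentationMask(values=residual, kind="binary")
        if residual_mask.values.any():
            dist2 = distance_map(residual_mask)
            pass2, regions2 = _run_pass(residual_mask, dist2, config,
                                        [min(config.peak_scales)], floor1 / 2.0,
                                        pass_index=1)
            candidates.extend(pass2)
            for cand in pass2:
                region_pixels[(1, cand.label)] = np.nonzero(
                    regions2.label_map == cand.label)
    # dedup: pass-1 priority, then larger distance value, then (y, x)
    candidates.sort(key=lambda c: (c.pass_index, -c.dist_value, c.y, c.x))
    min_sep = config.min_separation_frac * config.expected_diameter_px
    accepted: List[Tuple[_Candidate, np.ndarray, np.ndarray]] = []
    for cand in candidates:
        if all(np.hypot(cand.x - a.x, cand.y - a.y) >= min_sep
               for a, _, _ in accepted):
            ys, xs = region_pixels[(cand.pass_index, cand.label)]
            accepted.append((cand, ys, xs))
    return accepted


def dual_pass_localize(binary: SegmentationMask, dist: Optional[np.ndarray] = None,
                       config: Optional[PostprocessConfig] = None) -> ParticleSet:
    """Particle centers from a binary mask via the dual-pass pipeline."""
    if config is None:
        raise ValueError("a PostprocessConfig is required")
    if dist is None:
        dist = distance_map(binary)
    accepted = _dual_pass(binary, dist, config)
    h, w = binary.shape
    particles = [
        Particle(x=min(max(c.x, 0.0), w - 1e-9), y=min(max(c.y, 0.0), h - 1e-9),
                 diameter=c.diameter)
        for c, _, _ in accepted
    ]
    return ParticleSet(particles=particles, reference_shape=(h, w),
                       provenance="predicted")


def masks_to_particles(mask: SegmentationMask,
                       config: PostprocessConfig) -> ParticleSet:
    """Full localization: binarize -> distance map -> dual-pass -> scores.

    Each particle's diameter is its region's equivalent diameter and its
    score the mean mask probability over the region (clipped to [0, 1]).
    """
    prob = mask.values
    binary = mask if mask.kind == "binary" else binarize(mask, config.threshold)
    dist = distance_map(binary)
    accepted = _dual_pass(binary, dist, config)
    h, w = binary.shape
    particles = []
    for cand, ys, xs in accepted:
        score = float(np.clip(prob[ys, xs].mean(), 0.0, 1.0)) if ys.size else 0.0
        particles.append(Particle(
            x=min(max(cand.x, 0.0), w - 1e-9), y=min(max(cand.y, 0.0), h - 1e-9),
            diameter=cand.diameter, score=score,
        ))
    return ParticleSet(particles=particles, reference_shape=(h, w),
                       provenance="predicted")
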