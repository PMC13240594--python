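"""Particle matching and picking metrics.

A predicted particle counts as a true positive when it is paired one-to-one
with a ground-truth particle within ``match_radius`` pixels (greedy
nearest-first pairing). Precision, recall and F1 follow the usual
definitions with the 0/0 -> 0 convention; IoU is the pixel-count ratio of
intersection to union of the two sets rasterized as unions of particle
disks on the shared reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .datamodel import ParticleSet

__all__ = [
    "MatchResult",
    "match_particles",
    "precision_recall_f1",
    "particle_iou",
    "evaluate_particle_set",
    "MetricTable",
]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: Tuple[Tuple[int, int, float], ...]  # (pred idx, gt idx, distance px)
    match_radius: float

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of pairs")


def match_particles(pred: ParticleSet, gt: ParticleSet,
                    match_radius: float) -> MatchResult:
    """Greedy one-to-one matching by ascending center distance."""
    if not (match_radius > 0):
        raise ValueError("match_radius must be > 0")
    if pred.reference_shape != gt.reference_shape:
        raise ValueError(
            f"reference shapes differ: {pred.reference_shape} vs {gt.reference_shape}"
        )
    P, G = pred.coordinates(), gt.coordinates()
    pairs: List[Tuple[int, int, float]] = []
    if len(P) and len(G):
        d = np.hypot(P[:, None, 0] - G[None, :, 0], P[:, None, 1] - G[None, :, 1])
        ip, ig = np.nonzero(d <= match_radius)
        dist = d[ip, ig]
        order = np.lexsort((ig, ip, dist))  # ascending distance, stable ties
        used_p, used_g = set(), set()
        for k in order:
            a, b = int(ip[k]), int(ig[k])
            if a in used_p or b in used_g:
                continue
            used_p.add(a)
            used_g.add(b)
            pairs.append((a, b, float(dist[k])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(P) - tp, fn=len(G) - tp,
                       pairs=tuple(pairs), match_radius=float(match_radius))


def precision_recall_f1(m: MatchResult) -> Tuple[float, float, float]:
    """(precision, recall, F1) with 0/0 -> 0."""
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = 2.0 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def _rasterize(ps: ParticleSet) -> np.ndarray:
    h, w = ps.reference_shape
    out = np.zeros((h, w), dtype=bool)
    for p in ps.particles:
        r = p.diameter / 2.0
        x0, x1 = max(0, int(np.floor(p.x - r))), min(w, int(np.ceil(p.x + r)) + 1)
        y0, y1 = max(0, int(np.floor(p.y - r))), min(h, int(np.ceil(p.y + r)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] |= np.hypot(xx - p.x, yy - p.y) <= r
    return out


def particle_iou(pred: ParticleSet, gt: ParticleSet) -> float:
    """Pixel IoU of the two particle sets rasterized as disk unions."""
    if pred.reference_shape != gt.reference_shape:
        raise ValueError("reference shapes must match for IoU")
    a, b = _rasterize(pred), _rasterize(gt)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum()) / union


def evaluate_particle_set(pred: ParticleSet, gt: ParticleSet,
                          match_radius: float) -> Dict[str, float]:
    """All four picking metrics for one micrograph."""
    m = match_particles(pred, gt, match_radius)
    precision, recall, f1 = precision_recall_f1(m)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "iou": particle_iou(pred, gt),
        "tp": float(m.tp), "fp": float(m.fp), "fn": float(m.fn),
    }


METRIC_COLUMNS = ("precision", "recall", "f1", "iou")


@dataclass
class MetricTable:
    """Per-micrograph, per-method metric table (long format)."""

    frame: pd.DataFrame

    REQUIRED = ("method", "dataset", "micrograph") + METRIC_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metric table lacks columns {missing}")
        vals = self.frame[list(METRIC_COLUMNS)].to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            raise ValueError("all metrics must lie in [0, 1]")

    @classmethod
    def from_records(cls, records: List[Dict]) -> "MetricTable":
        return cls(pd.DataFrame.from_records(records))

    def methods(self) -> List[str]:
        return sorted(self.frame["method"].unique())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MetricTable":
        return cls(pd.read_csv(path, sep="\t"))
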