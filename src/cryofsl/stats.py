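"""Paired nonparametric comparison of particle-picking methods.

The procedure: per (method, dataset, metric), check normality of the paired
differences with Shapiro-Wilk, run a two-sided paired Wilcoxon signed-rank
test (normal approximation with tie correction, zero differences dropped),
report the rank-biserial effect size r = z / sqrt(N), and adjust p-values
per metric across all method x dataset tests with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .evaluation import METRIC_COLUMNS, MetricTable

__all__ = [
    "ShapiroResult",
    "WilcoxonResult",
    "shapiro_gate",
    "wilcoxon_paired",
    "rank_biserial",
    "bh_adjust",
    "compare_methods",
    "StatReport",
]


class ShapiroResult(NamedTuple):
    statistic: float
    pvalue: float
    is_normal: bool
    testable: bool


class WilcoxonResult(NamedTuple):
    statistic: float  # min(W+, W-), the classical signed-rank statistic
    z: float
    pvalue: float


def shapiro_gate(samples: Sequence[float], alpha: float = 0.05) -> ShapiroResult:
    """Shapiro-Wilk normality gate; constant samples are non-testable."""
    x = np.asarray(list(samples), dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs at least 3 samples, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above 5000 samples")
    if np.ptp(x) == 0.0:
        warnings.warn("constant sample: normality is not testable", stacklevel=2)
        return ShapiroResult(np.nan, np.nan, False, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.shapiro(x)
    return ShapiroResult(float(res.statistic), float(res.pvalue),
                         bool(res.pvalue >= alpha), True)


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; ranks of |d| are tie-corrected; z is
    signed by the direction of the rank sum (positive when a tends to
    exceed b). Degenerate input (all differences zero) yields z=0, p=1.
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate",
                      stacklevel=2)
        return WilcoxonResult(0.0, 0.0, 1.0)
    if n < 5:
        raise ValueError(
            f"need at least 5 nonzero paired differences, got {n}"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        warnings.warn("zero variance after tie correction; test is degenerate",
                      stacklevel=2)
        return WilcoxonResult(min(w_plus, w_minus), 0.0, 1.0)
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(min(w_plus, w_minus), float(z), float(min(p, 1.0)))


def rank_biserial(z: float, N: int) -> float:
    """Rank-biserial effect size r = z / sqrt(N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(z) / float(np.sqrt(N))


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(list(pvals), dtype=np.float64)
    if p.size == 0:
        return []
    if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass
class StatReport:
    """One row per (method, dataset, metric) comparison against the reference."""

    frame: pd.DataFrame
    reference: str

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, reference: str = "") -> "StatReport":
        return cls(pd.read_csv(path, sep="\t"), reference)


def compare_methods(table: MetricTable, reference: str,
                    metrics: Sequence[str] = METRIC_COLUMNS,
                    alpha: float = 0.05) -> StatReport:
    """Compare every method against ``reference``, per dataset and metric.

    Pairing is per micrograph within a dataset. Entries with fewer than 5
    valid pairs are flagged untestable and excluded from BH adjustment,
    which is applied per metric jointly over all method x dataset tests.
    """
    df = table.frame
    if reference not in set(df["method"]):
        raise ValueError(f"reference method {reference!r} absent from table")
    rows: List[Dict] = []
    for metric in metrics:
        for method in table.methods():
            if method == reference:
                continue
            for dataset in sorted(df["dataset"].unique()):
                ref_rows = df[(df.method == reference) & (df.dataset == dataset)]
                cmp_rows = df[(df.method == method) & (df.dataset == dataset)]
                merged = ref_rows.merge(cmp_rows, on="micrograph",
                                        suffixes=("_ref", "_cmp"))
                a = merged[f"{metric}_cmp"].to_numpy(dtype=float)
                b = merged[f"{metric}_ref"].to_numpy(dtype=float)
                row: Dict = {"method": method, "dataset": dataset,
                             "metric": metric, "n_pairs": int(len(merged))}
                diffs = a - b
                nonzero = int(np.count_nonzero(diffs))
                if len(merged) < 5 or (0 < nonzero < 5):
                    row.update(statistic=np.nan, z=np.nan, p_raw=np.nan,
                               effect_r=np.nan, shapiro_p=np.nan,
                               normal=False, testable=False)
                    rows.append(row)
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sh = (shapiro_gate(diffs) if len(diffs) >= 3
                          else ShapiroResult(np.nan, np.nan, False, False))
                    wres = wilcoxon_paired(a, b)
                r = rank_biserial(wres.z, len(merged))
                row.update(statistic=wres.statistic, z=wres.z, p_raw=wres.pvalue,
                           effect_r=r, shapiro_p=sh.pvalue, normal=sh.is_normal,
                           testable=True)
                rows.append(row)
    frame = pd.DataFrame.from_records(rows)
    frame["p_adj"] = np.nan
    for metric in metrics:
        sel = (frame.metric == metric) & frame.testable
        if sel.any():
            frame.loc[sel, "p_adj"] = bh_adjust(frame.loc[sel, "p_raw"].tolist())
    frame["significant"] = frame["p_adj"] < alpha
    return StatReport(frame=frame, reference=reference)
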