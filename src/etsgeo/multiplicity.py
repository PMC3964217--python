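"""Binding probability and relative binding signal versus ETS-motif copy number.

Promoters are binned by motif copy number k (0..kmax, default 6; promoters
with more motifs exist but are too few to analyze and are excluded).  The
probability curve is the fraction of promoters in each bin called bound; the
signal curve is the replicate-normalized mean binding signal of bound
promoters per bin.  An exponential law ``a * exp(b*k)`` is fitted by
log-linear least squares, a linear law by ordinary least squares; the
correlation coefficient R accompanies each fit (for the exponential fit R is
computed on log-transformed values; the raw-space R is reported alongside).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .signal import PromoterSignal

log = logging.getLogger(__name__)

KMAX = 6


@dataclass
class CurvePoint:
    k: int
    value: float
    n: int
    se: Optional[float] = None


@dataclass
class FitResult:
    model: str  # "exponential" or "linear"
    a: float
    b: float
    r: float
    r_raw: Optional[float] = None
    b_se: Optional[float] = None  # standard error of the slope
    degenerate: bool = False
    excluded_k: tuple[int, ...] = ()

    def predict(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        if self.model == "exponential":
            return self.a * np.exp(self.b * k)
        return self.a + self.b * k


def probability_curve(
    bound_ids: Iterable[str],
    counts: Mapping[str, int],
    kmax: int = KMAX,
) -> list[CurvePoint]:
    """Fraction of promoters bound per motif copy number bin 0..kmax.

    Promoters with more than ``kmax`` motifs are excluded; empty bins are
    omitted.
    """
    bound = set(bound_ids)
    points = []
    for k in range(kmax + 1):
        genes = [g for g, c in counts.items() if c == k]
        if not genes:
            continue
        nb = sum(g in bound for g in genes)
        points.append(CurvePoint(k, nb / len(genes), len(genes)))
    return points


def fit_exponential(
    points: Sequence[CurvePoint], exclude_k: Sequence[int] = ()
) -> FitResult:
    """Least squares of ln(value) on k over points with value > 0.

    Zero-probability bins cannot enter a log fit and are skipped (they remain
    reported in the curve itself); an explicit ``exclude_k`` drops stated
    bins, reproducing analyses that omit a discontinuous final point.
    """
    use = [p for p in points if p.value > 0 and p.k not in set(exclude_k)]
    if len(use) < 3:
        raise ValueError("exponential fit needs >= 3 positive points")
    x = np.array([p.k for p in use], dtype=float)
    y = np.log([p.value for p in use])
    if np.allclose(y, y[0]):
        return FitResult("exponential", math.exp(y[0]), 0.0, 0.0,
                         r_raw=0.0, degenerate=True, excluded_k=tuple(exclude_k))
    slope, intercept, r, _, se = stats.linregress(x, y)
    raw = np.array([p.value for p in use])
    r_raw = float(stats.pearsonr(x, raw)[0]) if not np.allclose(raw, raw[0]) else 0.0
    return FitResult("exponential", math.exp(intercept), float(slope), float(r),
                     r_raw=r_raw, b_se=float(se), excluded_k=tuple(exclude_k))


def fit_linear(points: Sequence[CurvePoint]) -> FitResult:
    """Ordinary least squares value ~ k with Pearson R."""
    if len(points) < 2:
        raise ValueError("linear fit needs >= 2 points")
    x = np.array([p.k for p in points], dtype=float)
    y = np.array([p.value for p in points], dtype=float)
    if np.allclose(y, y[0]):
        return FitResult("linear", float(y[0]), 0.0, 0.0, r_raw=0.0, degenerate=True)
    slope, intercept, r, _, se = stats.linregress(x, y)
    return FitResult("linear", float(intercept), float(slope), float(r),
                     r_raw=float(r), b_se=float(se))


def signal_curve(
    signals: Sequence[PromoterSignal],
    counts: Mapping[str, int],
    kmax: int = KMAX,
) -> list[CurvePoint]:
    """Replicate-normalized mean binding signal per motif copy number bin.

    Each replicate's promoter signals are divided by that replicate's mean
    signal per promoter (so replicate depth cancels and the grand mean is 1);
    each promoter is then summarized by its replicate mean, and bins report
    the mean over promoters with the standard error over promoters (absent
    for single-promoter bins).
    """
    if not signals:
        return []
    mat = np.array([s.replicate_signals for s in signals], dtype=float)
    rep_means = mat.mean(axis=0)
    if np.any(rep_means == 0):
        raise ValueError("a replicate has zero total signal; cannot normalize")
    norm = mat / rep_means
    per_prom = norm.mean(axis=1)
    ks = np.array([counts[s.gene_id] for s in signals])

    points = []
    for k in range(kmax + 1):
        sel = per_prom[ks == k]
        if sel.size == 0:
            continue
        se = float(sel.std(ddof=1) / math.sqrt(sel.size)) if sel.size > 1 else None
        points.append(CurvePoint(k, float(sel.mean()), int(sel.size), se=se))
    return points


def curve_to_tsv(points: Sequence[CurvePoint], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(p.k, p.value, p.n, "" if p.se is None else p.se) for p in points],
        columns=["k", "value", "n", "se"],
    ).to_csv(path, sep="\t", index=False)
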