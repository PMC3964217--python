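"""Contingency statistics tying binding calls to site and promoter classes.

Covers the three association analyses: isolated single/dimer ETS site regions
(propensity of a factor to bind lone sites vs inverted or direct site pairs),
factor co-binding, and enrichment of binding at bidirectional promoters.
All p-values are upper-tail hypergeometric, evaluated in log space so that
tails far below float underflow (the real-data analyses report p-values down
to 1e-300) remain finite and comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .annotation import BIDIRECTIONAL, PromoterPair, PromoterRegion

log = logging.getLogger(__name__)

ISOLATION_DISTANCE = 2000
DIMER_MAX_SPACING = 1000
BOUND_WINDOW = 500

SINGLE = "single"
INVERTED_DIMER = "inverted_dimer"
DIRECT_DIMER = "direct_dimer"


@dataclass
class ContingencyResult:
    label: str
    N: int  # universe size
    K: int  # class size
    n: int  # bound-set size
    k: int  # overlap
    fraction_bound: float
    p_value: float
    log10_p: float


@dataclass
class IsolatedRegion:
    chrom: str
    centers: tuple[int, ...]  # one site (single) or two (dimer)
    klass: str
    bound: bool = False

    @property
    def midpoint(self) -> int:
        return int(round(sum(self.centers) / len(self.centers)))


def _log_hypergeom_pmf(N: int, K: int, n: int, x: np.ndarray) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_upper_log(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k <= max(0, n + K - N):
        return 0.0
    xs = np.arange(k, min(K, n) + 1, dtype=float)
    return float(min(0.0, logsumexp(_log_hypergeom_pmf(N, K, n, xs))))


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), log-space evaluation."""
    return math.exp(hypergeom_upper_log(N, K, n, k))


def fraction_bound(k: int, class_size: int, decimals: Optional[int] = None) -> float:
    """Fraction of a site/promoter class bound by the factor (k / class size)."""
    if class_size <= 0:
        raise ValueError("class_size must be positive")
    if k > class_size:
        raise ValueError("bound count exceeds class size")
    f = k / class_size
    return round(f, decimals) if decimals is not None else f


def contingency(label: str, N: int, K: int, n: int, k: int) -> ContingencyResult:
    logp = hypergeom_upper_log(N, K, n, k)
    return ContingencyResult(
        label, N, K, n, k,
        fraction_bound=fraction_bound(k, K),
        p_value=math.exp(logp),
        log10_p=logp / math.log(10),
    )


def isolate_regions(
    sites: Sequence[tuple[str, int, str]],
    promoters: Sequence[PromoterRegion],
    peak_centers: Sequence[tuple[str, int]],
    isolation: int = ISOLATION_DISTANCE,
    dimer_max: int = DIMER_MAX_SPACING,
    bound_window: int = BOUND_WINDOW,
) -> list[IsolatedRegion]:
    """Classify isolated motif-site regions and flag binding.

    ``sites`` are genome-level motif occurrences as (chrom, center, strand).
    A *single* is a site with no other site and no promoter within
    ``isolation`` bases; a *dimer* is exactly two sites within ``dimer_max``
    of each other, with nothing else (site or promoter) within ``isolation``
    of either member.  Opposite-strand dimers are inverted, same-strand
    direct.  A region is bound if any peak center lies within
    ``bound_window`` of the region midpoint.  Distances are center-to-center;
    promoter proximity is distance to the promoter interval.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, center, strand in sites:
        by_chrom.setdefault(chrom, []).append((center, strand))
    prom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in promoters:
        prom_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    peaks_by_chrom: dict[str, np.ndarray] = {}
    for chrom, c in peak_centers:
        peaks_by_chrom.setdefault(chrom, []).append(c)  # type: ignore[attr-defined]
    peaks_by_chrom = {c: np.sort(np.asarray(v)) for c, v in peaks_by_chrom.items()}

    def promoter_clear(chrom: str, center: int) -> bool:
        for s, e in prom_by_chrom.get(chrom, ()):
            d = 0 if s <= center < e else min(abs(center - s), abs(center - (e - 1)))
            if d <= isolation:
                return False
        return True

    def is_bound(chrom: str, mid: int) -> bool:
        pk = peaks_by_chrom.get(chrom)
        if pk is None or pk.size == 0:
            return False
        i = int(np.searchsorted(pk, mid))
        near = [pk[j] for j in (i - 1, i) if 0 <= j < pk.size]
        return any(abs(int(c) - mid) <= bound_window for c in near)

    regions: list[IsolatedRegion] = []
    for chrom, lst in by_chrom.items():
        lst = sorted(lst)
        centers = [c for c, _ in lst]
        n = len(lst)
        for i, (c, strand) in enumerate(lst):
            neigh = [abs(centers[j] - c) for j in range(n) if j != i]
            if neigh and min(neigh) <= isolation:
                continue
            if not promoter_clear(chrom, c):
                continue
            regions.append(
                IsolatedRegion(chrom, (c,), SINGLE, bound=is_bound(chrom, c))
            )
        for i in range(n):
            c1, s1 = lst[i]
            for j in range(i + 1, n):
                c2, s2 = lst[j]
                if c2 - c1 > dimer_max:
                    break
                others = [
                    min(abs(centers[m] - c1), abs(centers[m] - c2))
                    for m in range(n)
                    if m not in (i, j)
                ]
                if others and min(others) <= isolation:
                    continue
                if not (promoter_clear(chrom, c1) and promoter_clear(chrom, c2)):
                    continue
                klass = INVERTED_DIMER if s1 != s2 else DIRECT_DIMER
                mid = (c1 + c2) // 2
                regions.append(
                    IsolatedRegion(chrom, (c1, c2), klass, bound=is_bound(chrom, mid))
                )
    return regions


def region_class_table(regions: Iterable[IsolatedRegion]) -> list[ContingencyResult]:
    """Per-class bound fractions with hypergeometric p over the region universe."""
    regions = list(regions)
    N = len(regions)
    n = sum(r.bound for r in regions)
    out = []
    for klass in (SINGLE, INVERTED_DIMER, DIRECT_DIMER):
        members = [r for r in regions if r.klass == klass]
        if not members:
            continue
        K = len(members)
        k = sum(r.bound for r in members)
        out.append(contingency(klass, N, K, n, k))
    return out


@dataclass
class BidirectionalOverlap:
    result: ContingencyResult
    n_regions: int  # promoter regions, pairs counted once
    n_bidirectional: int
    n_bound_regions: int
    overlap: int
    fraction_of_bound: float  # share of bound regions that are bidirectional
    fraction_of_bidirectional: float  # share of bidirectional regions bound


def bidirectional_overlap(
    bound_ids: Iterable[str],
    pairs: Sequence[PromoterPair],
    all_gene_ids: Sequence[str],
    count_pairs_once: bool = True,
) -> BidirectionalOverlap:
    """Enrichment of bound promoters among bidirectional promoter regions.

    With ``count_pairs_once`` (default, matching the region-level analysis) a
    bidirectional region is one unit: the universe is
    ``n_genes - n_bidirectional_pairs``, a region is bound if either member
    gene is bound, and each region contributes once to every count.
    """
    bound = set(bound_ids)
    bid_pairs = [p for p in pairs if p.kind == BIDIRECTIONAL]
    genes = set(all_gene_ids)
    member = {g: i for i, p in enumerate(bid_pairs) for g in (p.minus_gene, p.plus_gene)}

    if count_pairs_once:
        N = len(genes) - len(bid_pairs)
        K = len(bid_pairs)
        bound_regions: set = set()
        for g in bound:
            bound_regions.add(member.get(g, g))
        n = len(bound_regions)
        k = sum(
            1
            for i, p in enumerate(bid_pairs)
            if p.minus_gene in bound or p.plus_gene in bound
        )
    else:
        N = len(genes)
        K = 2 * len(bid_pairs)
        n = len(bound & genes)
        k = len(bound & set(member))

    res = contingency("bidirectional", N, K, n, k)
    return BidirectionalOverlap(
        result=res,
        n_regions=N,
        n_bidirectional=K,
        n_bound_regions=n,
        overlap=k,
        fraction_of_bound=k / n if n else 0.0,
        fraction_of_bidirectional=k / K if K else 0.0,
    )
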