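"""Synthetic annotation, promoter sequences with planted motifs, and simulated
ChIP reads.

The generator emulates the statistical structure the pipeline assumes so that
every stage is testable without external data: a gene set with a small
bidirectional-promoter fraction (~4-5%, as in the human genome), ETS 7-mer
placements whose pair-spacing distribution is sharply peaked near zero with
shoulders out to +/-1000, and three factor archetypes --

* ``p53``-like: binding probability rising exponentially with motif copy
  number, flat binding signal, spacing preference centered at -200 with
  depletion at closely spaced motifs;
* ``ets1``-like: similar, with preference kernels at -50 and +200;
* ``gabpa``-like: zero-centered spacing preference and binding signal
  proportional to motif copy number.

Reads are Poisson-sampled over a uniform background with enriched mass at
bound promoters and a fixed forward/reverse strand shift; negative-control
replicates carry background only.  All sampling is driven by a mandatory
seed; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, PromoterRegion, derive_promoters
from .motifs import IUPAC, MotifHit, _iupac_regex, reverse_complement

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FactorModel:
    """Binding law of one simulated factor.

    ``P(bound | k) = min(1, base_rate * exp(exponent * k))`` over motif copy
    number k, reweighted for two-motif inverted promoters by a spacing kernel
    (Gaussian bumps at ``kernel_centers`` over a ``kernel_floor`` baseline)
    and a multiplicative suppression well at distance 0.  The well is
    super-Gaussian (``depth * exp(-(d/width)^8)``), i.e. flat-bottomed over
    the closely-spaced range with sharp walls, so that the dense close-pair
    population is suppressed uniformly while spacings beyond ~width escape
    untouched.  The read mass of a bound promoter is ``enrichment_fold x
    background`` when ``signal_law`` is ``constant``, or additionally scaled
    by k/2 when ``proportional_to_k``.
    """

    name: str
    base_rate: float = 0.02
    exponent: float = 0.8
    kernel_centers: tuple[float, ...] = (-200.0,)
    kernel_sd: float = 30.0
    kernel_floor: float = 0.15
    zero_suppression: float = 0.9
    zero_suppression_width: float = 70.0
    signal_law: str = "constant"  # or "proportional_to_k"
    phase_center: Optional[float] = None  # degrees; optional phase preference
    phase_kappa: float = 0.0  # von Mises concentration of the preference

    def spacing_weight(self, d: float) -> float:
        bump = max(
            math.exp(-((d - c) ** 2) / (2 * self.kernel_sd**2))
            for c in self.kernel_centers
        )
        w = self.kernel_floor + (1 - self.kernel_floor) * bump
        if self.zero_suppression > 0:
            w *= 1 - self.zero_suppression * math.exp(
                -((abs(d) / self.zero_suppression_width) ** 8)
            )
        return w

    def phase_weight(self, phi: float) -> float:
        if self.phase_center is None or self.phase_kappa == 0:
            return 1.0
        return math.exp(
            self.phase_kappa * (math.cos(math.radians(phi - self.phase_center)) - 1)
        )


DEFAULT_FACTORS = (
    FactorModel("p53", base_rate=0.02, exponent=0.8, kernel_centers=(-200.0,),
                kernel_sd=30.0, kernel_floor=0.15, zero_suppression=0.97,
                signal_law="constant"),
    FactorModel("ets1", base_rate=0.03, exponent=0.7, kernel_centers=(-50.0, 200.0),
                kernel_sd=40.0, kernel_floor=0.2, zero_suppression=0.8,
                signal_law="constant"),
    FactorModel("gabpa", base_rate=0.04, exponent=0.5, kernel_centers=(0.0,),
                kernel_sd=40.0, kernel_floor=0.2, zero_suppression=0.0,
                signal_law="proportional_to_k"),
)

# motif copy number distribution over 0..13: most promoters carry 0-2 motifs,
# a thin tail reaches 13 (so the copy-number analyses must exclude 7..13)
DEFAULT_COUNT_PROBS = (
    0.42, 0.26, 0.15, 0.08, 0.04, 0.02, 0.01,
    0.005, 0.004, 0.003, 0.003, 0.002, 0.002, 0.001,
)


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 1000
    bidirectional_fraction: float = 0.044  # pairs per gene, as in hg annotation
    promoter_len: int = 1000
    pattern: str = "CCGGAAG"
    motif_count_probs: tuple[float, ...] = DEFAULT_COUNT_PROBS
    inverted_fraction: float = 0.8  # of two-motif promoters
    close_weight: float = 0.6  # spacing-mixture mass at |d| < 50
    close_range: tuple[int, int] = (8, 49)
    far_range: tuple[int, int] = (50, 993)
    factors: tuple[FactorModel, ...] = DEFAULT_FACTORS
    enrichment_fold: float = 10.0
    background_density: float = 0.02  # reads per base per replicate
    n_replicates: int = 3
    n_control_replicates: int = 3
    read_length: int = 50
    strand_shift: int = 120
    peak_sd: float = 35.0
    gap_range: tuple[int, int] = (2200, 4000)  # spacing between gene slots

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.motif_count_probs), 1.0, abs_tol=1e-9):
            raise ValueError("motif_count_probs must sum to 1")
        if not 0 <= self.bidirectional_fraction <= 0.5:
            raise ValueError("bidirectional_fraction out of range")


@dataclass
class SynthTruth:
    """Ground truth emitted by the generator."""

    hits: list[MotifHit]  # per-promoter coordinates
    counts: dict[str, int]
    pair_distance: dict[str, int]  # signed distance for 2-motif inverted promoters
    bound: dict[str, set[str]] = field(default_factory=dict)  # factor -> gene ids


def generate_annotation(
    cfg: SynthConfig, seed: int
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Lay out genes on one chromosome: bidirectional pairs at sampled TSS
    distances, all other genes isolated by >1 kb gaps.  Returns the gene set
    and chromosome lengths; deterministic under the seed."""
    rng = np.random.default_rng(seed)
    n_pairs = int(round(cfg.n_genes * cfg.bidirectional_fraction))
    n_single = cfg.n_genes - 2 * n_pairs
    if n_single < 0:
        raise ValueError("bidirectional_fraction too high for n_genes")
    slots = ["pair"] * n_pairs + ["single"] * n_single
    rng.shuffle(slots)

    genes: list[GeneRecord] = []
    cursor = cfg.promoter_len + 10
    gi = 0
    for slot in slots:
        if slot == "pair":
            d = int(rng.integers(2, cfg.promoter_len + 1))  # TSS distance
            minus_tss = cursor
            plus_tss = cursor + d
            a, b = f"g{gi:05d}", f"g{gi + 1:05d}"
            genes.append(GeneRecord(a, "chr1", "-", minus_tss))
            genes.append(GeneRecord(b, "chr1", "+", plus_tss))
            gi += 2
            cursor = minus_tss + cfg.promoter_len + 1  # end of minus promoter
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gi:05d}"
            if strand == "+":
                tss = cursor + cfg.promoter_len
                genes.append(GeneRecord(gid, "chr1", "+", tss))
                cursor = tss
            else:
                tss = cursor
                genes.append(GeneRecord(gid, "chr1", "-", tss))
                cursor = tss + cfg.promoter_len + 1
            gi += 1
        cursor += int(rng.integers(*cfg.gap_range))
    chrom_lengths = {"chr1": cursor + cfg.promoter_len + 10}
    return genes, chrom_lengths


def _sample_signed_distance(cfg: SynthConfig, rng: np.random.Generator) -> int:
    """Spacing mixture: uniform close component, shoulders decaying linearly
    toward +/-1000; signs (face-to-face vs back-to-back) are balanced."""
    if rng.random() < cfg.close_weight:
        lo, hi = cfg.close_range
        mag = int(rng.integers(lo, hi + 1))
    else:
        lo, hi = cfg.far_range
        # density proportional to (1000 - |d|) on [lo, hi], via inverse CDF
        ylo, yhi = 1000.0 - hi, 1000.0 - lo
        y = math.sqrt(rng.random() * (yhi**2 - ylo**2) + ylo**2)
        mag = int(round(1000.0 - y))
        mag = min(max(mag, lo), hi)
    return -mag if rng.random() < 0.5 else mag


def sample_pair_distances(cfg: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n signed pair distances from the configured spacing mixture."""
    return np.array([_sample_signed_distance(cfg, rng) for _ in range(n)], dtype=int)


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        ch if len(IUPAC[ch]) == 1 else IUPAC[ch][rng.integers(len(IUPAC[ch]))]
        for ch in pattern.upper()
    )


def plant_motifs(
    cfg: SynthConfig,
    genes: Sequence[GeneRecord],
    chrom_lengths: dict[str, int],
    seed: int,
) -> tuple[dict[str, str], list[PromoterRegion], SynthTruth]:
    """Build a pattern-free random genome and plant motifs into promoters.

    Per promoter a copy number k is drawn from the count distribution; for
    k = 2 an inverted pair is planted (with probability ``inverted_fraction``)
    at a signed distance from the spacing mixture.  The background is scrubbed
    of spurious pattern occurrences so that scanning recovers exactly the
    planted hits.  Ground truth (per-promoter hits, counts, pair distances) is
    derived from the planted genome coordinates, so motifs falling inside an
    overlapping partner promoter are attributed to it too.
    """
    if len(cfg.pattern) > cfg.promoter_len:
        raise ValueError("pattern longer than promoter")
    rng = np.random.default_rng(seed)
    promoters = derive_promoters(genes, cfg.promoter_len)
    mlen = len(cfg.pattern)

    genome = {
        chrom: rng.choice(_BASES, size=length) for chrom, length in chrom_lengths.items()
    }
    planted: dict[str, list[tuple[int, str]]] = {c: [] for c in chrom_lengths}

    pair_distance: dict[str, int] = {}
    probs = np.asarray(cfg.motif_count_probs)
    for prom in sorted(promoters, key=lambda p: p.gene_id):
        k = int(rng.choice(len(probs), p=probs))
        if k == 0:
            continue
        taken = [s for s, _ in planted[prom.chrom]]

        def free(gstart: int) -> bool:
            return all(abs(gstart - s) >= mlen + 1 for s in taken)

        if k == 2 and rng.random() < cfg.inverted_fraction:
            d = _sample_signed_distance(cfg, rng)
            D = abs(d)
            placed = False
            for _ in range(200):
                o_left = int(rng.integers(0, cfg.promoter_len - mlen - D + 1))
                g_left = prom.start + o_left
                g_right = g_left + D
                if free(g_left) and free(g_right):
                    left_strand, right_strand = ("+", "-") if d < 0 else ("-", "+")
                    for g, strand in ((g_left, left_strand), (g_right, right_strand)):
                        planted[prom.chrom].append((g, strand))
                        taken.append(g)
                    pair_distance[prom.gene_id] = d
                    placed = True
                    break
            if not placed:
                log.warning("could not place inverted pair in %s", prom.gene_id)
            continue
        for _ in range(k):
            for _ in range(200):
                o = int(rng.integers(0, cfg.promoter_len - mlen + 1))
                g = prom.start + o
                if free(g):
                    strand = "+" if rng.random() < 0.5 else "-"
                    planted[prom.chrom].append((g, strand))
                    taken.append(g)
                    break

    # write motifs and scrub spurious matches from the background
    fwd_re = _iupac_regex(cfg.pattern)
    rev_re = _iupac_regex(reverse_complement(cfg.pattern))
    for chrom, arr in genome.items():
        protected = np.zeros(arr.size, dtype=bool)
        for gstart, strand in planted[chrom]:
            word = _concrete_motif(cfg.pattern, rng)
            if strand == "-":
                word = reverse_complement(word)
            arr[gstart : gstart + mlen] = np.frombuffer(word.encode(), dtype="S1")
            protected[gstart : gstart + mlen] = True
        starts = {s for s, _ in planted[chrom]}
        for _ in range(50):
            text = arr.tobytes().decode()
            spurious = [
                m.start()
                for rex in (fwd_re, rev_re)
                for m in rex.finditer(text)
                if m.start() not in starts
            ]
            if not spurious:
                break
            for s in spurious:
                cand = [i for i in range(s, s + mlen) if not protected[i]]
                if not cand:
                    raise RuntimeError("spurious motif inside protected bases")
                i = cand[rng.integers(len(cand))]
                old = arr[i]
                choices = _BASES[_BASES != old]
                arr[i] = choices[rng.integers(len(choices))]
        else:
            raise RuntimeError("could not scrub spurious motifs")

    genome_str = {c: a.tobytes().decode() for c, a in genome.items()}

    hits: list[MotifHit] = []
    counts: dict[str, int] = {p.gene_id: 0 for p in promoters}
    for prom in promoters:
        for gstart, strand in planted[prom.chrom]:
            if prom.start <= gstart and gstart + mlen <= prom.end:
                off = gstart - prom.start
                hits.append(
                    MotifHit(prom.gene_id, off, strand,
                             genome_str[prom.chrom][gstart : gstart + mlen])
                )
                counts[prom.gene_id] += 1
    hits.sort(key=lambda h: (h.region_id, h.offset))
    # pair distances only stand for promoters that still hold exactly the pair
    pair_distance = {
        g: d for g, d in pair_distance.items() if counts.get(g) == 2
    }
    return genome_str, promoters, SynthTruth(hits, counts, pair_distance)


def _factor_bound_set(
    cfg: SynthConfig,
    factor: FactorModel,
    truth: SynthTruth,
    rng: np.random.Generator,
) -> set[str]:
    from .geometry import helical_phase

    bound = set()
    for gid in sorted(truth.counts):
        k = truth.counts[gid]
        p = min(1.0, factor.base_rate * math.exp(factor.exponent * k))
        d = truth.pair_distance.get(gid)
        if d is not None:
            p *= factor.spacing_weight(d)
            p *= factor.phase_weight(helical_phase(abs(d)))
        if rng.random() < p:
            bound.add(gid)
    return bound


def _place_reads(
    rng: np.random.Generator,
    centers: np.ndarray,
    cfg: SynthConfig,
    genome_len: int,
) -> pd.DataFrame:
    """Reads around fragment centers with the configured strand shift."""
    n = centers.size
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    half = cfg.strand_shift // 2
    starts = np.where(
        strands == "+", centers - half, centers + half - cfg.read_length
    )
    starts = np.clip(starts, 0, genome_len - cfg.read_length)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts.astype(int),
            "end": (starts + cfg.read_length).astype(int),
            "name": ".",
            "score": 0,
            "strand": strands,
        }
    )


def simulate_chip_reads(
    cfg: SynthConfig,
    promoters: Sequence[PromoterRegion],
    truth: SynthTruth,
    chrom_lengths: dict[str, int],
    seed: int,
) -> tuple[dict[str, list[pd.DataFrame]], list[pd.DataFrame], SynthTruth]:
    """Per-factor treatment replicates plus shared negative-control replicates.

    Background reads are uniform Poisson at ``background_density`` per
    replicate; each bound promoter adds Poisson read mass of
    ``enrichment_fold x`` its 1-kb background (scaled by k/2 for
    proportional-law factors) centered on its planted motifs.  The truth
    object is returned with the per-factor bound sets filled in.
    """
    G = chrom_lengths["chr1"]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    factor_seeds = ss.spawn(len(cfg.factors) + 1)
    prom_by_id = {p.gene_id: p for p in promoters}
    anchors: dict[str, int] = {}
    hit_centers: dict[str, list[int]] = {}
    mlen = len(cfg.pattern)
    for h in truth.hits:
        p = prom_by_id[h.region_id]
        hit_centers.setdefault(h.region_id, []).append(p.start + h.center(mlen))
    for gid, p in prom_by_id.items():
        cs = hit_centers.get(gid)
        anchors[gid] = int(np.mean(cs)) if cs else (p.start + p.end) // 2

    bg_per_prom = cfg.background_density * cfg.promoter_len

    treatments: dict[str, list[pd.DataFrame]] = {}
    for factor, fseed in zip(cfg.factors, factor_seeds):
        rng = np.random.default_rng(fseed)
        bound = _factor_bound_set(cfg, factor, truth, rng)
        truth.bound[factor.name] = bound
        reps = []
        for _ in range(cfg.n_replicates):
            n_bg = rng.poisson(cfg.background_density * G)
            bg_centers = rng.integers(0, G, size=n_bg)
            parts = [_place_reads(rng, bg_centers, cfg, G)]
            for gid in sorted(bound):
                k = truth.counts[gid]
                lam = cfg.enrichment_fold * bg_per_prom
                if factor.signal_law == "proportional_to_k":
                    lam *= max(k, 1) / 2.0
                n = rng.poisson(lam)
                if n == 0:
                    continue
                centers = np.rint(
                    rng.normal(anchors[gid], cfg.peak_sd, size=n)
                ).astype(int)
                parts.append(_place_reads(rng, np.clip(centers, 0, G - 1), cfg, G))
            reps.append(pd.concat(parts, ignore_index=True))
        treatments[factor.name] = reps

    rng = np.random.default_rng(factor_seeds[-1])
    controls = []
    for _ in range(cfg.n_control_replicates):
        n_bg = rng.poisson(cfg.background_density * G)
        bg_centers = rng.integers(0, G, size=n_bg)
        controls.append(_place_reads(rng, bg_centers, cfg, G))
    return treatments, controls, truth


def genes_to_tsv(genes: Sequence[GeneRecord], path) -> None:
    rows = []
    for g in genes:
        if g.strand == "+":
            rows.append((g.gene_id, g.chrom, g.strand, g.tss, g.tss + 100))
        else:
            rows.append((g.gene_id, g.chrom, g.strand, max(0, g.tss - 99), g.tss + 1))
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "txStart", "txEnd"]).to_csv(
        path, sep="\t", index=False
    )


def genome_to_fasta(genome: dict[str, str], path) -> None:
    from .io import write_fasta

    write_fasta(genome, path)


def reads_to_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)
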