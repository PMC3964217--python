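"""Gene annotation handling: TSS extraction, fixed-width promoters, and
divergent (bidirectional) / convergent (face-to-face) promoter-pair calling.

Coordinates are 0-based, half-open throughout (BED convention).  The TSS of a
``+`` strand gene is its smallest start coordinate; for a ``-`` strand gene it
is the rightmost transcribed base, ``txEnd - 1``.  For genes annotated with
several transcripts only the most 5' TSS is kept.

A *bidirectional* promoter is the region between two divergently transcribed
genes whose TSSs sit back-to-back within 1 kb; a *face-to-face* pair has the
TSSs pointing toward each other within 1 kb (their promoters do not overlap,
so such regions are not bidirectional promoters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

PROMOTER_LEN = 1000
PAIR_MAX_DISTANCE = 1000

UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"
FACE_TO_FACE = "face_to_face"


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A gene reduced to its most 5' transcription start site."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based position of the first transcribed base

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass
class PromoterRegion:
    """A fixed-width (default 1 kb) interval immediately upstream of a TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    pair_class: str = UNIDIRECTIONAL
    partner_id: Optional[str] = None
    clipped: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterPair:
    """Two opposite-strand genes with TSSs within ``PAIR_MAX_DISTANCE``."""

    minus_gene: str
    plus_gene: str
    tss_distance: int
    kind: str  # BIDIRECTIONAL or FACE_TO_FACE


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene table (TSV with header gene_id/chrom/strand/txStart/txEnd,
    or headerless BED6) and reduce multi-transcript genes to one record at the
    most 5' TSS.

    Rows with a malformed strand symbol are dropped with a warning; an empty
    file (or a file with no usable rows) raises ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"empty gene table: {path}")
    if "gene_id" in first:
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "strand", "txStart", "txEnd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
    else:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "txStart", "txEnd", "gene_id", "score", "strand"],
        )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        for _, row in df[bad].iterrows():
            log.warning("dropping row with malformed strand %r (gene %s)", row["strand"], row["gene_id"])
        df = df[~bad]
    if df.empty:
        raise ValueError(f"no usable rows in gene table: {path}")

    records: list[GeneRecord] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        strands = grp["strand"].unique()
        if len(strands) > 1:
            log.warning("gene %s annotated on both strands; dropped", gene_id)
            continue
        strand = strands[0]
        chrom = grp["chrom"].iloc[0]
        if strand == "+":
            tss = int(grp["txStart"].min())
        else:
            tss = int(grp["txEnd"].max()) - 1  # 0-based last transcribed base
        records.append(GeneRecord(str(gene_id), str(chrom), strand, tss))
    return records


def derive_promoters(
    genes: Iterable[GeneRecord], length: int = PROMOTER_LEN
) -> list[PromoterRegion]:
    """Derive the ``length``-bp promoter immediately upstream of each TSS.

    ``+`` strand: ``[tss - length, tss)``; ``-`` strand: ``[tss + 1,
    tss + 1 + length)``.  Promoters running off the chromosome start are
    truncated and flagged.
    """
    out: list[PromoterRegion] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - length, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + length
        clipped = False
        if start < 0:
            log.warning("promoter of %s clipped at chromosome start", g.gene_id)
            start, clipped = 0, True
        out.append(PromoterRegion(g.gene_id, g.chrom, start, end, g.strand, clipped=clipped))
    return out


def classify_promoter_pairs(
    genes: Sequence[GeneRecord],
    promoters: Optional[Sequence[PromoterRegion]] = None,
    max_distance: int = PAIR_MAX_DISTANCE,
) -> list[PromoterPair]:
    """Pair opposite-strand genes whose TSSs lie within ``max_distance``.

    Divergent geometry (``-`` TSS at or left of a ``+`` TSS) is a
    bidirectional promoter; convergent geometry is face-to-face.  Each gene
    joins at most one pair: candidates are taken nearest-first, with ties
    broken lexicographically on gene ids, so the result is independent of
    input order.  If ``promoters`` is given, member regions get their
    ``pair_class`` and ``partner_id`` updated in place.
    """
    by_chrom: dict[str, dict[str, list[GeneRecord]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, {"+": [], "-": []})[g.strand].append(g)

    candidates: list[tuple[int, str, str, GeneRecord, GeneRecord]] = []
    for chrom, groups in by_chrom.items():
        for minus in groups["-"]:
            for plus in groups["+"]:
                d = plus.tss - minus.tss
                if 0 <= d <= max_distance:
                    kind = BIDIRECTIONAL
                elif 0 < -d <= max_distance:
                    kind = FACE_TO_FACE
                else:
                    continue
                lo, hi = sorted((minus.gene_id, plus.gene_id))
                candidates.append((abs(d), lo, hi, minus, plus, kind))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    paired: set[str] = set()
    pairs: list[PromoterPair] = []
    for d, _, _, minus, plus, kind in candidates:
        if minus.gene_id in paired or plus.gene_id in paired:
            continue
        paired.update((minus.gene_id, plus.gene_id))
        pairs.append(PromoterPair(minus.gene_id, plus.gene_id, d, kind))

    if promoters is not None:
        by_id = {p.gene_id: p for p in promoters}
        for pair in pairs:
            for gid, partner in (
                (pair.minus_gene, pair.plus_gene),
                (pair.plus_gene, pair.minus_gene),
            ):
                if gid in by_id:
                    by_id[gid].pair_class = pair.kind
                    by_id[gid].partner_id = partner
    return pairs


def promoters_to_bed(promoters: Iterable[PromoterRegion], path: str | Path) -> None:
    """Write promoters as BED6; the name field carries gene id and pair class."""
    with open(path, "w") as fh:
        for p in sorted(promoters, key=lambda p: (p.chrom, p.start, p.gene_id)):
            name = f"{p.gene_id}|{p.pair_class}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t{p.strand}\n")


def pairs_to_tsv(pairs: Iterable[PromoterPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.minus_gene, p.plus_gene, p.tss_distance, p.kind) for p in pairs],
        columns=["minus_gene", "plus_gene", "tss_distance", "kind"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[PromoterPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        PromoterPair(str(r.minus_gene), str(r.plus_gene), int(r.tss_distance), str(r.kind))
        for r in df.itertuples()
    ]
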