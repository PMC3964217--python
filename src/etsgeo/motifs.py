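"""Oriented motif scanning and 7-mer over-representation.

Motif patterns are IUPAC strings (default the canonical ETS 7-mer CCGGAAG,
the GGAA-core element bound by ETS-family factors).  Scanning reports every
occurrence, including overlapping ones, on both strands: a ``-`` strand hit is
a position where the reverse complement of the pattern matches the forward
sequence.  Offsets are 0-based positions of the match start on the forward
sequence; ``matched`` is the forward-sequence slice.

Over-representation compares presence/absence of each of the 4^7 7-mers
(either strand) between bound-promoter sequences and the full promoter
universe with an upper-tail hypergeometric test; raw and Bonferroni-adjusted
p-values are both reported.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import hypergeom_upper

log = logging.getLogger(__name__)

DEFAULT_PATTERN = "CCGGAAG"
KMER_LEN = 7

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int  # match start on the forward sequence, 0-based
    strand: str
    matched: str

    def center(self, motif_len: int | None = None) -> int:
        n = motif_len if motif_len is not None else len(self.matched)
        return self.offset + n // 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern {pattern!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all reported; N in the
    # sequence never matches because the classes list ACGT only
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    seq: str, pattern: str = DEFAULT_PATTERN, region_id: str = ""
) -> list[MotifHit]:
    """All occurrences of ``pattern`` on both strands of ``seq`` (IUPAC-aware,
    overlapping matches included), sorted by offset."""
    seq = seq.upper()
    hits = [
        MotifHit(region_id, m.start(), "+", m.group(1))
        for m in _iupac_regex(pattern).finditer(seq)
    ]
    rc = reverse_complement(pattern)
    hits += [
        MotifHit(region_id, m.start(), "-", m.group(1))
        for m in _iupac_regex(rc).finditer(seq)
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def motif_count(hits: Iterable[MotifHit]) -> int:
    """Total motif occurrences in one promoter, regardless of strand."""
    return sum(1 for _ in hits)


def count_per_region(hits: Iterable[MotifHit]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.region_id] = counts.get(h.region_id, 0) + 1
    return counts


def _two_strand_kmer_set(seq: str, k: int) -> set[str]:
    """Distinct k-mers present on either strand of ``seq`` (ACGT only; a k-mer
    counts as present if it or its reverse complement occurs forward)."""
    seq = seq.upper()
    fwd = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w and set(w) <= set("ACGT"):
            fwd.add(w)
    return fwd | {reverse_complement(w) for w in fwd}


def enrich_7mers(
    bound_seqs: Mapping[str, str],
    all_seqs: Mapping[str, str],
    k: int = KMER_LEN,
) -> pd.DataFrame:
    """Rank every k-mer by upper-tail hypergeometric over-representation in
    bound promoters relative to the full promoter universe.

    Returns a DataFrame (kmer, bound_with, all_with, n_bound, n_all, p_value,
    p_bonferroni) sorted ascending by p-value.
    """
    missing = set(bound_seqs) - set(all_seqs)
    if missing:
        raise ValueError(f"bound ids not in universe: {sorted(missing)[:5]}")

    all_counts: dict[str, int] = {}
    bound_counts: dict[str, int] = {}
    n_all = n_bound = 0
    for rid, seq in all_seqs.items():
        if len(seq) < k:
            log.warning("sequence %s shorter than %d; skipped", rid, k)
            continue
        present = _two_strand_kmer_set(seq, k)
        n_all += 1
        for w in present:
            all_counts[w] = all_counts.get(w, 0) + 1
        if rid in bound_seqs:
            n_bound += 1
            for w in present:
                bound_counts[w] = bound_counts.get(w, 0) + 1

    n_tests = 4 ** k
    rows = []
    for kmer in ("".join(t) for t in itertools.product("ACGT", repeat=k)):
        K = all_counts.get(kmer, 0)
        x = bound_counts.get(kmer, 0)
        p = hypergeom_upper(n_all, K, n_bound, x) if x > 0 else 1.0
        rows.append((kmer, x, K, n_bound, n_all, p, min(1.0, p * n_tests)))
    df = pd.DataFrame(
        rows,
        columns=["kmer", "bound_with", "all_with", "n_bound", "n_all", "p_value", "p_bonferroni"],
    )
    return df.sort_values(["p_value", "kmer"], kind="mergesort").reset_index(drop=True)


def hits_to_bed(hits: Sequence[MotifHit], path, motif_len: int = KMER_LEN) -> None:
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.region_id, h.offset)):
            fh.write(
                f"{h.region_id}\t{h.offset}\t{h.offset + motif_len}\t{h.matched}\t0\t{h.strand}\n"
            )
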