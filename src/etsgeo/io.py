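"""FASTA I/O thin wrappers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seqs[k]), id=k, description="") for k in sorted(seqs)]
    SeqIO.write(records, str(path), "fasta")
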