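"""FASTA sequence summaries (length and GC content).

A small utility for reporting the descriptive statistics of barcode
sequences (e.g. a mitochondrial 12S rRNA fragment deposited alongside a
survey): sequence length in bases and GC fraction.  GC is computed over
unambiguous bases only — (G+C)/(A+C+G+T), with U counted as T and
N/ambiguity codes excluded from both numerator and denominator — so the
reported fraction is insensitive to the number of undetermined positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import BioloadError


@dataclass(frozen=True)
class SequenceSummary:
    id: str
    length: int
    gc_fraction: float

    def __post_init__(self):
        if self.length < 1:
            raise BioloadError(f"sequence {self.id!r} is empty")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise BioloadError(f"gc_fraction out of [0, 1] for {self.id!r}")


def summarize_sequence(seq_id: str, sequence: str) -> SequenceSummary:
    """Summary of one sequence string (case- and wrap-insensitive)."""
    s = sequence.upper().replace("U", "T")
    if len(s) == 0:
        raise BioloadError(f"sequence {seq_id!r} is empty")
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    gc_fraction = gc / denom if denom else 0.0
    return SequenceSummary(id=seq_id, length=len(s), gc_fraction=gc_fraction)


def summarize_fasta(path: str | Path) -> list[SequenceSummary]:
    """Summaries for every record in a FASTA file, in file order.

    Raises :class:`BioloadError` naming the record if a sequence is empty,
    and propagates I/O errors for unreadable paths.
    """
    path = Path(path)
    summaries = [
        summarize_sequence(record.id, str(record.seq))
        for record in SeqIO.parse(path, "fasta")
    ]
    if not summaries:
        raise BioloadError(f"no FASTA records in {path}")
    return summaries
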