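"""Read-quality filtering for FASTQ input.

The pooled-sequencing pipeline retains only reads with at most five bases
below Phred quality 20 before any downstream use.  Parsing is delegated to
Biopython's FASTQ reader (Phred+33, the modern Illumina encoding).
"""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .errors import FormatError


def filter_reads(
    records: Iterable[SeqRecord],
    max_low_qual: int = 5,
    qual_threshold: int = 20,
) -> Iterator[SeqRecord]:
    """Yield reads with at most ``max_low_qual`` bases of quality below
    ``qual_threshold``, preserving input order.

    The threshold is strict: a base at exactly ``qual_threshold`` is not
    counted as low quality.
    """
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise FormatError(
                f"read {rec.id!r}: quality string does not match sequence length"
            )
        n_low = sum(1 for q in quals if q < qual_threshold)
        if n_low <= max_low_qual:
            yield rec


def filter_fastq_file(
    in_path,
    out_path,
    max_low_qual: int = 5,
    qual_threshold: int = 20,
) -> tuple[int, int]:
    """Filter a FASTQ file on disk; returns (reads_in, reads_kept)."""
    n_in = 0

    def _counted():
        nonlocal n_in
        for rec in SeqIO.parse(in_path, "fastq"):
            n_in += 1
            yield rec

    n_kept = SeqIO.write(
        filter_reads(_counted(), max_low_qual, qual_threshold), out_path, "fastq"
    )
    return n_in, n_kept
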