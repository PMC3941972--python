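"""Read quality trimming and filtering.

Two rules, applied in order to each read:

1. trim: remove the maximal 3'-terminal run of bases with quality below
   a threshold, capped at a maximum trim length (default 16 bp).
2. filter: discard the trimmed read if it still carries more than a
   maximum number of bases below the threshold (default: more than 2
   bases under Q20), or if it has become shorter than a minimum length.

Trimming is run-based (a contiguous low-quality 3' tail), not windowed.
Phred+33 is the only supported encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import FastqRead


@dataclass
class QCParams:
    max_3prime_trim: int = 16
    qual_threshold: int = 20
    max_low_qual_bases: int = 2
    min_length_after_trim: int = 0

    def __post_init__(self) -> None:
        if min(self.max_3prime_trim, self.max_low_qual_bases,
               self.min_length_after_trim) < 0:
            raise ValueError("QC parameters must be non-negative")
        if not 0 <= self.qual_threshold <= 93:
            raise ValueError("qual_threshold must be in [0, 93]")


def trim_3prime(read: FastqRead, params: QCParams) -> FastqRead:
    """Remove up to max_3prime_trim 3'-terminal bases with quality below
    qual_threshold.  Internal low-quality bases are never touched."""
    quals = read.qualities
    n = len(quals)
    run = 0
    while run < n and quals[n - 1 - run] < params.qual_threshold:
        run += 1
    cut = min(run, params.max_3prime_trim)
    if cut == 0:
        return read
    keep = n - cut
    return FastqRead(read.id, read.sequence[:keep], quals[:keep])


def filter_read(read: FastqRead, params: QCParams) -> bool:
    """True iff the (already trimmed) read should be kept."""
    if len(read.sequence) < params.min_length_after_trim:
        return False
    low = sum(1 for q in read.qualities if q < params.qual_threshold)
    return low <= params.max_low_qual_bases


@dataclass
class QCSummary:
    n_input: int = 0
    n_trimmed: int = 0
    n_discarded: int = 0

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_discarded


def qc_pipeline(
    reads: Iterable[FastqRead], params: QCParams | None = None,
    summary: QCSummary | None = None,
) -> Iterator[FastqRead]:
    """Trim then filter a read stream, order-preserving.

    Pass a QCSummary to collect input / trimmed / discarded counts as the
    stream is consumed.
    """
    params = params or QCParams()
    for i, read in enumerate(reads):
        if len(read.sequence) != len(read.qualities):
            raise ValueError(f"malformed FASTQ record at index {i}: {read.id}")
        if summary is not None:
            summary.n_input += 1
        trimmed = trim_3prime(read, params)
        if summary is not None and len(trimmed.sequence) < len(read.sequence):
            summary.n_trimmed += 1
        if filter_read(trimmed, params):
            yield trimmed
        elif summary is not None:
            summary.n_discarded += 1
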