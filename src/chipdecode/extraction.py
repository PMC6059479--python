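"""Parse amplicon reads: locate the constant region, slice index and barcode.

This is the counting step of the screen: every sequencing read is scanned for
the amplicon's constant region (the anchor); on a hit, the sample index and
the clone barcode are read off at fixed offsets and tallied into a
barcode x index count matrix.  Reads without a recognisable anchor, reads too
short to contain the configured intervals, and reads with non-ACGT bases in
the sliced intervals are tallied by rejection reason, never silently dropped.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import AmpliconDesign
from .matrix import (BarcodeCountMatrix, REJECT_AMBIGUOUS, REJECT_NO_ANCHOR,
                     REJECT_TRUNCATED)

_VALID = frozenset("ACGT")


class FastqFormatError(ValueError):
    """Raised when a FASTQ record cannot be parsed."""


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def locate_anchor(read: str, design: AmpliconDesign) -> Optional[int]:
    """Leftmost start of the constant region within the search window.

    Positions are scanned left to right; the first position where the anchor
    matches with at most ``design.max_anchor_mismatches`` substitutions wins
    (so ties resolve leftmost).  Returns ``None`` when no window matches.
    """
    if not read:
        raise ValueError("read must be nonempty")
    anchor = design.constant_region
    k = len(anchor)
    lo, hi = design.search_window
    stop = min(hi, len(read) - k + 1)
    mm = design.max_anchor_mismatches
    for p in range(lo, stop):
        seg = read[p:p + k]
        if seg == anchor:
            return p
        if mm and _mismatches(seg, anchor, mm) <= mm:
            return p
    return None


def extract_read(read: str, design: AmpliconDesign
                 ) -> Union[Tuple[str, str], str]:
    """Extract ``(index, barcode)`` from one read, or a rejection reason.

    Rejection reasons are ``"no-anchor"`` (constant region not found),
    ``"truncated"`` (an interval runs off the read) and ``"ambiguous-base"``
    (a non-ACGT base inside an interval).
    """
    pos = locate_anchor(read, design)
    if pos is None:
        return REJECT_NO_ANCHOR
    pieces = []
    for start, end in (design.index_interval(pos), design.barcode_interval(pos)):
        if start < 0 or end > len(read):
            return REJECT_TRUNCATED
        seg = read[start:end]
        if set(seg) - _VALID:
            return REJECT_AMBIGUOUS
        pieces.append(seg)
    return pieces[0], pieces[1]


def _iter_sequences(reads, design) -> Iterator[str]:
    """Yield raw sequences from a path, open handle, or iterable of strings."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from _iter_fastq(fh)
    elif hasattr(reads, "read"):
        yield from _iter_fastq(reads)
    else:
        yield from reads


def _iter_fastq(handle) -> Iterator[str]:
    record_no = 0
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            record_no += 1
            yield seq
    except ValueError as exc:
        raise FastqFormatError(
            f"malformed FASTQ near record {record_no + 1}: {exc}") from exc


def count_barcodes(reads, design: AmpliconDesign) -> BarcodeCountMatrix:
    """Tally a barcode x index count matrix from a FASTQ stream.

    ``reads`` may be a path to a FASTQ/FASTQ.gz file, an open text handle, or
    any iterable of read sequences.  Streaming: memory scales with the number
    of distinct (barcode, index) pairs, not with read count.
    """
    matrix = BarcodeCountMatrix()
    for seq in _iter_sequences(reads, design):
        result = extract_read(seq, design)
        if isinstance(result, tuple):
            matrix.add(result[1], result[0])
        else:
            matrix.reject(result)
    return matrix
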