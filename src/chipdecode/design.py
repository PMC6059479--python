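"""Amplicon geometry: where the sample index and clone barcode sit in a read.

Every amplicon in a barcode-ChIP screen shares one constant region (the
"anchor", a stretch of the reporter cassette adjacent to the barcode).  Reads
are parsed by locating the anchor and slicing the sample index and the clone
barcode at fixed offsets on either side of it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Tuple

import yaml

_VALID_BASES = frozenset("ACGT")
_INDEX_LENGTHS = (6, 12)
_BARCODE_LENGTHS = (15, 20)


@dataclass(frozen=True)
class AmpliconDesign:
    """Geometry of a barcode amplicon.

    Parameters
    ----------
    name
        Locus label, e.g. ``"BC_UP"``, ``"BC_DN"`` or ``"BC_5p_ADE2"``.
    constant_region
        Uppercase ACGT anchor sequence searched for in each read.
    index_length
        Length of the pool/sample index (6 or 12 bases).
    index_side
        ``"upstream"`` or ``"downstream"`` of the anchor.
    index_offset
        Gap in bases between the anchor and the index interval.
    barcode_length
        Length of the clone barcode (20 for the reporter-cassette barcodes,
        15 for the CRISPR-inserted barcodes).
    barcode_side, barcode_offset
        As for the index.
    max_anchor_mismatches
        Substitutions tolerated when locating the anchor.
    search_window
        Half-open range of read positions at which the anchor may start.
    """

    name: str
    constant_region: str
    index_length: int = 6
    index_side: str = "upstream"
    index_offset: int = 0
    barcode_length: int = 20
    barcode_side: str = "downstream"
    barcode_offset: int = 0
    max_anchor_mismatches: int = 1
    search_window: Tuple[int, int] = (0, 30)

    def __post_init__(self) -> None:
        if not self.constant_region or set(self.constant_region) - _VALID_BASES:
            raise ValueError("constant_region must be nonempty uppercase ACGT")
        if self.index_length not in _INDEX_LENGTHS:
            raise ValueError(f"index_length must be one of {_INDEX_LENGTHS}")
        if self.barcode_length not in _BARCODE_LENGTHS:
            raise ValueError(f"barcode_length must be one of {_BARCODE_LENGTHS}")
        for side in (self.index_side, self.barcode_side):
            if side not in ("upstream", "downstream"):
                raise ValueError("sides must be 'upstream' or 'downstream'")
        if self.index_offset < 0 or self.barcode_offset < 0:
            raise ValueError("offsets must be nonnegative")
        lo, hi = self.search_window
        if lo < 0 or hi <= lo:
            raise ValueError("search_window must be a nonempty half-open range")

    # -- interval helpers (0-based, half-open) -------------------------------

    def index_interval(self, anchor_start: int) -> Tuple[int, int]:
        return self._interval(anchor_start, self.index_side,
                              self.index_offset, self.index_length)

    def barcode_interval(self, anchor_start: int) -> Tuple[int, int]:
        return self._interval(anchor_start, self.barcode_side,
                              self.barcode_offset, self.barcode_length)

    def _interval(self, anchor_start: int, side: str, offset: int,
                  length: int) -> Tuple[int, int]:
        if side == "upstream":
            end = anchor_start - offset
            return end - length, end
        start = anchor_start + len(self.constant_region) + offset
        return start, start + length

    def with_mismatches(self, max_anchor_mismatches: int) -> "AmpliconDesign":
        return replace(self, max_anchor_mismatches=max_anchor_mismatches)

    # -- serialisation -------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["search_window"] = list(self.search_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AmpliconDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["search_window"] = tuple(d["search_window"])
        return cls(**d)


# Example designs used by the simulator and the CLI.  The anchor sequences are
# synthetic stand-ins with the right geometry (real cassette anchors are
# project-specific); real screens should supply their own design file.
KANMX_UP = AmpliconDesign(name="BC_UP", constant_region="ACGTTGGACTAGCCATGACG",
                          index_length=6, barcode_length=20)
KANMX_DN = AmpliconDesign(name="BC_DN", constant_region="TGACCAGTTCGGATACCTGA",
                          index_length=6, barcode_length=20)
ADE2_5P = AmpliconDesign(name="BC_5p_ADE2", constant_region="GATTCCAGCTAGGCATTGCA",
                         index_length=6, barcode_length=15)

BUILTIN_DESIGNS = {d.name: d for d in (KANMX_UP, KANMX_DN, ADE2_5P)}
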