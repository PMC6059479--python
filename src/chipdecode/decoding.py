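"""Decode barcode -> well positions from row/column pool sequencing.

An arrayed 384-well library is pooled once per row (16 pools) and once per
column (24 pools) per plate, and each pool is sequenced.  A barcode called in
exactly one row pool and one column pool of the same plate is assigned to the
intersecting well.  Barcodes matching more than one (row, column) pair are
rejected as multimatches; wells claimed by more than one barcode reject all
their claimants as collisions; barcodes with partial support (one axis only)
remain unassigned.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import pandas as pd

from .matrix import BarcodeCountMatrix

STATUS_ASSIGNED = "assigned"
STATUS_MULTIMATCH = "rejected-multimatch"
STATUS_COLLISION = "rejected-collision"
STATUS_UNASSIGNED = "unassigned"


@dataclass
class PoolIndexMap:
    """Pool metadata: pool_id -> (plate, axis, label) and optional index."""

    table: pd.DataFrame  # columns: pool_id, plate, axis, label[, index]

    def __post_init__(self) -> None:
        t = self.table
        required = {"pool_id", "plate", "axis", "label"}
        if not required <= set(t.columns):
            raise ValueError(f"pool map needs columns {sorted(required)}")
        if t["pool_id"].duplicated().any():
            raise ValueError("duplicate pool_id in pool map")
        if t[["plate", "axis", "label"]].duplicated().any():
            raise ValueError("duplicate (plate, axis, label) in pool map")
        bad = set(t["axis"]) - {"row", "col"}
        if bad:
            raise ValueError(f"unknown axis values: {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path) -> "PoolIndexMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"label": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def pools(self, axis: str) -> pd.DataFrame:
        return self.table[self.table["axis"] == axis]

    def index_to_pool(self) -> Dict[str, str]:
        if "index" not in self.table.columns:
            raise ValueError("pool map has no 'index' column")
        return dict(zip(self.table["index"], self.table["pool_id"]))


@dataclass
class WellCall:
    status: str
    plate: Optional[int] = None
    row: Optional[str] = None
    col: Optional[int] = None
    row_reads: int = 0
    col_reads: int = 0


@dataclass
class WellAssignment:
    """Per-barcode decode calls plus unknown-pool warnings."""

    calls: Dict[str, WellCall] = field(default_factory=dict)
    unknown_pools: Dict[str, int] = field(default_factory=dict)

    def by_status(self, status: str) -> Set[str]:
        return {b for b, c in self.calls.items() if c.status == status}

    @property
    def assigned(self) -> Dict[str, Tuple[int, str, int]]:
        return {b: (c.plate, c.row, c.col) for b, c in self.calls.items()
                if c.status == STATUS_ASSIGNED}


def call_pool_barcodes(pool_counts: BarcodeCountMatrix, min_reads: int = 50,
                       ) -> Dict[str, Set[str]]:
    """Call the barcode set of each pool by a read-count floor.

    A barcode is called in a pool iff its count there is at least
    ``min_reads`` (presets from the original screens: 50 or 100).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    calls: Dict[str, Set[str]] = defaultdict(set)
    for (bc, pool), n in pool_counts.counts.items():
        if n >= min_reads:
            calls[pool].add(bc)
    return dict(calls)


def split_calls(calls: Mapping[str, Set[str]], pool_map: PoolIndexMap,
                ) -> Tuple[Dict[str, Set[str]], Dict[str, Set[str]],
                           Dict[str, int]]:
    """Split per-pool calls into row and column pools; tally unknown pools."""
    axis_of = dict(zip(pool_map.table["pool_id"], pool_map.table["axis"]))
    row_calls: Dict[str, Set[str]] = {}
    col_calls: Dict[str, Set[str]] = {}
    unknown: Dict[str, int] = {}
    for pool, bcs in calls.items():
        axis = axis_of.get(pool)
        if axis == "row":
            row_calls[pool] = set(bcs)
        elif axis == "col":
            col_calls[pool] = set(bcs)
        else:
            unknown[pool] = len(bcs)
            warnings.warn(f"pool {pool!r} absent from pool map; ignored")
    return row_calls, col_calls, unknown


def decode_coordinates(row_calls: Mapping[str, Set[str]],
                       col_calls: Mapping[str, Set[str]],
                       pool_map: PoolIndexMap,
                       pool_counts: Optional[BarcodeCountMatrix] = None,
                       ) -> WellAssignment:
    """Intersect row and column calls into well assignments.

    (row, column) pairs are only formed within one plate's pools.  A barcode
    with exactly one matching pair is tentatively assigned; more than one
    pair rejects it as a multimatch; support on one axis only leaves it
    unassigned.  Wells tentatively claimed by more than one barcode then
    reject all their claimants as collisions.
    """
    meta = {r.pool_id: (r.plate, r.axis, r.label)
            for r in pool_map.table.itertuples(index=False)}
    for pool in list(row_calls) + list(col_calls):
        if pool not in meta:
            raise KeyError(f"pool {pool!r} not covered by pool map")

    # barcode -> set of (plate, row_label, col_label)
    pairs: Dict[str, Set[Tuple[int, str, int]]] = defaultdict(set)
    seen: Set[str] = set()
    # group pools per plate
    by_plate_rows: Dict[int, Dict[str, Set[str]]] = defaultdict(dict)
    by_plate_cols: Dict[int, Dict[str, Set[str]]] = defaultdict(dict)
    for pool, bcs in row_calls.items():
        plate, _, label = meta[pool]
        by_plate_rows[plate][label] = bcs
        seen |= bcs
    for pool, bcs in col_calls.items():
        plate, _, label = meta[pool]
        by_plate_cols[plate][label] = bcs
        seen |= bcs
    for plate, rows in by_plate_rows.items():
        cols = by_plate_cols.get(plate, {})
        for rlabel, rset in rows.items():
            for clabel, cset in cols.items():
                for bc in rset & cset:
                    pairs[bc].add((plate, rlabel, int(clabel)))

    assignment = WellAssignment()
    tentative: Dict[Tuple[int, str, int], list] = defaultdict(list)
    for bc in sorted(seen):
        matched = pairs.get(bc, set())
        if len(matched) == 1:
            plate, row, col = next(iter(matched))
            tentative[(plate, row, col)].append(bc)
        elif len(matched) > 1:
            assignment.calls[bc] = WellCall(STATUS_MULTIMATCH)
        else:
            assignment.calls[bc] = WellCall(STATUS_UNASSIGNED)

    for (plate, row, col), bcs in tentative.items():
        status = STATUS_ASSIGNED if len(bcs) == 1 else STATUS_COLLISION
        for bc in bcs:
            call = WellCall(status, plate, row, col)
            if status == STATUS_COLLISION:
                call = WellCall(status)
            assignment.calls[bc] = call

    if pool_counts is not None:
        _attach_support(assignment, pool_counts, meta)
    return assignment


def _attach_support(assignment: WellAssignment,
                    pool_counts: BarcodeCountMatrix, meta) -> None:
    row_support: Dict[str, int] = defaultdict(int)
    col_support: Dict[str, int] = defaultdict(int)
    for (bc, pool), n in pool_counts.counts.items():
        if pool not in meta:
            continue
        axis = meta[pool][1]
        if axis == "row":
            row_support[bc] += n
        else:
            col_support[bc] += n
    for bc, call in assignment.calls.items():
        call.row_reads = row_support.get(bc, 0)
        call.col_reads = col_support.get(bc, 0)


def decode_report(assignment: WellAssignment,
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise a decode: per-plate status counts and a full plate map.

    Returns ``(summary, plate_map)``; the plate map has one row per barcode
    (plate/row/col empty for non-assigned statuses) and is TSV-ready.
    """
    rows = [(c.plate, c.row, c.col, bc, c.status, c.row_reads, c.col_reads)
            for bc, c in sorted(assignment.calls.items())]
    plate_map = pd.DataFrame(rows, columns=["plate", "row", "col", "barcode",
                                            "status", "row_reads",
                                            "col_reads"])
    summary = (plate_map.groupby("status", dropna=False)
               .size().rename("barcodes").reset_index())
    return summary, plate_map
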