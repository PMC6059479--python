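"""From raw barcode counts to normalized per-factor binding scores.

The chain mirrors the screen's preprocessing: a raw-count floor, mapping of
barcode-index cells to factor x sample tables via the strain map and sample
sheet, per-sample median normalization (each plate/sample was amplified and
indexed separately, so sequencing yield differs), log2(IP/input) per
replicate, and finally rank-mean quantile normalization across replicate
score vectors to equalise their dynamic range.  Each barcoded locus is
processed separately; no between-locus normalization is performed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import BarcodeCountMatrix


# -- sample sheet ------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"index": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"index", "plate", "fraction", "condition", "replicate"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if sheet["index"].duplicated().any():
        raise ValueError("duplicate sample index in sheet")
    key = sheet[["plate", "fraction", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (plate, fraction, condition, replicate)")
    bad = set(sheet["fraction"]) - {"IP", "input"}
    if bad:
        raise ValueError(f"fraction must be IP or input, got {sorted(bad)}")
    return sheet


# -- factor tables -----------------------------------------------------------

def counts_to_factor_table(matrix: BarcodeCountMatrix,
                           strain_map: pd.DataFrame,
                           sheet: pd.DataFrame) -> pd.DataFrame:
    """Factor x sample wide table (NaN = absent) for one locus.

    ``strain_map`` has columns barcode, orf (one locus); cells whose barcode
    or index is not in the maps are dropped (they belong to other loci or
    stray sequences).
    """
    orf_of = dict(zip(strain_map["barcode"], strain_map["orf"]))
    known_idx = set(sheet["index"])
    rows = [(orf_of[bc], idx, n) for (bc, idx), n in matrix.counts.items()
            if bc in orf_of and idx in known_idx]
    if not rows:
        return pd.DataFrame(columns=sorted(known_idx))
    long = pd.DataFrame(rows, columns=["factor", "index", "count"])
    wide = long.pivot_table(index="factor", columns="index", values="count",
                            aggfunc="sum")
    return wide.reindex(columns=[i for i in sheet["index"] if i in wide])


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Equalise per-sample medians by a multiplicative rescale of raw counts.

    Each column is scaled by (reference median / its median of present
    values), where the reference is the median of all per-column medians.
    """
    medians = table.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no present counts: {bad}")
    reference = float(np.median(medians.to_numpy()))
    return table * (reference / medians)


def remove_low_input(table: pd.DataFrame, sheet: pd.DataFrame,
                     min_input: int = 10,
                     min_replicates: Optional[int] = None) -> pd.DataFrame:
    """Drop factors whose input counts are too low to trust.

    A factor is kept only if its raw input count reaches ``min_input`` in at
    least ``min_replicates`` replicates (default: all but two); such factors
    are otherwise likely missing from the library or failed to amplify.
    Removal is whole-factor.
    """
    if min_input < 0:
        raise ValueError("min_input must be >= 0")
    input_idx = sheet.loc[sheet["fraction"] == "input", "index"]
    input_cols = [i for i in input_idx if i in table.columns]
    n_reps = len(input_idx)
    if min_replicates is None:
        min_replicates = max(1, n_reps - 2)
    ok = (table[input_cols].fillna(-1) >= min_input).sum(axis=1)
    return table.loc[ok >= min_replicates]


def log2_scores(table: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate binding scores: log2(IP) - log2(input).

    IP and input samples are paired by (plate, condition, replicate); result
    columns are labelled ``{condition}_r{replicate}`` (prefixed with the
    plate when several plates are present).  Scores are absent wherever
    either fraction is absent.
    """
    key_cols = ["plate", "condition", "replicate"]
    pivot = sheet.pivot_table(index=key_cols, columns="fraction",
                              values="index", aggfunc="first")
    orphans = pivot[pivot.isna().any(axis=1)]
    if len(orphans):
        raise ValueError(f"unpaired samples: {list(orphans.index)}")
    multi_plate = sheet["plate"].nunique() > 1
    scores = {}
    for (plate, condition, replicate), row in pivot.iterrows():
        ip, inp = row["IP"], row["input"]
        label = f"{condition}_r{replicate}"
        if multi_plate:
            label = f"p{plate}_{label}"
        ip_col = table[ip] if ip in table.columns else np.nan
        in_col = table[inp] if inp in table.columns else np.nan
        scores[label] = np.log2(ip_col) - np.log2(in_col)
    return pd.DataFrame(scores, index=table.index)


def quantile_normalize(panel: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across replicate columns.

    Each column's values are ranked and the value at every rank replaced by
    the mean across columns of that rank's value, so all columns share one
    distribution afterwards.  Ties take the mean of the tied positions
    (average-rank convention).  Missing values stay missing and are excluded
    from the rank-mean computation; columns with unequal numbers of present
    values contribute via interpolation of their sorted values onto a common
    quantile grid.
    """
    if panel.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 replicates")
    sorted_cols = []
    n_present = []
    for col in panel.columns:
        v = panel[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"column {col!r} has no present values")
        sorted_cols.append(np.sort(v))
        n_present.append(v.size)

    n_ref = max(n_present)
    grid = (np.arange(n_ref) + 0.5) / n_ref
    ref = np.zeros(n_ref)
    for v in sorted_cols:
        q = (np.arange(v.size) + 0.5) / v.size
        ref += np.interp(grid, q, v)
    ref /= len(sorted_cols)

    out = panel.copy()
    for col in panel.columns:
        mask = panel[col].notna()
        v = panel.loc[mask, col].to_numpy(dtype=float)
        # average ranks map tied values to the mean of their positions
        ranks = rankdata(v, method="average")
        q = (ranks - 0.5) / v.size
        out.loc[mask, col] = np.interp(q, grid, ref)
    return out


def binding_scores(matrix: BarcodeCountMatrix, sheet: pd.DataFrame,
                   strain_map: pd.DataFrame, min_count: int = 10,
                   min_input: int = 10,
                   min_replicates: Optional[int] = None,
                   quantile_on: str = "scores",
                   ) -> pd.DataFrame:
    """Full chain: floor, map, filter, normalize, log-ratio, quantile.

    ``quantile_on`` selects where quantile normalization acts: on the
    per-replicate score vectors (default) or on the normalized counts
    (``"counts"``), or not at all (``"none"``).
    """
    if quantile_on not in ("scores", "counts", "none"):
        raise ValueError("quantile_on must be scores|counts|none")
    floored = matrix.filter_min_count(min_count)
    table = counts_to_factor_table(floored, strain_map, sheet)
    table = remove_low_input(table, sheet, min_input, min_replicates)
    table = median_normalize(table)
    if quantile_on == "counts":
        table = quantile_normalize(table)
    panel = log2_scores(table, sheet)
    if quantile_on == "scores":
        panel = quantile_normalize(panel)
    return panel
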