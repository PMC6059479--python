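"""The barcode x sample-index count matrix, the pipeline's central table."""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Tuple

import pandas as pd

#: rejection reasons tallied during extraction
REJECT_NO_ANCHOR = "no-anchor"
REJECT_TRUNCATED = "truncated"
REJECT_AMBIGUOUS = "ambiguous-base"
REJECTION_REASONS = (REJECT_NO_ANCHOR, REJECT_TRUNCATED, REJECT_AMBIGUOUS)


class BarcodeCountMatrix:
    """Sparse integer counts keyed by (barcode sequence, sample index).

    Also carries a tally of rejected reads by reason, so that
    ``n_accepted + n_rejected == reads processed`` always holds.
    """

    def __init__(self,
                 counts: Mapping[Tuple[str, str], int] | None = None,
                 rejected: Mapping[str, int] | None = None) -> None:
        self.counts: Counter = Counter()
        if counts:
            for key, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative count for {key}")
                if n:
                    self.counts[key] = int(n)
        self.rejected: Counter = Counter(rejected or {})

    # -- accumulation --------------------------------------------------------

    def add(self, barcode: str, index: str, n: int = 1) -> None:
        self.counts[(barcode, index)] += n

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejected[reason] += n

    # -- summaries -----------------------------------------------------------

    @property
    def n_accepted(self) -> int:
        return sum(self.counts.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def n_reads(self) -> int:
        return self.n_accepted + self.n_rejected

    def barcodes(self) -> set:
        return {b for b, _ in self.counts}

    def sample_indexes(self) -> set:
        return {i for _, i in self.counts}

    # -- transforms ----------------------------------------------------------

    def filter_min_count(self, threshold: int = 10) -> "BarcodeCountMatrix":
        """Drop every cell with count below ``threshold``.

        The raw-count floor applied before any normalization; cells below the
        floor become absent, not zero.
        """
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        kept = {k: v for k, v in self.counts.items() if v >= threshold}
        return BarcodeCountMatrix(kept, dict(self.rejected))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns barcode, index, count (sorted)."""
        rows = sorted((b, i, n) for (b, i), n in self.counts.items())
        return pd.DataFrame(rows, columns=["barcode", "index", "count"])

    def to_wide(self) -> pd.DataFrame:
        """Barcode x index pivot with absent cells as NaN."""
        df = self.to_frame()
        return df.pivot(index="barcode", columns="index", values="count")

    def rejection_summary(self) -> pd.DataFrame:
        rows = [(r, self.rejected.get(r, 0)) for r in REJECTION_REASONS]
        extra = sorted(set(self.rejected) - set(REJECTION_REASONS))
        rows += [(r, self.rejected[r]) for r in extra]
        return pd.DataFrame(rows, columns=["reason", "reads"])

    # -- IO ------------------------------------------------------------------

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BarcodeCountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "index": str})
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BarcodeCountMatrix":
        m = cls()
        for b, i, n in df[["barcode", "index", "count"]].itertuples(index=False):
            m.add(str(b), str(i), int(n))
        return m

    def __eq__(self, other) -> bool:
        if not isinstance(other, BarcodeCountMatrix):
            return NotImplemented
        return self.counts == other.counts and self.rejected == other.rejected

    def __repr__(self) -> str:
        return (f"BarcodeCountMatrix({len(self.counts)} cells, "
                f"{self.n_accepted} accepted, {self.n_rejected} rejected)")
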