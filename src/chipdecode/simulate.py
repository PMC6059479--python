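"""Ground-truthed simulation of a barcoded TAP-tag ChIP screen.

The generator emulates the experimental design end to end: an arrayed library
of ~4,000 barcoded, TAP-tagged strains on 384-well plates; IP and input
sequencing counts with multiplicative log2 enrichment effects and negative
binomial overdispersion; single-end amplicon reads (index + constant region +
barcode) with i.i.d. substitution errors; and row/column pooling of plates for
positional decoding.  Everything is deterministic given the seed, so the
truth object doubles as the oracle for round-trip and recovery tests.

Model summary
-------------
* input count ~ NegBin(mean = depth * abundance_g / sum(abundance)), with
  abundance log-normal across strains;
* IP count ~ NegBin(mean = input-mean * 2**effect_g * scale_r), where effect_g
  is 0 for non-binders and truncated-Normal(effect_mean, effect_sd) >= 0 for
  binders, and scale_r is a per-IP-sample log-uniform factor in [0.5, 2] that
  exercises the median normalization downstream;
* NegBin dispersion alpha gives variance mu + alpha*mu^2 and reduces to
  Poisson at alpha = 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .design import AmpliconDesign
from .matrix import BarcodeCountMatrix

PLATE_ROWS = "ABCDEFGHIJKLMNOP"          # 16 rows
PLATE_COLS = tuple(range(1, 25))         # 24 columns
WELLS_PER_PLATE = len(PLATE_ROWS) * len(PLATE_COLS)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# spawn-key tags giving each simulation stage its own independent stream
_TAG_LIBRARY, _TAG_INDEXES, _TAG_COUNTS, _TAG_READS, _TAG_POOLS = range(5)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(tag,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults describe the reference experiment: a ~4,000-strain library
    screened in 6 biological replicates at 1e6 reads per sample, with ~12%
    of strains true binders at log2 effects around 1.
    """

    n_strains: int = 4000
    n_replicates: int = 6
    depth: float = 1_000_000.0
    dispersion: float = 0.05
    error_rate: float = 0.001
    frac_binders: float = 0.12
    effect_mean: float = 1.0
    effect_sd: float = 0.5
    abundance_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_replicates < 1:
            raise ValueError("n_strains and n_replicates must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if not 0 <= self.frac_binders <= 1:
            raise ValueError("frac_binders must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated library.

    ``strains`` is a DataFrame with one row per strain: strain_id, orf,
    plate, row, col, abundance, and per-locus columns ``barcode_<locus>``
    and ``effect_<locus>``.
    """

    strains: pd.DataFrame
    loci: List[str]
    seed: int

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def barcodes(self, locus: Optional[str] = None) -> pd.Series:
        locus = locus or self.loci[0]
        return self.strains[f"barcode_{locus}"]

    def effects(self, locus: Optional[str] = None) -> pd.Series:
        locus = locus or self.loci[0]
        return self.strains[f"effect_{locus}"]

    def strain_map(self, locus: Optional[str] = None) -> pd.DataFrame:
        """Barcode -> ORF map for one locus (TSV-ready)."""
        locus = locus or self.loci[0]
        return pd.DataFrame({
            "barcode": self.barcodes(locus),
            "orf": self.strains["orf"],
            "locus": locus,
        })

    def write_tsv(self, path) -> None:
        self.strains.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, seed: int = -1) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t")
        loci = [c[len("barcode_"):] for c in df.columns
                if c.startswith("barcode_")]
        return cls(strains=df, loci=loci, seed=seed)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (self.loci == other.loci and self.seed == other.seed
                and self.strains.equals(other.strains))


def _random_unique_barcodes(rng: np.random.Generator, n: int, length: int,
                            max_redraws: int = 100) -> List[str]:
    seen: set = set()
    out: List[str] = []
    for _ in range(n):
        for attempt in range(max_redraws + 1):
            bc = b"".join(_BASES[rng.integers(0, 4, size=length)]).decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                break
        else:
            raise RuntimeError(
                f"barcode collision persisted after {max_redraws} redraws; "
                f"barcode length {length} too short for {n} strains")
    return out


def simulate_library(config: SimulationConfig,
                     design: Union[AmpliconDesign, Sequence[AmpliconDesign]],
                     ) -> SyntheticTruth:
    """Draw a barcoded strain library with plate layout and true effects.

    One locus per design: each strain receives a unique random barcode of the
    design's barcode length at every locus.  Plates fill row-major (A1, A2,
    ... A24, B1, ...).  A strain is a binder with probability
    ``frac_binders``; binders draw an independent truncated-Normal(>=0)
    effect per locus, non-binders have effect exactly 0 everywhere.
    """
    designs = [design] if isinstance(design, AmpliconDesign) else list(design)
    if not designs:
        raise ValueError("at least one design required")
    for d in designs:
        if d.barcode_length < 10:
            raise ValueError("barcode length < 10 risks collisions")
    rng = _rng(config.seed, _TAG_LIBRARY)
    n = config.n_strains

    plate = np.arange(n) // WELLS_PER_PLATE + 1
    well = np.arange(n) % WELLS_PER_PLATE
    rows = np.array(list(PLATE_ROWS))[well // len(PLATE_COLS)]
    cols = well % len(PLATE_COLS) + 1

    df = pd.DataFrame({
        "strain_id": [f"S{i:05d}" for i in range(n)],
        "orf": [f"ORF{i:05d}" for i in range(n)],
        "plate": plate,
        "row": rows,
        "col": cols,
    })

    is_binder = rng.random(n) < config.frac_binders
    for d in designs:
        df[f"barcode_{d.name}"] = _random_unique_barcodes(rng, n,
                                                          d.barcode_length)
        eff = np.zeros(n)
        if is_binder.any():
            k = int(is_binder.sum())
            draws = rng.normal(config.effect_mean, config.effect_sd, size=k)
            if config.effect_sd > 0:
                # truncate at zero by redrawing
                bad = draws < 0
                while bad.any():
                    draws[bad] = rng.normal(config.effect_mean,
                                            config.effect_sd,
                                            size=int(bad.sum()))
                    bad = draws < 0
            eff[is_binder] = np.maximum(draws, 0.0)
        df[f"effect_{d.name}"] = eff

    df["abundance"] = np.exp(rng.normal(0.0, config.abundance_sigma, size=n))
    return SyntheticTruth(strains=df, loci=[d.name for d in designs],
                          seed=config.seed)


# -- sample sheet ------------------------------------------------------------

def design_sample_sheet(config: SimulationConfig,
                        condition: str = "untreated") -> pd.DataFrame:
    """Deterministic sample sheet for one simulated screen.

    One IP and one input sample per replicate, each with a unique random 6-bp
    sample index (derived from ``config.seed`` only, so counts and reads
    agree on indexes).  Columns: index, plate, fraction, condition, replicate.
    """
    rng = _rng(config.seed, _TAG_INDEXES)
    n_samples = 2 * config.n_replicates
    indexes = _random_unique_barcodes(rng, n_samples, 6)
    rows = []
    k = 0
    for r in range(1, config.n_replicates + 1):
        for fraction in ("input", "IP"):
            rows.append((indexes[k], 1, fraction, condition, r))
            k += 1
    return pd.DataFrame(rows, columns=["index", "plate", "fraction",
                                       "condition", "replicate"])


def _negbin(rng: np.random.Generator, mean: np.ndarray,
            dispersion: float) -> np.ndarray:
    """NegBin(mean mu, var mu + alpha mu^2) via gamma-Poisson; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(truth: SyntheticTruth, config: SimulationConfig,
                    locus: Optional[str] = None,
                    sheet: Optional[pd.DataFrame] = None,
                    ) -> BarcodeCountMatrix:
    """Draw IP/input counts for every strain barcode at one locus.

    Per replicate r: input ~ NegBin(depth * abundance share); IP ~
    NegBin(input-mean * 2**effect * scale_r) with scale_r log-uniform in
    [0.5, 2].  Zero draws become absent cells (a barcode never sequenced has
    no table entry).
    """
    locus = locus or truth.loci[0]
    if sheet is None:
        sheet = design_sample_sheet(config)
    rng = _rng(config.seed, _TAG_COUNTS)

    abundance = truth.strains["abundance"].to_numpy()
    share = abundance / abundance.sum()
    input_mean = config.depth * share
    effects = truth.effects(locus).to_numpy()
    barcodes = truth.barcodes(locus).to_numpy()

    matrix = BarcodeCountMatrix()
    by_rep = {(row.fraction, row.replicate): row.index
              for row in sheet.itertuples(index=False)}
    for r in range(1, config.n_replicates + 1):
        scale_r = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        input_counts = _negbin(rng, input_mean, config.dispersion)
        ip_counts = _negbin(rng, input_mean * 2.0 ** effects * scale_r,
                            config.dispersion)
        for fraction, counts in (("input", input_counts), ("IP", ip_counts)):
            idx = by_rep[(fraction, r)]
            for bc, n in zip(barcodes, counts):
                if n > 0:
                    matrix.add(bc, idx, int(n))
    return matrix


# -- reads -------------------------------------------------------------------

def _apply_errors(rng: np.random.Generator, seq: str,
                  error_rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size:
        # substitute with one of the three other bases
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(counts: BarcodeCountMatrix, truth: SyntheticTruth,
                   design: AmpliconDesign, error_rate: float, seed: int,
                   out=None):
    """Emit one FASTQ read per count unit.

    Reads are assembled as index + constant region + barcode per the design,
    with i.i.d. substitution errors at ``error_rate`` and a constant quality
    string.  ``out`` may be a path or text handle; when ``None`` an iterator
    of 4-line FASTQ strings is returned.  Deterministic given ``seed``
    (cells are emitted in sorted order).
    """
    known = set(truth.barcodes(design.name))
    for bc, _ in counts.counts:
        if bc not in known:
            raise ValueError(f"barcode {bc} in counts but not in truth")

    def reads():
        rng = _rng(seed, _TAG_READS)
        serial = 0
        for (bc, idx), n in sorted(counts.counts.items()):
            base = idx + design.constant_region + bc
            qual = "I" * len(base)
            for _ in range(n):
                seq = base if error_rate == 0 else _apply_errors(
                    rng, base, error_rate)
                yield f"@sim_{serial}\n{seq}\n+\n{qual}\n"
                serial += 1

    if out is None:
        return reads()
    if hasattr(out, "write"):
        for rec in reads():
            out.write(rec)
        return None
    with open(out, "w") as fh:
        for rec in reads():
            fh.write(rec)
    return None


# -- row/column pooling ------------------------------------------------------

def simulate_pools(truth: SyntheticTruth, depth_per_pool: float,
                   dropout: float, seed: int, design: AmpliconDesign,
                   out_dir=None,
                   ) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Simulate row/column pool sequencing of the arrayed library.

    For each plate, 16 row pools and 24 column pools are formed; every strain
    contributes Poisson(``depth_per_pool``) reads to each of its two pools
    (``depth_per_pool`` is the expected per-strain coverage within a pool).
    With probability ``dropout`` a strain is silently omitted from one pool,
    independently per (strain, pool), exercising the decoder's rejection
    paths.  Reads use the given (15-bp barcode) design and a pool-specific
    6-bp index.

    Returns ``(pool_map, pool_reads)``: a pool map DataFrame (pool_id, plate,
    axis, label, index) and a dict pool_id -> list of FASTQ records.  When
    ``out_dir`` is given, one ``<pool_id>.fastq`` file per pool is written
    there as well.
    """
    if "plate" not in truth.strains.columns:
        raise ValueError("truth has no plate layout")
    rng = _rng(seed, _TAG_POOLS)
    locus = design.name
    barcodes = truth.barcodes(locus)
    strains = truth.strains

    plates = sorted(strains["plate"].unique())
    pool_rows = []
    for plate in plates:
        for r in PLATE_ROWS:
            pool_rows.append((f"P{plate}_row_{r}", plate, "row", str(r)))
        for c in PLATE_COLS:
            pool_rows.append((f"P{plate}_col_{c}", plate, "col", str(c)))
    pool_map = pd.DataFrame(pool_rows,
                            columns=["pool_id", "plate", "axis", "label"])
    pool_map["index"] = _random_unique_barcodes(rng, len(pool_map), 6)
    index_of = dict(zip(pool_map["pool_id"], pool_map["index"]))

    membership: Dict[str, List[str]] = {p: [] for p in pool_map["pool_id"]}
    for row in strains.itertuples(index=False):
        bc = getattr(row, f"barcode_{locus}")
        membership[f"P{row.plate}_row_{row.row}"].append(bc)
        membership[f"P{row.plate}_col_{row.col}"].append(bc)

    pool_reads: Dict[str, List[str]] = {}
    for pool_id in pool_map["pool_id"]:
        idx = index_of[pool_id]
        records: List[str] = []
        serial = 0
        for bc in membership[pool_id]:
            if dropout and rng.random() < dropout:
                continue
            n = int(rng.poisson(depth_per_pool))
            base = idx + design.constant_region + bc
            qual = "I" * len(base)
            for _ in range(n):
                records.append(f"@{pool_id}_{serial}\n{base}\n+\n{qual}\n")
                serial += 1
        pool_reads[pool_id] = records

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pool_id, records in pool_reads.items():
            (out_dir / f"{pool_id}.fastq").write_text("".join(records))
    return pool_map, pool_reads
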