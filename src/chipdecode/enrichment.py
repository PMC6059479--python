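"""Functional enrichment over binder sets.

Three analyses: one-sided Fisher exact tests of GO slim term
over-representation among binders; assignment of factors to four coarse
functional categories (DNA binding, RNA binding or processing, metabolism,
other) by a fixed priority scheme over GO slim process terms; and a weighted
Kolmogorov-Smirnov running-sum enrichment over factors ranked by the
difference of their binding scores at the two barcoded loci, with a
permutation p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


# -- gene set IO -------------------------------------------------------------

def read_gmt(path) -> Dict[str, Set[str]]:
    """Read GMT gene sets (term <tab> description <tab> members...)."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {m for m in parts[2:] if m}
            if members:
                sets[parts[0]] = members
    return sets


def read_term_tsv(path) -> Dict[str, Set[str]]:
    """Read a two-column factor<tab>term mapping into term -> factor sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["factor", "term"],
                     comment="#")
    sets: Dict[str, Set[str]] = {}
    for term, grp in df.groupby("term"):
        sets[str(term)] = set(grp["factor"].astype(str))
    return sets


# -- Fisher over-representation ---------------------------------------------

def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for [[a, b], [c, d]].

    Equals the hypergeometric upper tail P(X >= a) with margins fixed.
    """
    return float(sps.fisher_exact([[a, b], [c, d]],
                                  alternative="greater")[1])


def fisher_enrichment(binders: Set[str], universe: Set[str],
                      sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Per-term over-representation of ``binders`` within ``universe``.

    Returns a table (term, overlap, set_size, binders, universe, p, fdr)
    sorted by p.  Terms disjoint from the universe get p = 1 with a warning.
    """
    binders = set(binders)
    universe = set(universe)
    if not binders <= universe:
        raise ValueError("binders must be a subset of the universe")
    rows = []
    for term in sorted(sets):
        members = sets[term] & universe
        if not members:
            warnings.warn(f"term {term!r} is disjoint from the universe")
            rows.append((term, 0, 0, 1.0))
            continue
        a = len(binders & members)
        b = len(binders - members)
        c = len(members - binders)
        d = len(universe) - a - b - c
        rows.append((term, a, len(members), fisher_greater(a, b, c, d)))
    out = pd.DataFrame(rows, columns=["term", "overlap", "set_size", "p"])
    out["binders"] = len(binders)
    out["universe"] = len(universe)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


# -- category scheme ---------------------------------------------------------

@dataclass
class CategoryScheme:
    """Ordered category -> GO slim term lists; order is match priority."""

    categories: Dict[str, List[str]]
    fallback: str = "other"

    @classmethod
    def default(cls) -> "CategoryScheme":
        """The packaged four-category scheme over GO slim process terms."""
        text = (resources.files("chipdecode.data")
                / "go_slim_categories.json").read_text()
        return cls(categories=json.loads(text))


def assign_categories(factors: Iterable[str],
                      go_slim: Mapping[str, Set[str]],
                      scheme: Optional[CategoryScheme] = None,
                      ) -> Dict[str, str]:
    """Map each factor to its highest-priority category, else the fallback.

    ``go_slim`` maps term label -> factor set; every term named by the
    scheme must resolve against it.
    """
    scheme = scheme or CategoryScheme.default()
    missing = [t for terms in scheme.categories.values() for t in terms
               if t not in go_slim]
    if missing:
        raise KeyError(f"scheme terms not in the GO slim collection: "
                       f"{sorted(set(missing))}")
    member_of: Dict[str, Set[str]] = {}
    for cat, terms in scheme.categories.items():
        s: Set[str] = set()
        for t in terms:
            s |= go_slim[t]
        member_of[cat] = s
    out = {}
    for f in factors:
        for cat in scheme.categories:  # dict order = priority
            if f in member_of[cat]:
                out[f] = cat
                break
        else:
            out[f] = scheme.fallback
    return out


# -- running-sum enrichment ---------------------------------------------------

@dataclass
class RunningSumResult:
    es: float
    p: float
    leading_edge: List[str]
    running_sum: np.ndarray = field(repr=False, default=None)


def rank_by_score_difference(scores_a: pd.Series, scores_b: pd.Series,
                             ) -> pd.Series:
    """Ranking metric: score at locus A minus score at locus B, descending.

    Ties break by factor name (stable), so the ranking is deterministic.
    """
    common = scores_a.index.intersection(scores_b.index)
    metric = (scores_a.loc[common] - scores_b.loc[common]).dropna()
    order = sorted(metric.index, key=lambda f: (-metric[f], f))
    return metric.loc[order]


def _running_sum(in_set: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = in_set.size
    n_set = int(in_set.sum())
    w_in = np.where(in_set, weights, 0.0)
    total = w_in.sum()
    if total == 0:
        # all in-set weights zero (e.g. exponent*metric degenerate): uniform
        w_in = in_set.astype(float)
        total = w_in.sum()
    steps = w_in / total - (~in_set) / (n - n_set)
    return np.cumsum(steps)


def running_sum_enrichment(ranked, gene_set: Set[str], exponent: float = 1,
                           n_perm: int = 10_000, seed: int = 0,
                           ) -> RunningSumResult:
    """Weighted KS running-sum enrichment of a gene set along a ranking.

    ``ranked`` is an ordered Series (factor -> ranking metric) or an ordered
    factor sequence (metric defaults to 1).  Walking down the ranking,
    in-set positions add |metric|**exponent normalized by the in-set total
    and out-of-set positions subtract 1/(N - n_set); the enrichment score is
    the running sum's maximum signed deviation from zero.  The p-value
    permutes set membership over the ranked factors:
    p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1).
    """
    if isinstance(ranked, pd.Series):
        factors = list(ranked.index)
        metric = ranked.to_numpy(dtype=float)
    else:
        factors = list(ranked)
        metric = np.ones(len(factors))
    n = len(factors)
    in_set = np.array([f in gene_set for f in factors])
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_set == n:
        raise ValueError("gene set covers the entire ranking; "
                         "out-of-set step undefined")

    weights = np.abs(metric) ** exponent
    rs = _running_sum(in_set, weights)
    peak = int(np.argmax(np.abs(rs)))
    es = float(rs[peak])

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_set, replace=False)] = True
        rs_p = _running_sum(perm, weights)
        if np.max(np.abs(rs_p)) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)

    if es >= 0:
        leading = [f for f, m in zip(factors[:peak + 1], in_set) if m]
    else:
        leading = [f for f, m in zip(factors[peak:], in_set[peak:]) if m]
    return RunningSumResult(es=es, p=p, leading_edge=leading,
                            running_sum=rs)
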