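"""Empirical-Bayes moderated t-tests for binder calling and contrasts.

Per-factor variances estimated from a handful of replicates are noisy; the
moderated test borrows strength across the ~4,000 factors by shrinking each
sample variance s_g^2 toward a prior variance s0^2 fitted to all of them,
assuming a scaled inverse chi-square prior with d0 degrees of freedom:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = M_g / (s~_g / sqrt(n_g)),   t_g ~ t(d0 + d_g) under the null.

(d0, s0^2) are fitted by the method of moments on log variances, using the
fact that log of a scaled chi-square variate has known digamma/trigamma
moments.  Binders are factors with positive mean log2(IP/input) at
Benjamini-Hochberg FDR < 0.01; condition contrasts use a two-sample
moderated t restricted to the union of binders of the two conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ModeratedPrior:
    """Scaled inverse chi-square variance prior: d0 df, scale s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the no-shrinkage limit (ordinary t-test)
        if not (self.d0 >= 0):
            raise ValueError("d0 must be nonnegative (may be inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma(x):
    return special.polygamma(1, x)


def _solve_trigamma(target: float, lo: float = 1e-4, hi: float = 1e6,
                    tol: float = 1e-8) -> float:
    """Solve trigamma(d0/2) = target for d0 by bisection.

    trigamma is strictly decreasing on (0, inf), so bisection is safe.
    Targets below the range's reach return inf (no variance spread beyond
    sampling noise); targets above it clamp to the lower bound.
    """
    if target <= _trigamma(hi / 2):
        return math.inf
    if target >= _trigamma(lo / 2):
        return lo
    a, b = lo, hi
    while b - a > tol * max(1.0, a):
        mid = 0.5 * (a + b)
        if _trigamma(mid / 2) > target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def estimate_prior(variances, df) -> ModeratedPrior:
    """Fit (d0, s0^2) to per-factor sample variances by moments on logs.

    With e_g = log(s_g^2) - psi(d_g/2) + log(d_g/2), the model implies
    E[e_g] = log(s0^2) + psi(d0/2) - log(d0/2) and
    Var[e_g] = psi'(d_g/2) + psi'(d0/2); the excess spread of e over its
    sampling component identifies d0.  Zero/negative variances carry no
    information on the log scale and are excluded from the fit.
    """
    s2 = np.asarray(variances, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if np.all(s2 <= 0):
        raise ValueError("all variances are zero; degenerate data")
    keep = (s2 > 0) & (d >= 1)
    s2, d = s2[keep], d[keep]
    g = s2.size
    if g < 10:
        raise ValueError(f"need >= 10 positive variances, got {g}")

    e = np.log(s2) - special.psi(d / 2) + np.log(d / 2)
    ebar = e.mean()
    evar = ((e - ebar) ** 2).mean() * g / (g - 1) - _trigamma(d / 2).mean()
    evar = max(0.0, float(evar))
    if evar == 0.0:
        d0 = math.inf
        s0_sq = float(np.exp(ebar))
    else:
        d0 = _solve_trigamma(evar)
        if math.isinf(d0):
            s0_sq = float(np.exp(ebar))
        else:
            s0_sq = float(np.exp(ebar + special.psi(d0 / 2)
                                 - np.log(d0 / 2)))
    return ModeratedPrior(d0=d0, s0_sq=s0_sq)


def _moderated_t(mean, s2, d, n_eff, prior: ModeratedPrior):
    """Shrink variances and compute t and two-sided p.

    ``n_eff`` is the precision factor: n for a one-sample mean, the
    1/(1/nA+1/nB) equivalent for a two-sample difference.
    """
    if math.isinf(prior.d0):
        s2_post = np.full_like(np.asarray(s2, float), prior.s0_sq)
        df_total = np.full_like(np.asarray(d, float), np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
        df_total = prior.d0 + d
    se = np.sqrt(s2_post / n_eff)
    t = np.asarray(mean) / se
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return t, p, s2_post, df_total


def moderated_one_sample_test(panel: pd.DataFrame,
                              prior: ModeratedPrior | None = None,
                              ) -> pd.DataFrame:
    """Moderated one-sample t of per-replicate log-ratios against zero.

    ``panel`` is factor x replicate; factors with fewer than 2 finite scores
    are dropped.  When ``prior`` is None it is estimated from the panel's
    own sample variances.  Returns a table with columns logFC, s2, df, n,
    t, p, fdr.
    """
    values = panel.to_numpy(dtype=float)
    finite = np.isfinite(values)
    n = finite.sum(axis=1)
    usable = n >= 2
    if not usable.any():
        raise ValueError("no factor has >= 2 finite replicate scores")
    values = np.where(finite, values, np.nan)[usable]
    n = n[usable]
    index = panel.index[usable]

    mean = np.nanmean(values, axis=1)
    s2 = np.nanvar(values, axis=1, ddof=1)
    d = n - 1.0
    if prior is None:
        prior = estimate_prior(s2, d)
    t, p, s2_post, df_total = _moderated_t(mean, s2, d, n, prior)
    out = pd.DataFrame({"logFC": mean, "s2": s2, "df": d, "n": n,
                        "t": t, "p": p}, index=index)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out.attrs["prior"] = prior
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_binders(table: pd.DataFrame, fdr_cut: float = 0.01) -> pd.DataFrame:
    """Flag binders: positive fold-change AND FDR below the cut (strict)."""
    out = table.copy()
    out["binder"] = (out["logFC"] > 0) & (out["fdr"] < fdr_cut)
    return out


def differential_binding(panel_a: pd.DataFrame, panel_b: pd.DataFrame,
                         binder_union_cut: float = 0.05,
                         diff_fdr_cut: float = 0.05) -> pd.DataFrame:
    """Two-sample moderated contrast of binding between two conditions.

    Restricted to factors that are binders (positive logFC, FDR below
    ``binder_union_cut``) in at least one condition.  Per factor the pooled
    within-condition variance (df = nA + nB - 2) is shrunk by a prior fitted
    on this restricted set; logFC is mean(A) - mean(B).  Returns columns
    logFC, t, p, fdr, significant.
    """
    binders_a = call_binders(moderated_one_sample_test(panel_a),
                             binder_union_cut)
    binders_b = call_binders(moderated_one_sample_test(panel_b),
                             binder_union_cut)
    union = (set(binders_a.index[binders_a["binder"]])
             | set(binders_b.index[binders_b["binder"]]))
    if not union:
        warnings.warn("no binders in either condition; empty contrast")
        return pd.DataFrame(columns=["logFC", "t", "p", "fdr", "significant"])
    factors = [f for f in panel_a.index if f in union and f in panel_b.index]

    va = panel_a.loc[factors].to_numpy(dtype=float)
    vb = panel_b.loc[factors].to_numpy(dtype=float)
    na = np.isfinite(va).sum(axis=1)
    nb = np.isfinite(vb).sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    factors = [f for f, u in zip(factors, usable) if u]
    va, vb, na, nb = va[usable], vb[usable], na[usable], nb[usable]

    mean_a = np.nanmean(va, axis=1)
    mean_b = np.nanmean(vb, axis=1)
    ss_a = np.nansum((va - mean_a[:, None]) ** 2, axis=1)
    ss_b = np.nansum((vb - mean_b[:, None]) ** 2, axis=1)
    d = na + nb - 2.0
    s2 = (ss_a + ss_b) / d
    n_eff = 1.0 / (1.0 / na + 1.0 / nb)

    prior = estimate_prior(s2, d)
    t, p, _, _ = _moderated_t(mean_a - mean_b, s2, d, n_eff, prior)
    out = pd.DataFrame({"logFC": mean_a - mean_b, "t": t, "p": p},
                       index=pd.Index(factors, name=panel_a.index.name))
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < diff_fdr_cut
    out.attrs["prior"] = prior
    return out
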