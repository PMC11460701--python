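"""Enrichment statistics.

Group-vs-group RBP binding-site abundance comparisons (two-sided Fisher exact
tests with Benjamini-Hochberg adjustment and a minimum-abundance gate),
distribution comparisons for intron subsets (two-sample Kolmogorov-Smirnov
with a Monte-Carlo false-hit control), and host-gene category enrichment.

Two-sided Fisher p-values are computed with exact integer hypergeometric
weights (sum of the probabilities of all tables as or less probable than the
observed one, ties decided in exact arithmetic), so that batch computation
over many tables is fast and tie handling is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from flexiscan.rbp import BindingProfile


# ------------------------------------------------------------- Fisher exact


def _two_sided_from_weights(weights: list[int], denom: int, a_idx: int) -> float:
    """Two-sided p from integer hypergeometric weights: sum of all weights
    <= the observed one, over the total."""
    w_obs = weights[a_idx]
    num = sum(w for w in weights if w <= w_obs)
    return min(1.0, num / denom)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[Optional[float], float]:
    """Two-sided Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The odds ratio is the sample odds ratio
    (None when a margin is zero, where p = 1 by convention).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative cell count")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return None, 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1)]
    p = _two_sided_from_weights(weights, comb(n, r1), a - lo)
    oddsr = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else None)
    return oddsr, p


def fisher_pvalues_for_margins(n: int, r1: int, c1: int) -> np.ndarray:
    """Two-sided p for every table sharing the margins (n, r1, c1), indexed
    by a - max(0, r1 + c1 - n).  Used for batch/exhaustive computation."""
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1)]
    denom = comb(n, r1)
    return np.array(
        [_two_sided_from_weights(weights, denom, i) for i in range(len(weights))]
    )


# -------------------------------------------------------- enrichment tables


@dataclass
class EnrichmentRow:
    rbp: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    pct_a: float
    pct_b: float
    odds_ratio: Optional[float]
    p: float
    p_adj: float
    key: str  # over / under / ns


def binding_abundance_table(
    profiles_a: dict[str, BindingProfile],
    profiles_b: dict[str, BindingProfile],
    total_a: Optional[int] = None,
    total_b: Optional[int] = None,
) -> pd.DataFrame:
    """Per-RBP collapsed presence counts and binding-site abundance
    percentages in two disjoint intron groups.

    ``pct`` is the RBP's share of all collapsed binding-site presences in the
    group (sums to 100 per group).  ``total_a``/``total_b`` override the group
    sizes (number of introns) used for the Fisher margins; they default to
    the number of profiled introns.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("empty profile group")
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for profs, counts in ((profiles_a, counts_a), (profiles_b, counts_b)):
        for p in profs.values():
            for r in p.rbps:
                counts[r] = counts.get(r, 0) + 1
    rbps = sorted(set(counts_a) | set(counts_b))
    pres_a = sum(counts_a.values())
    pres_b = sum(counts_b.values())
    rows = [
        {
            "rbp": r,
            "count_a": counts_a.get(r, 0),
            "count_b": counts_b.get(r, 0),
            "total_a": total_a if total_a is not None else len(profiles_a),
            "total_b": total_b if total_b is not None else len(profiles_b),
            "pct_a": counts_a.get(r, 0) / pres_a * 100 if pres_a else 0.0,
            "pct_b": counts_b.get(r, 0) / pres_b * 100 if pres_b else 0.0,
        }
        for r in rbps
    ]
    return pd.DataFrame(rows)


def fisher_bh(
    table: pd.DataFrame, alpha: float = 0.05, min_pct: float = 1.0
) -> pd.DataFrame:
    """Per-RBP two-sided Fisher tests with BH adjustment and abundance gate.

    The 2x2 per RBP is (count_a, total_a - count_a) vs (count_b,
    total_b - count_b).  ``key`` is 'over'/'under' (direction of group A
    relative to B) only when the RBP passes the abundance gate
    (max(pct_a, pct_b) >= min_pct) and p_adj <= alpha; otherwise 'ns'.
    The BH family is all RBPs in the comparison.
    """
    if table.empty:
        return table.assign(odds_ratio=[], p=[], p_adj=[], key=[])
    ors, ps = [], []
    for row in table.itertuples(index=False):
        oddsr, p = fisher_exact_two_sided(
            row.count_a,
            row.total_a - row.count_a,
            row.count_b,
            row.total_b - row.count_b,
        )
        ors.append(oddsr)
        ps.append(p)
    p_adj = multipletests(ps, method="fdr_bh")[1]
    out = table.copy()
    out["odds_ratio"] = ors
    out["p"] = ps
    out["p_adj"] = p_adj
    keys = []
    for i, row in enumerate(out.itertuples(index=False)):
        gate = max(row.pct_a, row.pct_b) >= min_pct
        if gate and row.p_adj <= alpha:
            fa = row.count_a / row.total_a if row.total_a else 0.0
            fb = row.count_b / row.total_b if row.total_b else 0.0
            keys.append("over" if fa > fb else "under")
        else:
            keys.append("ns")
    out["key"] = keys
    return out


# --------------------------------------------------------------- KS + Monte-Carlo


@dataclass
class KsMcResult:
    feature: str
    p_ks: float
    n_subset: int
    mc_false_hit_rate: Optional[float]
    verdict: str  # significant / rejected_false_hit / ns


def ks_with_mc(
    values_subset: Sequence[float],
    values_rest: Sequence[float],
    feature: str = "",
    n_mc: int = 1000,
    p_cut: float = 0.01,
    fpr_cut: float = 0.05,
    seed: int = 0,
) -> KsMcResult:
    """Two-sample KS test of a subset vs the rest, with Monte-Carlo false-hit
    control.

    When the observed KS p is below ``p_cut``, ``n_mc`` replicates each draw a
    random subset of the same size (without replacement) from the pooled
    values and test it against its complement; the significance is rejected
    as a false hit when more than ``fpr_cut`` of replicates also reach
    p < ``p_cut``.  Seeded and reproducible.
    """
    subset = np.asarray(values_subset, dtype=float)
    rest = np.asarray(values_rest, dtype=float)
    if subset.size < 2:
        raise ValueError("subset must have >= 2 values")
    pool = np.concatenate([subset, rest])
    if subset.size > pool.size:
        raise ValueError("subset larger than pool")
    p_ks = float(sp_stats.ks_2samp(subset, rest).pvalue)
    if p_ks >= p_cut:
        return KsMcResult(feature, p_ks, subset.size, None, "ns")
    rng = np.random.default_rng(seed)
    n_hits = 0
    for _ in range(n_mc):
        idx = rng.choice(pool.size, size=subset.size, replace=False)
        mask = np.zeros(pool.size, dtype=bool)
        mask[idx] = True
        p = sp_stats.ks_2samp(pool[mask], pool[~mask]).pvalue
        if p < p_cut:
            n_hits += 1
    rate = n_hits / n_mc
    verdict = "rejected_false_hit" if rate > fpr_cut else "significant"
    return KsMcResult(feature, p_ks, subset.size, rate, verdict)


# -------------------------------------------------- host-gene category test


def hostgene_category_enrichment(
    fg_genes: set, bg_genes: set, category_genes: set
) -> tuple[float, float, float]:
    """Fisher exact test of category membership among foreground host genes
    vs the background host-gene set.  Returns (pct_fg, pct_bg, p)."""
    if not bg_genes:
        raise ValueError("empty background gene set")
    if not fg_genes:
        raise ValueError("empty foreground gene set")
    a = len(fg_genes & category_genes)
    b = len(fg_genes) - a
    c = len(bg_genes & category_genes)
    d = len(bg_genes) - c
    _, p = fisher_exact_two_sided(a, b, c, d)
    return a / len(fg_genes) * 100, c / len(bg_genes) * 100, p
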