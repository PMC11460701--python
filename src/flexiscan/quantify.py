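"""Abundance calibration and fraction analysis.

Copies-per-cell are estimated from a log10-log10 ordinary least squares fit
of known sncRNA standards (copies per cell vs RPM), with 95% prediction
intervals.  Host-gene reads can be down-sampled (multivariate hypergeometric)
to match FLEXI read depth before correlating abundances across samples;
correlations are compared with Fisher's r-to-z.  Nuclear/cytoplasmic
enrichment is classified by a normalized fold change > 1.5 in either
direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass
class CopyNumberModel:
    """OLS of log10(copies per cell) on log10(RPM)."""

    slope: float
    intercept: float
    residual_sd: float
    n_standards: int
    x_mean: float
    sxx: float
    standards: list  # (name, rpm, copies)

    def predict(self, rpm: float, interval: str = "prediction") -> tuple[float, float, float]:
        """Point estimate and 95% interval (back-transformed from log10).

        ``interval`` is 'prediction' (default; a single new observation) or
        'confidence' (the regression mean).
        """
        if rpm <= 0:
            raise ValueError("rpm must be positive")
        lx = np.log10(rpm)
        ly = self.slope * lx + self.intercept
        dof = self.n_standards - 2
        t = sp_stats.t.ppf(0.975, dof)
        lever = 1.0 / self.n_standards + (lx - self.x_mean) ** 2 / self.sxx
        var = lever + (1.0 if interval == "prediction" else 0.0)
        half = t * self.residual_sd * np.sqrt(var)
        return 10**ly, 10 ** (ly - half), 10 ** (ly + half)


def fit_copy_number_model(standards: Sequence[tuple[str, float, float]]) -> CopyNumberModel:
    """Fit the copies-per-cell calibration from (name, rpm, copies_per_cell)
    standards; nonpositive standards are dropped with a warning and >= 3 are
    required."""
    clean = []
    for name, rpm, copies in standards:
        if rpm <= 0 or copies <= 0:
            warnings.warn(f"standard {name} has nonpositive value; dropped")
            continue
        clean.append((name, float(rpm), float(copies)))
    if len(clean) < 3:
        raise ValueError(f"need >= 3 usable standards, got {len(clean)}")
    x = np.log10([s[1] for s in clean])
    y = np.log10([s[2] for s in clean])
    res = sp_stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = len(clean) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CopyNumberModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        n_standards=len(clean),
        x_mean=float(np.mean(x)),
        sxx=float(np.sum((x - np.mean(x)) ** 2)),
        standards=clean,
    )


def predict_copies(
    model: CopyNumberModel, rpm: float, interval: str = "prediction"
) -> tuple[float, float, float]:
    return model.predict(rpm, interval=interval)


def downsample_gene_reads(
    gene_read_counts: dict[str, int], target_total: int, seed: int = 0
) -> dict[str, int]:
    """Down-sample per-gene read counts to ``target_total`` total reads by a
    multivariate hypergeometric draw (random read picking without
    replacement).  Seeded and total-preserving."""
    genes = sorted(gene_read_counts)
    counts = np.array([gene_read_counts[g] for g in genes], dtype=np.int64)
    total = int(counts.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total reads {total}")
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts, target_total)
    return dict(zip(genes, (int(d) for d in drawn)))


def compare_correlations(
    x1: Sequence[float],
    y1: Sequence[float],
    x2: Sequence[float],
    y2: Sequence[float],
    log2_transform: bool = True,
) -> tuple[float, float, float, float]:
    """Pearson correlations of two abundance scatter sets and Fisher's
    r-to-z comparison: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),
    two-sided normal p.  Abundances are log2-transformed by default.
    """
    def _prep(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 4:
            raise ValueError("need >= 4 pairs")
        if log2_transform:
            x, y = np.log2(x), np.log2(y)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance")
        return x, y

    x1, y1 = _prep(x1, y1)
    x2, y2 = _prep(x2, y2)
    r1 = float(np.corrcoef(x1, y1)[0, 1])
    r2 = float(np.corrcoef(x2, y2)[0, 1])
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1 / (x1.size - 3) + 1 / (x2.size - 3)
    )
    p = 2 * sp_stats.norm.sf(abs(z))
    return r1, r2, float(z), float(p)


# ------------------------------------------------------- fraction enrichment


@dataclass
class FractionCall:
    intron_id: str
    count_nuc: float
    count_cyt: float
    fc: float  # size-factor-normalized cytoplasmic/nuclear fold change
    classification: str  # nuclear / cytoplasmic / ns


def _size_factors(nuc: np.ndarray, cyt: np.ndarray) -> tuple[float, float]:
    """Median-of-ratios size factors over introns nonzero in both fractions;
    total-count scaling fallback when fewer than 10 such introns."""
    both = (nuc > 0) & (cyt > 0)
    if both.sum() < 10:
        tn, tc = nuc.sum(), cyt.sum()
        mean = (tn + tc) / 2
        return tn / mean, tc / mean
    geo = np.sqrt(nuc[both] * cyt[both])
    return float(np.median(nuc[both] / geo)), float(np.median(cyt[both] / geo))


def classify_fraction_enrichment(
    counts_nuc: dict[str, float],
    counts_cyt: dict[str, float],
    fc_threshold: float = 1.5,
    pseudocount: float = 0.5,
) -> list[FractionCall]:
    """Classify introns as nuclear / cytoplasmic / ns from fraction counts.

    Counts are normalized by median-of-ratios size factors, a pseudocount is
    added, and an intron is cytoplasmic when fc = cyt/nuc > ``fc_threshold``,
    nuclear when 1/fc > ``fc_threshold`` (strict inequalities, so swapping
    the fractions exactly swaps the labels).
    """
    ids = sorted(set(counts_nuc) | set(counts_cyt))
    nuc = np.array([counts_nuc.get(i, 0) for i in ids], dtype=float)
    cyt = np.array([counts_cyt.get(i, 0) for i in ids], dtype=float)
    if nuc.sum() == 0 or cyt.sum() == 0:
        raise ValueError("a fraction has all-zero counts")
    sf_n, sf_c = _size_factors(nuc, cyt)
    out = []
    for iid, n, c in zip(ids, nuc, cyt):
        fc = (c / sf_c + pseudocount) / (n / sf_n + pseudocount)
        if fc > fc_threshold:
            cls = "cytoplasmic"
        elif 1 / fc > fc_threshold:
            cls = "nuclear"
        else:
            cls = "ns"
        out.append(FractionCall(iid, n, c, fc, cls))
    return out


def fraction_calls_to_frame(calls: list[FractionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intron_id": c.intron_id,
                "count_nuc": c.count_nuc,
                "count_cyt": c.count_cyt,
                "fc_cyt_over_nuc": c.fc,
                "classification": c.classification,
            }
            for c in calls
        ]
    )
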