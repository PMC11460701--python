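"""RBP binding-site intersection and location analysis.

Binding-site intervals (eCLIP/PAR-CLIP-style BED exports, RBP name in column
4) are intersected with the intron catalog; any >=1 nt same-strand overlap
counts, and multiple sites of one RBP on one intron collapse to a single
presence (all site midpoints are retained for the location analysis).
Midpoints are expressed as percent of intron length (values <0 or >100 mark
sites extending into the flanking exons), which feeds the I / SS-I / SS-E
location classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from flexiscan.annotations import IntronCatalog, IntronRecord, read_bed_intervals

STRANDS = ("+", "-")


@dataclass
class RbpSite:
    rbp: str
    chrom: str
    start: int
    end: int
    strand: str
    source_label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("site end <= start")


@dataclass
class BindingProfile:
    """Collapsed per-intron RBP presence plus raw site midpoints."""

    intron_id: str
    rbps: set = field(default_factory=set)
    site_midpoint_pcts: dict = field(default_factory=dict)  # rbp -> [pct, ...]

    def add_site(self, rbp: str, midpoint_pct: float) -> None:
        self.rbps.add(rbp)
        self.site_midpoint_pcts.setdefault(rbp, []).append(midpoint_pct)


def read_site_bed(path: Union[str, Path], source_label: str = "") -> list[RbpSite]:
    """Read a BED6 site file (RBP name in column 4)."""
    df = read_bed_intervals(path)
    return [
        RbpSite(
            rbp=str(row.name),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            source_label=source_label or str(path),
        )
        for row in df.itertuples(index=False)
    ]


def _midpoint_pct(intron: IntronRecord, site: RbpSite) -> float:
    mid = (site.start + site.end) / 2
    pct = (mid - intron.start) / intron.length * 100
    if intron.strand == "-":
        pct = 100 - pct
    return pct


def intersect_sites(
    catalog: IntronCatalog,
    sites: Iterable[RbpSite],
    intron_ids: Optional[set] = None,
) -> dict[str, BindingProfile]:
    """Assign sites to introns on >=1 nt same-strand overlap.

    ``intron_ids`` restricts the result to a subset (e.g. FLEXI-called
    introns).  Sites with unknown strand match both strands (warning).
    Returns profiles only for introns with >=1 site.
    """
    profiles: dict[str, BindingProfile] = {}
    n_unstranded = 0
    for site in sites:
        strand = site.strand
        if strand not in STRANDS:
            n_unstranded += 1
            strand = None
        for intron in catalog.overlapping(site.chrom, site.start, site.end, strand):
            if intron_ids is not None and intron.intron_id not in intron_ids:
                continue
            prof = profiles.setdefault(
                intron.intron_id, BindingProfile(intron_id=intron.intron_id)
            )
            prof.add_site(site.rbp, _midpoint_pct(intron, site))
    if n_unstranded:
        warnings.warn(f"{n_unstranded} sites with unknown strand matched to both strands")
    return profiles


def profiles_to_frame(profiles: dict[str, BindingProfile]) -> pd.DataFrame:
    rows = [
        {
            "intron_id": p.intron_id,
            "rbps": ",".join(sorted(p.rbps)),
            "n_rbps": len(p.rbps),
        }
        for p in profiles.values()
    ]
    return pd.DataFrame(rows, columns=["intron_id", "rbps", "n_rbps"]).sort_values(
        "intron_id"
    ).reset_index(drop=True)


def presence_matrix(
    profiles: dict[str, BindingProfile], intron_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Boolean intron x RBP presence matrix (collapsed)."""
    ids = sorted(profiles) if intron_ids is None else list(intron_ids)
    rbps = sorted({r for p in profiles.values() for r in p.rbps})
    mat = pd.DataFrame(False, index=ids, columns=rbps)
    for iid in ids:
        p = profiles.get(iid)
        if p is not None:
            mat.loc[iid, sorted(p.rbps)] = True
    return mat


def rbps_with_min_flexis(
    profiles: dict[str, BindingProfile], min_count: int = 30
) -> pd.DataFrame:
    """RBPs bound to >= ``min_count`` distinct introns of the profile set,
    descending by count, ties alphabetical."""
    counts: dict[str, int] = {}
    for p in profiles.values():
        for r in p.rbps:
            counts[r] = counts.get(r, 0) + 1
    rows = [
        {"rbp": r, "n_flexis": n}
        for r, n in counts.items()
        if n >= min_count
    ]
    df = pd.DataFrame(rows, columns=["rbp", "n_flexis"])
    return df.sort_values(["n_flexis", "rbp"], ascending=[False, True]).reset_index(
        drop=True
    )


# ------------------------------------------------------------ midpoint plots


def midpoint_density(
    profiles: dict[str, BindingProfile],
    rbp: str,
    bin_pct: float = 2.0,
    lo: float = -50.0,
    hi: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized-position density of an RBP's site midpoints.

    Returns (density, bin_centers) over [lo, hi] percent of intron length;
    the density integrates to 1.  Midpoints outside the range clip to the
    terminal bins.
    """
    pts = [
        m
        for p in profiles.values()
        for m in p.site_midpoint_pcts.get(rbp, [])
    ]
    if not pts:
        raise ValueError(f"no midpoints for RBP {rbp!r}")
    edges = np.arange(lo, hi + bin_pct / 2, bin_pct)
    clipped = np.clip(pts, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    density = counts / counts.sum() / bin_pct
    centers = (edges[:-1] + edges[1:]) / 2
    return density, centers


def classify_location(
    density: np.ndarray,
    bin_centers: np.ndarray,
    edge_pct: float = 15.0,
    peak_frac: float = 0.5,
) -> Optional[str]:
    """Classify a midpoint density as I, SS-I, or SS-E.

    A peak is a local maximum >= ``peak_frac`` of the global maximum.  When
    the density is bimodal with one peak within ``edge_pct`` of the 5' splice
    site (0%) and one within ``edge_pct`` of the 3' splice site (100%), the
    class is SS-I if both peak midpoints lie inside [0, 100]% and SS-E if
    both lie outside; any other shape is interior enrichment (I).  Invariant
    to rescaling of the density.
    """
    d = np.asarray(density, dtype=float)
    if d.size == 0 or d.sum() == 0:
        return None
    gmax = d.max()
    peaks = []
    for i in range(d.size):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < d.size - 1 else -np.inf
        if d[i] >= peak_frac * gmax and d[i] >= left and d[i] >= right:
            if peaks and peaks[-1][0] == i - 1 and d[i] == d[i - 1]:
                continue  # plateau counts once
            peaks.append((i, bin_centers[i]))
    near5 = [c for _, c in peaks if abs(c - 0.0) <= edge_pct]
    near3 = [c for _, c in peaks if abs(c - 100.0) <= edge_pct]
    if near5 and near3:
        p5 = min(near5, key=lambda c: abs(c))
        p3 = min(near3, key=lambda c: abs(c - 100))
        if 0 <= p5 <= 100 and 0 <= p3 <= 100:
            return "SS-I"
        if not (0 <= p5 <= 100) and not (0 <= p3 <= 100):
            return "SS-E"
        return "SS-I"  # mixed straddle: midpoints partly inside
    return "I"


# --------------------------------------------- full-length read enrichment


def _covering_fraction(
    reads: Sequence[tuple[str, int, int]],
    catalog: IntronCatalog,
    flexi_ids: set,
    min_len_frac: float,
) -> float:
    if not reads:
        return 0.0
    n_cover = 0
    for chrom, start, end in reads:
        for intron in catalog.overlapping(chrom, start, end):
            if intron.intron_id not in flexi_ids:
                continue
            ov = min(end, intron.end) - max(start, intron.start)
            if ov / intron.length >= min_len_frac:
                n_cover += 1
                break
    return n_cover / len(reads)


def fulllength_read_enrichment(
    clip_reads: dict[str, Sequence[tuple[str, int, int]]],
    control_reads: Sequence[tuple[str, int, int]],
    catalog: IntronCatalog,
    flexi_ids: set,
    min_len_frac: float = 0.95,
) -> pd.DataFrame:
    """Per-RBP fold enrichment of reads covering >= ``min_len_frac`` of some
    FLEXI, relative to a control read set.  Fold is null when the control
    fraction is 0.
    """
    ctrl = _covering_fraction(control_reads, catalog, flexi_ids, min_len_frac)
    if ctrl == 0.0:
        warnings.warn("control covering fraction is 0; folds are null")
    rows = []
    for rbp in sorted(clip_reads):
        frac = _covering_fraction(clip_reads[rbp], catalog, flexi_ids, min_len_frac)
        rows.append(
            {
                "rbp": rbp,
                "fraction": frac,
                "control_fraction": ctrl,
                "fold": frac / ctrl if ctrl > 0 else None,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------- intron fragment merging


def merge_intron_fragments(
    fragments: Iterable,  # AlignmentFragment or (chrom, start, end, strand)
    catalog: IntronCatalog,
    size_class: Optional[str] = None,
    flexi_ids: Optional[set] = None,
) -> dict[str, list[tuple[int, int]]]:
    """Per-intron union of overlapping fragment intervals (clipped to the
    intron), for downstream site intersection of non-FLEXI intron fragments.

    ``size_class`` restricts to 'short' or 'long' introns; ``flexi_ids``
    excludes FLEXI-called introns ("other" introns).
    """
    per_intron: dict[str, list[tuple[int, int]]] = {}
    for frag in fragments:
        if hasattr(frag, "frag_start"):
            chrom, start, end, strand = (
                frag.chrom,
                frag.frag_start,
                frag.frag_end,
                frag.strand,
            )
        else:
            chrom, start, end, strand = frag
        for intron in catalog.overlapping(chrom, start, end, strand):
            if size_class is not None and intron.size_class != size_class:
                continue
            if flexi_ids is not None and intron.intron_id in flexi_ids:
                continue
            per_intron.setdefault(intron.intron_id, []).append(
                (max(start, intron.start), min(end, intron.end))
            )
    merged: dict[str, list[tuple[int, int]]] = {}
    for iid, ivs in per_intron.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[iid] = [tuple(x) for x in out]
    return merged


def intersect_sites_with_intervals(
    intervals: dict[str, list[tuple[int, int]]],
    catalog: IntronCatalog,
    sites: Iterable[RbpSite],
) -> dict[str, BindingProfile]:
    """Intersect sites with merged per-intron fragment intervals (same
    collapse rule as :func:`intersect_sites`)."""
    profiles: dict[str, BindingProfile] = {}
    site_list = list(sites)
    for iid, ivs in intervals.items():
        intron = catalog[iid]
        for site in site_list:
            if site.chrom != intron.chrom:
                continue
            if site.strand in STRANDS and site.strand != intron.strand:
                continue
            if any(site.start < e and site.end > s for s, e in ivs):
                prof = profiles.setdefault(iid, BindingProfile(intron_id=iid))
                prof.add_site(site.rbp, _midpoint_pct(intron, site))
    return profiles
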