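"""FLEXI calling from paired-end alignments.

A FLEXI fragment is a continuous (splice-free) read-pair fragment whose span
begins and ends at or within ``end_window`` nucleotides (default 3) of an
annotated intron's splice sites.  Soft-clipped bases — non-templated
nucleotides added to cDNA 3' ends during library preparation — are excluded
from the span so that tailed full-length reads still qualify.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd
import pysam

from flexiscan.annotations import IntronCatalog, IntronRecord

logger = logging.getLogger(__name__)


@dataclass
class AlignmentFragment:
    """Span of a properly paired read pair, 0-based half-open.

    ``frag_start``/``frag_end`` run from the leftmost to the rightmost aligned
    base of the pair, excluding soft clips.  ``is_continuous`` is False when
    either mate's CIGAR contains a reference skip (N).  ``mate_spans`` holds
    the aligned interval of each mate.
    """

    chrom: str
    frag_start: int
    frag_end: int
    strand: str
    is_continuous: bool = True
    softclip_5: int = 0
    softclip_3: int = 0
    mate_spans: tuple = ()
    name: str = ""

    def __post_init__(self):
        if self.frag_end <= self.frag_start:
            raise ValueError("fragment end <= start")
        if self.softclip_5 < 0 or self.softclip_3 < 0:
            raise ValueError("negative soft clip")


@dataclass
class FlexiCall:
    """Per-intron per-sample FLEXI detection result."""

    intron_id: str
    sample_id: str
    n_flexi_fragments: int = 0
    n_intron_fragments: int = 0
    n_exon_junction: int = 0
    rpm: float = 0.0
    end_offset_hist_5: Counter = field(default_factory=Counter)
    end_offset_hist_3: Counter = field(default_factory=Counter)
    offset_pairs: Counter = field(default_factory=Counter)

    @property
    def full_length_fraction(self) -> float:
        if self.n_intron_fragments == 0:
            return 0.0
        return self.n_flexi_fragments / self.n_intron_fragments


def fragments_from_alignments(
    alignments: Union[str, Path, pysam.AlignmentFile],
) -> Iterator[AlignmentFragment]:
    """Yield one fragment per properly paired primary pair of a
    coordinate-sorted SAM/BAM.

    Secondary, supplementary, and unmapped records are ignored; orphan mates
    are skipped (counted in the log).  Fragment strand follows the library
    orientation of read 1 (forward read 1 = '+').
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r")
        own = True
    so = (alignments.header.to_dict().get("HD") or {}).get("SO")
    if so not in (None, "coordinate"):
        raise ValueError(f"alignments must be coordinate-sorted, got SO:{so}")
    pending: dict[str, pysam.AlignedSegment] = {}
    n_orphans = 0
    try:
        for read in alignments:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
            ):
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            frag = _pair_to_fragment(mate, read)
            if frag is not None:
                yield frag
        n_orphans = len(pending)
    finally:
        if own:
            alignments.close()
    if n_orphans:
        logger.warning("skipped %d orphan mates", n_orphans)


def _clips(read: pysam.AlignedSegment) -> tuple[int, int]:
    cig = read.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] == 4 else 0
    right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    return left, right


def _pair_to_fragment(a: pysam.AlignedSegment, b: pysam.AlignedSegment):
    if a.reference_name != b.reference_name:
        return None
    left, right = (a, b) if a.reference_start <= b.reference_start else (b, a)
    frag_start = left.reference_start
    frag_end = max(left.reference_end, right.reference_end)
    continuous = not any(
        op == 3 for op, _ in (a.cigartuples or [])
    ) and not any(op == 3 for op, _ in (b.cigartuples or []))
    r1 = a if a.is_read1 else b
    strand = "-" if r1.is_reverse else "+"
    sc5, _ = _clips(left)
    _, sc3 = _clips(right if right.reference_end >= left.reference_end else left)
    return AlignmentFragment(
        chrom=a.reference_name,
        frag_start=frag_start,
        frag_end=frag_end,
        strand=strand,
        is_continuous=continuous,
        softclip_5=sc5,
        softclip_3=sc3,
        mate_spans=(
            (a.reference_start, a.reference_end),
            (b.reference_start, b.reference_end),
        ),
        name=a.query_name,
    )


def _flexi_candidates(
    frag: AlignmentFragment,
    catalog: IntronCatalog,
    end_window: int,
    require_strand: bool,
) -> list[tuple[IntronRecord, int, int]]:
    """Introns for which the fragment satisfies the end-window rule, with the
    signed (5', 3') genomic offsets (positive = outside the intron start /
    past the intron end)."""
    strand = frag.strand if require_strand else None
    out = []
    for intron in catalog.overlapping(
        frag.chrom, frag.frag_start - end_window, frag.frag_end + end_window, strand
    ):
        off_l = frag.frag_start - intron.start
        off_r = frag.frag_end - intron.end
        if abs(off_l) <= end_window and abs(off_r) <= end_window:
            out.append((intron, off_l, off_r))
    return out


def _signed_offsets(intron: IntronRecord, off_l: int, off_r: int) -> tuple[int, int]:
    """Orient genomic left/right offsets to the intron's 5'/3' ends.

    Convention: negative = inside the intron, positive = extending into the
    flanking exon.
    """
    if intron.strand == "+":
        return -off_l, off_r
    return off_r, -off_l


def call_flexis(
    fragments: Iterable[AlignmentFragment],
    catalog: IntronCatalog,
    sample_id: str,
    end_window: int = 3,
    total_mapped: Optional[int] = None,
    require_strand: bool = True,
) -> dict[str, FlexiCall]:
    """Call FLEXIs: continuous fragments beginning and ending within
    ``end_window`` nt of an intron's annotated splice sites.

    Every fragment overlapping an intron by >=1 nt increments that intron's
    ``n_intron_fragments``; pairs with one mate fully inside the intron and
    the other extending into a flanking exon increment ``n_exon_junction``.
    A :class:`FlexiCall` is emitted for every intron with >=1 FLEXI fragment
    (RPM computed against ``total_mapped``, default the number of fragments
    seen).  A fragment satisfying the window rule for two introns is assigned
    to the one with the smaller total |offset|; exact ties are skipped with a
    warning.
    """
    if end_window < 0:
        raise ValueError("end_window must be >= 0")
    if not require_strand:
        warnings.warn("strand agreement disabled; introns matched on both strands")
    calls: dict[str, FlexiCall] = {}
    n_fragments = 0

    def _call(intron_id: str) -> FlexiCall:
        if intron_id not in calls:
            calls[intron_id] = FlexiCall(intron_id=intron_id, sample_id=sample_id)
        return calls[intron_id]

    for frag in fragments:
        n_fragments += 1
        strand = frag.strand if require_strand else None
        overlapped = catalog.overlapping(frag.chrom, frag.frag_start, frag.frag_end, strand)
        for intron in overlapped:
            c = _call(intron.intron_id)
            c.n_intron_fragments += 1
            if frag.mate_spans and _is_exon_junction(frag, intron):
                c.n_exon_junction += 1
        if not frag.is_continuous:
            continue
        cands = _flexi_candidates(frag, catalog, end_window, require_strand)
        if not cands:
            continue
        if len(cands) > 1:
            cands.sort(key=lambda t: (abs(t[1]) + abs(t[2]), t[0].intron_id))
            if abs(cands[0][1]) + abs(cands[0][2]) == abs(cands[1][1]) + abs(cands[1][2]):
                warnings.warn(
                    f"fragment {frag.name or frag.frag_start} ambiguous between "
                    f"{cands[0][0].intron_id} and {cands[1][0].intron_id}; skipped"
                )
                continue
        intron, off_l, off_r = cands[0]
        off5, off3 = _signed_offsets(intron, off_l, off_r)
        c = _call(intron.intron_id)
        c.n_flexi_fragments += 1
        c.end_offset_hist_5[off5] += 1
        c.end_offset_hist_3[off3] += 1
        c.offset_pairs[(off5, off3)] += 1

    denom = total_mapped if total_mapped is not None else n_fragments
    out = {k: v for k, v in calls.items() if v.n_flexi_fragments >= 1}
    for c in out.values():
        c.rpm = c.n_flexi_fragments / denom * 1e6 if denom else 0.0
    return out


def _is_exon_junction(frag: AlignmentFragment, intron: IntronRecord) -> bool:
    """One mate fully inside the intron, the other extending past a boundary."""
    inside = [
        intron.start <= s and e <= intron.end for s, e in frag.mate_spans
    ]
    outside = [s < intron.start or e > intron.end for s, e in frag.mate_spans]
    return (inside[0] and outside[1]) or (inside[1] and outside[0])


# ------------------------------------------------------------------ summaries


def length_fraction_histogram(
    fragments: Iterable[AlignmentFragment],
    catalog: IntronCatalog,
    flexi_intron_ids: Optional[set] = None,
    exclude_sno: bool = False,
    bin_pct: int = 10,
    require_strand: bool = True,
) -> pd.DataFrame:
    """Histogram of fragment span as a percentage of intron length, per intron
    class (FLEXI-called vs other), in ``bin_pct``-wide bins with a final
    '>100%' bin.  Percentages per class sum to 100.

    ``exclude_sno`` drops fragments on snoRNA/scaRNA-encoding introns.
    """
    edges = list(range(0, 101, bin_pct))
    labels = [f"{a}-{b}%" for a, b in zip(edges, edges[1:])] + [">100%"]
    counts = {cls: Counter() for cls in ("flexi", "other")}
    flexi_intron_ids = flexi_intron_ids or set()
    for frag in fragments:
        strand = frag.strand if require_strand else None
        for intron in catalog.overlapping(frag.chrom, frag.frag_start, frag.frag_end, strand):
            if exclude_sno and intron.flags.get("snoRNA_encoding"):
                continue
            pct = (frag.frag_end - frag.frag_start) / intron.length * 100
            if pct > 100:
                label = ">100%"
            else:
                idx = min(int(pct // bin_pct), len(edges) - 2)
                label = labels[idx]
            cls = "flexi" if intron.intron_id in flexi_intron_ids else "other"
            counts[cls][label] += 1
    rows = []
    for cls, c in counts.items():
        total = sum(c.values())
        for label in labels:
            rows.append(
                {
                    "intron_class": cls,
                    "bin": label,
                    "count": c[label],
                    "pct": c[label] / total * 100 if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def end_offset_profile(
    flexi_calls: Iterable[FlexiCall], end_window: int = 3
) -> pd.DataFrame:
    """Pooled 2-D (5' offset x 3' offset) percentage table over all calls.

    Offsets beyond the window are pooled into '<-w' / '>+w' tails; percentages
    sum to 100.
    """
    pooled: Counter = Counter()
    for call in flexi_calls:
        pooled.update(call.offset_pairs)
    total = sum(pooled.values())

    def _bucket(off: int) -> str:
        if off < -end_window:
            return f"<-{end_window}"
        if off > end_window:
            return f">+{end_window}"
        return str(off)

    axis = [f"<-{end_window}"] + [str(i) for i in range(-end_window, end_window + 1)] + [
        f">+{end_window}"
    ]
    table = pd.DataFrame(0.0, index=axis, columns=axis)
    for (o5, o3), n in pooled.items():
        table.loc[_bucket(o5), _bucket(o3)] += n
    if total:
        table = table / total * 100
    table.index.name = "offset_5p"
    table.columns.name = "offset_3p"
    return table


def calls_to_frame(calls: dict[str, FlexiCall]) -> pd.DataFrame:
    rows = [
        {
            "intron_id": c.intron_id,
            "sample_id": c.sample_id,
            "n_flexi_fragments": c.n_flexi_fragments,
            "n_intron_fragments": c.n_intron_fragments,
            "n_exon_junction": c.n_exon_junction,
            "full_length_fraction": c.full_length_fraction,
            "rpm": c.rpm,
        }
        for c in calls.values()
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "intron_id",
            "sample_id",
            "n_flexi_fragments",
            "n_intron_fragments",
            "n_exon_junction",
            "full_length_fraction",
            "rpm",
        ],
    )
    return df.sort_values("intron_id").reset_index(drop=True)
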