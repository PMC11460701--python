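"""Intron catalog construction from gene annotations.

Introns are the gaps between consecutive exons of a transcript.  The catalog
deduplicates introns shared between isoforms/genes on (chrom, start, end,
strand), labels each by size class (short = length <= ``short_threshold``,
default 300 nt), and carries category flags: embedded snoRNA/scaRNA, agotron,
mirtron, shared splice site with a longer intron, annotated retained intron,
and in-frame retention.

Coordinates are 0-based half-open throughout the package; GTF (1-based,
closed) is converted on read, BED is consumed natively.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class IntronRecord:
    """One deduplicated annotated intron.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``length``
    equals ``end - start``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str
    size_class: str = "short"
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"intron end {self.end} <= start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def intron_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    @staticmethod
    def parse_id(intron_id: str) -> tuple[str, int, int, str]:
        m = re.fullmatch(r"(.+):(\d+)-(\d+)\(([+-])\)", intron_id)
        if m is None:
            raise ValueError(f"unparseable intron_id {intron_id!r}")
        return m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)


FLAG_NAMES = (
    "snoRNA_encoding",
    "agotron",
    "mirtron",
    "shares_ss_with_longer",
    "annotated_retained_intron",
    "in_frame_retained",
    "alt_spliced",
)


class IntronCatalog:
    """Ordered, deduplicated intron collection with interval lookup.

    Records are kept in deterministic order (chrom, start, end, strand).
    ``overlapping`` returns exactly the records intersecting a query interval
    on the requested strand.
    """

    def __init__(self, records: Sequence[IntronRecord], short_threshold: int = 300):
        seen = set()
        uniq = []
        for r in records:
            key = (r.chrom, r.start, r.end, r.strand)
            if key in seen:
                continue
            seen.add(key)
            uniq.append(r)
        uniq.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
        for r in uniq:
            r.size_class = "short" if r.length <= short_threshold else "long"
        self.records: list[IntronRecord] = uniq
        self.short_threshold = short_threshold
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for i, r in enumerate(uniq):
            self._trees.setdefault((r.chrom, r.strand), IntervalTree()).addi(
                r.start, r.end, i
            )
        self._by_id = {r.intron_id: r for r in uniq}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IntronRecord]:
        return iter(self.records)

    def __getitem__(self, intron_id: str) -> IntronRecord:
        return self._by_id[intron_id]

    def __contains__(self, intron_id: str) -> bool:
        return intron_id in self._by_id

    def overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[IntronRecord]:
        """Records overlapping [start, end) by >=1 nt; strand=None matches both."""
        strands = STRANDS if strand is None else (strand,)
        hits = []
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is None:
                continue
            hits.extend(iv.data for iv in tree.overlap(start, end))
        return [self.records[i] for i in sorted(set(hits))]

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "intron_id": r.intron_id,
                "gene_id": r.gene_id,
                "strand": r.strand,
                "gene_name": r.gene_name,
                "length": r.length,
                "size_class": r.size_class,
            }
            for f in FLAG_NAMES:
                row[f] = r.flags.get(f)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], short_threshold: int = 300) -> "IntronCatalog":
        df = pd.read_csv(path, sep="\t")
        records = []
        for row in df.itertuples(index=False):
            flags = {}
            for f in FLAG_NAMES:
                v = getattr(row, f, None)
                if pd.notna(v):
                    flags[f] = bool(v)
            records.append(
                IntronRecord(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    gene_id=row.gene_id,
                    gene_name=row.gene_name,
                    flags=flags,
                )
            )
        return cls(records, short_threshold=short_threshold)


# ---------------------------------------------------------------------- GTF


def _parse_attributes(attr_field: str) -> dict:
    return dict(_ATTR_RE.findall(attr_field))


def iter_gtf_features(
    lines: Iterable[str], feature_types: Optional[set] = None
) -> Iterator[dict]:
    """Yield GTF features as dicts with 0-based half-open coordinates.

    Raises :class:`GtfParseError` with the offending line number on malformed
    input.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, frame, attrs = fields
        if feature_types is not None and ftype not in feature_types:
            continue
        try:
            start_i = int(start) - 1  # GTF is 1-based inclusive
            end_i = int(end)
        except ValueError:
            raise GtfParseError(lineno, f"non-integer coordinates {start!r}/{end!r}")
        if strand not in ("+", "-", "."):
            raise GtfParseError(lineno, f"bad strand {strand!r}")
        yield {
            "chrom": chrom,
            "type": ftype,
            "start": start_i,
            "end": end_i,
            "strand": strand,
            "frame": frame,
            "attributes": _parse_attributes(attrs),
            "lineno": lineno,
        }


def _open_lines(annotation: Union[str, Path, Iterable[str]]) -> list[str]:
    if isinstance(annotation, (str, Path)):
        return Path(annotation).read_text().splitlines()
    return list(annotation)


def _transcript_exons(lines: list[str]) -> dict[str, dict]:
    """Group exon features by transcript_id; each value has chrom/strand/gene
    info and the sorted exon list."""
    transcripts: dict[str, dict] = {}
    for feat in iter_gtf_features(lines, feature_types={"exon"}):
        attrs = feat["attributes"]
        tid = attrs.get("transcript_id")
        if tid is None:
            raise GtfParseError(feat["lineno"], "exon without transcript_id")
        tx = transcripts.setdefault(
            tid,
            {
                "chrom": feat["chrom"],
                "strand": feat["strand"],
                "gene_id": attrs.get("gene_id", ""),
                "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                "exons": [],
            },
        )
        tx["exons"].append((feat["start"], feat["end"]))
    for tx in transcripts.values():
        tx["exons"].sort()
    return transcripts


def build_intron_catalog(
    annotation: Union[str, Path, Iterable[str]], short_threshold: int = 300
) -> IntronCatalog:
    """Extract introns as gaps between consecutive exons of each transcript,
    deduplicate on (chrom, start, end, strand), and label size classes.

    Both short and long introns are retained.  Gene attribution for an intron
    shared by several genes with identical coordinates is the lexicographically
    first gene_id (deterministic).  Transcripts with overlapping exons are
    skipped with a warning.
    """
    lines = _open_lines(annotation)
    transcripts = _transcript_exons(lines)
    best_gene: dict[tuple, tuple[str, str]] = {}
    for tid in sorted(transcripts):
        tx = transcripts[tid]
        exons = tx["exons"]
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            warnings.warn(f"transcript {tid} has overlapping exons; skipped")
            continue
        if tx["strand"] not in STRANDS:
            warnings.warn(f"transcript {tid} unstranded; skipped")
            continue
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 == s2:  # abutting exons leave no intron
                continue
            key = (tx["chrom"], e1, s2, tx["strand"])
            cand = (tx["gene_id"], tx["gene_name"])
            if key not in best_gene or cand[0] < best_gene[key][0]:
                best_gene[key] = cand
    records = [
        IntronRecord(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            gene_id=gid,
            gene_name=gname,
        )
        for (chrom, start, end, strand), (gid, gname) in best_gene.items()
    ]
    return IntronCatalog(records, short_threshold=short_threshold)


# ------------------------------------------------------------ category flags


def read_bed_intervals(path: Union[str, Path]) -> pd.DataFrame:
    """Read a BED(6) file into a DataFrame (chrom, start, end, name, score,
    strand); missing columns filled."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(cols)]
    df.columns = cols[: df.shape[1]]
    for c, default in (("name", "."), ("score", 0), ("strand", ".")):
        if c not in df.columns:
            df[c] = default
    return df


# categories requiring the interval to lie fully inside the intron
_CONTAINMENT_CATEGORIES = {"snoRNA_encoding"}
_CATEGORY_FLAGS = {
    "sno": "snoRNA_encoding",
    "agotron": "agotron",
    "mirtron": "mirtron",
}


def flag_category_overlaps(
    catalog: IntronCatalog,
    category_intervals: dict[str, Union[str, Path, pd.DataFrame]],
) -> IntronCatalog:
    """Set category flags on the catalog's records (in place; catalog returned).

    ``category_intervals`` maps category names ('sno', 'agotron', 'mirtron')
    to BED paths or DataFrames.  A flag is set on >=1 nt same-strand overlap;
    snoRNA/scaRNA additionally requires the sncRNA interval fully inside the
    intron.  Unstranded BED rows match both strands (with a warning).
    """
    for r in catalog:
        for flag in _CATEGORY_FLAGS.values():
            r.flags.setdefault(flag, False)
    for name, bed in category_intervals.items():
        if name not in _CATEGORY_FLAGS:
            raise ValueError(
                f"unknown category {name!r}; expected one of {sorted(_CATEGORY_FLAGS)}"
            )
        flag = _CATEGORY_FLAGS[name]
        df = bed if isinstance(bed, pd.DataFrame) else read_bed_intervals(bed)
        for row in df.itertuples(index=False):
            strand = getattr(row, "strand", ".")
            if strand not in STRANDS:
                warnings.warn(
                    f"unstranded {name} interval {row.chrom}:{row.start}-{row.end}; "
                    "matching both strands"
                )
                strand = None
            for intron in catalog.overlapping(row.chrom, int(row.start), int(row.end), strand):
                if flag in _CONTAINMENT_CATEGORIES:
                    if intron.start <= int(row.start) and int(row.end) <= intron.end:
                        intron.flags[flag] = True
                else:
                    intron.flags[flag] = True
    return catalog


def _cds_frames(lines: list[str]) -> dict[str, list[tuple[int, int, int]]]:
    """Per transcript, CDS intervals with their annotated frame."""
    out: dict[str, list[tuple[int, int, int]]] = {}
    for feat in iter_gtf_features(lines, feature_types={"CDS"}):
        tid = feat["attributes"].get("transcript_id", "")
        frame = feat["frame"]
        out.setdefault(tid, []).append(
            (feat["start"], feat["end"], int(frame) if frame.isdigit() else 0)
        )
    for v in out.values():
        v.sort()
    return out


def flag_splice_relationships(
    catalog: IntronCatalog,
    annotation: Union[str, Path, Iterable[str]],
    genome=None,
) -> IntronCatalog:
    """Flag shared splice sites, annotated retained introns, in-frame
    retention, and alternative splicing.

    ``shares_ss_with_longer``: another catalog intron of greater length shares
    this intron's start or end on the same strand.  ``annotated_retained_intron``:
    some transcript's exon fully covers the intron.  ``in_frame_retained``
    additionally requires length divisible by 3 and, when a genome sequence
    source is given, no stop codon in the frame continued from the upstream
    exon (frame from CDS annotation); without CDS or genome the flag is null.
    ``alt_spliced``: the intron is absent from >=1 overlapping transcript of
    the same gene.
    """
    lines = _open_lines(annotation)
    transcripts = _transcript_exons(lines)
    cds = _cds_frames(lines)

    by_boundary: dict[tuple[str, str, str, int], list[int]] = {}
    for r in catalog:
        by_boundary.setdefault((r.chrom, r.strand, "start", r.start), []).append(r.length)
        by_boundary.setdefault((r.chrom, r.strand, "end", r.end), []).append(r.length)
    for r in catalog:
        starts = by_boundary[(r.chrom, r.strand, "start", r.start)]
        ends = by_boundary[(r.chrom, r.strand, "end", r.end)]
        r.flags["shares_ss_with_longer"] = any(
            l > r.length for l in starts
        ) or any(l > r.length for l in ends)

    exon_trees: dict[tuple[str, str], IntervalTree] = {}
    tx_trees: dict[tuple[str, str], IntervalTree] = {}
    tx_introns: dict[str, set] = {}
    for tid, tx in transcripts.items():
        key = (tx["chrom"], tx["strand"])
        exons = tx["exons"]
        if not exons:
            continue
        tx_trees.setdefault(key, IntervalTree()).addi(exons[0][0], exons[-1][1], tid)
        introns = set()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                introns.add((e1, s2))
        tx_introns[tid] = introns
        for s, e in exons:
            exon_trees.setdefault(key, IntervalTree()).addi(s, e, tid)

    for r in catalog:
        key = (r.chrom, r.strand)
        etree = exon_trees.get(key)
        covering = (
            [iv for iv in etree.overlap(r.start, r.end) if iv.begin <= r.start and iv.end >= r.end]
            if etree
            else []
        )
        retained = bool(covering)
        r.flags["annotated_retained_intron"] = retained
        if retained and r.length % 3 == 0:
            r.flags["in_frame_retained"] = _in_frame_retained(r, covering, cds, genome)
        else:
            r.flags["in_frame_retained"] = False if retained or r.length % 3 else False

        ttree = tx_trees.get(key)
        alt = False
        if ttree is not None:
            gene_tids = {
                iv.data
                for iv in ttree.overlap(r.start, r.end)
                if transcripts[iv.data]["gene_id"] == r.gene_id
            }
            alt = any((r.start, r.end) not in tx_introns.get(t, set()) for t in gene_tids)
        r.flags["alt_spliced"] = alt
    return catalog


_STOPS_PLUS = {"TAA", "TAG", "TGA"}


def _in_frame_retained(intron: IntronRecord, covering, cds, genome) -> Optional[bool]:
    """In-frame retention check: needs CDS phase and a genome sequence source.

    Returns None (flag null) with a warning when either is unavailable.
    """
    if genome is None:
        warnings.warn(
            f"in-frame evaluation for {intron.intron_id} needs a genome sequence; flag null"
        )
        return None
    # frame from any CDS whose reading frame runs into the intron boundary
    frame_offset = None
    for tid in sorted(cds):
        for cs, ce, frame in cds[tid]:
            if cs <= intron.start < ce:
                # reading-frame position of intron start within the CDS
                if intron.strand == "+":
                    frame_offset = ((intron.start - cs) - frame) % 3
                else:
                    frame_offset = ((ce - intron.end) - frame) % 3
                break
        if frame_offset is not None:
            break
    if frame_offset is None:
        warnings.warn(
            f"no CDS phase available for retained intron {intron.intron_id}; flag null"
        )
        return None
    seq = _fetch_seq(genome, intron)
    # codons continuing the upstream exon frame
    start = (3 - frame_offset) % 3
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS_PLUS:
            return False
    return True


_COMP = str.maketrans("ACGTN", "TGCAN")


def _fetch_seq(genome, intron: IntronRecord) -> str:
    """Spliced-strand intron sequence from a pyfaidx.Fasta-like or dict source."""
    if isinstance(genome, dict):
        s = genome[intron.chrom][intron.start : intron.end]
    else:
        s = str(genome[intron.chrom][intron.start : intron.end])
    s = s.upper()
    if intron.strand == "-":
        s = s.translate(_COMP)[::-1]
    return s
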