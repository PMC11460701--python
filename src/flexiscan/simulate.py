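"""Synthetic-data generator with full ground truth.

Produces a toy genome (FASTA), gene annotation (GTF), coordinate-sorted
paired-end alignments (SAM), RBP binding-site BED files with planted
co-enrichment clusters, a per-base conservation bedGraph, and sncRNA
copy-number standards, so that every pipeline stage is testable without any
download.

The read model emulates full-length excised linear intron sequencing:
planted FLEXI introns emit continuous read pairs spanning the intron with
small end offsets (default mostly 0, within +/-3 nt) and occasional
soft-clipped non-templated 3' tails; non-FLEXI introns emit fragmented
sub-intron pairs; exons emit exonic and exon-junction pairs.  RBP site files
plant clusters of co-occurring RBPs on disjoint intron subsets over a uniform
background, and the standards follow a configurable log10-log10 linear
copy-number model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from flexiscan.annotations import IntronCatalog, build_intron_catalog

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class RbpClusterSpec:
    """One planted co-enrichment cluster: every member RBP receives a site on
    each target intron with probability ``site_probability``."""

    rbps: list
    n_target_introns: int = 40
    site_probability: float = 1.0
    location: str = "interior"  # interior | ss_spanning_in | ss_spanning_out


def default_rbp_clusters() -> list:
    return [
        RbpClusterSpec(["AGO1", "AGO2", "DICER", "LARP4"], 40, 1.0, "interior"),
        RbpClusterSpec(["DKC1", "NOLC1", "AATF", "SMNDC1"], 40, 1.0, "ss_spanning_in"),
        RbpClusterSpec(["SRSF1", "U2AF2", "PRPF8", "SF3B4"], 40, 1.0, "interior"),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults give ~60 genes x 3 introns with mostly short (60-300 nt)
    introns, roughly 85% of short introns planted as FLEXIs with 20-60
    full-length read pairs each, end offsets concentrated at 0 within the
    +/-3 nt window with a small out-of-window tail, and three planted
    4-RBP co-enrichment clusters on 40-intron subsets over a uniform
    background.
    """

    n_genes: int = 60
    introns_per_gene: int = 3
    exon_len_range: tuple = (80, 200)
    short_intron_len_range: tuple = (60, 300)
    long_intron_len_range: tuple = (320, 1200)
    long_intron_fraction: float = 0.15
    gc_content: float = 0.5
    u12_fraction: float = 0.06
    flexi_fraction: float = 0.85
    reads_per_flexi: tuple = (20, 60)
    # probabilities for offsets -3..+3 (centered list of 7), plus a rate of
    # offsets outside the window (drawn from +/-{4,5})
    end_offset_probs: tuple = (0.01, 0.04, 0.10, 0.70, 0.10, 0.04, 0.01)
    out_of_window_rate: float = 0.10
    nta_tail_rate: float = 0.3
    nta_tail_len_range: tuple = (1, 3)
    reads_per_other_intron: tuple = (5, 20)
    exonic_reads_per_gene: int = 8
    exon_junction_reads_per_flexi: int = 2
    rbp_clusters: list = field(default_factory=default_rbp_clusters)
    n_background_rbps: int = 12
    background_site_rate: float = 0.05
    conserved_fraction: float = 0.2
    conserved_mean: float = 0.9
    nonconserved_mean: float = 0.15
    copy_model: tuple = (1.0, 2.0, 0.1)  # slope, intercept, log10 noise sd
    n_standards: int = 12
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (
            self.exon_len_range,
            self.short_intron_len_range,
            self.long_intron_len_range,
            self.reads_per_flexi,
            self.nta_tail_len_range,
            self.reads_per_other_intron,
        ):
            if lo > hi or lo < 1:
                raise ValueError("length/count ranges must be ordered and positive")
        for p in (
            self.long_intron_fraction,
            self.flexi_fraction,
            self.out_of_window_rate,
            self.nta_tail_rate,
            self.background_site_rate,
            self.conserved_fraction,
            self.u12_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.end_offset_probs) - 1.0) > 1e-9:
            raise ValueError("end_offset_probs must sum to 1")


@dataclass
class PlantedIntron:
    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    size_class: str
    is_flexi: bool
    splice_type: str  # u2 | u12
    conserved_mean: float


@dataclass
class SyntheticTruth:
    planted_flexi_ids: list = field(default_factory=list)
    introns: dict = field(default_factory=dict)  # intron_id -> PlantedIntron fields
    flexi_read_counts: dict = field(default_factory=dict)
    flexi_offsets: dict = field(default_factory=dict)  # intron_id -> [(off5, off3)]
    n_fragments_total: int = 0
    rbp_cluster_members: dict = field(default_factory=dict)  # cluster -> rbps
    rbp_cluster_introns: dict = field(default_factory=dict)  # cluster -> intron ids
    background_rbps: list = field(default_factory=list)
    copy_model: tuple = (1.0, 2.0, 0.1)

    def to_json(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


# ------------------------------------------------------------------- genome

U12_5SS = "GTATCCTTT"
U2_5SS = "GTAAGT"
U2_BP = "CTAAC"
U12_BP = "TTCCTTAAC"


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _intron_seq(rng: np.random.Generator, length: int, gc: float, splice_type: str) -> str:
    """Spliced-strand intron sequence with planted splice-site and
    branch-point consensus."""
    body = list(_random_seq(rng, length, gc))
    if splice_type == "u12":
        five = U12_5SS
        bp = U12_BP
        body[-2:] = "AC"
        body[0:2] = "AT"
    else:
        five = U2_5SS
        bp = U2_BP
        body[-2:] = "AG"
        body[0:2] = "GT"
    body[: len(five)] = five if splice_type == "u2" else U12_5SS
    if splice_type == "u12":
        body[0:2] = "AT"  # AU-AC minor-class ends
    # branch point ~25 nt upstream of the 3' end
    bp_start = length - 25 - len(bp)
    if bp_start > len(five):
        body[bp_start : bp_start + len(bp)] = bp
    return "".join(body)


def simulate_genome_and_annotation(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict, list, SyntheticTruth]:
    """Random genome and annotation with planted intron structure.

    Returns (genome dict {chrom: sequence}, GTF lines, truth).  Planted
    major-class (U2) introns carry GU...AG ends with a branch-point consensus
    in the last 40 nt; minor-class (U12) introns carry AU...AC ends.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    truth = SyntheticTruth(copy_model=tuple(config.copy_model))
    chrom = "chrS1"
    parts: list[str] = []
    gtf: list[str] = []
    pos = 0
    short_ids: list[str] = []
    for g in range(config.n_genes):
        gid = f"G{g:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(100, 300))
        parts.append(_random_seq(rng, gap, config.gc_content))
        pos += gap
        exon_lens = rng.integers(
            config.exon_len_range[0],
            config.exon_len_range[1] + 1,
            size=config.introns_per_gene + 1,
        )
        introns = []
        for _ in range(config.introns_per_gene):
            if rng.random() < config.long_intron_fraction:
                lo, hi = config.long_intron_len_range
                size_class = "long"
            else:
                lo, hi = config.short_intron_len_range
                size_class = "short"
            length = int(rng.integers(lo, hi + 1))
            splice_type = "u12" if rng.random() < config.u12_fraction else "u2"
            introns.append((length, size_class, splice_type))
        # lay out exon/intron alternation
        exon_coords = []
        for i, elen in enumerate(exon_lens):
            estart = pos
            parts.append(_random_seq(rng, int(elen), config.gc_content))
            pos += int(elen)
            exon_coords.append((estart, pos))
            if i < len(introns):
                ilen, size_class, splice_type = introns[i]
                iseq = _intron_seq(rng, ilen, config.gc_content, splice_type)
                genomic = iseq if strand == "+" else _revcomp(iseq)
                parts.append(genomic)
                istart = pos
                pos += ilen
                conserved = rng.random() < config.conserved_fraction
                mean = config.conserved_mean if conserved else config.nonconserved_mean
                rec = PlantedIntron(
                    intron_id=f"{chrom}:{istart}-{pos}({strand})",
                    gene_id=gid,
                    chrom=chrom,
                    start=istart,
                    end=pos,
                    strand=strand,
                    size_class=size_class,
                    is_flexi=False,
                    splice_type=splice_type,
                    conserved_mean=round(mean, 4),
                )
                truth.introns[rec.intron_id] = asdict(rec)
                if size_class == "short":
                    short_ids.append(rec.intron_id)
        tid = f"{gid}.t1"
        gstart, gend = exon_coords[0][0], exon_coords[-1][1]
        attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}";'
        gtf.append(
            f"{chrom}\tsim\ttranscript\t{gstart+1}\t{gend}\t.\t{strand}\t.\t{attrs}"
        )
        for es, ee in exon_coords:
            gtf.append(f"{chrom}\tsim\texon\t{es+1}\t{ee}\t.\t{strand}\t.\t{attrs}")
    parts.append(_random_seq(rng, 200, config.gc_content))
    genome = {chrom: "".join(parts)}

    n_flexi = int(round(config.flexi_fraction * len(short_ids)))
    flexi_ids = sorted(
        np.array(short_ids)[rng.choice(len(short_ids), size=n_flexi, replace=False)]
    )
    for iid in flexi_ids:
        truth.introns[iid]["is_flexi"] = True
    truth.planted_flexi_ids = list(flexi_ids)
    return genome, gtf, truth


# -------------------------------------------------------------------- reads


def _sample_offset(rng: np.random.Generator, config: SimConfig) -> int:
    if rng.random() < config.out_of_window_rate:
        return int(rng.choice([-5, -4, 4, 5]))
    return int(rng.choice(np.arange(-3, 4), p=np.array(config.end_offset_probs)))


class _SamWriter:
    def __init__(self, genome: dict):
        self.genome = genome
        self.records: list[tuple[str, int, str]] = []
        self._n = 0

    def add_pair(
        self,
        chrom: str,
        frag_start: int,
        frag_end: int,
        strand: str,
        tail3: int = 0,
        rng: Optional[np.random.Generator] = None,
        prefix: str = "frag",
        mate_spans: Optional[tuple] = None,
    ) -> None:
        """Emit a properly paired pair covering [frag_start, frag_end).

        ``tail3`` adds a soft-clipped non-templated tail at the fragment's
        RNA 3' end (genomic right on '+', genomic left on '-').
        """
        self._n += 1
        name = f"{prefix}{self._n:07d}"
        L = frag_end - frag_start
        mlen = max(min(L, int(np.ceil(L * 0.6))), 1)
        if mate_spans is None:
            left_span = (frag_start, frag_start + mlen)
            right_span = (frag_end - mlen, frag_end)
        else:
            left_span, right_span = mate_spans
        seq_l = self.genome[chrom][left_span[0] : left_span[1]]
        seq_r = self.genome[chrom][right_span[0] : right_span[1]]
        cig_l = f"{left_span[1]-left_span[0]}M"
        cig_r = f"{right_span[1]-right_span[0]}M"
        if tail3 > 0:
            tail = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=tail3)]
            ) if rng is not None else "A" * tail3
            if strand == "+":
                cig_r = f"{right_span[1]-right_span[0]}M{tail3}S"
                seq_r = seq_r + tail
            else:
                cig_l = f"{tail3}S{left_span[1]-left_span[0]}M"
                seq_l = tail + seq_l
        tlen = frag_end - frag_start
        if strand == "+":
            flag_l, flag_r = 99, 147  # R1 forward / R2 reverse
        else:
            flag_l, flag_r = 163, 83  # R2 forward / R1 reverse
        rec_l = (
            f"{name}\t{flag_l}\t{chrom}\t{left_span[0]+1}\t60\t{cig_l}\t=\t"
            f"{right_span[0]+1}\t{tlen}\t{seq_l}\t*"
        )
        rec_r = (
            f"{name}\t{flag_r}\t{chrom}\t{right_span[0]+1}\t60\t{cig_r}\t=\t"
            f"{left_span[0]+1}\t{-tlen}\t{seq_r}\t*"
        )
        self.records.append((chrom, left_span[0], rec_l))
        self.records.append((chrom, right_span[0], rec_r))

    def lines(self) -> list[str]:
        header = ["@HD\tVN:1.6\tSO:coordinate"]
        for chrom in sorted(self.genome):
            header.append(f"@SQ\tSN:{chrom}\tLN:{len(self.genome[chrom])}")
        body = [rec for _, _, rec in sorted(self.records, key=lambda r: (r[0], r[1]))]
        return header + body


def simulate_alignments(
    config: SimConfig,
    genome: dict,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Emit SAM lines for planted FLEXI pairs, fragmented other-intron pairs,
    exonic pairs, and exon-junction pairs; updates the truth with per-intron
    read counts and offsets."""
    rng = rng or np.random.default_rng(config.seed + 1)
    writer = _SamWriter(genome)
    flexi_set = set(truth.planted_flexi_ids)
    for iid, rec in sorted(truth.introns.items()):
        chrom, start, end, strand = (
            rec["chrom"],
            rec["start"],
            rec["end"],
            rec["strand"],
        )
        if iid in flexi_set:
            n_reads = int(rng.integers(*config.reads_per_flexi))
            offsets = []
            for _ in range(n_reads):
                # genomic offsets at the left/right intron boundaries
                off_l = _sample_offset(rng, config)
                off_r = _sample_offset(rng, config)
                fs, fe = start + off_l, end + off_r
                tail = 0
                if rng.random() < config.nta_tail_rate:
                    tail = int(
                        rng.integers(
                            config.nta_tail_len_range[0],
                            config.nta_tail_len_range[1] + 1,
                        )
                    )
                writer.add_pair(chrom, fs, fe, strand, tail3=tail, rng=rng, prefix="flexi")
                if strand == "+":
                    off5, off3 = -off_l, off_r
                else:
                    off5, off3 = off_r, -off_l
                offsets.append((off5, off3))
            truth.flexi_read_counts[iid] = n_reads
            truth.flexi_offsets[iid] = offsets
            for _ in range(config.exon_junction_reads_per_flexi):
                # one mate inside the intron, the other in the flanking exon
                m1 = (start + 5, min(start + 45, end - 5))
                m2 = (end + 5, end + 45)
                writer.add_pair(
                    chrom, m1[0], m2[1], strand, mate_spans=(m1, m2), prefix="ej"
                )
        else:
            n_reads = int(rng.integers(*config.reads_per_other_intron))
            L = end - start
            for _ in range(n_reads):
                o1 = int(rng.integers(5, max(L // 3, 6)))
                o2 = int(rng.integers(5, max(L // 3, 6)))
                fs, fe = start + o1, end - o2
                if fe - fs < 10:
                    fs, fe = start + 5, end - 5
                writer.add_pair(chrom, fs, fe, strand, prefix="ifrag")
    # exonic pairs: place in intergenic-safe exon interiors via gene gaps
    genes = sorted({rec["gene_id"] for rec in truth.introns.values()})
    by_gene: dict[str, list] = {}
    for rec in truth.introns.values():
        by_gene.setdefault(rec["gene_id"], []).append(rec)
    for gid in genes:
        recs = sorted(by_gene[gid], key=lambda r: r["start"])
        first = recs[0]
        for _ in range(config.exonic_reads_per_gene):
            # upstream exon interior (exons are >= 80 nt)
            fe = first["start"] - 5
            fs = fe - int(rng.integers(40, 70))
            writer.add_pair(first["chrom"], fs, fe, first["strand"], prefix="ex")
    lines = writer.lines()
    truth.n_fragments_total = sum(1 for l in lines if not l.startswith("@")) // 2
    return lines


# ---------------------------------------------------------------- RBP sites


def simulate_rbp_sites(
    config: SimConfig,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """BED6 lines with planted co-enriched site clusters plus uniform
    background sites; updates truth with cluster membership."""
    rng = rng or np.random.default_rng(config.seed + 2)
    flexi_ids = list(truth.planted_flexi_ids)
    lines = []
    used: set = set()
    for ci, spec in enumerate(config.rbp_clusters):
        avail = [i for i in flexi_ids if i not in used]
        if len(avail) < spec.n_target_introns:
            raise ValueError(
                f"not enough unassigned FLEXI introns for cluster {ci} "
                f"({len(avail)} < {spec.n_target_introns})"
            )
        chosen = sorted(
            np.array(avail)[
                rng.choice(len(avail), size=spec.n_target_introns, replace=False)
            ]
        )
        used.update(chosen)
        cname = f"cluster{ci+1}"
        truth.rbp_cluster_members[cname] = list(spec.rbps)
        truth.rbp_cluster_introns[cname] = list(chosen)
        for iid in chosen:
            rec = truth.introns[iid]
            for rbp in spec.rbps:
                if rng.random() >= spec.site_probability:
                    continue
                lines.append(_site_line(rec, rbp, spec.location, rng))
    background = [f"BG{j:02d}" for j in range(config.n_background_rbps)]
    truth.background_rbps = background
    all_introns = sorted(truth.introns)
    for rbp in background:
        for iid in all_introns:
            if rng.random() < config.background_site_rate:
                lines.append(_site_line(truth.introns[iid], rbp, "interior", rng))
    return lines


def _site_line(rec: dict, rbp: str, location: str, rng: np.random.Generator) -> str:
    start, end, L = rec["start"], rec["end"], rec["end"] - rec["start"]
    w = int(rng.integers(10, 21))
    if location == "interior":
        lo = start + max(L // 4, 3)
        hi = max(start + (3 * L) // 4 - w, lo + 1)
        s = int(rng.integers(lo, hi))
        e = s + w
    elif location == "ss_spanning_in":
        # spans a splice site, midpoint just inside the intron
        boundary = start if rng.random() < 0.5 else end
        s = boundary - w // 4 if boundary == start else boundary - (3 * w) // 4
        e = s + w
    elif location == "ss_spanning_out":
        boundary = start if rng.random() < 0.5 else end
        s = boundary - (3 * w) // 4 if boundary == start else boundary - w // 4
        e = s + w
    else:
        raise ValueError(f"unknown site location {location!r}")
    return f"{rec['chrom']}\t{s}\t{e}\t{rbp}\t0\t{rec['strand']}"


# --------------------------------------------- standards and conservation


def simulate_standards(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list:
    """Standards TSV lines: log10(copies) = slope*log10(rpm) + intercept +
    Gaussian noise."""
    rng = rng or np.random.default_rng(config.seed + 3)
    slope, intercept, sd = config.copy_model
    lines = ["name\trpm\tcopies_per_cell"]
    lrpm = rng.uniform(-1, 3, size=config.n_standards)
    for i, lx in enumerate(sorted(lrpm)):
        ly = slope * lx + intercept + (rng.normal(0, sd) if sd > 0 else 0.0)
        lines.append(f"STD{i:02d}\t{10**lx:.6g}\t{10**ly:.6g}")
    return lines


def simulate_conservation_track(truth: SyntheticTruth) -> list:
    """bedGraph lines: each intron covered at its planted mean score."""
    lines = []
    for iid, rec in sorted(truth.introns.items()):
        lines.append(
            f"{rec['chrom']}\t{rec['start']}\t{rec['end']}\t{rec['conserved_mean']}"
        )
    return lines


# ------------------------------------------------------------------ bundler


@dataclass
class SimulatedData:
    genome: dict
    gtf_lines: list
    sam_lines: list
    site_lines: list
    standards_lines: list
    bedgraph_lines: list
    truth: SyntheticTruth
    paths: dict = field(default_factory=dict)


def simulate_all(config: SimConfig, outdir: Optional[Union[str, Path]] = None) -> SimulatedData:
    """Run all generators with seeds derived from ``config.seed``, self-audit
    the outputs against the truth, and (optionally) write the files."""
    genome, gtf, truth = simulate_genome_and_annotation(config)
    sam = simulate_alignments(config, genome, truth)
    sites = simulate_rbp_sites(config, truth)
    standards = simulate_standards(config)
    bedgraph = simulate_conservation_track(truth)
    data = SimulatedData(genome, gtf, sam, sites, standards, bedgraph, truth)
    _self_audit(config, data)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = []
        for chrom, seq in sorted(genome.items()):
            fasta.append(f">{chrom}")
            fasta.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "sam": outdir / "alignments.sam",
            "sites": outdir / "rbp_sites.bed",
            "standards": outdir / "standards.tsv",
            "bedgraph": outdir / "conservation.bedgraph",
            "truth": outdir / "truth.json",
        }
        paths["genome"].write_text("\n".join(fasta) + "\n")
        paths["gtf"].write_text("\n".join(gtf) + "\n")
        paths["sam"].write_text("\n".join(sam) + "\n")
        paths["sites"].write_text("\n".join(sites) + "\n")
        paths["standards"].write_text("\n".join(standards) + "\n")
        paths["bedgraph"].write_text("\n".join(bedgraph) + "\n")
        truth.to_json(paths["truth"])
        data.paths = {k: str(v) for k, v in paths.items()}
    return data


def _self_audit(config: SimConfig, data: SimulatedData) -> None:
    """Cross-check emitted files against the truth before returning."""
    catalog = build_intron_catalog(data.gtf_lines, short_threshold=300)
    got = {r.intron_id for r in catalog}
    want = set(data.truth.introns)
    if got != want:
        raise AssertionError(
            f"self-audit: catalog/truth intron mismatch ({len(got)} vs {len(want)})"
        )
    for r in catalog:
        if r.size_class != data.truth.introns[r.intron_id]["size_class"]:
            raise AssertionError(f"self-audit: size class mismatch for {r.intron_id}")
    n_body = sum(1 for l in data.sam_lines if not l.startswith("@"))
    if n_body != 2 * data.truth.n_fragments_total:
        raise AssertionError("self-audit: SAM record count mismatch")
    # planted splice ends present in the genome
    for iid, rec in data.truth.introns.items():
        seq = data.genome[rec["chrom"]][rec["start"] : rec["end"]]
        if rec["strand"] == "-":
            seq = _revcomp(seq)
        want_ends = ("AT", "AC") if rec["splice_type"] == "u12" else ("GT", "AG")
        if (seq[:2], seq[-2:]) != want_ends:
            raise AssertionError(f"self-audit: splice ends not planted for {iid}")
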