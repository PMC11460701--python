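"""Intron catalog construction, deduplication, and category flags."""

import numpy as np
import pandas as pd
import pytest

from flexiscan import annotations
from flexiscan.annotations import (
    GtfParseError,
    IntronCatalog,
    IntronRecord,
    build_intron_catalog,
    flag_category_overlaps,
    flag_splice_relationships,
)


def gtf_line(chrom, ftype, start0, end, strand, gid="G1", tid="T1"):
    # start0 is 0-based half-open; GTF is written 1-based inclusive
    attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}";'
    return f"{chrom}\tsrc\t{ftype}\t{start0+1}\t{end}\t.\t{strand}\t.\t{attrs}"


def transcript_gtf(exons, strand="+", gid="G1", tid="T1", chrom="chr1"):
    return [gtf_line(chrom, "exon", s, e, strand, gid, tid) for s, e in exons]


class TestBuildCatalog:
    def test_gaps_between_exons(self):
        lines = transcript_gtf([(0, 100), (200, 300), (400, 500)])
        cat = build_intron_catalog(lines)
        assert [(r.start, r.end) for r in cat] == [(100, 200), (300, 400)]

    def test_shared_intron_deduplicated(self):
        lines = transcript_gtf([(0, 100), (200, 300)], tid="T1") + transcript_gtf(
            [(0, 100), (200, 300), (400, 500)], tid="T2"
        )
        cat = build_intron_catalog(lines)
        assert sum(1 for r in cat if (r.start, r.end) == (100, 200)) == 1

    @pytest.mark.parametrize("length,expected", [(300, "short"), (301, "long")])
    def test_size_class_boundary(self, length, expected):
        lines = transcript_gtf([(0, 100), (100 + length, 100 + length + 50)])
        cat = build_intron_catalog(lines, short_threshold=300)
        assert cat.records[0].size_class == expected

    def test_overlapping_exons_skipped_with_warning(self):
        lines = transcript_gtf([(0, 100), (50, 300)])
        with pytest.warns(UserWarning, match="overlapping exons"):
            cat = build_intron_catalog(lines)
        assert len(cat) == 0

    def test_malformed_line_reports_line_number(self):
        lines = transcript_gtf([(0, 100), (200, 300)])
        lines.insert(1, "chr1\tonly\tthree")
        with pytest.raises(GtfParseError, match="line 2"):
            build_intron_catalog(lines)

    def test_gene_attribution_lexicographic_on_tie(self):
        lines = transcript_gtf([(0, 100), (200, 300)], gid="GB", tid="T1")
        lines += transcript_gtf([(0, 100), (200, 300)], gid="GA", tid="T2")
        cat = build_intron_catalog(lines)
        assert cat.records[0].gene_id == "GA"

    def test_deterministic_rebuild(self):
        rng = np.random.default_rng(0)
        lines = []
        for t in range(20):
            starts = np.cumsum(rng.integers(50, 200, size=8))
            exons = list(zip(starts[::2], starts[1::2]))
            lines += transcript_gtf(exons, tid=f"T{t}", gid=f"G{t % 5}")
        c1 = build_intron_catalog(lines)
        c2 = build_intron_catalog(lines)
        assert [r.intron_id for r in c1] == [r.intron_id for r in c2]

    def test_matches_bruteforce_gap_enumeration(self):
        rng = np.random.default_rng(7)
        lines, expected = [], set()
        for t in range(30):
            strand = "+" if rng.random() < 0.5 else "-"
            starts = np.cumsum(rng.integers(30, 150, size=10))
            exons = list(zip(starts[::2], starts[1::2]))
            lines += transcript_gtf(exons, strand=strand, tid=f"T{t}")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                expected.add(("chr1", int(e1), int(s2), strand))
        cat = build_intron_catalog(lines)
        got = {(r.chrom, r.start, r.end, r.strand) for r in cat}
        assert got == expected


class TestIntronRecord:
    def test_id_round_trip(self):
        r = IntronRecord("chr2", 10, 99, "-", "G", "G")
        assert IntronRecord.parse_id(r.intron_id) == ("chr2", 10, 99, "-")

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            IntronRecord("chr1", 100, 100, "+", "G", "G")

    def test_catalog_tsv_round_trip(self, tmp_path):
        lines = transcript_gtf([(0, 100), (200, 300), (400, 500)], strand="-")
        cat = build_intron_catalog(lines)
        cat.records[0].flags["agotron"] = True
        cat.to_tsv(tmp_path / "introns.tsv")
        back = IntronCatalog.from_tsv(tmp_path / "introns.tsv")
        assert [r.intron_id for r in back] == [r.intron_id for r in cat]
        assert back.records[0].flags["agotron"] is True


def bed_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestCategoryFlags:
    @pytest.fixture()
    def cat(self):
        lines = transcript_gtf([(0, 100), (200, 300)])
        return build_intron_catalog(lines)  # intron [100, 200) +

    def test_snorna_containment_required(self, cat):
        inside = bed_df([("chr1", 120, 190, "SNORD1", 0, "+")])
        flag_category_overlaps(cat, {"sno": inside})
        assert cat.records[0].flags["snoRNA_encoding"] is True
        cat2 = build_intron_catalog(transcript_gtf([(0, 100), (200, 300)]))
        crossing = bed_df([("chr1", 150, 250, "SNORD1", 0, "+")])
        flag_category_overlaps(cat2, {"sno": crossing})
        assert cat2.records[0].flags["snoRNA_encoding"] is False

    def test_agotron_any_overlap(self, cat):
        flag_category_overlaps(cat, {"agotron": bed_df([("chr1", 100, 200, "a", 0, "+")])})
        assert cat.records[0].flags["agotron"] is True

    def test_opposite_strand_ignored(self, cat):
        flag_category_overlaps(cat, {"mirtron": bed_df([("chr1", 120, 180, "m", 0, "-")])})
        assert cat.records[0].flags["mirtron"] is False

    def test_unknown_category_rejected(self, cat):
        with pytest.raises(ValueError, match="unknown category"):
            flag_category_overlaps(cat, {"oncogene": bed_df([])})

    def test_flagged_sno_introns_contain_their_interval(self):
        rng = np.random.default_rng(3)
        lines = []
        for t in range(15):
            starts = np.cumsum(rng.integers(50, 200, size=6))
            lines += transcript_gtf(list(zip(starts[::2], starts[1::2])), tid=f"T{t}")
        cat = build_intron_catalog(lines)
        rows = [
            ("chr1", int(s), int(s + rng.integers(10, 120)), "sno", 0, "+")
            for s in rng.integers(0, 3000, size=40)
        ]
        flag_category_overlaps(cat, {"sno": bed_df(rows)})
        for r in cat:
            if r.flags["snoRNA_encoding"]:
                assert any(r.start <= s and e <= r.end for _, s, e, *_ in rows)


class TestSpliceRelationships:
    def test_shared_start_with_longer(self):
        lines = transcript_gtf([(0, 100), (200, 300)], tid="T1")
        lines += transcript_gtf([(0, 100), (400, 500)], tid="T2")
        cat = build_intron_catalog(lines)
        flag_splice_relationships(cat, lines)
        short = cat["chr1:100-200(+)"]
        long = cat["chr1:100-400(+)"]
        assert short.flags["shares_ss_with_longer"] is True
        assert long.flags["shares_ss_with_longer"] is False

    def test_retained_intron_flag(self):
        lines = transcript_gtf([(0, 100), (200, 300)], tid="T1")
        lines += transcript_gtf([(50, 250)], tid="T2")  # exon covers the intron
        cat = build_intron_catalog(lines)
        flag_splice_relationships(cat, lines)
        assert cat["chr1:100-200(+)"].flags["annotated_retained_intron"] is True

    def test_in_frame_retained_stop_codon(self):
        # 90-nt retained intron, CDS phase 0 at the intron start, TAA in frame
        intron_seq = "TAA" + "A" * 87
        genome = {"chr1": "G" * 100 + intron_seq + "G" * 100}
        lines = transcript_gtf([(0, 100), (190, 290)], tid="T1")
        lines += transcript_gtf([(50, 250)], tid="T2")
        lines.append(gtf_line("chr1", "CDS", 10, 290, "+", tid="T1"))
        cat = build_intron_catalog(lines)
        flag_splice_relationships(cat, lines, genome=genome)
        assert cat["chr1:100-190(+)"].flags["in_frame_retained"] is False

    def test_in_frame_retained_no_stop(self):
        genome = {"chr1": "G" * 100 + "GCA" * 30 + "G" * 100}
        lines = transcript_gtf([(0, 100), (190, 290)], tid="T1")
        lines += transcript_gtf([(50, 250)], tid="T2")
        lines.append(gtf_line("chr1", "CDS", 10, 290, "+", tid="T1"))
        cat = build_intron_catalog(lines)
        flag_splice_relationships(cat, lines, genome=genome)
        assert cat["chr1:100-190(+)"].flags["in_frame_retained"] is True

    def test_alt_spliced_when_isoform_lacks_intron(self):
        lines = transcript_gtf([(0, 100), (200, 300)], tid="T1")
        lines += transcript_gtf([(0, 300)], tid="T2")  # overlapping, intronless
        cat = build_intron_catalog(lines)
        flag_splice_relationships(cat, lines)
        assert cat["chr1:100-200(+)"].flags["alt_spliced"] is True


class TestIntervalLookup:
    def test_lookup_equals_linear_scan(self):
        rng = np.random.default_rng(5)
        ivs = []
        pos = 0
        for _ in range(60):
            pos += int(rng.integers(10, 80))
            s = pos
            pos += int(rng.integers(20, 200))
            ivs.append((s, pos, "+" if rng.random() < 0.5 else "-"))
        records = [
            IntronRecord("chr1", s, e, st, "G", "G") for s, e, st in ivs
        ]
        cat = IntronCatalog(records)
        for _ in range(100):
            q0 = int(rng.integers(0, pos))
            q1 = q0 + int(rng.integers(1, 150))
            strand = rng.choice(["+", "-", None])
            got = {r.intron_id for r in cat.overlapping("chr1", q0, q1, strand)}
            want = {
                r.intron_id
                for r in records
                if r.start < q1 and r.end > q0 and (strand is None or r.strand == strand)
            }
            assert got == want
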