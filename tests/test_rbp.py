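"""RBP site intersection, collapse rules, midpoint densities, location classes."""

import numpy as np
import pytest

from flexiscan import rbp
from flexiscan.rbp import (
    RbpSite,
    classify_location,
    fulllength_read_enrichment,
    intersect_sites,
    merge_intron_fragments,
    midpoint_density,
    rbps_with_min_flexis,
)

from conftest import make_catalog


def site(rbp_name, start, end, strand="+", chrom="chr1"):
    return RbpSite(rbp=rbp_name, chrom=chrom, start=start, end=end, strand=strand)


class TestIntersect:
    def test_overlap_one_nt_and_exonward_midpoint(self):
        cat = make_catalog([(100, 200)])
        profs = intersect_sites(cat, [site("X", 195, 215)])
        p = profs["chr1:100-200(+)"]
        assert p.rbps == {"X"}
        assert p.site_midpoint_pcts["X"] == [pytest.approx(105.0)]

    def test_multiple_sites_collapse_but_keep_midpoints(self):
        cat = make_catalog([(100, 200)])
        profs = intersect_sites(cat, [site("X", 110, 120), site("X", 150, 160)])
        p = profs["chr1:100-200(+)"]
        assert p.rbps == {"X"}
        assert len(p.site_midpoint_pcts["X"]) == 2

    def test_strand_orientation_required(self):
        cat = make_catalog([(100, 200)])
        assert intersect_sites(cat, [site("X", 120, 140, strand="-")]) == {}

    def test_unknown_strand_matches_both(self):
        cat = make_catalog([(100, 200, "+"), (300, 400, "-")])
        with pytest.warns(UserWarning, match="unknown strand"):
            profs = intersect_sites(
                cat, [site("X", 120, 140, strand="."), site("X", 320, 340, strand=".")]
            )
        assert len(profs) == 2

    def test_minus_strand_midpoint_mirrored(self):
        cat = make_catalog([(100, 200, "-")])
        profs = intersect_sites(cat, [site("X", 110, 130, strand="-")])
        # genomic midpoint 120 -> 20% from left -> 80% from the RNA 5' end
        assert profs["chr1:100-200(-)"].site_midpoint_pcts["X"] == [pytest.approx(80.0)]

    def test_matches_quadratic_bruteforce(self):
        rng = np.random.default_rng(12)
        introns, pos = [], 0
        for _ in range(40):
            pos += int(rng.integers(20, 80))
            s = pos
            pos += int(rng.integers(50, 250))
            introns.append((s, pos, "+" if rng.random() < 0.5 else "-"))
        cat = make_catalog(introns)
        sites = [
            site(
                f"R{rng.integers(0, 8)}",
                int(s0 := rng.integers(0, pos)),
                int(s0 + rng.integers(5, 60)),
                strand="+" if rng.random() < 0.5 else "-",
            )
            for _ in range(400)
        ]
        profs = intersect_sites(cat, sites)
        got = {(iid, r) for iid, p in profs.items() for r in p.rbps}
        want = set()
        for s, e, st in introns:
            iid = f"chr1:{s}-{e}({st})"
            for sv in sites:
                if sv.start < e and sv.end > s and sv.strand == st:
                    want.add((iid, sv.rbp))
        assert got == want

    def test_collapse_idempotent(self):
        cat = make_catalog([(100, 200)])
        sites = [site("X", 110, 120), site("X", 150, 160), site("Y", 100, 200)]
        p1 = intersect_sites(cat, sites)
        # re-running on the same input changes nothing
        p2 = intersect_sites(cat, sites)
        assert {k: v.rbps for k, v in p1.items()} == {k: v.rbps for k, v in p2.items()}


class TestMinFlexiRanking:
    def test_threshold_boundary(self):
        cat = make_catalog([(i * 100, i * 100 + 50) for i in range(1, 40)])
        sites = []
        for i in range(1, 31):  # A on exactly 30 introns
            sites.append(site("A", i * 100 + 5, i * 100 + 15))
        for i in range(1, 30):  # B on 29
            sites.append(site("B", i * 100 + 20, i * 100 + 30))
        profs = intersect_sites(cat, sites)
        ranked = rbps_with_min_flexis(profs, min_count=30)
        assert list(ranked["rbp"]) == ["A"]

    def test_counts_equal_presence_matrix_sums(self):
        rng = np.random.default_rng(3)
        cat = make_catalog([(i * 100, i * 100 + 60) for i in range(1, 60)])
        sites = [
            site(f"R{rng.integers(0, 5)}", int(i * 100 + 5), int(i * 100 + 20))
            for i in rng.integers(1, 60, size=300)
        ]
        profs = intersect_sites(cat, sites)
        ranked = rbps_with_min_flexis(profs, min_count=1)
        mat = rbp.presence_matrix(profs)
        for row in ranked.itertuples(index=False):
            assert row.n_flexis == int(mat[row.rbp].sum())

    def test_empty_profiles(self):
        assert rbps_with_min_flexis({}, min_count=30).empty


class TestMidpointDensity:
    def make_profiles(self, pts):
        p = rbp.BindingProfile("i1")
        for x in pts:
            p.add_site("X", x)
        return {"i1": p}

    def test_unit_mass_single_bin(self):
        d, centers = midpoint_density(self.make_profiles([50.0] * 10), "X")
        assert d[np.argmin(np.abs(centers - 51))] > 0
        assert np.sum(d > 0) == 1

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        d, centers = midpoint_density(
            self.make_profiles(list(rng.uniform(-40, 140, 500))), "X"
        )
        assert np.trapezoid(d, centers) == pytest.approx(1.0, abs=0.03)
        assert d.sum() * 2.0 == pytest.approx(1.0, abs=1e-9)


class TestLocationClass:
    def density_from_points(self, pts):
        p = rbp.BindingProfile("i1")
        for x in pts:
            p.add_site("X", x)
        return midpoint_density({"i1": p}, "X")

    def test_interior_single_peak(self):
        d, c = self.density_from_points(list(np.random.default_rng(1).normal(50, 5, 400)))
        assert classify_location(d, c) == "I"

    def test_ss_i_bimodal_inside(self):
        pts = list(np.random.default_rng(2).normal(5, 2, 200)) + list(
            np.random.default_rng(3).normal(95, 2, 200)
        )
        d, c = self.density_from_points(pts)
        assert classify_location(d, c) == "SS-I"

    def test_ss_e_bimodal_outside(self):
        pts = list(np.random.default_rng(4).normal(-8, 2, 200)) + list(
            np.random.default_rng(5).normal(108, 2, 200)
        )
        d, c = self.density_from_points(pts)
        assert classify_location(d, c) == "SS-E"

    def test_rescaling_invariance(self):
        d, c = self.density_from_points(
            list(np.random.default_rng(6).normal(50, 10, 300))
        )
        assert classify_location(d, c) == classify_location(d * 37.5, c)

    def test_empty_density_null(self):
        assert classify_location(np.array([]), np.array([])) is None


class TestFullLengthEnrichment:
    def test_fold_ratio_and_boundary(self):
        cat = make_catalog([(0, 100)])
        flexi = {"chr1:0-100(+)"}
        covering = ("chr1", 0, 96)   # 96% coverage
        near = ("chr1", 0, 94)       # 94%: below the 95% cut
        other = ("chr1", 500, 540)
        clip = {"X": [covering, other, other, other]}       # 1/4
        ctrl = [covering, other, other, other, other, other, other, other]  # 1/8
        df = fulllength_read_enrichment(clip, ctrl, cat, flexi)
        assert df.loc[0, "fold"] == pytest.approx(2.0)
        df2 = fulllength_read_enrichment({"X": [near]}, ctrl, cat, flexi)
        assert df2.loc[0, "fraction"] == 0.0

    def test_identical_sets_fold_one(self):
        cat = make_catalog([(0, 100)])
        reads = [("chr1", 0, 100), ("chr1", 200, 240)]
        df = fulllength_read_enrichment({"X": reads}, reads, cat, {"chr1:0-100(+)"})
        assert df.loc[0, "fold"] == pytest.approx(1.0)

    def test_zero_control_null(self):
        cat = make_catalog([(0, 100)])
        with pytest.warns(UserWarning, match="control"):
            df = fulllength_read_enrichment(
                {"X": [("chr1", 0, 100)]}, [("chr1", 500, 520)], cat, {"chr1:0-100(+)"}
            )
        assert df.loc[0, "fold"] is None


class TestFragmentMerging:
    def test_overlapping_union(self):
        cat = make_catalog([(100, 200)])
        frags = [("chr1", 100, 150, "+"), ("chr1", 140, 180, "+")]
        merged = merge_intron_fragments(frags, cat)
        assert merged["chr1:100-200(+)"] == [(100, 180)]

    def test_disjoint_stay_separate(self):
        cat = make_catalog([(100, 200)])
        frags = [("chr1", 100, 120, "+"), ("chr1", 150, 180, "+")]
        merged = merge_intron_fragments(frags, cat)
        assert merged["chr1:100-200(+)"] == [(100, 120), (150, 180)]

    def test_matches_bruteforce_union(self):
        rng = np.random.default_rng(5)
        cat = make_catalog([(0, 1000)])
        frags = []
        for _ in range(200):
            s = int(rng.integers(0, 950))
            frags.append(("chr1", s, s + int(rng.integers(5, 50)), "+"))
        merged = merge_intron_fragments(frags, cat)["chr1:0-1000(+)"]
        covered = np.zeros(1000, dtype=bool)
        for _, s, e, _ in frags:
            covered[s:e] = True
        brute = []
        in_run = False
        for i, c in enumerate(covered):
            if c and not in_run:
                brute.append([i, i + 1])
                in_run = True
            elif c:
                brute[-1][1] = i + 1
            else:
                in_run = False
        assert merged == [tuple(x) for x in brute]


class TestMergedIntervalIntersection:
    def test_sites_hit_only_covered_fragments(self):
        from flexiscan.rbp import intersect_sites_with_intervals

        cat = make_catalog([(100, 300)])
        merged = {"chr1:100-300(+)": [(100, 150), (200, 260)]}
        hits = intersect_sites_with_intervals(
            merged, cat, [site("X", 140, 160), site("Y", 160, 190), site("Z", 250, 270)]
        )
        p = hits["chr1:100-300(+)"]
        assert p.rbps == {"X", "Z"}  # Y falls in the uncovered gap

    def test_strand_respected(self):
        from flexiscan.rbp import intersect_sites_with_intervals

        cat = make_catalog([(100, 300, "-")])
        merged = {"chr1:100-300(-)": [(100, 300)]}
        hits = intersect_sites_with_intervals(merged, cat, [site("X", 150, 170, "+")])
        assert hits == {}
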