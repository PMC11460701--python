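"""Fisher/BH enrichment, KS + Monte-Carlo control, host-gene category tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats as sp_stats

from flexiscan import stats
from flexiscan.rbp import BindingProfile
from flexiscan.stats import (
    binding_abundance_table,
    fisher_bh,
    fisher_exact_two_sided,
    hostgene_category_enrichment,
    ks_with_mc,
)


def exact_fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher p in exact rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = [
        Fraction(comb(r1, k) * comb(n - r1, c1 - k), comb(n, c1))
        for k in range(lo, hi + 1)
    ]
    obs = probs[a - lo]
    return float(min(Fraction(1), sum(p for p in probs if p <= obs)))


class TestFisherExact:
    def test_matches_exact_oracle_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            _, p = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(exact_fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-12)

    def test_cross_check_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            _, p = fisher_exact_two_sided(a, b, c, d)
            p_sp = sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert p == pytest.approx(p_sp, rel=1e-6)

    def test_zero_margin_conventions(self):
        assert fisher_exact_two_sided(0, 0, 5, 5) == (None, 1.0)
        assert fisher_exact_two_sided(0, 5, 0, 5) == (None, 1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 1, 1, 1)

    def test_margin_class_helper_consistent(self):
        ps = stats.fisher_pvalues_for_margins(30, 12, 9)
        lo = max(0, 12 + 9 - 30)
        for i, p in enumerate(ps):
            a = lo + i
            _, p_single = fisher_exact_two_sided(a, 12 - a, 9 - a, 30 - 12 - 9 + a)
            assert p == pytest.approx(p_single, rel=1e-12)


def profiles_from_matrix(mat, prefix="i"):
    """dict of BindingProfile from a boolean intron x RBP matrix."""
    profs = {}
    n_introns, n_rbps = mat.shape
    for i in range(n_introns):
        p = BindingProfile(f"{prefix}{i}")
        for j in range(n_rbps):
            if mat[i, j]:
                p.add_site(f"R{j:02d}", 50.0)
        profs[f"{prefix}{i}"] = p
    return profs


class TestAbundanceTable:
    def test_percentages_normalize_to_100(self):
        rng = np.random.default_rng(2)
        a = profiles_from_matrix(rng.random((30, 6)) < 0.4, "a")
        b = profiles_from_matrix(rng.random((25, 6)) < 0.4, "b")
        t = binding_abundance_table(a, b)
        assert t["pct_a"].sum() == pytest.approx(100)
        assert t["pct_b"].sum() == pytest.approx(100)

    def test_counts_equal_bruteforce_matrix_sums(self):
        rng = np.random.default_rng(3)
        ma = rng.random((20, 5)) < 0.5
        mb = rng.random((15, 5)) < 0.5
        t = binding_abundance_table(
            profiles_from_matrix(ma, "a"), profiles_from_matrix(mb, "b")
        )
        for row in t.itertuples(index=False):
            j = int(row.rbp[1:])
            assert row.count_a == ma[:, j].sum()
            assert row.count_b == mb[:, j].sum()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            binding_abundance_table({}, profiles_from_matrix(np.ones((2, 2), bool)))


class TestFisherBH:
    def test_identical_proportions_ns(self):
        mat = np.zeros((20, 3), dtype=bool)
        mat[:10] = [True, True, False]
        a = profiles_from_matrix(mat[:10], "a")
        b = profiles_from_matrix(mat[:10], "b")
        res = fisher_bh(binding_abundance_table(a, b))
        assert (res["key"] == "ns").all()
        assert (res["p"] == 1.0).all()

    def test_abundance_gate_forces_ns(self):
        # R00 strongly enriched but held at < 2% abundance by a dominant R01
        a_mat = np.zeros((60, 2), dtype=bool)
        a_mat[:, 1] = True
        a_mat[0, 0] = True  # 1/61 presences ~ 1.6%
        b_mat = np.zeros((60, 2), dtype=bool)
        b_mat[:, 1] = True
        a = profiles_from_matrix(a_mat, "a")
        b = profiles_from_matrix(b_mat, "b")
        res = fisher_bh(binding_abundance_table(a, b), min_pct=2.0)
        assert (res["key"] == "ns").all()

    def test_direction_keys(self):
        a_mat = np.zeros((50, 2), dtype=bool)
        a_mat[:40, 0] = True
        a_mat[:10, 1] = True
        b_mat = np.zeros((50, 2), dtype=bool)
        b_mat[:10, 0] = True
        b_mat[:40, 1] = True
        res = fisher_bh(
            binding_abundance_table(
                profiles_from_matrix(a_mat, "a"), profiles_from_matrix(b_mat, "b")
            ),
            min_pct=1.0,
        )
        keyed = dict(zip(res["rbp"], res["key"]))
        assert keyed == {"R00": "over", "R01": "under"}

    def test_padj_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        a = profiles_from_matrix(rng.random((40, 10)) < rng.uniform(0.1, 0.9, 10), "a")
        b = profiles_from_matrix(rng.random((40, 10)) < rng.uniform(0.1, 0.9, 10), "b")
        res = fisher_bh(binding_abundance_table(a, b)).sort_values("p")
        assert (res["p_adj"] <= 1).all()
        assert (res["p_adj"].to_numpy() >= res["p"].to_numpy() - 1e-12).all()
        # BH adjusted values are monotone non-decreasing in raw p
        assert (np.diff(res["p_adj"].to_numpy()) >= -1e-12).all()


class TestKsMc:
    def test_identical_distributions_ns(self):
        vals = list(np.random.default_rng(0).normal(0, 1, 200))
        res = ks_with_mc(vals, vals, "gc", seed=1)
        assert res.verdict == "ns"
        assert res.mc_false_hit_rate is None

    def test_shifted_subset_significant(self):
        rng = np.random.default_rng(5)
        rest = rng.normal(0, 1, 2000)
        subset = rng.normal(3, 1, 200)  # 3 pooled SDs away
        res = ks_with_mc(subset, rest, "length", n_mc=200, seed=2)
        assert res.verdict == "significant"
        assert res.mc_false_hit_rate <= 0.05

    def test_null_subset_rejected_as_false_hit(self):
        rng = np.random.default_rng(6)
        pool = rng.normal(0, 1, 2000)
        n_rejected = 0
        for seed in range(10):
            rs = np.random.default_rng(seed + 100)
            idx = rs.choice(2000, 200, replace=False)
            mask = np.zeros(2000, dtype=bool)
            mask[idx] = True
            # force the MC stage by setting the p cut above the observed p
            res = ks_with_mc(
                pool[mask], pool[~mask], n_mc=200, p_cut=0.999, seed=seed
            )
            if res.verdict == "rejected_false_hit":
                n_rejected += 1
        assert n_rejected >= 8

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        rest = rng.normal(0, 1, 500)
        subset = rng.normal(1.5, 1, 100)
        r1 = ks_with_mc(subset, rest, n_mc=100, seed=9)
        r2 = ks_with_mc(subset, rest, n_mc=100, seed=9)
        assert (r1.p_ks, r1.mc_false_hit_rate, r1.verdict) == (
            r2.p_ks,
            r2.mc_false_hit_rate,
            r2.verdict,
        )

    def test_tiny_subset_rejected(self):
        with pytest.raises(ValueError):
            ks_with_mc([1.0], [1, 2, 3], seed=0)


class TestHostGeneEnrichment:
    def test_equal_rates_p_one(self):
        fg = {f"g{i}" for i in range(100)}
        bg = {f"h{i}" for i in range(100)}
        cat = {f"g{i}" for i in range(10)} | {f"h{i}" for i in range(10)}
        pct_fg, pct_bg, p = hostgene_category_enrichment(fg, bg, cat)
        assert (pct_fg, pct_bg) == (10.0, 10.0)
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_toy(self):
        fg = {f"g{i}" for i in range(8)}
        bg = {f"g{i}" for i in range(8, 20)}
        cat = {"g0", "g1", "g2", "g9"}
        _, _, p = hostgene_category_enrichment(fg, bg, cat)
        assert p == pytest.approx(exact_fisher_oracle(3, 5, 1, 11), rel=1e-12)

    def test_disjoint_category(self):
        pct_fg, _, _ = hostgene_category_enrichment({"a"}, {"b", "c"}, {"z"})
        assert pct_fg == 0.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hostgene_category_enrichment({"a"}, set(), {"a"})
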