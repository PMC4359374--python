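"""SNP windows, hypergeometric enrichment vs exact enumeration, the two
empirical null models, and the randomized-overlap z-test."""

import math

import numpy as np
import pytest

from crmshare.core import GeneModel, GenomicInterval, LeadSNP, ValidationError
from crmshare.cross_species import PhyloAssignment
from crmshare.enrichment import (
    build_snp_windows,
    hypergeom_pvalue,
    hypergeometric_enrichment,
    null_matched_snps,
    null_shuffle_labels,
    randomized_overlap_ztest,
)
from conftest import make_region


def snp(rsid, pos, trait="t", summary="s", maf=0.2, proxies=()):
    return LeadSNP(rsid, "chr1", pos, trait, summary, maf, tuple(proxies))


class TestSnpWindows:
    def test_fixed_window(self):
        (w,) = build_snp_windows([snp("rs1", 10_000)], mode="fixed", halfwidth=2500)
        assert (w.interval.start, w.interval.end) == (7_500, 12_501)

    def test_ld_degenerates_to_one_bp_without_proxies(self):
        (w,) = build_snp_windows([snp("rs1", 10_000)], mode="ld")
        assert (w.interval.start, w.interval.end) == (10_000, 10_001)

    def test_ld_fallback_flag(self):
        (w,) = build_snp_windows([snp("rs1", 10_000)], mode="ld",
                                 ld_fallback_fixed=True)
        assert (w.interval.start, w.interval.end) == (7_500, 12_501)

    def test_ld_span_uses_qualifying_proxies(self):
        s = snp("rs1", 10_000, proxies=[(9_500, 0.9), (12_000, 0.85),
                                        (90_000, 0.5)])
        (w,) = build_snp_windows([s], mode="ld", r2_min=0.8)
        assert (w.interval.start, w.interval.end) == (9_500, 12_001)

    def test_overlapping_windows_merge_and_dedup_traits(self):
        snps = [snp("rs1", 10_000, trait="LDL", summary="blood lipid"),
                snp("rs2", 11_000, trait="LDL", summary="blood lipid")]
        windows = build_snp_windows(snps, mode="fixed", halfwidth=2500)
        assert len(windows) == 1
        assert windows[0].traits == {("LDL", "blood lipid")}
        assert windows[0].member_snps == ("rs1", "rs2")

    def test_merging_is_idempotent(self):
        snps = [snp(f"rs{i}", 10_000 + 800 * i) for i in range(6)]
        w1 = build_snp_windows(snps, halfwidth=500)
        starts = [w.interval.start for w in w1]
        ends = [w.interval.end for w in w1]
        for s, e, s2, e2 in zip(starts, ends, starts[1:], ends[1:]):
            assert e <= s2  # already disjoint: a second merge changes nothing

    def test_negative_halfwidth_rejected(self):
        with pytest.raises(ValidationError):
            build_snp_windows([snp("rs1", 10_000)], halfwidth=-1)


def enumerated_upper_tail(x, K, n, N):
    """Exact tail probability via integer combinatorics (independent oracle)."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i)
              for i in range(x, min(K, n) + 1))
    return num / math.comb(N, n)


class TestHypergeometric:
    def test_matches_enumeration_small(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for x in range(min(K, n) + 1):
                        assert abs(hypergeom_pvalue(x, K, n, N) -
                                   enumerated_upper_tail(x, K, n, N)) < 1e-12

    def test_fold_examples(self):
        regions = [make_region("human", i * 10_000, i * 10_000 + 100,
                               rid=f"r{i}") for i in range(100)]
        assigns = {}
        for i, r in enumerate(regions):
            cat = "deeply_shared" if i < 20 else "human_only"
            assigns[r.id] = PhyloAssignment(r.id, frozenset(), 3 if i < 20 else 1,
                                            cat, i < 20, False, False)
        # windows covering regions 0..4 (deep) and 20..24 (not): n=10, x=5
        snps = [snp(f"rs{i}", i * 10_000 + 50, trait="T", summary="T")
                for i in list(range(5)) + list(range(20, 25))]
        windows = build_snp_windows(snps, halfwidth=100)
        results = hypergeometric_enrichment(regions, assigns, windows)
        deep = next(r for r in results if r.category == "deeply_shared:crm")
        assert (deep.x, deep.K, deep.n, deep.N) == (5, 20, 10, 100)
        assert deep.fold == pytest.approx(2.5)
        assert deep.p == pytest.approx(enumerated_upper_tail(5, 20, 10, 100))
        # fold 1 when x sits exactly at expectation
        assert (2 / 10) / (20 / 100) == 1.0

    def test_maximal_overlap_matches_enumeration(self):
        assert hypergeom_pvalue(5, 5, 5, 30) == \
            pytest.approx(enumerated_upper_tail(5, 5, 5, 30), abs=1e-14)

    def test_bonferroni_spans_all_tested_pairs(self):
        regions = [make_region("human", i * 10_000, i * 10_000 + 100,
                               rid=f"r{i}") for i in range(10)]
        assigns = {r.id: PhyloAssignment(r.id, frozenset(), 1, "human_only",
                                         False, False, False) for r in regions}
        snps = [snp("rs1", 50, trait="A", summary="A"),
                snp("rs2", 10_050, trait="B", summary="B")]
        results = hypergeometric_enrichment(regions, assigns,
                                            build_snp_windows(snps, halfwidth=100))
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p * len(results)))


def _toy_setup(rng, n_regions=30, n_deep=10):
    regions = [make_region("human", i * 10_000, i * 10_000 + 200, rid=f"r{i}")
               for i in range(n_regions)]
    assigns = {}
    for i, r in enumerate(regions):
        cat = "deeply_shared" if i < n_deep else "human_only"
        assigns[r.id] = PhyloAssignment(r.id, frozenset(), 3 if i < n_deep else 1,
                                        cat, i < n_deep, False, False)
    genes = [GeneModel(f"g{j}", "chr1", "+", j * 20_000, ((j * 20_000,
                                                           j * 20_000 + 100),))
             for j in range(10)]
    return regions, assigns, genes


class TestShuffleNull:
    def test_identical_labels_never_significant(self, rng):
        regions, assigns, _ = _toy_setup(rng)
        snps = [snp(f"rs{i}", i * 10_000 + 100, trait="only", summary="only")
                for i in range(20)]
        out = null_shuffle_labels(snps, regions, assigns, n_iter=200, seed=1)
        for res in out.values():
            assert res.frac_null_le == pytest.approx(1.0)
            assert not res.significant

    def test_planted_association_flagged(self, rng):
        regions, assigns, _ = _toy_setup(rng)
        # trait X snps sit exactly on the deep regions, trait Y elsewhere
        snps = [snp(f"x{i}", i * 10_000 + 100, trait="X", summary="X")
                for i in range(10)]
        snps += [snp(f"y{i}", (15 + i) * 10_000 + 100, trait="Y", summary="Y")
                 for i in range(10)]
        out = null_shuffle_labels(snps, regions, assigns, n_iter=400, seed=2,
                                  halfwidth=100)
        assert out[("deeply_shared:crm", "X")].significant
        assert not out[("deeply_shared:crm", "Y")].significant

    def test_low_iteration_count_warns(self, rng):
        regions, assigns, _ = _toy_setup(rng)
        snps = [snp("rs0", 100, trait="A", summary="A"),
                snp("rs1", 10_100, trait="B", summary="B")]
        with pytest.warns(UserWarning, match="n_iter"):
            null_shuffle_labels(snps, regions, assigns, n_iter=10, seed=0)


class TestMatchedNull:
    def test_universe_equal_to_snps_reproduces_observed(self, rng):
        regions, assigns, genes = _toy_setup(rng)
        # one snp per MAF bin => each matches only itself in the universe
        mafs = [0.05, 0.15, 0.25, 0.35, 0.45]
        snps = [snp(f"rs{i}", i * 10_000 + 100, trait="T", summary="T", maf=m)
                for i, m in enumerate(mafs)]
        out = null_matched_snps(snps, snps, genes, regions, assigns,
                                n_iter=100, seed=3, halfwidth=100)
        for res in out.values():
            assert res.frac_null_le == pytest.approx(1.0)
            assert not res.significant

    def test_empty_bin_falls_back_with_warning(self, rng):
        regions, assigns, genes = _toy_setup(rng)
        snps = [snp("rs0", 100, maf=0.05)]
        universe = [snp("u0", 5_000, maf=0.45)]
        with pytest.warns(UserWarning, match="empty matching bin"):
            null_matched_snps(snps, universe, genes, regions, assigns,
                              n_iter=100, seed=4)

    def test_planted_enrichment_flagged(self, rng):
        regions, assigns, genes = _toy_setup(rng)
        # liver snps on deep regions; universe uniform background
        snps = [snp(f"l{i}", i * 10_000 + 100, trait="liver", summary="liver")
                for i in range(10)]
        snps += [snp(f"o{i}", int(rng.integers(0, 300_000)), trait="other",
                     summary="other") for i in range(10)]
        universe = [snp(f"u{i}", int(rng.integers(0, 300_000)), maf=0.2)
                    for i in range(2_000)]
        out = null_matched_snps(snps, universe, genes, regions, assigns,
                                n_iter=300, seed=5, halfwidth=100)
        assert out[("deeply_shared:crm", "liver")].significant


class TestOverlapZTest:
    def test_reference_covering_universe_is_degenerate(self):
        universe = [GenomicInterval("h", "chr1", 0, 10_000)]
        reference = [GenomicInterval("h", "chr1", 0, 10_000)]
        queries = [make_region("human", 100, 200, rid="q")]
        res = randomized_overlap_ztest(queries, reference, universe, n_iter=50,
                                       seed=0)
        assert res.degenerate and res.z is None
        assert res.observed == 1

    def test_empty_reference_is_degenerate_zero(self):
        universe = [GenomicInterval("h", "chr1", 0, 10_000)]
        queries = [make_region("human", 100, 200, rid="q")]
        res = randomized_overlap_ztest(queries, [], universe, n_iter=50, seed=0)
        assert res.observed == 0 and res.degenerate

    def test_planted_excess_gives_positive_z(self, rng):
        universe = [GenomicInterval("h", "chr1", 0, 1_000_000)]
        reference = [GenomicInterval("h", "chr1", i * 10_000, i * 10_000 + 500)
                     for i in range(30)]
        queries = [make_region("human", i * 10_000 + 100, i * 10_000 + 300,
                               rid=f"q{i}") for i in range(30)]
        res = randomized_overlap_ztest(queries, reference, universe,
                                       n_iter=400, seed=7)
        assert res.observed == 30
        assert res.z is not None and res.z > 3
        assert res.p < 1e-3
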