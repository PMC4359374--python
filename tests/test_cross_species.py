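"""Projection arithmetic, sharing decisions vs a per-base oracle, and
phylogenetic category assignment."""

import numpy as np
import pytest

from crmshare.core import GenomicInterval, ValidationError
from crmshare.cross_species import (
    AlignmentMap,
    Block,
    alignability,
    assign_phylo_categories,
    compute_sharing,
    compute_sharing_all,
    overlap_threshold_sweep,
    pairwise_sharing_percent,
    project_interval,
)
from conftest import identity_map, make_region, perbase_image, random_block_map

ROLES = {"macaque": "primate", "dog": "non_primate",
         "mouse": "non_primate", "rat": "non_primate"}


def iv(start, end, species="human", chrom="chr1"):
    return GenomicInterval(species, chrom, start, end)


class TestProjection:
    def test_offset_block(self):
        amap = AlignmentMap()
        amap.add_block("human", "mouse", Block("chr1", 0, 5000, "chr2", 1000, "+"))
        out = project_interval(iv(100, 300), amap, "mouse")
        assert out == [iv(1100, 1300, "mouse", "chr2")]

    def test_reverse_strand_reflection(self):
        amap = AlignmentMap()
        amap.add_block("human", "mouse", Block("chr1", 100, 200, "chr1", 500, "-"))
        # base x maps to 500 + (200 - 1 - x); interval [150,160) -> [540,550)
        out = project_interval(iv(150, 160), amap, "mouse")
        assert out == [iv(540, 550, "mouse", "chr1")]

    def test_outside_blocks_is_empty(self):
        amap = AlignmentMap()
        amap.add_block("human", "mouse", Block("chr1", 1000, 2000, "chr1", 0, "+"))
        assert project_interval(iv(100, 200), amap, "mouse") == []
        assert project_interval(iv(100, 200, chrom="chr9"), amap, "mouse") == []

    def test_unknown_pair_raises(self):
        amap = identity_map("human", "mouse")
        with pytest.raises(ValidationError):
            project_interval(iv(0, 10), amap, "rat")

    def test_spanning_blocks_discontiguous(self):
        amap = AlignmentMap()
        amap.add_block("human", "mouse", Block("chr1", 0, 100, "chr1", 0, "+"))
        amap.add_block("human", "mouse", Block("chr1", 200, 300, "chr1", 500, "+"))
        out = project_interval(iv(50, 250), amap, "mouse")
        assert out == [iv(50, 100, "mouse"), iv(500, 550, "mouse")]

    def test_matches_perbase_oracle(self, rng):
        for _ in range(30):
            amap = random_block_map(rng, "human", "mouse")
            image = perbase_image(amap, "human", "mouse", 10_000)
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(1, 900))
            pieces = project_interval(iv(s, e), amap, "mouse")
            got = sorted(p for piece in pieces for p in range(piece.start, piece.end))
            expected = sorted(image[x] for x in range(s, e) if x in image)
            assert got == expected

    def test_round_trip_recovers_aligned_subintervals(self, rng):
        for _ in range(20):
            amap = random_block_map(rng, "human", "mouse")
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(1, 900))
            fwd = project_interval(iv(s, e), amap, "mouse")
            back = [piece for f in fwd
                    for piece in project_interval(f, amap, "human")]
            back_positions = sorted(p for b in back for p in range(b.start, b.end))
            assert all(s <= p < e for p in back_positions)
            aligned = sum(len(f) for f in fwd)
            assert len(back_positions) == aligned


class TestComputeSharing:
    def _pair(self, a_span, b_span, min_overlap=10):
        amap = identity_map("human", "mouse", offset=1000 - 0)
        # human [x, y) maps to mouse [x+1000, y+1000)
        amap2 = AlignmentMap()
        amap2.add_block("human", "mouse", Block("chr1", 0, 100_000, "chr1", 1000, "+"))
        ra = [make_region("human", *a_span, rid="a0")]
        rb = [make_region("mouse", *b_span, rid="b0")]
        return compute_sharing(ra, rb, amap2, min_overlap)

    def test_overlap_below_threshold_not_shared(self):
        # human CRM [0,300) projects to mouse [1000,1300); partner [1295,1400)
        recs = self._pair((0, 300), (1295, 1400))
        assert recs[0].overlap_bp == 5 and not recs[0].shared

    def test_overlap_above_threshold_shared(self):
        recs = self._pair((0, 300), (1250, 1400))
        assert recs[0].overlap_bp == 50 and recs[0].shared
        assert recs[0].matched_region_id == "b0"

    def test_overlap_summed_per_partner_not_across(self):
        amap = AlignmentMap()
        amap.add_block("human", "mouse", Block("chr1", 0, 100, "chr1", 0, "+"))
        amap.add_block("human", "mouse", Block("chr1", 200, 300, "chr1", 100, "+"))
        ra = [make_region("human", 94, 206, rid="a0")]  # pieces [94,100)+[100,106)
        rb = [make_region("mouse", 90, 104, rid="b0")]  # overlap 6+4=10 -> shared
        recs = compute_sharing(ra, rb, amap, 10)
        assert recs[0].overlap_bp == 10 and recs[0].shared
        # two partners each overlapping 6 and 4 bp must NOT combine
        rb2 = [make_region("mouse", 90, 100, rid="b1"),
               make_region("mouse", 100, 104, rid="b2")]
        recs2 = compute_sharing(ra, rb2, amap, 10)
        assert not recs2[0].shared and recs2[0].overlap_bp == 6

    def test_singleton_requires_same_tf(self):
        amap = identity_map("human", "mouse")
        ra = [make_region("human", 100, 300, "singleton", ("CEBPA",), "a")]
        rb_same = [make_region("mouse", 100, 300, "singleton", ("CEBPA",), "b")]
        rb_diff = [make_region("mouse", 100, 300, "singleton", ("HNF4A",), "b")]
        assert compute_sharing(ra, rb_same, amap, 10, "singleton_same_tf")[0].shared
        assert not compute_sharing(ra, rb_diff, amap, 10, "singleton_same_tf")[0].shared

    def test_crm_mode_ignores_tf_composition(self):
        amap = identity_map("human", "mouse")
        ra = [make_region("human", 100, 300, "crm", ("CEBPA", "HNF4A"), "a")]
        rb = [make_region("mouse", 100, 300, "crm", ("FOXA1", "ONECUT1"), "b")]
        assert compute_sharing(ra, rb, amap, 10)[0].shared

    def test_composition_filter_restricts_a_side(self):
        amap = identity_map("human", "mouse")
        all4 = ("CEBPA", "HNF4A", "FOXA1", "ONECUT1")
        ra = [make_region("human", 100, 300, "crm", all4, "a4"),
              make_region("human", 1000, 1300, "crm", ("CEBPA", "HNF4A"), "a2")]
        rb = [make_region("mouse", 100, 300, "crm", ("CEBPA", "HNF4A"), "b")]
        recs = compute_sharing(ra, rb, amap, 10, "crm_composition_filter",
                               required_tfs=set(all4))
        assert [r.region_id for r in recs] == ["a4"]

    def test_min_overlap_below_one_rejected(self):
        amap = identity_map("human", "mouse")
        with pytest.raises(ValidationError):
            compute_sharing([make_region("human", 0, 100)], [], amap, 0)

    def test_matches_perbase_oracle_random(self, rng):
        for _ in range(30):
            amap = random_block_map(rng, "human", "mouse")
            image = perbase_image(amap, "human", "mouse", 10_000)
            ra = [make_region("human", s, s + int(rng.integers(20, 300)),
                              rid=f"a{i}")
                  for i, s in enumerate(rng.integers(0, 9_500, size=15))]
            rb = [make_region("mouse", s, s + int(rng.integers(20, 300)),
                              rid=f"b{i}")
                  for i, s in enumerate(rng.integers(0, 9_500, size=15))]
            for min_ov in (1, 10, 25, 50):
                recs = compute_sharing(ra, rb, amap, min_ov)
                for rec, region in zip(recs, ra):
                    img = {image[x] for x in
                           range(region.span.start, region.span.end) if x in image}
                    best = 0
                    for b in rb:
                        best = max(best, len(img & set(
                            range(b.span.start, b.span.end))))
                    assert rec.shared == (best >= min_ov), (min_ov, rec)


class TestSweepAndPercent:
    def test_percent_arithmetic(self):
        amap = identity_map("human", "mouse")
        ra = [make_region("human", i * 1000, i * 1000 + 200, rid=f"a{i}")
              for i in range(10)]
        rb = [make_region("mouse", i * 1000, i * 1000 + 200, rid=f"b{i}")
              for i in range(3)]  # 3 of 10 A regions shared; all 3 B shared
        ab = compute_sharing(ra, rb, amap, 10)
        ba = compute_sharing(rb, ra, amap, 10)
        pw = pairwise_sharing_percent(ab, ba)
        assert pw.pct_a_to_b == 30.0 and pw.pct_b_to_a == 100.0
        assert pw.average_pct == 65.0
        assert (pw.n_alignable_a, pw.n_alignable_b) == (10, 3)

    def test_no_alignable_reported_missing(self):
        pw = pairwise_sharing_percent([], [])
        assert pw.average_pct is None

    def test_sweep_monotone_and_limits(self, rng):
        amap = random_block_map(rng, "human", "mouse")
        ra = [make_region("human", s, s + 100, rid=f"a{i}")
              for i, s in enumerate(range(0, 9000, 600))]
        rb = [make_region("mouse", s, s + 100, rid=f"b{i}")
              for i, s in enumerate(range(50, 9000, 700))]
        sweep = overlap_threshold_sweep(ra, rb, amap, [1, 10, 25, 50, 1000])
        vals = [sweep[t] for t in (1, 10, 25, 50, 1000)]
        assert vals == sorted(vals, reverse=True)
        assert sweep[1000] == 0  # larger than any region width
        any_overlap = sum(r.shared for r in compute_sharing(ra, rb, amap, 1))
        assert sweep[1] == any_overlap
        with pytest.raises(ValidationError):
            overlap_threshold_sweep(ra, rb, amap, [10, 1])


class TestCategories:
    def _assign(self, shared_species, rid="r0"):
        region = make_region("human", 0, 200, rid=rid)
        amap = AlignmentMap()
        records = {}
        for sp in ROLES:
            rec_shared = sp in shared_species
            from crmshare.cross_species import SharingRecord
            records[sp] = [SharingRecord(rid, sp, 50 if rec_shared else 0,
                                         rec_shared, None, True)]
        return assign_phylo_categories([region], records, ROLES)[0]

    def test_reference_only(self):
        a = self._assign(set())
        assert a.category == "human_only" and a.n_species == 1
        assert not (a.deeply_shared or a.beyond_primates or a.primates_only)

    def test_primates_only(self):
        a = self._assign({"macaque"})
        assert a.category == "primates_only" and a.n_species == 2
        assert a.primates_only and not a.beyond_primates

    def test_deeply_shared_takes_precedence(self):
        a = self._assign({"macaque", "mouse"})
        assert a.category == "deeply_shared" and a.n_species == 3
        assert a.deeply_shared and a.beyond_primates

    def test_beyond_primates_two_species(self):
        a = self._assign({"dog"})
        assert a.category == "beyond_primates" and a.n_species == 2

    def test_labels_partition_regions(self, rng):
        regions = [make_region("human", i * 500, i * 500 + 200, rid=f"r{i}")
                   for i in range(40)]
        from crmshare.cross_species import SharingRecord
        records = {
            sp: [SharingRecord(r.id, sp, 50, bool(rng.random() < 0.4), None, True)
                 for r in regions]
            for sp in ROLES
        }
        assigns = assign_phylo_categories(regions, records, ROLES)
        assert len(assigns) == len(regions)
        from collections import Counter
        counts = Counter(a.category for a in assigns)
        assert sum(counts.values()) == len(regions)
        # order invariance over species processing
        rev = dict(reversed(list(records.items())))
        assert assign_phylo_categories(regions, rev, ROLES) == assigns

    def test_missing_role_rejected(self):
        region = make_region("human", 0, 200, rid="r0")
        from crmshare.cross_species import SharingRecord
        records = {"weasel": [SharingRecord("r0", "weasel", 50, True, None, True)]}
        with pytest.raises(ValidationError):
            assign_phylo_categories([region], records, ROLES)


class TestAlignability:
    def test_full_and_empty_coverage(self):
        regions = [make_region("human", i * 1000, i * 1000 + 100, rid=f"r{i}")
                   for i in range(5)]
        full = identity_map("human", "mouse")
        frac, flags = alignability(regions, full, "mouse")
        assert frac == 1.0 and all(flags.values())
        empty = AlignmentMap()
        empty.register_pair("human", "mouse")
        frac0, flags0 = alignability(regions, empty, "mouse")
        assert frac0 == 0.0 and not any(flags0.values())
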