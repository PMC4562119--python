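import math

import numpy as np
import pytest
from scipy import stats

import ctskit as ck
from ctskit.classify import OccupancyClass
from ctskit.enrichment import (
    ContingencyTable,
    GeneModel,
    Transcript,
    read_tss_bed,
)


def mk_peak(chrom, start, end, score=1.0):
    return ck.Peak(
        ck.GenomicInterval(chrom, start, end), (start + end) // 2, score
    )


def mk_region(chrom, start, end, occupancy):
    return ck.ClassifiedRegion(
        mk_peak(chrom, start, end), occupancy, ck.SiteArity.ONE_X, []
    )


def tss_set(positions, chrom="c", with_ids=True):
    ivs = [ck.GenomicInterval(chrom, p, p + 1, "+") for p in positions]
    ids = [f"g{i}" for i in range(len(positions))] if with_ids else None
    return ck.AnnotationSet("tss", ivs, gene_ids=ids, anchor="point")


class TestActiveRegions:
    def test_both_marks_required(self):
        tss = tss_set([10_000, 50_000])
        mark1 = [mk_peak("c", 9000, 9500)]  # near first TSS only
        mark2 = [mk_peak("c", 11_000, 11_500)]
        active = ck.active_regions(tss, mark1, mark2, flank=2000)
        assert active.gene_ids == ["g0"]
        only_one = ck.active_regions(tss, mark1, [], flank=2000)
        assert len(only_one) == 0

    def test_matches_brute_force_random_layouts(self, rng):
        for _ in range(20):
            tss_pos = sorted(rng.integers(0, 100_000, 25).tolist())
            tss = ck.AnnotationSet(
                "t",
                [ck.GenomicInterval("c", p, p + 1) for p in tss_pos],
                anchor="point",
            )
            def peaks(n):
                out = []
                for _ in range(n):
                    s = int(rng.integers(0, 100_000))
                    out.append(mk_peak("c", s, s + int(rng.integers(50, 800))))
                return out
            m1, m2 = peaks(10), peaks(10)
            active = ck.active_regions(tss, m1, m2, flank=2000)
            got = {(iv.chrom, iv.start) for iv in active.intervals}
            expected = set()
            for p in tss_pos:
                lo, hi = max(0, p - 2000), p + 2001
                w = ck.GenomicInterval("c", lo, hi)
                if any(w.overlaps(q.interval) for q in m1) and any(
                    w.overlaps(q.interval) for q in m2
                ):
                    expected.add(("c", p))
            assert got == expected

    def test_enhancer_mode_direct_intersection(self):
        m1 = [mk_peak("c", 100, 200), mk_peak("c", 1000, 1100)]
        m2 = [mk_peak("c", 150, 250)]
        enh = ck.active_enhancers(m1, m2)
        assert [(iv.start, iv.end) for iv in enh.intervals] == [(100, 200)]


class TestClassAssociation:
    def test_constructed_fraction(self):
        tss = tss_set([i * 100_000 for i in range(10)])
        regions = [
            mk_region("c", i * 100_000 + 3000, i * 100_000 + 3400,
                      OccupancyClass.CTCF_AND_BORIS)
            for i in range(9)
        ]
        fracs = ck.class_association(tss, regions, flank=4000)
        assert fracs["raw"][OccupancyClass.CTCF_AND_BORIS] == pytest.approx(0.9)
        assert fracs["raw"][OccupancyClass.CTCF_ONLY] == 0.0

    def test_inclusive_boundary(self):
        tss = tss_set([10_000])
        # peak start exactly flank bp from anchor
        region = mk_region("c", 14_000, 14_400, OccupancyClass.CTCF_ONLY)
        fracs = ck.class_association(tss, [region], flank=4000)
        assert fracs["raw"][OccupancyClass.CTCF_ONLY] == 1.0
        fracs2 = ck.class_association(tss, [region], flank=3999)
        assert fracs2["raw"][OccupancyClass.CTCF_ONLY] == 0.0

    def test_empty_classified_list(self):
        fracs = ck.class_association(tss_set([100]), [], flank=4000)
        assert all(v == 0.0 for v in fracs["raw"].values())

    def test_monotone_in_flank(self, rng):
        tss = tss_set(sorted(rng.integers(0, 500_000, 40).tolist()))
        regions = [
            mk_region("c", int(s), int(s) + 300, OccupancyClass.CTCF_ONLY)
            for s in rng.integers(0, 500_000, 20)
        ]
        prev = 0.0
        for flank in (0, 1000, 5000, 20_000):
            frac = ck.class_association(tss, regions, flank)["raw"][
                OccupancyClass.CTCF_ONLY
            ]
            assert frac >= prev
            prev = frac


class TestBoundGeneSet:
    def test_flank_boundary(self):
        tss = tss_set([10_000, 50_000])
        near = mk_region("c", 14_999, 15_400, OccupancyClass.CTCF_ONLY)
        far = mk_region("c", 55_001, 55_400, OccupancyClass.CTCF_ONLY)
        bound = ck.bound_gene_set([near, far], tss, flank=5000)
        assert bound == {"g0"}

    def test_matches_brute_force(self, rng):
        positions = sorted(rng.integers(0, 300_000, 50).tolist())
        tss = tss_set(positions)
        regions = [
            mk_region("c", int(s), int(s) + 200, OccupancyClass.CTCF_AND_BORIS)
            for s in rng.integers(0, 300_000, 15)
        ]
        bound = ck.bound_gene_set(regions, tss, flank=5000)
        expected = set()
        for gid, p in zip(tss.gene_ids, positions):
            for r in regions:
                d = (
                    0
                    if r.peak.start <= p < r.peak.end
                    else min(abs(p - r.peak.start), abs(p - (r.peak.end - 1)))
                )
                if d <= 5000:
                    expected.add(gid)
        assert bound == expected

    def test_missing_gene_ids_rejected(self):
        tss = tss_set([100], with_ids=False)
        with pytest.raises(ValueError):
            ck.bound_gene_set([], tss)


def enumerate_fisher_greater(a, b, c, d):
    """Hypergeometric tail by explicit enumeration over table space."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        for x in range(lo, hi + 1)
    }
    return sum(p for x, p in probs.items() if x >= a)


class TestFisherEnrichment:
    def test_odds_ratio_arithmetic(self):
        res = ck.fisher_enrichment(ContingencyTable(20, 10, 10, 20))
        assert res.odds_ratio == pytest.approx(4.0)
        res2 = ck.fisher_enrichment(ContingencyTable(30, 70, 30, 70))
        assert res2.odds_ratio == pytest.approx(1.0)

    def test_infinite_and_undefined_ratio(self):
        res = ck.fisher_enrichment(ContingencyTable(5, 0, 0, 5))
        assert math.isinf(res.odds_ratio)
        res2 = ck.fisher_enrichment(ContingencyTable(0, 5, 0, 5))
        assert math.isnan(res2.odds_ratio)
        assert 0 < res2.pvalue <= 1

    def test_matches_enumeration_small_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, 4))
            if a + b + c + d == 0:
                continue
            res = ck.fisher_enrichment(ContingencyTable(a, b, c, d), "greater")
            assert res.pvalue == pytest.approx(
                enumerate_fisher_greater(a, b, c, d), abs=1e-12
            )

    def test_two_sided_matches_scipy(self):
        res = ck.fisher_enrichment(ContingencyTable(8, 2, 1, 5), "two_sided")
        _, p = stats.fisher_exact([[8, 2], [1, 5]], "two-sided")
        assert res.pvalue == pytest.approx(p)

    def test_exact_ci_covers_point_estimate(self):
        t = ContingencyTable(30, 20, 15, 35)
        lo, hi = ck.odds_ratio_confint(t)
        assert lo < (30 * 35) / (20 * 15) < hi

    def test_degenerate_margin_ci(self):
        lo, hi = ck.odds_ratio_confint(ContingencyTable(0, 10, 5, 5))
        assert lo == 0.0 and hi < math.inf


class TestGenomicDistribution:
    model = GeneModel(
        [
            Transcript("t1", "c", 10_000, 20_000, "+", ((10_000, 11_000), (19_000, 20_000))),
            Transcript("t2", "c", 50_000, 70_000, "-", ((50_000, 52_000), (69_000, 70_000))),
            Transcript("t3", "c", 100_000, 110_000, "+", ((100_000, 110_000),)),
        ]
    )

    def test_upstream_summit_is_promoter(self):
        peaks = [mk_peak("c", 9400, 9600)]  # summit 9500, 500 bp upstream of t1 TSS
        dist = ck.genomic_distribution(peaks, self.model)
        assert dist["promoter"] == 1.0

    def test_fractions_sum_to_one(self, rng):
        peaks = [
            mk_peak("c", int(s), int(s) + 200)
            for s in rng.integers(0, 200_000, 100)
        ]
        dist = ck.genomic_distribution(peaks, self.model)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_matches_brute_force_and_invariances(self, rng):
        peaks = [
            mk_peak("c", int(s), int(s) + 100)
            for s in rng.integers(0, 150_000, 200)
        ]
        dist = ck.genomic_distribution(peaks, self.model)

        def brute_category(pos):
            for t in self.model.transcripts:
                if abs(pos - t.tss) <= 2000:
                    return "promoter"
            for t in self.model.transcripts:
                if any(s <= pos < e for s, e in t.exons):
                    return "exon"
            for t in self.model.transcripts:
                if t.start <= pos < t.end:
                    return "intron"
            return "intergenic"

        from collections import Counter

        counts = Counter(brute_category(p.summit) for p in peaks)
        for cat in ("promoter", "exon", "intron", "intergenic"):
            assert dist[cat] == pytest.approx(counts[cat] / len(peaks))

        # peak order and transcript duplication invariance
        rng.shuffle(peaks)
        assert ck.genomic_distribution(peaks, self.model) == dist
        dup = GeneModel(self.model.transcripts * 3)
        assert ck.genomic_distribution(peaks, dup) == dist


class TestReadTssBed:
    def test_bed6_with_gene_names(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text("c\t100\t101\tGENE1\t0\t+\nc\t500\t501\tGENE2\t0\t-\n")
        tss = read_tss_bed(str(p))
        assert tss.gene_ids == ["GENE1", "GENE2"]
        assert tss.anchor_points() == [("c", 100), ("c", 500)]
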