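"""Consensus-region building, promoter/enhancer classification, gene windows."""

import pytest

from regland.intervals import GenomicInterval, TSSRecord
from regland.regions import (
    TSSIndex,
    annotate_promoter,
    assign_window_genes,
    classify_regions,
    consensus_regions,
)

from conftest import make_peak
from oracles import brute_consensus, brute_nearest_tss


class TestConsensusRegions:
    def test_two_replicates_merge_and_pass(self):
        peaks = [
            make_peak("chr1", 100, 200, rep="rep1"),
            make_peak("chr1", 150, 250, rep="rep2"),
        ]
        (region,) = consensus_regions(peaks, "A", min_replicates=2)
        assert region.interval == GenomicInterval("chr1", 100, 250)
        assert region.support == 2
        assert region.net_signal == pytest.approx(8.0)  # two peaks of net 4.0

    def test_single_replicate_discarded(self):
        peaks = [make_peak("chr1", 100, 200, rep="rep1")]
        assert consensus_regions(peaks, "A", min_replicates=2) == []
        assert len(consensus_regions(peaks, "A", min_replicates=1)) == 1

    def test_chained_component_counts_all_touching_replicates(self):
        # Bases 100-170 are covered by rep2 only, but support is region-level.
        peaks = [
            make_peak("chr1", 0, 100, rep="rep1"),
            make_peak("chr1", 90, 180, rep="rep2"),
            make_peak("chr1", 170, 260, rep="rep3"),
        ]
        (region,) = consensus_regions(peaks, "A", min_replicates=2)
        assert region.interval == GenomicInterval("chr1", 0, 260)
        assert region.support == 3

    def test_mixed_conditions_rejected(self):
        peaks = [make_peak("chr1", 0, 10), make_peak("chr1", 0, 10, condition="B")]
        with pytest.raises(ValueError, match="condition"):
            consensus_regions(peaks, "A")

    def test_emitted_regions_are_disjoint(self, rng):
        peaks = [
            make_peak("chr1", int(s), int(s) + int(l), rep=f"rep{r}")
            for s, l, r in zip(
                rng.integers(0, 50_000, 120),
                rng.integers(50, 3_000, 120),
                rng.integers(1, 5, 120),
            )
        ]
        regions = consensus_regions(peaks, "A", 2)
        for a, b in zip(regions, regions[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start

    def test_matches_union_find_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 50))
            peaks = [
                make_peak(
                    ["chr1", "chr2"][int(rng.integers(2))],
                    int(s), int(s) + int(l),
                    ip=float(ip), rep=f"rep{int(r)}",
                )
                for s, l, ip, r in zip(
                    rng.integers(0, 20_000, n),
                    rng.integers(1, 1_500, n),
                    rng.uniform(1, 30, n),
                    rng.integers(1, 4, n),
                )
            ]
            got = [
                (r.interval.chrom, r.interval.start, r.interval.end, r.support,
                 pytest.approx(r.net_signal))
                for r in consensus_regions(peaks, "A", 2)
            ]
            assert got == brute_consensus(peaks, 2)


def region(start, end, chrom="chr1", condition="A", support=2, signal=10.0):
    from regland.regions import ConsensusRegion

    return ConsensusRegion(GenomicInterval(chrom, start, end), condition, support, signal)


class TestClassification:
    def test_distance_thresholds(self, small_tss):
        # centres at 2400 (1500 bp from geneB@1300... use explicit cases)
        tss = [TSSRecord("g1", "chr1", 10_000)]
        promoter = region(9_500 - 750, 9_500 + 750)        # centre 9500, d=500
        enhancer_at_2k = region(11_250, 12_750)            # centre 12000, d=2000
        far = region(99_000, 100_000)                      # d >> 2000
        out = classify_regions([promoter, enhancer_at_2k, far], tss)
        assert [r.klass for r in out] == ["promoter", "enhancer", "enhancer"]
        assert out[0].anchor_gene == "g1"
        assert out[1].tss_distance == 2000  # strict <: boundary is enhancer

    def test_centre_on_tss_is_promoter(self):
        tss = [TSSRecord("g1", "chr1", 5_000)]
        (out,) = classify_regions([region(4_500, 5_500)], tss)
        assert out.klass == "promoter" and out.anchor_gene == "g1"
        assert out.tss_distance == 0

    def test_no_tss_chromosome_flagged_enhancer(self):
        tss = [TSSRecord("g1", "chr2", 5_000)]
        (out,) = classify_regions([region(4_500, 5_500)], tss)
        assert out.klass == "enhancer" and out.no_tss_chrom

    def test_partition(self, rng, small_tss):
        regions = [
            region(int(s), int(s) + 1_000, chrom=["chr1", "chr2"][int(rng.integers(2))])
            for s in rng.integers(0, 60_000, 40)
        ]
        out = classify_regions(regions, small_tss)
        n_prom = sum(1 for r in out if r.klass == "promoter")
        n_enh = sum(1 for r in out if r.klass == "enhancer")
        assert n_prom + n_enh == len(regions)


class TestAnnotatePromoter:
    def test_nearest_wins(self):
        tss = [TSSRecord("geneA", "chr1", 900), TSSRecord("geneB", "chr1", 1300)]
        assert annotate_promoter(GenomicInterval("chr1", 500, 1500), tss) == "geneA"

    def test_tie_breaks_lexicographically(self):
        tss = [TSSRecord("geneB", "chr1", 1100), TSSRecord("geneA", "chr1", 900)]
        # centre 1000: both 100 bp away
        assert annotate_promoter(GenomicInterval("chr1", 500, 1500), tss) == "geneA"

    def test_single_tss(self):
        tss = [TSSRecord("only", "chr1", 99)]
        assert annotate_promoter(GenomicInterval("chr1", 0, 10), tss) == "only"

    def test_no_tss_on_chromosome_errors(self):
        with pytest.raises(ValueError, match="chr1"):
            annotate_promoter(GenomicInterval("chr1", 0, 10), [TSSRecord("g", "chr2", 0)])

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            tss = [
                TSSRecord(f"g{i}", ["chr1", "chr2"][int(rng.integers(2))],
                          int(rng.integers(0, 100_000)))
                for i in range(n)
            ]
            pos = int(rng.integers(0, 100_000))
            chrom = ["chr1", "chr2"][int(rng.integers(2))]
            expected = brute_nearest_tss(tss, chrom, pos)
            index = TSSIndex(tss)
            assert index.nearest(chrom, pos) == expected


class TestWindowGenes:
    def test_window_bounds(self):
        enh = GenomicInterval("chr1", 1_000_000, 1_001_000)
        tss = [
            TSSRecord("at_lower", "chr1", 600_000),     # == start - 400k: included
            TSSRecord("below", "chr1", 599_999),        # excluded
            TSSRecord("at_upper", "chr1", 1_401_000),   # == end + 400k: excluded
            TSSRecord("just_in", "chr1", 1_400_999),
            TSSRecord("inside", "chr1", 1_000_500),
        ]
        genes = assign_window_genes(enh, tss, 400)
        assert set(genes) == {"at_lower", "just_in", "inside"}
        assert genes[0] == "inside"  # distance 0 sorts first

    def test_empty_window(self):
        enh = GenomicInterval("chr1", 0, 1_000)
        assert assign_window_genes(enh, [TSSRecord("g", "chr2", 0)], 400) == []

    def test_monotone_in_window_size(self, rng):
        tss = [
            TSSRecord(f"g{i}", "chr1", int(p))
            for i, p in enumerate(rng.integers(0, 2_000_000, 200))
        ]
        enh = GenomicInterval("chr1", 900_000, 905_000)
        g100 = set(assign_window_genes(enh, tss, 100))
        g200 = set(assign_window_genes(enh, tss, 200))
        g400 = set(assign_window_genes(enh, tss, 400))
        assert g100 <= g200 <= g400

    def test_duplicate_gene_ids_collapse_to_nearest(self):
        enh = GenomicInterval("chr1", 10_000, 11_000)
        tss = [TSSRecord("dup", "chr1", 5_000), TSSRecord("dup", "chr1", 10_500)]
        assert assign_window_genes(enh, tss, 100) == ["dup"]
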