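"""Regulatory-window construction: strand-aware promoters, symmetric
enhancers, and intron-containment host-gene assignment."""

from __future__ import annotations

import numpy as np
import pytest

from mirreg.intervals import GenomicInterval, IntervalSet
from mirreg.io_formats import AnnotationSet, GeneModel, MiRNALocus
from mirreg.regions import (
    build_region_set, enhancer_window, find_host_gene, promoter_window,
)


def gi(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestPromoterWindow:
    def test_plus_strand_directly_upstream(self):
        w = promoter_window(gi("chr1", 10000, 10090, "+"), 2000)
        assert (w.start, w.end, w.strand) == (8000, 10000, "+")

    def test_minus_strand_mirror(self):
        w = promoter_window(gi("chr1", 10000, 10090, "-"), 2000)
        assert (w.start, w.end, w.strand) == (10090, 12090, "-")

    def test_clipped_at_chromosome_origin(self):
        w = promoter_window(gi("chr1", 500, 600, "+"), 2000)
        assert (w.start, w.end) == (0, 500)

    def test_clipped_at_chromosome_length_on_minus_strand(self):
        w = promoter_window(gi("chr1", 500, 600, "-"), 2000, chrom_length=1500)
        assert (w.start, w.end) == (600, 1500)

    def test_unstranded_locus_rejected_with_instruction(self):
        with pytest.raises(ValueError, match="unstranded"):
            promoter_window(gi("chr1", 10000, 10090, "."), 2000)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_promoter_abuts_locus_and_never_overlaps_body(self, strand):
        locus = gi("chr1", 50000, 50100, strand)
        w = promoter_window(locus, 2000)
        if strand == "+":
            assert w.end == locus.start
        else:
            assert w.start == locus.end
        assert not w.overlaps(locus)


class TestEnhancerWindow:
    def test_symmetric_extension_with_clip(self):
        w = enhancer_window(gi("chr1", 10000, 10090), 10000)
        assert (w.start, w.end) == (0, 20090)

    def test_symmetric_extension(self):
        w = enhancer_window(gi("chr2", 50000, 50100), 10000)
        assert (w.start, w.end) == (40000, 60100)

    def test_size_zero_degenerates_to_locus(self):
        locus = gi("chr1", 10000, 10090)
        w = enhancer_window(locus, 0)
        assert (w.start, w.end) == (locus.start, locus.end)

    def test_contains_locus_and_monotone_in_size(self):
        locus = gi("chr1", 50000, 50100)
        prev = None
        for s in (0, 100, 1000, 10000):
            w = enhancer_window(locus, s)
            assert w.contains(locus)
            if prev is not None:
                assert w.contains(prev)
            prev = w


def _gene(gene_id, chrom, start, end, exons, strand="+"):
    return GeneModel(gene_id=gene_id, interval=gi(chrom, start, end, strand),
                     exons=IntervalSet([gi(chrom, s, e, strand) for s, e in exons]))


class TestFindHostGene:
    def test_mirna_inside_intron_is_hosted(self):
        g = _gene("G1", "chr1", 1000, 5000, [(1000, 1200), (4000, 5000)])
        mir = MiRNALocus("m", gi("chr1", 1500, 1600, "+"))
        assert find_host_gene(mir, [g]) is g

    def test_exon_overlapping_mirna_is_not_hosted(self):
        g = _gene("G1", "chr1", 1000, 5000, [(1000, 1200), (4000, 5000)])
        mir = MiRNALocus("m", gi("chr1", 1100, 1150, "+"))
        assert find_host_gene(mir, [g]) is None

    def test_gene_without_exons_never_hosts(self):
        g = GeneModel("G1", gi("chr1", 1000, 5000, "+"))
        mir = MiRNALocus("m", gi("chr1", 1500, 1600, "+"))
        assert find_host_gene(mir, [g]) is None

    def test_smallest_gene_wins_then_lexicographic_id(self):
        big = _gene("A", "chr1", 0, 10000, [(0, 100), (9000, 10000)])
        small = _gene("B", "chr1", 500, 6000, [(500, 600), (5000, 6000)])
        tie = _gene("Aa", "chr1", 400, 5900, [(400, 500), (5800, 5900)])
        small2 = _gene("C", "chr1", 400, 5900, [(400, 500), (5800, 5900)])
        mir = MiRNALocus("m", gi("chr1", 2000, 2100, "+"))
        assert find_host_gene(mir, [big, small]).gene_id == "B"
        assert find_host_gene(mir, [big, tie, small2]).gene_id == "Aa"

    def test_random_placements_match_per_base_intron_oracle(self, demo_bundle):
        """200 random miRNA placements vs a per-base exon/intron labelling."""
        ann = demo_bundle.annotation
        clen = demo_bundle.config.chromosome_length_bp
        rng = np.random.default_rng(11)

        # per-base oracle: for each gene, label exonic bases
        exonic = {}
        for g in ann.genes:
            mask = np.zeros(clen, dtype=bool)
            for e in g.exons:
                mask[e.start:e.end] = True
            exonic[g.gene_id] = mask

        for _ in range(200):
            chrom = f"chr{int(rng.integers(1, demo_bundle.config.n_chromosomes + 1))}"
            start = int(rng.integers(0, clen - 150))
            mir = MiRNALocus("probe", gi(chrom, start, start + int(rng.integers(50, 150)), "+"))
            hosts = []
            for g in ann.genes:
                if g.interval.chrom != chrom or len(g.exons) == 0:
                    continue
                inside = g.interval.start <= mir.interval.start and \
                    mir.interval.end <= g.interval.end
                touches_exon = exonic[g.gene_id][mir.interval.start:mir.interval.end].any()
                if inside and not touches_exon:
                    hosts.append(g)
            expected = min(hosts, key=lambda g: (g.interval.length, g.gene_id)) if hosts else None
            got = find_host_gene(mir, ann.genes)
            assert (got.gene_id if got else None) == (expected.gene_id if expected else None)


class TestBuildRegionSet:
    @pytest.fixture()
    def annotation(self):
        g = _gene("G1", "chr1", 30000, 40000, [(30000, 30400), (39000, 40000)], "-")
        return AnnotationSet(
            genes=[g],
            mirnas=[MiRNALocus("intronic", gi("chr1", 33000, 33100, "+")),
                    MiRNALocus("intergenic", gi("chr1", 80000, 80100, "-"))])

    def test_intergenic_mirna_yields_two_regions(self, annotation):
        rs = build_region_set(annotation.get_mirna("intergenic"), annotation)
        assert sorted(r.region_type for r in rs.regions) == ["mir_enhancer", "mir_promoter"]
        assert rs.host_gene_id is None

    def test_intronic_mirna_yields_four_regions_from_host_strand(self, annotation):
        rs = build_region_set(annotation.get_mirna("intronic"), annotation)
        assert sorted(r.region_type for r in rs.regions) == [
            "host_enhancer", "host_promoter", "mir_enhancer", "mir_promoter"]
        assert rs.host_gene_id == "G1"
        host_prom = rs.get("host_promoter")
        # host gene is on -, so its promoter sits directly downstream-in-coordinates
        assert host_prom.interval.start == 40000

    def test_region_set_sizes_match_generator_truth(self, demo_bundle):
        for rs in demo_bundle.region_sets:
            intronic = demo_bundle.truth.intronic[rs.mir_id]
            assert len(rs.regions) == (4 if intronic else 2)
            assert (rs.host_gene_id is not None) == intronic
            assert rs.host_gene_id == demo_bundle.truth.host_genes[rs.mir_id]
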