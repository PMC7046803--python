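"""Regulatory-window construction around miRNA loci.

The analysed windows follow the study design: a strand-aware proximal
promoter covering the 2 kb directly upstream of a locus, and an enhancer
neighbourhood covering everything within 10 kb of the locus (symmetric,
including the locus body). For miRNAs encoded inside an intron of a host
gene, the host gene's own promoter and enhancer windows are additionally
queried.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import STRAND_FWD, STRAND_NONE, STRAND_REV, GenomicInterval, merge_intervals
from .io_formats import AnnotationSet, GeneModel, MiRNALocus

PROMOTER_BP = 2000
ENHANCER_BP = 10000

REGION_TYPES = ("mir_promoter", "mir_enhancer", "host_promoter", "host_enhancer")


@dataclass(frozen=True)
class RegulatoryRegion:
    """One typed window derived from a miRNA locus or its host gene."""

    region_type: str
    interval: GenomicInterval
    source_id: str
    mir_id: str

    def __post_init__(self) -> None:
        if self.region_type not in REGION_TYPES:
            raise ValueError(f"unknown region type {self.region_type!r}")


@dataclass
class RegulatoryRegionSet:
    """All windows queried for one miRNA: always its own promoter and
    enhancer, plus the host gene's pair when the miRNA is intronic."""

    mir_id: str
    regions: list[RegulatoryRegion] = field(default_factory=list)
    host_gene_id: str | None = None

    def __iter__(self):
        return iter(self.regions)

    def get(self, region_type: str) -> RegulatoryRegion | None:
        for r in self.regions:
            if r.region_type == region_type:
                return r
        return None

    def union(self):
        """Merged union of all window intervals (for deduplicated counting)."""
        return merge_intervals([r.interval for r in self.regions])


def promoter_window(
    locus_interval: GenomicInterval,
    size_bp: int = PROMOTER_BP,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """The ``size_bp`` window directly upstream of a locus.

    Upstream is strand-dependent: on + the window ends where the locus
    starts; on - it begins where the locus ends. Clipped at position 0 and,
    when known, at the chromosome length. The output carries the locus
    strand.
    """
    if size_bp <= 0:
        raise ValueError(f"promoter size must be positive, got {size_bp}")
    if locus_interval.strand == STRAND_NONE:
        raise ValueError(
            f"locus {locus_interval} is unstranded; promoter placement requires a "
            "strand - set one explicitly on the annotation record"
        )
    if locus_interval.strand == STRAND_FWD:
        start = max(0, locus_interval.start - size_bp)
        end = locus_interval.start
    else:
        start = locus_interval.end
        end = locus_interval.end + size_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
    if start >= end:
        raise ValueError(
            f"promoter window of {locus_interval} collapses to zero length at the "
            "chromosome boundary"
        )
    return GenomicInterval(locus_interval.chrom, start, end, locus_interval.strand)


def enhancer_window(
    locus_interval: GenomicInterval,
    size_bp: int = ENHANCER_BP,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Everything within ``size_bp`` of the locus: the symmetric span
    [start - size_bp, end + size_bp), clipped, including the locus body."""
    if size_bp < 0:
        raise ValueError(f"enhancer size must be non-negative, got {size_bp}")
    start = max(0, locus_interval.start - size_bp)
    end = locus_interval.end + size_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(locus_interval.chrom, start, end, locus_interval.strand)


def find_host_gene(mirna: MiRNALocus, genes: list[GeneModel]) -> GeneModel | None:
    """The host gene of an intronic miRNA, or None for intergenic ones.

    A gene qualifies iff the miRNA lies fully inside the gene body and
    overlaps none of its exons, i.e. sits in an intron. Genes without exon
    structure count as single-exon and can never host. Among multiple
    qualifying genes the shortest wins; ties break lexicographically on
    gene_id.
    """
    candidates = []
    for g in genes:
        if not g.interval.contains(mirna.interval):
            continue
        if len(g.exons) == 0:
            continue  # single-exon convention: no introns to host anything
        if any(mirna.interval.overlaps(ex) for ex in g.exons):
            continue
        candidates.append(g)
    if not candidates:
        return None
    return min(candidates, key=lambda g: (g.interval.length, g.gene_id))


def build_region_set(
    mirna: MiRNALocus,
    annotation: AnnotationSet,
    promoter_bp: int = PROMOTER_BP,
    enhancer_bp: int = ENHANCER_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> RegulatoryRegionSet:
    """All regulatory windows queried for one miRNA.

    Always the miRNA's own promoter and enhancer; plus the host gene's
    promoter and enhancer when :func:`find_host_gene` assigns one.
    """
    clen = (chrom_lengths or {}).get(mirna.interval.chrom)
    regions = [
        RegulatoryRegion("mir_promoter",
                         promoter_window(mirna.interval, promoter_bp, clen),
                         mirna.mir_id, mirna.mir_id),
        RegulatoryRegion("mir_enhancer",
                         enhancer_window(mirna.interval, enhancer_bp, clen),
                         mirna.mir_id, mirna.mir_id),
    ]
    host = find_host_gene(mirna, annotation.genes)
    if host is not None:
        regions.append(RegulatoryRegion(
            "host_promoter", promoter_window(host.interval, promoter_bp, clen),
            host.gene_id, mirna.mir_id))
        regions.append(RegulatoryRegion(
            "host_enhancer", enhancer_window(host.interval, enhancer_bp, clen),
            host.gene_id, mirna.mir_id))
    return RegulatoryRegionSet(
        mir_id=mirna.mir_id, regions=regions,
        host_gene_id=host.gene_id if host else None,
    )


def build_all_region_sets(
    annotation: AnnotationSet,
    promoter_bp: int = PROMOTER_BP,
    enhancer_bp: int = ENHANCER_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> list[RegulatoryRegionSet]:
    """Region sets for every miRNA in the annotation, in annotation order."""
    return [
        build_region_set(m, annotation, promoter_bp, enhancer_bp, chrom_lengths)
        for m in annotation.mirnas
    ]
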