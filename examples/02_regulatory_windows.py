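"""Build the regulatory windows queried around a miRNA locus.

Constructs a toy annotation with one intronic and one intergenic miRNA and
prints the windows the pipeline counts binding in: the 2 kb strand-aware
proximal promoter, the 10 kb symmetric enhancer neighbourhood, and - for
the intronic miRNA - the host gene's own promoter and enhancer.
"""

from mirreg import (
    AnnotationSet, GeneModel, GenomicInterval, IntervalSet, MiRNALocus,
    build_region_set,
)

gene = GeneModel(
    gene_id="HOST1",
    interval=GenomicInterval("chr1", 30_000, 42_000, "+"),
    exons=IntervalSet([GenomicInterval("chr1", 30_000, 30_400, "+"),
                       GenomicInterval("chr1", 41_000, 42_000, "+")]),
)
annotation = AnnotationSet(
    genes=[gene],
    mirnas=[MiRNALocus("mir-intronic", GenomicInterval("chr1", 35_000, 35_090, "-")),
            MiRNALocus("mir-intergenic", GenomicInterval("chr1", 80_000, 80_100, "+"))],
)

for mir in annotation.mirnas:
    rs = build_region_set(mir, annotation)
    host = rs.host_gene_id or "none (intergenic)"
    print(f"{mir.mir_id} at {mir.interval}  host gene: {host}")
    for region in rs.regions:
        iv = region.interval
        print(f"  {region.region_type:<14} {iv.chrom}:{iv.start:>6}-{iv.end:<6} "
              f"({iv.length} bp, from {region.source_id})")
    print()

print("The promoter always abuts the locus on its upstream side (strand-aware);")
print("the enhancer spans the locus plus 10 kb on both flanks.")
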