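# Methods

## Coordinate model

All internal coordinates are 0-based half-open (BED-native), on named
chromosomes with strand in {`+`, `-`, `.`}. GFF3's 1-based closed
coordinates are converted once, at read time; peak files (BED6, ENCODE
narrowPeak/broadPeak, and a "clustered" BED5+cell-line dialect) pass
through unchanged. Overlap is ≥ 1 bp under half-open semantics — abutting
intervals do not overlap — and ignores strand, since ChIP-seq peaks are
unstranded evidence. Merging coalesces overlapping *and* abutting
same-chromosome intervals (union of covered bases), matching how clustered
evidence tracks merge contiguous sites; merging is idempotent and
coverage-preserving, which the tests check against a per-base oracle.
Repeated region queries use an interval-tree index whose results are
asserted equal to the O(n·m) pairwise scan on seeded random instances.

## Regulatory windows

The proximal promoter is the `promoter_bp` (default 2000) window directly
upstream of a locus, strand-aware, abutting the locus boundary, clipped at
position 0 and at the chromosome end when the length is known. Unstranded
loci are rejected rather than defaulted: promoter placement is meaningless
without a strand. The enhancer neighbourhood is the symmetric span
`[start - enhancer_bp, end + enhancer_bp)` (default 10000), clipped,
including the locus body. "Within 10 kb" does not specify a direction, so
the window is taken symmetric from the locus edges; it is deliberately not
promoter-subtracted — a peak in the upstream 2 kb lies in both windows,
and per-miRNA deduplicated totals are reported alongside for a
double-counting-free view.

A miRNA is intronic in gene G iff its interval is fully contained in G's
body and overlaps none of G's exons. Genes without exon structure are
treated as single-exon and never host. Among multiple qualifying genes the
shortest wins (most specific host), ties breaking lexicographically on
gene id. Intronic miRNAs contribute four windows (their own pair plus the
host's), intergenic ones two.

## Occupancy and chromatin state

Per TF label, peaks are optionally merged across cell lines first
(default on: one genomic site supported by several cell lines counts
once); `entries[(miRNA, TF, window)]` is the merged-peak overlap count and
`dedup_totals[(miRNA, TF)]` the count of distinct merged sites overlapping
the union of that miRNA's windows, so
max ≤ dedup ≤ sum over windows holds per (miRNA, TF).

Chromatin state per window is called from histone-mark overlap flags with
the precedence: any H3K4me3 → `active_promoter`; else H3K4me1 with
H3K27ac → `active_enhancer`; else H3K4me1 alone → `poised_enhancer`; else
`unmarked`. The call annotates windows and never filters counts by
default; an opt-in `require_marked` switch restricts counting to windows
whose call is not `unmarked`, reflecting that histone evidence is a
confidence overlay rather than an exclusion criterion.

## Motif model

A motif is a 4×L count matrix smoothed per column as
p(b) = (count_b + pseudocount) / (Σ counts + 4·pseudocount) and scored as
log2(p(b)/background_b) bits (pseudocount 0.5, uniform background by
default; both configurable and recorded). The IUPAC consensus takes a
single base at probability ≥ 0.6, a two-base degeneracy code when the top
two sum to ≥ 0.8, else N. Scanning reports every window reaching
`min_score_frac` × the maximum attainable score, on both strands
(minus-strand windows scored on the reverse complement, reported at +
coordinates); N contributes the background-expected score of 0 bits. By
default scanning is restricted to TF-bound peak intervals — motifs are
matched where the factor binds — with whole-sequence scanning available.
Equal-offset hits on both strands are both reported; there is no basis to
prefer a strand.

## Synthetic landscapes

The generator emulates the structure of the real inputs at desk scale.
Defaults (the demo fixture, seed 17): 2 chromosomes × 200 kb, 6 genes of
9–14 kb with 3 exons each, the seven study miRNAs with fraction_intronic
0.5, 8 TFs drawn from the study's families, 0–6 planted sites per (miRNA,
TF, window), background peaks at 5/Mb restricted to untracked territory
(≥ 1 bp clear of every window), histone peaks co-placed with windows at
per-window-type probabilities, one 12-column ~1.7 bits/column motif with 6
occurrences embedded at recorded offsets inside designated peaks, and a
serum qPCR design (27 + 27 samples, planted ΔCT difference 1.5 cycles,
SD 0.8, 10% hemolysed). Genes and intergenic miRNAs occupy evenly spaced
jittered slots so every 10 kb neighbourhood stays on-chromosome.

Two constructions keep truth exact rather than probabilistic: same-TF
peaks are placed with ≥ 1 bp separation genome-wide, so cross-cell-line
merging is the identity on planted data; and after placement every truth
field (per-window counts, dedup totals, chromatin calls, host
assignments, motif positions) is derived from the placed objects with the
naive pairwise-overlap primitive — the promoter window is a subset of the
enhancer window, so a promoter planting legitimately counts in both, and
the truth table accounts for every such containment. All randomness flows
from one numpy generator seeded from the config; fixtures are
byte-reproducible per seed.

What the generator does **not** emulate: realistic peak shapes, signal
strength, read-level noise, correlated TF co-binding, sequence
composition bias, or real hg19 coordinates. Passing tests therefore
demonstrate the correctness of the counting, classification, scanning and
quantification machinery on data whose answer is known — not concordance
with any browser-derived count on real tracks, which depends on versioned
external data and manual window judgement.

## qPCR quantification

Technical replicates are collapsed by mean CT. Hemolysis QC computes
ΔCT = CT(miR-23a-3p) − CT(miR-451a) and excludes samples strictly above
7 (the boundary value passes); samples missing a marker are un-assessable
and excluded with a logged reason. Relative expression is
2^(−(CT_target − mean(CT_refs))); the arithmetic mean of reference CTs is
exactly geometric-mean normalization of linear-scale reference
quantities, unifying the two normalization conventions in use. Fold
change is the ratio of group means on the linear scale (equal to
2^(−ΔΔCT) for comparative-CT values). Values are log-converted before
testing (base 10 by default; the base is configurable and recorded, as
the convention is not standardized). Group comparison uses the unpaired
two-sided t-test for two groups and one-way ANOVA followed by pairwise
t-tests otherwise, with mean ± SD and min–max descriptives; a Spearman
helper covers covariate checks. CT values ≥ 40 are flagged as
near-undetected but kept. No outlier handling beyond hemolysis QC, and no
amplification-efficiency correction (no standard curves in the workflow
modelled).

## Numerical and design choices

- Reference panels are fully user-specified, never hard-coded: panel
  nomenclature varies (e.g. miR-423-4p vs miR-423-5p) and the package
  does not arbitrate it.
- The default TF-family map reproduces the study field's "FOXO" grouping,
  which in fact pools FOXA/FOXM/FOXP factors; it is plain data and fully
  overridable.
- Headline summaries default to per-window sums (the enumeration over all
  four window types); deduplicated variants are always emitted alongside,
  since published reporting mixes both conventions.
- All rankings and serializations break ties lexicographically and order
  rows/columns deterministically; analysis outputs are byte-identical
  across reruns, and run logs carry config hashes but no timestamps.
- Identical (chrom, start, end, label) peak records are deduplicated at
  read time with a logged count (browser exports can repeat records).
- Problem sizes in the test suite (for example 1,000 random instances for
  the interval-engine oracle, 1,000/500 replicates for type-I error and
  power) were chosen so the whole suite completes in seconds while the
  binomial confidence bands remain tight.

## Known limitations

- No BAM/bigWig support, peak calling, or signal-level quantification;
  inputs are already-called peak intervals.
- No stranded or minimum-overlap-fraction counting (overlap is ≥ 1 bp).
- Motif scores are not p-value calibrated and the background model is
  mononucleotide.
- Host-gene assignment uses gene-body containment with exon exclusion; it
  does not consult transcript isoforms.
- The subtype comparison reports raw counts; it attaches no statistical
  test, since window counts from a handful of loci do not support one.
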