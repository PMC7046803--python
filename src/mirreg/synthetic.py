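"""Synthetic regulatory landscapes and CT tables with planted ground truth.

The generator emulates the statistical structure of the study's inputs at
desk scale: a small multi-chromosome genome; intergenic and intronic miRNA
loci on both strands (intronic ones strictly inside a host-gene intron);
per-TF peak sets planted inside designated promoter/enhancer windows, plus
background peaks kept clear of every tracked window; histone-mark peaks
co-placed with regulatory windows; and motif occurrences embedded at
recorded offsets inside designated TF peaks over an otherwise
uniform-random sequence.

Truth is exact by construction: after placement, every truth field
(occupancy counts, deduplicated totals, chromatin-state calls, host-gene
assignments, motif positions) is derived from the placed objects with the
naive pairwise-overlap primitive, so downstream stages can be checked for
exact agreement. Placement keeps same-TF peaks globally separated by at
least 1 bp, which makes the cross-cell-line merge policy the identity on
planted data and the counts unambiguous.

All randomness flows from a single numpy Generator seeded from the config,
so fixtures are byte-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .intervals import GenomicInterval, IntervalSet, merge_intervals
from .io_formats import (
    AnnotationSet, GeneModel, MiRNALocus, PeakRecord,
    write_fasta, write_gff3, write_peaks,
)
from .motifs import MotifModel, pwm_from_counts, reverse_complement, write_counts_matrix
from .occupancy import HISTONE_MARKS
from .qpcr import CtRecord, CtTable
from .regions import RegulatoryRegionSet, build_all_region_sets

ENCODE_CELL_LINES = (
    "GM12878", "H1-hESC", "HeLa-S3", "HepG2", "HSMM",
    "HUVEC", "K562", "NHEK", "NHLF",
)

STUDY_MIRNAS = (
    "miR-21-5p", "miR-150-5p", "miR-30e-5p",
    "miR-151a-3p", "miR-423-5p", "let-7a-5p", "let-7f-5p",
)

DEMO_TFS = ("ESR1", "FOS", "FoxA1", "FoxA2", "IRF4", "JunD", "RELA", "Stat3")

DEFAULT_HISTONE_PROBS = {
    "mir_promoter": {"H3K4me3": 0.9, "H3K4me1": 0.5, "H3K27ac": 0.5},
    "mir_enhancer": {"H3K4me3": 0.1, "H3K4me1": 0.9, "H3K27ac": 0.6},
    "host_promoter": {"H3K4me3": 0.9, "H3K4me1": 0.5, "H3K27ac": 0.5},
    "host_enhancer": {"H3K4me3": 0.1, "H3K4me1": 0.9, "H3K27ac": 0.6},
}


@dataclass
class GroupSpec:
    """One sample group of the simulated qPCR design."""

    delta_ct_mean: float
    delta_ct_sd: float
    n: int


@dataclass
class QpcrSimConfig:
    """The simulated serum qPCR design.

    Defaults emulate the study's serum panel: a miR-21-5p target
    normalized to a four-miRNA reference panel, patient and control groups
    of realistic size, and a fraction of hemolysed samples whose indicator
    dCT exceeds the exclusion threshold of 7 cycles.
    """

    target: str = "miR-21-5p"
    reference_means: dict[str, float] = field(default_factory=lambda: {
        "miR-93-5p": 24.0, "miR-191-5p": 23.0, "miR-423-4p": 25.0, "miR-103a": 24.5,
    })
    reference_ct_sd: float = 0.3
    groups: dict[str, GroupSpec] = field(default_factory=lambda: {
        "MG": GroupSpec(delta_ct_mean=3.0, delta_ct_sd=0.8, n=27),
        "HC": GroupSpec(delta_ct_mean=4.5, delta_ct_sd=0.8, n=27),
    })
    hemolysis_fraction: float = 0.1
    marker_451a_mean: float = 19.0

    def validate(self) -> None:
        for g, spec in self.groups.items():
            if spec.n < 2:
                raise ValueError(f"qPCR group {g!r} needs n >= 2")
            if spec.delta_ct_sd < 0:
                raise ValueError(f"qPCR group {g!r} has negative SD")
        if not (0 <= self.hemolysis_fraction <= 1):
            raise ValueError("hemolysis_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions of the demo landscape.

    Defaults are the fixture the test suite and acceptance checks run on:
    2 chromosomes x 200 kb, 6 genes, the study's 7 miRNAs with roughly
    half placed intronically, 8 TFs with 0-6 planted sites per window,
    and a 5 peaks/Mb untracked background.
    """

    seed: int = 17
    n_chromosomes: int = 2
    chromosome_length_bp: int = 200_000
    n_genes: int = 6
    exons_per_gene: int = 3
    mir_ids: tuple[str, ...] = STUDY_MIRNAS
    fraction_intronic: float = 0.5
    tf_names: tuple[str, ...] = DEMO_TFS
    promoter_bp: int = 2000
    enhancer_bp: int = 10000
    max_planted_per_region: int = 6
    planted_counts: dict | None = None  # (mir, tf, region_type) -> count override
    background_rate_per_mb: float = 5.0
    peak_length_range: tuple[int, int] = (60, 150)
    histone_probs: dict = field(default_factory=lambda: {
        rt: dict(ms) for rt, ms in DEFAULT_HISTONE_PROBS.items()})
    histone_length_range: tuple[int, int] = (300, 800)
    cell_lines: tuple[str, ...] = ENCODE_CELL_LINES
    motif_tf: str = "FoxA1"
    motif_length: int = 12
    motif_occurrences: int = 6  # number of motif_tf peaks given one embedded site
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)

    def validate(self) -> None:
        if not (0 <= self.fraction_intronic <= 1):
            raise ValueError("fraction_intronic must be in [0, 1]")
        if self.background_rate_per_mb < 0 or self.max_planted_per_region < 0:
            raise ValueError("rates and counts must be non-negative")
        if round(len(self.mir_ids) * self.fraction_intronic) > self.n_genes:
            raise ValueError("more intronic miRNAs requested than genes available")
        self.qpcr.validate()


@dataclass
class TruthTable:
    """Machine-readable ground truth of a generated landscape."""

    occupancy: dict[tuple[str, str, str], int] = field(default_factory=dict)
    dedup_totals: dict[tuple[str, str], int] = field(default_factory=dict)
    chromatin_calls: dict[tuple[str, str], str] = field(default_factory=dict)
    host_genes: dict[str, str | None] = field(default_factory=dict)
    intronic: dict[str, bool] = field(default_factory=dict)
    motif_occurrences: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class LandscapeBundle:
    """Everything one simulation emits, in memory."""

    config: SimulationConfig
    annotation: AnnotationSet
    sequences: dict[str, str]
    chrom_lengths: dict[str, int]
    tf_peaks: list[PeakRecord]
    histone_peaks: list[PeakRecord]
    region_sets: list[RegulatoryRegionSet]
    motif: MotifModel
    truth: TruthTable


class PlacementError(RuntimeError):
    """Raised when a planted object cannot be placed under its constraints."""


def _place_disjoint(
    rng: np.random.Generator,
    lo: int, hi: int,
    length: int,
    taken: list[tuple[int, int]],
    what: str,
    max_tries: int = 500,
) -> tuple[int, int]:
    """A [s, s+length) span inside [lo, hi) separated >= 1 bp from ``taken``."""
    if hi - lo < length:
        raise PlacementError(f"cannot place {what}: window [{lo},{hi}) shorter than {length}")
    for _ in range(max_tries):
        s = int(rng.integers(lo, hi - length + 1))
        e = s + length
        # require a >= 1 bp gap so the merge policy never coalesces plantings
        if all(e < ts or s > te for ts, te in taken):
            return s, e
    raise PlacementError(f"cannot place {what} in [{lo},{hi}) after {max_tries} tries")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, size=length)].copy()


def _build_genes_and_mirnas(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[MiRNALocus], dict[str, bool], dict[str, str | None]]:
    """Slot-based deterministic layout of genes and miRNA loci.

    Elements (genes and intergenic miRNAs) occupy evenly spaced, jittered
    slots so their 10 kb neighbourhoods stay on-chromosome; intronic
    miRNAs go strictly inside an intron of a distinct host gene.
    """
    n_mir = len(cfg.mir_ids)
    n_intronic = int(round(n_mir * cfg.fraction_intronic))
    order = list(rng.permutation(n_mir))
    intronic_ids = [cfg.mir_ids[i] for i in order[:n_intronic]]
    intergenic_ids = [cfg.mir_ids[i] for i in order[n_intronic:]]

    margin = cfg.enhancer_bp + cfg.promoter_bp + 1000
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    elements: list[tuple[str, str]] = [("gene", f"GENE{i + 1}") for i in range(cfg.n_genes)]
    elements += [("mir", mid) for mid in intergenic_ids]
    per_chrom: dict[str, list[tuple[str, str]]] = {c: [] for c in chroms}
    for i, el in enumerate(elements):
        per_chrom[chroms[i % len(chroms)]].append(el)

    genes: list[GeneModel] = []
    mirnas: dict[str, MiRNALocus] = {}
    for chrom in chroms:
        els = per_chrom[chrom]
        if not els:
            continue
        usable = cfg.chromosome_length_bp - 2 * margin
        slot = usable // len(els)
        if slot < 20_000:
            raise PlacementError(
                f"{chrom}: slot width {slot} bp too small for the requested element "
                "count; enlarge chromosomes or reduce genes/miRNAs"
            )
        for k, (kind, name) in enumerate(els):
            center = margin + slot * k + slot // 2 + int(rng.integers(-2000, 2001))
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                glen = int(rng.integers(9000, 14001))
                g_start = center - glen // 2
                exon_lens = rng.integers(300, 601, size=cfg.exons_per_gene)
                intron_total = glen - int(exon_lens.sum())
                n_introns = max(cfg.exons_per_gene - 1, 0)
                if n_introns and intron_total < 2500 * n_introns:
                    raise PlacementError(f"gene {name}: introns too short for hosting")
                exons = []
                pos = g_start
                for i_ex in range(cfg.exons_per_gene):
                    exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i_ex]), strand))
                    pos += int(exon_lens[i_ex])
                    if i_ex < n_introns:
                        base = intron_total // n_introns
                        extra = intron_total - base * n_introns if i_ex == 0 else 0
                        pos += base + extra
                genes.append(GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, g_start, g_start + glen, strand),
                    exons=IntervalSet(exons),
                ))
            else:
                mlen = int(rng.integers(80, 121))
                m_start = center - mlen // 2
                mirnas[name] = MiRNALocus(
                    mir_id=name, mature_names=[name],
                    interval=GenomicInterval(chrom, m_start, m_start + mlen, strand))

    host_of: dict[str, str | None] = {mid: None for mid in intergenic_ids}
    host_genes = list(rng.permutation(len(genes)))[:len(intronic_ids)]
    for mid, gi in zip(intronic_ids, host_genes):
        gene = genes[gi]
        introns = gene.introns().intervals
        if not introns:
            raise PlacementError(f"gene {gene.gene_id} has no intron to host {mid}")
        intron = introns[int(rng.integers(0, len(introns)))]
        mlen = int(rng.integers(80, 121))
        # strictly inside the intron, >= 1 bp clear of both flanking exons
        s, _ = _place_disjoint(rng, intron.start + 1, intron.end - 1, mlen, [],
                               what=f"intronic miRNA {mid}")
        strand = "+" if rng.random() < 0.5 else "-"
        mirnas[mid] = MiRNALocus(
            mir_id=mid, mature_names=[mid],
            interval=GenomicInterval(intron.chrom, s, s + mlen, strand))
        host_of[mid] = gene.gene_id

    ordered = [mirnas[mid] for mid in cfg.mir_ids]
    intronic_flag = {mid: (host_of.get(mid) is not None) for mid in cfg.mir_ids}
    return genes, ordered, intronic_flag, host_of


def simulate_regulatory_landscape(config: SimulationConfig | None = None) -> LandscapeBundle:
    """Generate a complete desk-scale fixture with exact planted truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = {f"chr{i + 1}": cfg.chromosome_length_bp
                     for i in range(cfg.n_chromosomes)}

    genes, mirnas, intronic_flag, host_of = _build_genes_and_mirnas(cfg, rng)
    annotation = AnnotationSet(genes=genes, mirnas=mirnas, genome_build="synthetic-v1")
    region_sets = build_all_region_sets(
        annotation, cfg.promoter_bp, cfg.enhancer_bp, chrom_lengths)

    # --- planted TF peaks, globally >= 1 bp apart per TF -------------------
    taken_by_tf: dict[str, list[tuple[int, int]]] = {t: [] for t in cfg.tf_names}
    taken_by_chrom_tf: dict[tuple[str, str], list[tuple[int, int]]] = {}
    tf_peaks: list[PeakRecord] = []

    def _add_peak(tf: str, chrom: str, s: int, e: int) -> None:
        n_cl = int(rng.integers(1, 4))
        cls = frozenset(str(x) for x in rng.choice(cfg.cell_lines, size=n_cl, replace=False))
        tf_peaks.append(PeakRecord(
            interval=GenomicInterval(chrom, s, e), label=tf, cell_lines=cls,
            score=float(np.round(rng.uniform(100, 1000), 1))))
        taken_by_chrom_tf.setdefault((chrom, tf), []).append((s, e))

    for rs in region_sets:
        for region in rs.regions:
            for tf in cfg.tf_names:
                if cfg.planted_counts is not None:
                    k = int(cfg.planted_counts.get(
                        (rs.mir_id, tf, region.region_type), 0))
                else:
                    k = int(rng.integers(0, cfg.max_planted_per_region + 1))
                for _ in range(k):
                    plen = int(rng.integers(*cfg.peak_length_range))
                    s, e = _place_disjoint(
                        rng, region.interval.start, region.interval.end, plen,
                        taken_by_chrom_tf.get((region.interval.chrom, tf), []),
                        what=f"{tf} peak in {rs.mir_id}/{region.region_type}")
                    _add_peak(tf, region.interval.chrom, s, e)

    # --- background peaks: only in untracked territory ---------------------
    tracked = merge_intervals([r.interval for rs in region_sets for r in rs.regions])
    tracked_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in tracked:
        tracked_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    gaps: list[tuple[str, int, int]] = []
    for chrom, clen in chrom_lengths.items():
        pos = 0
        for ts, te in sorted(tracked_by_chrom.get(chrom, [])):
            if ts - 1 > pos:  # keep >= 1 bp clear of every tracked window
                gaps.append((chrom, pos, ts - 1))
            pos = max(pos, te + 1)
        if clen > pos:
            gaps.append((chrom, pos, clen))
    genome_mb = sum(chrom_lengths.values()) / 1e6
    n_bg = int(rng.poisson(cfg.background_rate_per_mb * genome_mb))
    gap_lens = np.array([e - s for _, s, e in gaps], dtype=float)
    for _ in range(n_bg):
        tf = str(rng.choice(cfg.tf_names))
        plen = int(rng.integers(*cfg.peak_length_range))
        ok = gap_lens >= plen
        if not ok.any():
            raise PlacementError("no untracked gap can hold a background peak")
        probs = np.where(ok, gap_lens, 0.0)
        gi = int(rng.choice(len(gaps), p=probs / probs.sum()))
        chrom, lo, hi = gaps[gi]
        s, e = _place_disjoint(rng, lo, hi, plen,
                               taken_by_chrom_tf.get((chrom, tf), []),
                               what=f"background {tf} peak")
        _add_peak(tf, chrom, s, e)

    # --- histone peaks ------------------------------------------------------
    histone_peaks: list[PeakRecord] = []
    for rs in region_sets:
        for region in rs.regions:
            probs = cfg.histone_probs.get(region.region_type, {})
            for mark in HISTONE_MARKS:
                if rng.random() < probs.get(mark, 0.0):
                    hlen = int(rng.integers(*cfg.histone_length_range))
                    hlen = min(hlen, region.interval.length)
                    s = int(rng.integers(region.interval.start,
                                         region.interval.end - hlen + 1))
                    histone_peaks.append(PeakRecord(
                        interval=GenomicInterval(region.interval.chrom, s, s + hlen),
                        label=mark,
                        score=float(np.round(rng.uniform(100, 1000), 1))))

    # --- genome sequence and embedded motif occurrences ---------------------
    seq_arrays = {c: _random_sequence(rng, l) for c, l in chrom_lengths.items()}
    consensus = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=cfg.motif_length))
    counts = np.full((4, cfg.motif_length), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97.0
    motif = pwm_from_counts(counts, pseudocount=0.5, name=cfg.motif_tf)
    motif_truth: list[tuple[str, int, str]] = []
    host_peaks = [p for p in tf_peaks if p.label == cfg.motif_tf
                  and p.interval.length >= cfg.motif_length + 2]
    for p in host_peaks[:cfg.motif_occurrences]:
        off = int(rng.integers(p.interval.start + 1,
                               p.interval.end - cfg.motif_length))
        strand = "+" if rng.random() < 0.5 else "-"
        word = consensus if strand == "+" else reverse_complement(consensus)
        seq_arrays[p.interval.chrom][off:off + cfg.motif_length] = \
            np.frombuffer(word.encode(), dtype=np.uint8)
        motif_truth.append((p.interval.chrom, off, strand))
    sequences = {c: a.tobytes().decode() for c, a in seq_arrays.items()}

    # --- derive exact truth from the placements (naive pairwise overlaps) ---
    truth = TruthTable(host_genes=host_of, intronic=intronic_flag,
                       motif_occurrences=sorted(motif_truth))
    peaks_by_tf: dict[str, list[PeakRecord]] = {t: [] for t in cfg.tf_names}
    for p in tf_peaks:
        peaks_by_tf[p.label].append(p)
    for rs in region_sets:
        for tf in cfg.tf_names:
            for region in rs.regions:
                truth.occupancy[(rs.mir_id, tf, region.region_type)] = sum(
                    1 for p in peaks_by_tf[tf] if region.interval.overlaps(p.interval))
            truth.dedup_totals[(rs.mir_id, tf)] = sum(
                1 for p in peaks_by_tf[tf]
                if any(region.interval.overlaps(p.interval) for region in rs.regions))
        for region in rs.regions:
            flags = {mark: any(region.interval.overlaps(h.interval)
                               for h in histone_peaks if h.label == mark)
                     for mark in HISTONE_MARKS}
            if flags["H3K4me3"]:
                call = "active_promoter"
            elif flags["H3K4me1"] and flags["H3K27ac"]:
                call = "active_enhancer"
            elif flags["H3K4me1"]:
                call = "poised_enhancer"
            else:
                call = "unmarked"
            truth.chromatin_calls[(rs.mir_id, region.region_type)] = call

    return LandscapeBundle(
        config=cfg, annotation=annotation, sequences=sequences,
        chrom_lengths=chrom_lengths, tf_peaks=tf_peaks,
        histone_peaks=histone_peaks, region_sets=region_sets,
        motif=motif, truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture serialization
# ---------------------------------------------------------------------------


def write_fixture(bundle: LandscapeBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a landscape bundle as standard files plus truth TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "annotation.gff3",
        "tf_peaks": out / "tf_peaks.clustered.bed",
        "histone_peaks": out / "histone_peaks.broadPeak",
        "motif": out / "motif.pfm",
        "truth_occupancy": out / "truth_occupancy.tsv",
        "truth_dedup": out / "truth_dedup.tsv",
        "truth_chromatin": out / "truth_chromatin.tsv",
        "truth_loci": out / "truth_loci.tsv",
        "truth_motifs": out / "truth_motifs.tsv",
        "config": out / "config.yaml",
    }
    write_fasta(bundle.sequences, paths["fasta"])
    write_gff3(bundle.annotation, paths["gff3"])
    write_peaks(bundle.tf_peaks, paths["tf_peaks"], dialect="clustered")
    write_peaks(bundle.histone_peaks, paths["histone_peaks"], dialect="broadPeak")
    write_counts_matrix(bundle.motif, paths["motif"])

    t = bundle.truth
    lines = ["mir_id\ttf\tregion_type\tcount"]
    for (m, tf, rt), v in sorted(t.occupancy.items()):
        lines.append(f"{m}\t{tf}\t{rt}\t{v}")
    paths["truth_occupancy"].write_text("\n".join(lines) + "\n")

    lines = ["mir_id\ttf\tcount"]
    for (m, tf), v in sorted(t.dedup_totals.items()):
        lines.append(f"{m}\t{tf}\t{v}")
    paths["truth_dedup"].write_text("\n".join(lines) + "\n")

    lines = ["mir_id\tregion_type\tcall"]
    for (m, rt), call in sorted(t.chromatin_calls.items()):
        lines.append(f"{m}\t{rt}\t{call}")
    paths["truth_chromatin"].write_text("\n".join(lines) + "\n")

    lines = ["mir_id\tintronic\thost_gene"]
    for m in bundle.config.mir_ids:
        lines.append(f"{m}\t{int(t.intronic[m])}\t{t.host_genes[m] or '.'}")
    paths["truth_loci"].write_text("\n".join(lines) + "\n")

    lines = ["chrom\tposition\tstrand"]
    for chrom, pos, strand in t.motif_occurrences:
        lines.append(f"{chrom}\t{pos}\t{strand}")
    paths["truth_motifs"].write_text("\n".join(lines) + "\n")

    cfg = bundle.config
    paths["config"].write_text(yaml.safe_dump({
        "seed": cfg.seed, "n_chromosomes": cfg.n_chromosomes,
        "chromosome_length_bp": cfg.chromosome_length_bp,
        "n_genes": cfg.n_genes, "mir_ids": list(cfg.mir_ids),
        "fraction_intronic": cfg.fraction_intronic,
        "tf_names": list(cfg.tf_names),
        "promoter_bp": cfg.promoter_bp, "enhancer_bp": cfg.enhancer_bp,
        "background_rate_per_mb": cfg.background_rate_per_mb,
    }, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


@dataclass
class CtTruth:
    """Per-sample ground truth of a simulated CT table."""

    group: dict[str, str] = field(default_factory=dict)
    hemolysed: dict[str, bool] = field(default_factory=dict)
    true_delta_ct: dict[str, float] = field(default_factory=dict)


def simulate_ct_table(
    config: QpcrSimConfig | None = None, seed: int = 17
) -> tuple[CtTable, CtTruth]:
    """Simulate a CT table per the configured serum design.

    Target CTs are the per-sample mean reference CT plus a normal dCT
    draw, so with zero SDs :func:`mirreg.qpcr.relative_expression`
    recovers the configured group means exactly. A designated fraction of
    samples per group receives a hemolysis-indicator dCT above 7 so QC
    exclusions are exercised; exactly round(n x fraction) samples per
    group are hemolysed, chosen by the seeded generator.
    """
    cfg = config or QpcrSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    truth = CtTruth()
    groups: dict[str, str] = {}
    for gname in sorted(cfg.groups):
        spec = cfg.groups[gname]
        n_hem = int(round(spec.n * cfg.hemolysis_fraction))
        hem_idx = set(int(i) for i in rng.choice(spec.n, size=n_hem, replace=False))
        for i in range(spec.n):
            sid = f"{gname}_{i + 1:02d}"
            groups[sid] = gname
            ref_cts = {a: m + rng.normal(0.0, cfg.reference_ct_sd)
                       for a, m in sorted(cfg.reference_means.items())}
            delta = rng.normal(spec.delta_ct_mean, spec.delta_ct_sd)
            target_ct = float(np.mean(list(ref_cts.values()))) + delta
            hem = i in hem_idx
            ct_451 = cfg.marker_451a_mean + rng.normal(0.0, cfg.reference_ct_sd)
            d_hem = rng.uniform(8.0, 12.0) if hem else rng.uniform(2.0, 5.0)
            for assay, ct in (list(ref_cts.items())
                              + [(cfg.target, target_ct),
                                 ("miR-451a", ct_451),
                                 ("miR-23a-3p", ct_451 + d_hem)]):
                records.append(CtRecord(sample_id=sid, assay=assay, ct=float(ct)))
            truth.group[sid] = gname
            truth.hemolysed[sid] = hem
            truth.true_delta_ct[sid] = float(delta)
    table = CtTable(records=records, sample_groups=groups,
                    metadata={"seed": seed, "target": cfg.target,
                              "references": sorted(cfg.reference_means)})
    return table, truth
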