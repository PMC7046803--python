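"""Readers and writers for the pipeline's on-disk formats.

Formats handled: GFF3 annotations (via gffutils), FASTA genomes (via
Biopython), the BED peak dialects (bed6, ENCODE narrowPeak/broadPeak, and
"clustered" BED with a cell-line column), tab-separated occupancy matrices,
CT-value tables and YAML configs.

Coordinate policy: GFF3 is 1-based closed on disk and is converted to the
package-internal 0-based half-open convention here, at the single read
point. BED dialects are already 0-based half-open and pass through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import STRAND_NONE, GenomicInterval, IntervalSet, merge_intervals

log = logging.getLogger(__name__)

DEFAULT_MIRNA_FEATURES = ("miRNA", "miRNA_primary_transcript")
DEFAULT_GENE_FEATURES = ("gene", "protein_coding_gene")

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")


# ---------------------------------------------------------------------------
# Annotation domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with optional exon structure.

    Genes without exons are treated as single-exon and therefore intron-free
    for host-gene assignment purposes.
    """

    gene_id: str
    interval: GenomicInterval
    exons: IntervalSet = field(default_factory=IntervalSet)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(
                    f"exon {ex} of gene {self.gene_id} extends outside gene body "
                    f"{self.interval}"
                )

    def introns(self) -> IntervalSet:
        """Gaps between merged exons, in coordinate order; empty if < 2 exons."""
        merged = merge_intervals(self.exons)
        out: list[GenomicInterval] = []
        prev_end: int | None = None
        for ex in merged:
            if prev_end is not None and ex.start > prev_end:
                out.append(GenomicInterval(ex.chrom, prev_end, ex.start))
            prev_end = ex.end
        return IntervalSet(out)


@dataclass
class MiRNALocus:
    """A miRNA locus: precursor/locus identifier plus its mature product names."""

    mir_id: str
    interval: GenomicInterval
    mature_names: list[str] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """Genes and miRNA loci of one genome annotation."""

    genes: list[GeneModel] = field(default_factory=list)
    mirnas: list[MiRNALocus] = field(default_factory=list)
    genome_build: str = ""

    def __post_init__(self) -> None:
        gids = [g.gene_id for g in self.genes]
        if len(gids) != len(set(gids)):
            raise ValueError("duplicate gene identifiers in annotation")
        mids = [m.mir_id for m in self.mirnas]
        if len(mids) != len(set(mids)):
            raise ValueError("duplicate miRNA identifiers in annotation")

    def get_mirna(self, mir_id: str) -> MiRNALocus:
        for m in self.mirnas:
            if m.mir_id == mir_id:
                return m
        raise KeyError(f"miRNA {mir_id!r} not in annotation")


@dataclass
class PeakRecord:
    """One ChIP-seq peak (TF or histone mark), unstranded.

    ``cell_lines`` carries the contributing cell-line labels for clustered
    tracks; ``summit_offset`` is the narrowPeak point-source offset from
    ``interval.start`` (absent when the file records -1).
    """

    interval: GenomicInterval
    label: str
    cell_lines: frozenset[str] = frozenset()
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"peak {self.interval} has an empty label")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak {self.interval}"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    mirna_feature_types: Sequence[str] = DEFAULT_MIRNA_FEATURES,
    gene_feature_types: Sequence[str] = DEFAULT_GENE_FEATURES,
) -> AnnotationSet:
    """Parse a GFF3 annotation into an :class:`AnnotationSet`.

    1-based closed GFF coordinates become 0-based half-open. Exons are
    attached to their gene through the ``Parent`` attribute; exons whose
    parent is unknown are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    genome_build = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("##genome-build"):
                genome_build = line.split(None, 1)[1].strip() if " " in line else ""
            if not line.startswith("#"):
                break

    genes: dict[str, GeneModel] = {}
    mirnas: list[MiRNALocus] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        try:
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or STRAND_NONE)
        except ValueError as exc:
            raise ValueError(f"{path}: bad coordinates for feature {feat.id!r}: {exc}") from exc
        if feat.featuretype in gene_feature_types:
            gid = feat.attributes.get("ID", [feat.id])[0]
            biotype = (
                feat.attributes.get("biotype", [])
                or feat.attributes.get("gene_biotype", ["protein_coding"])
            )[0]
            genes[gid] = GeneModel(gene_id=gid, interval=iv, biotype=biotype)
        elif feat.featuretype in mirna_feature_types:
            mid = feat.attributes.get("ID", [feat.id])[0]
            # gffutils splits multi-valued attributes on commas already
            mature_names = [n for v in feat.attributes.get("mature", [])
                            for n in v.split(",")]
            mirnas.append(MiRNALocus(mir_id=mid, interval=iv, mature_names=mature_names))

    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent", [])
        if not parents or parents[0] not in genes:
            log.warning("exon at %s:%d-%d has unknown Parent %s; skipped",
                        feat.seqid, feat.start, feat.end, parents)
            continue
        gene = genes[parents[0]]
        ex = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or STRAND_NONE)
        if not gene.interval.contains(ex):
            raise ValueError(
                f"{path}: exon {ex} outside parent gene {gene.gene_id} {gene.interval}"
            )
        gene.exons.intervals.append(ex)

    return AnnotationSet(genes=list(genes.values()), mirnas=mirnas, genome_build=genome_build)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Emit an AnnotationSet as GFF3 (inverse of :func:`read_gff3`)."""
    lines = ["##gff-version 3"]
    if annotation.genome_build:
        lines.append(f"##genome-build {annotation.genome_build}")
    for gene in annotation.genes:
        iv = gene.interval
        attrs = f"ID={gene.gene_id};biotype={gene.biotype}"
        lines.append(
            f"{iv.chrom}\tmirreg\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
        )
        for i, ex in enumerate(gene.exons, start=1):
            lines.append(
                f"{ex.chrom}\tmirreg\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t"
                f"ID={gene.gene_id}.exon{i};Parent={gene.gene_id}"
            )
    for mir in annotation.mirnas:
        iv = mir.interval
        attrs = f"ID={mir.mir_id}"
        if mir.mature_names:
            attrs += f";mature={','.join(mir.mature_names)}"
        lines.append(
            f"{iv.chrom}\tmirreg\tmiRNA_primary_transcript\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Peak BED dialects
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"bed6": 6, "narrowPeak": 10, "broadPeak": 9, "clustered": 6}


def read_peaks(
    path: str | Path,
    dialect: str,
    label: str | None = None,
) -> list[PeakRecord]:
    """Read one peak file in the given BED dialect.

    ``label`` overrides the name column (useful for per-TF files whose name
    column carries something else). Records identical in
    (chrom, start, end, label) are deduplicated with a logged count, since
    browser exports can repeat records.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}; expected one of {sorted(_DIALECT_COLS)}")
    want = _DIALECT_COLS[dialect]
    out: list[PeakRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != want:
                raise ValueError(
                    f"{path}:{lineno}: expected {want} columns for dialect "
                    f"{dialect!r}, found {len(cols)}"
                )
            chrom, start_s, end_s, name = cols[0], cols[1], cols[2], cols[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                score = float(cols[4]) if cols[4] not in (".", "") else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {cols[4]!r}") from exc
            cell_lines: frozenset[str] = frozenset()
            summit: int | None = None
            if dialect == "clustered":
                cells = cols[5]
                if cells and cells != ".":
                    cell_lines = frozenset(cells.split(","))
            elif dialect == "narrowPeak":
                summit_raw = int(cols[9])
                summit = None if summit_raw == -1 else summit_raw
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            lab = label if label is not None else name
            key = (chrom, start, end, lab)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            out.append(
                PeakRecord(interval=iv, label=lab, cell_lines=cell_lines,
                           score=score, summit_offset=summit)
            )
    if n_dup:
        log.info("%s: deduplicated %d repeated peak record(s)", path, n_dup)
    return out


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path, dialect: str = "clustered") -> None:
    """Write peaks in the given dialect (inverse of :func:`read_peaks`)."""
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    lines = []
    for p in peaks:
        iv = p.interval
        base = [iv.chrom, str(iv.start), str(iv.end), p.label, _fmt_num(p.score)]
        if dialect == "bed6":
            cols = base + ["."]
        elif dialect == "clustered":
            cells = ",".join(sorted(p.cell_lines)) if p.cell_lines else "."
            cols = base + [cells]
        elif dialect == "broadPeak":
            cols = base + [".", "0", "-1", "-1"]
        else:  # narrowPeak
            summit = -1 if p.summit_offset is None else p.summit_offset
            cols = base + [".", "0", "-1", "-1", str(summit)]
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercased sequence}.

    Names are taken up to the first whitespace. Duplicate names are an
    error; characters outside the IUPAC nucleotide alphabet are replaced
    with N (warned once per sequence).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            log.warning("%s: sequence %s contains non-IUPAC characters %s; replaced with N",
                        path, rec.id, sorted(bad))
            seq = "".join(c if c in _IUPAC_NT else "N" for c in seq)
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Occupancy TSV
# ---------------------------------------------------------------------------


def write_occupancy_tsv(table, path: str | Path) -> None:
    """Serialize an OccupancyTable's per-region entries as TSV.

    Header is ``mir_id, region_type`` followed by TF names; one row per
    (miRNA, region type); rows and columns in lexicographic order so output
    is byte-deterministic.
    """
    tfs = sorted({tf for (_, tf, _) in table.entries})
    keys = sorted({(m, r) for (m, _, r) in table.entries})
    lines = ["\t".join(["mir_id", "region_type"] + tfs)]
    for mir, rt in keys:
        row = [mir, rt] + [str(table.entries.get((mir, tf, rt), 0)) for tf in tfs]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_occupancy_tsv(path: str | Path):
    """Read back a TSV written by :func:`write_occupancy_tsv`."""
    from .occupancy import OccupancyTable

    df = pd.read_csv(path, sep="\t", dtype={"mir_id": str, "region_type": str})
    entries: dict[tuple[str, str, str], int] = {}
    tf_cols = [c for c in df.columns if c not in ("mir_id", "region_type")]
    for _, row in df.iterrows():
        for tf in tf_cols:
            entries[(row["mir_id"], tf, row["region_type"])] = int(row[tf])
    return OccupancyTable(entries=entries)


def write_dedup_totals_tsv(table, path: str | Path) -> None:
    """Serialize per-(miRNA, TF) deduplicated binding-site totals as TSV."""
    tfs = sorted({tf for (_, tf) in table.dedup_totals})
    mirs = sorted({m for (m, _) in table.dedup_totals})
    lines = ["\t".join(["mir_id"] + tfs)]
    for mir in mirs:
        lines.append("\t".join([mir] + [str(table.dedup_totals.get((mir, tf), 0)) for tf in tfs]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CT tables and config
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path):
    """Read a CT-value TSV (columns: sample_id, assay, ct[, replicate][, group])."""
    from .qpcr import CtRecord, CtTable

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CT table missing column(s) {sorted(missing)}")
    records = []
    groups: dict[str, str] = {}
    for _, row in df.iterrows():
        rep = int(row["replicate"]) if "replicate" in df.columns and pd.notna(row.get("replicate")) else None
        records.append(CtRecord(sample_id=str(row["sample_id"]), assay=str(row["assay"]),
                                ct=float(row["ct"]), replicate=rep))
        if "group" in df.columns and pd.notna(row.get("group")):
            groups[str(row["sample_id"])] = str(row["group"])
    return CtTable(records=records, sample_groups=groups)


def write_ct_table(table, path: str | Path) -> None:
    rows = []
    for r in table.records:
        rows.append({
            "sample_id": r.sample_id, "assay": r.assay, "ct": r.ct,
            "replicate": r.replicate if r.replicate is not None else "",
            "group": table.sample_groups.get(r.sample_id, ""),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML key/value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
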