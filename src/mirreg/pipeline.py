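"""End-to-end orchestration: regions -> occupancy -> chromatin state ->
motifs -> summaries, plus the qPCR quantification pipeline.

All analysis stages are deterministic (randomness lives only in
:mod:`mirreg.synthetic`), and the run log carries no timestamps, so
outputs are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .io_formats import (
    load_config, read_ct_table, read_fasta, read_gff3, read_peaks,
    write_dedup_totals_tsv, write_occupancy_tsv,
)
from .motifs import read_counts_matrix, scan_peaks
from .occupancy import classify_all_regions, filter_marked_regions, tabulate_occupancy
from .qpcr import compare_groups, expression_table, qc_table
from .regions import build_all_region_sets
from .summaries import FamilyMap, SubtypeMap, subtype_comparison, top_occupancy

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated inputs and parameters of one pipeline run."""

    outdir: str
    annotation_path: str | None = None
    fasta_path: str | None = None
    peak_files: list[dict] = field(default_factory=list)   # {path, dialect[, label]}
    histone_files: list[dict] = field(default_factory=list)
    motif_files: list[str] = field(default_factory=list)
    family_map: dict | None = None     # None -> package defaults
    subtype_map: dict | None = None    # None -> skip the subtype summary
    ct_path: str | None = None
    ct_target: str = "miR-21-5p"
    ct_references: list[str] = field(default_factory=list)
    promoter_bp: int = 2000
    enhancer_bp: int = 10000
    merge_cell_lines: bool = True
    require_marked: bool = False
    min_score_frac: float = 0.8
    hemolysis_threshold: float = 7.0
    log_base: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**load_config(path))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in ([self.annotation_path, self.fasta_path, self.ct_path]
                  + [f["path"] for f in self.peak_files + self.histone_files]
                  + list(self.motif_files)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not (0 < self.min_score_frac <= 1):
            raise ValueError("min_score_frac must be in (0, 1]")
        if self.promoter_bp <= 0 or self.enhancer_bp < 0:
            raise ValueError("window sizes out of range")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _write_log(outdir: Path, config: PipelineConfig, stage_counts: dict) -> Path:
    path = outdir / "run_log.json"
    path.write_text(json.dumps({
        "mirreg_version": __version__,
        "config_sha256": config.digest(),
        "parameters": asdict(config),
        "stage_record_counts": stage_counts,
    }, sort_keys=True, indent=2) + "\n")
    return path


def run_occupancy_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run regions -> occupancy -> chromatin state -> motifs -> summaries.

    The chromatin-state table is only written when histone files are
    configured, and the motif stage only when motif files (and a genome
    FASTA) are; occupancy is unaffected either way.
    """
    config.validate()
    if config.annotation_path is None:
        raise ValueError("occupancy pipeline requires annotation_path")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, Path] = {}

    annotation = read_gff3(config.annotation_path)
    counts["mirnas"] = len(annotation.mirnas)
    counts["genes"] = len(annotation.genes)

    sequences = read_fasta(config.fasta_path) if config.fasta_path else {}
    chrom_lengths = {c: len(s) for c, s in sequences.items()} or None

    region_sets = build_all_region_sets(
        annotation, config.promoter_bp, config.enhancer_bp, chrom_lengths)
    counts["regions"] = sum(len(rs.regions) for rs in region_sets)

    peaks = []
    for spec in config.peak_files:
        peaks.extend(read_peaks(spec["path"], spec["dialect"], spec.get("label")))
    counts["tf_peaks"] = len(peaks)

    histones = []
    for spec in config.histone_files:
        histones.extend(read_peaks(spec["path"], spec["dialect"], spec.get("label")))
    counts["histone_peaks"] = len(histones)

    if histones:
        states = classify_all_regions(region_sets, histones)
        lines = ["mir_id\tregion_type\tchrom\tstart\tend\tH3K4me3\tH3K4me1\tH3K27ac\tcall"]
        for st in sorted(states, key=lambda s: (s.region.mir_id, s.region.region_type)):
            r = st.region
            lines.append("\t".join([
                r.mir_id, r.region_type, r.interval.chrom,
                str(r.interval.start), str(r.interval.end),
                str(int(st.has_H3K4me3)), str(int(st.has_H3K4me1)),
                str(int(st.has_H3K27ac)), st.call]))
        outputs["chromatin_state"] = out / "chromatin_state.tsv"
        outputs["chromatin_state"].write_text("\n".join(lines) + "\n")
        counts["chromatin_states"] = len(states)
        if config.require_marked:
            region_sets = filter_marked_regions(region_sets, histones)
    elif config.require_marked:
        raise ValueError("require_marked set but no histone files configured")

    table = tabulate_occupancy(region_sets, peaks, config.merge_cell_lines)
    table.metadata.update({"promoter_bp": config.promoter_bp,
                           "enhancer_bp": config.enhancer_bp})
    outputs["occupancy"] = out / "occupancy.tsv"
    write_occupancy_tsv(table, outputs["occupancy"])
    outputs["dedup_totals"] = out / "dedup_totals.tsv"
    write_dedup_totals_tsv(table, outputs["dedup_totals"])
    counts["occupancy_entries"] = len(table.entries)

    if config.motif_files:
        if not sequences:
            raise ValueError("motif stage requires fasta_path")
        bed_lines = []
        n_hits = 0
        for mpath in config.motif_files:
            motif = read_counts_matrix(mpath)
            tf_peaks = [p for p in peaks if p.label == motif.name]
            hits = scan_peaks(sequences, tf_peaks, motif, config.min_score_frac)
            n_hits += len(hits)
            for h in hits:
                score = min(1000, max(0, int(round(h.score * 100))))
                bed_lines.append("\t".join([
                    h.seq_id, str(h.offset), str(h.offset + motif.length),
                    motif.name, str(score), h.strand]))
        outputs["motif_hits"] = out / "motif_hits.bed"
        outputs["motif_hits"].write_text(
            "\n".join(bed_lines) + ("\n" if bed_lines else ""))
        counts["motif_hits"] = n_hits
    else:
        log.info("no motif files configured; motif stage skipped")

    fam = (FamilyMap.from_config(config.family_map)
           if config.family_map else FamilyMap.default())
    ranked = top_occupancy(table, n=max(1, len(table.tf_names())))
    report = None
    if config.subtype_map is not None:
        subs = SubtypeMap.from_config(config.subtype_map)
        for count_field in ("per_region_sum", "dedup_total"):
            report = subtype_comparison(table, subs, fam, count_field)
            sub_names = sorted(subs.subtypes) + ["unassigned"]
            lines = ["\t".join(["family"] + sub_names)]
            for family in sorted({f for (f, _) in report.per_family_per_subtype}):
                lines.append("\t".join(
                    [family] + [str(report.per_family_per_subtype.get((family, s), 0))
                                for s in sub_names]))
            key = f"family_subtype_{count_field}"
            outputs[key] = out / f"{key}.tsv"
            outputs[key].write_text("\n".join(lines) + "\n")

    lines = ["tf\tper_region_sum\tdedup_total"]
    for tf, _ in ranked:
        lines.append(f"{tf}\t{table.total(tf, 'per_region_sum')}\t{table.total(tf, 'dedup_total')}")
    outputs["per_tf_totals"] = out / "per_tf_totals.tsv"
    outputs["per_tf_totals"].write_text("\n".join(lines) + "\n")

    outputs["run_log"] = _write_log(out, config, counts)
    return outputs


def run_quant_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run hemolysis QC -> relative expression -> group comparison."""
    config.validate()
    if config.ct_path is None:
        raise ValueError("quant pipeline requires ct_path")
    if not config.ct_references:
        raise ValueError("quant pipeline requires at least one reference assay")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    table = read_ct_table(config.ct_path)
    counts["ct_records"] = len(table.records)
    qc = qc_table(table, threshold=config.hemolysis_threshold)
    lines = ["sample_id\tdelta_ct_hemolysis\tpassed\treason"]
    for r in qc:
        d = "" if r.delta_ct_hemolysis is None else f"{r.delta_ct_hemolysis:.4f}"
        lines.append(f"{r.sample_id}\t{d}\t{int(r.passed)}\t{r.reason}")
    outputs["qc"] = out / "qc.tsv"
    outputs["qc"].write_text("\n".join(lines) + "\n")
    counts["qc_excluded"] = sum(1 for r in qc if not r.passed)
    if all(not r.passed for r in qc):
        raise ValueError("no samples pass QC")

    expr = expression_table(table, config.ct_target, config.ct_references,
                            qc=qc, log_base=config.log_base)
    lines = ["sample_id\tassay\tgroup\tvalue\tlog_value"]
    for e in expr:
        lines.append(f"{e.sample_id}\t{e.assay}\t"
                     f"{table.sample_groups.get(e.sample_id, '')}\t"
                     f"{e.value:.6g}\t{e.log_value:.6g}")
    outputs["expression"] = out / "expression.tsv"
    outputs["expression"].write_text("\n".join(lines) + "\n")
    counts["quantified_samples"] = len(expr)

    by_group: dict[str, list[float]] = {}
    for e in expr:
        g = table.sample_groups.get(e.sample_id)
        if g:
            by_group.setdefault(g, []).append(e.log_value)
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        design = "two_group" if len(by_group) == 2 else "multi_group"
        cmp = compare_groups(by_group, design=design)
        lines = ["metric\tvalue"]
        stat_name = "t" if design == "two_group" else "F"
        lines.append(f"{stat_name}_statistic\t{cmp.statistic:.6g}")
        lines.append(f"p_value\t{cmp.p_value:.6g}")
        for g in sorted(cmp.descriptives):
            d = cmp.descriptives[g]
            lines.append(f"{g}:n\t{d.n}")
            lines.append(f"{g}:mean\t{d.mean:.6g}")
            lines.append(f"{g}:sd\t{d.sd:.6g}")
            lines.append(f"{g}:min\t{d.minimum:.6g}")
            lines.append(f"{g}:max\t{d.maximum:.6g}")
        for (a, b), (t, p) in sorted(cmp.pairwise.items()):
            lines.append(f"{a}-vs-{b}:t\t{t:.6g}")
            lines.append(f"{a}-vs-{b}:p\t{p:.6g}")
        outputs["group_comparison"] = out / "group_comparison.tsv"
        outputs["group_comparison"].write_text("\n".join(lines) + "\n")
    else:
        log.info("fewer than 2 usable groups; group comparison skipped")

    outputs["run_log"] = _write_log(out, config, counts)
    return outputs
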