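"""TF binding-site counting per regulatory window and chromatin-state calls.

Occupancy is the count of distinct binding sites overlapping a window by at
least 1 bp. By default same-TF evidence is merged across cell lines first,
so one genomic site supported by several of the nine ENCODE cell lines
counts once - the clustered-track convention. Because the promoter window
is contained in the enhancer window, a single peak can legitimately appear
in several per-region counts; the deduplicated per-miRNA totals
(``dedup_totals``) count each merged site once against the union of that
miRNA's windows.

Chromatin state annotates each window from the three histone marks:
H3K4me3 marks active promoters, H3K4me1 poised/active regulatory elements,
and H3K27ac active regulatory elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, IntervalSet, OverlapIndex, merge_intervals
from .io_formats import PeakRecord
from .regions import RegulatoryRegion, RegulatoryRegionSet

log = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac")

ACTIVE_PROMOTER = "active_promoter"
ACTIVE_ENHANCER = "active_enhancer"
POISED_ENHANCER = "poised_enhancer"
UNMARKED = "unmarked"


@dataclass
class OccupancyTable:
    """Binding-site counts indexed by (miRNA, TF, region type).

    ``entries`` holds the per-window counts; ``dedup_totals`` the distinct
    merged sites per (miRNA, TF) over the union of that miRNA's windows;
    ``metadata`` records the window sizes and merge policy used.
    """

    entries: dict[tuple[str, str, str], int] = field(default_factory=dict)
    dedup_totals: dict[tuple[str, str], int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def tf_names(self) -> list[str]:
        return sorted({tf for (_, tf, _) in self.entries})

    def mir_ids(self) -> list[str]:
        return sorted({m for (m, _, _) in self.entries})

    def per_region_sum(self, mir_id: str, tf: str) -> int:
        """Sum of counts over all region types - the headline count field."""
        return sum(v for (m, t, _), v in self.entries.items() if m == mir_id and t == tf)

    def total(self, tf: str, count_field: str = "per_region_sum") -> int:
        if count_field == "per_region_sum":
            return sum(v for (_, t, _), v in self.entries.items() if t == tf)
        if count_field == "dedup_total":
            return sum(v for (_, t), v in self.dedup_totals.items() if t == tf)
        raise ValueError(f"unknown count field {count_field!r}")


@dataclass(frozen=True)
class ChromatinState:
    """Histone-mark overlap flags and the resulting regulatory call."""

    region: RegulatoryRegion
    has_H3K4me3: bool
    has_H3K4me1: bool
    has_H3K27ac: bool
    call: str


def merge_peaks_by_label(
    peaks: Iterable[PeakRecord], merge: bool = True
) -> dict[str, IntervalSet]:
    """Group peaks by TF/mark label; optionally merge intervals per label.

    Merging coalesces same-label evidence across cell lines into distinct
    genomic sites. Without merging each input record counts separately.
    """
    by_label: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_label.setdefault(p.label, []).append(p.interval)
    if merge:
        return {lab: merge_intervals(ivs) for lab, ivs in by_label.items()}
    return {lab: IntervalSet(sorted(ivs, key=lambda i: (i.chrom, i.start, i.end)))
            for lab, ivs in by_label.items()}


def tabulate_occupancy(
    region_sets: Sequence[RegulatoryRegionSet],
    peaks: Iterable[PeakRecord],
    merge_cell_lines: bool = True,
) -> OccupancyTable:
    """Count TF binding sites in every regulatory window.

    For each TF label, ``entries[(mir, tf, region_type)]`` is the number of
    (merged) peaks overlapping that window, and ``dedup_totals[(mir, tf)]``
    the number of distinct merged sites overlapping the union of the
    miRNA's windows.
    """
    peaks = list(peaks)
    if not peaks:
        log.warning("tabulate_occupancy called with no peaks; all counts are zero")
    by_tf = merge_peaks_by_label(peaks, merge=merge_cell_lines)
    indexes = {tf: OverlapIndex(ivs) for tf, ivs in by_tf.items()}
    entries: dict[tuple[str, str, str], int] = {}
    dedup: dict[tuple[str, str], int] = {}
    for rs in region_sets:
        union = rs.union()
        for tf in sorted(by_tf):
            idx = indexes[tf]
            for region in rs.regions:
                entries[(rs.mir_id, tf, region.region_type)] = idx.count(region.interval)
            hit_ids: set[int] = set()
            for u in union:
                hit_ids |= idx.query_indices(u)
            dedup[(rs.mir_id, tf)] = len(hit_ids)
    return OccupancyTable(
        entries=entries,
        dedup_totals=dedup,
        metadata={"merge_cell_lines": merge_cell_lines,
                  "n_peaks": len(peaks), "tf_names": sorted(by_tf)},
    )


def classify_region(
    region: RegulatoryRegion,
    histone_peaks: Mapping[str, Iterable[PeakRecord]] | Iterable[PeakRecord],
) -> ChromatinState:
    """Call the chromatin state of one window from histone-mark peaks.

    Precedence: any overlapping H3K4me3 -> active_promoter; else
    H3K4me1 with H3K27ac -> active_enhancer; else H3K4me1 alone ->
    poised_enhancer; else unmarked. Mark labels outside the three known
    marks are an error.
    """
    if isinstance(histone_peaks, Mapping):
        grouped = {m: list(ps) for m, ps in histone_peaks.items()}
    else:
        grouped = {}
        for p in histone_peaks:
            grouped.setdefault(p.label, []).append(p)
    unknown = set(grouped) - set(HISTONE_MARKS)
    if unknown:
        raise ValueError(
            f"unknown histone mark label(s) {sorted(unknown)}; expected {HISTONE_MARKS}"
        )
    flags = {}
    for mark in HISTONE_MARKS:
        flags[mark] = any(region.interval.overlaps(p.interval) for p in grouped.get(mark, []))
    if flags["H3K4me3"]:
        call = ACTIVE_PROMOTER
    elif flags["H3K4me1"] and flags["H3K27ac"]:
        call = ACTIVE_ENHANCER
    elif flags["H3K4me1"]:
        call = POISED_ENHANCER
    else:
        call = UNMARKED
    return ChromatinState(
        region=region,
        has_H3K4me3=flags["H3K4me3"],
        has_H3K4me1=flags["H3K4me1"],
        has_H3K27ac=flags["H3K27ac"],
        call=call,
    )


def classify_all_regions(
    region_sets: Sequence[RegulatoryRegionSet],
    histone_peaks: Iterable[PeakRecord],
) -> list[ChromatinState]:
    """Chromatin-state calls for every window of every region set."""
    grouped: dict[str, list[PeakRecord]] = {}
    for p in histone_peaks:
        grouped.setdefault(p.label, []).append(p)
    return [classify_region(r, grouped) for rs in region_sets for r in rs.regions]


def filter_marked_regions(
    region_sets: Sequence[RegulatoryRegionSet],
    histone_peaks: Iterable[PeakRecord],
) -> list[RegulatoryRegionSet]:
    """Restrict region sets to windows whose chromatin call is not unmarked.

    Optional confidence filter; by default chromatin state only annotates
    and never excludes windows from counting.
    """
    hp = list(histone_peaks)
    out = []
    for rs in region_sets:
        kept = [r for r in rs.regions
                if classify_region(r, [p for p in hp]).call != UNMARKED]
        out.append(RegulatoryRegionSet(mir_id=rs.mir_id, regions=kept,
                                       host_gene_id=rs.host_gene_id))
    return out
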