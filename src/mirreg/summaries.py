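"""Headline aggregation of occupancy tables.

Three summaries mirror the study's reporting: per-TF totals with a ranked
occupancy list, TF-family totals, and the family x disease-subtype matrix
comparing AChR+ against MuSK+ miRNA sets.

Note on the default family map: the study's "FOXO" grouping in fact pools
FOXA/FOXM/FOXP factors. The defaults reproduce that grouping for fidelity
to the source; both maps are plain data and fully overridable from config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .occupancy import OccupancyTable

log = logging.getLogger(__name__)

DEFAULT_FAMILIES: dict[str, set[str]] = {
    "FOXO_group": {"FoxA1", "FoxA2", "FoxM1", "FoxP2"},
    "AP1": {"FOS", "Jun", "JunB", "JunD"},
    "IRF": {"IRF1", "IRF3", "IRF4"},
    "STAT": {"Stat1", "Stat3", "Stat5a"},
    "NFKB": {"RELA"},
    "ESR": {"ESR1"},
    "NFAT": {"NFATC1"},
    "EGR": {"EGR1"},
}

DEFAULT_SUBTYPES: dict[str, set[str]] = {
    "AChR+": {"miR-150-5p", "miR-21-5p", "miR-30e-5p"},
    "MuSK+": {"miR-151a-3p", "miR-423-5p", "let-7a-5p", "let-7f-5p"},
}

UNASSIGNED = "unassigned"

COUNT_FIELDS = ("per_region_sum", "dedup_total")


@dataclass
class FamilyMap:
    """Partition of TF names into named families (each TF in at most one)."""

    families: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, tfs in self.families.items():
            for tf in tfs:
                if tf in seen:
                    raise ValueError(
                        f"TF {tf!r} assigned to both families {seen[tf]!r} and {fam!r}"
                    )
                seen[tf] = fam

    @classmethod
    def default(cls) -> "FamilyMap":
        return cls({f: set(tfs) for f, tfs in DEFAULT_FAMILIES.items()})

    @classmethod
    def from_config(cls, mapping: Mapping[str, list[str] | set[str]]) -> "FamilyMap":
        return cls({f: set(tfs) for f, tfs in mapping.items()})

    def family_of(self, tf: str) -> str:
        for fam, tfs in self.families.items():
            if tf in tfs:
                return fam
        return UNASSIGNED


@dataclass
class SubtypeMap:
    """Disjoint disease-subtype miRNA sets (AChR+ vs MuSK+ by default)."""

    subtypes: dict[str, set[str]]

    def __post_init__(self) -> None:
        names = list(self.subtypes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shared = self.subtypes[a] & self.subtypes[b]
                if shared:
                    raise ValueError(
                        f"subtypes {a!r} and {b!r} share miRNA(s) {sorted(shared)}"
                    )

    @classmethod
    def default(cls) -> "SubtypeMap":
        return cls({s: set(ms) for s, ms in DEFAULT_SUBTYPES.items()})

    @classmethod
    def from_config(cls, mapping: Mapping[str, list[str] | set[str]]) -> "SubtypeMap":
        return cls({s: set(ms) for s, ms in mapping.items()})

    def subtype_of(self, mir_id: str) -> str:
        for sub, mirs in self.subtypes.items():
            if mir_id in mirs:
                return sub
        return UNASSIGNED


@dataclass
class SummaryReport:
    """Aggregated occupancy: totals, family and family-x-subtype counts."""

    per_tf_totals: dict[str, int] = field(default_factory=dict)
    per_family_totals: dict[str, int] = field(default_factory=dict)
    per_family_per_subtype: dict[tuple[str, str], int] = field(default_factory=dict)
    rankings: list[tuple[str, int]] = field(default_factory=list)
    count_field: str = "per_region_sum"


def _tf_mir_counts(table: OccupancyTable, count_field: str) -> dict[tuple[str, str], int]:
    if count_field == "per_region_sum":
        out: dict[tuple[str, str], int] = {}
        for (m, t, _), v in table.entries.items():
            out[(m, t)] = out.get((m, t), 0) + v
        return out
    if count_field == "dedup_total":
        return dict(table.dedup_totals)
    raise ValueError(f"unknown count field {count_field!r}; expected one of {COUNT_FIELDS}")


def aggregate_by_family(
    table: OccupancyTable,
    fam: FamilyMap,
    count_field: str = "per_region_sum",
) -> SummaryReport:
    """Per-TF and per-family totals over all miRNAs in the table.

    Family members absent from the table contribute zero (logged);
    table TFs outside every family are pooled under "unassigned" so the
    family totals conserve the grand total.
    """
    counts = _tf_mir_counts(table, count_field)
    tf_totals: dict[str, int] = {}
    for (m, t), v in counts.items():
        tf_totals[t] = tf_totals.get(t, 0) + v
    for family, tfs in fam.families.items():
        for tf in tfs - set(tf_totals):
            log.info("family %s member %s absent from table; contributes 0", family, tf)
    fam_totals: dict[str, int] = {f: 0 for f in fam.families}
    for tf, v in tf_totals.items():
        fam_totals.setdefault(fam.family_of(tf), 0)
        fam_totals[fam.family_of(tf)] += v
    rankings = sorted(tf_totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return SummaryReport(per_tf_totals=dict(sorted(tf_totals.items())),
                         per_family_totals=fam_totals,
                         rankings=rankings, count_field=count_field)


def subtype_comparison(
    table: OccupancyTable,
    subtypes: SubtypeMap,
    fam: FamilyMap,
    count_field: str = "per_region_sum",
) -> SummaryReport:
    """Family x subtype count matrix plus overall totals and rankings.

    Every miRNA named in the subtype map must be present in the table;
    table miRNAs outside every subtype are pooled under "unassigned".
    """
    table_mirs = set(table.mir_ids()) | {m for (m, _) in table.dedup_totals}
    missing = sorted(m for ms in subtypes.subtypes.values() for m in ms if m not in table_mirs)
    if missing:
        raise ValueError(f"subtype miRNA(s) absent from occupancy table: {missing}")
    report = aggregate_by_family(table, fam, count_field)
    counts = _tf_mir_counts(table, count_field)
    cell: dict[tuple[str, str], int] = {}
    for (m, t), v in counts.items():
        key = (fam.family_of(t), subtypes.subtype_of(m))
        cell[key] = cell.get(key, 0) + v
    for family in list(fam.families) + [UNASSIGNED]:
        for sub in list(subtypes.subtypes) + [UNASSIGNED]:
            cell.setdefault((family, sub), 0)
    report.per_family_per_subtype = dict(sorted(cell.items()))
    return report


def top_occupancy(
    table: OccupancyTable, n: int, count_field: str = "dedup_total"
) -> list[tuple[str, int]]:
    """Top-n TFs by total occupancy (deduplicated sites by default).

    Ties break lexicographically on TF name. Requesting more TFs than exist
    returns them all (logged).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    counts = _tf_mir_counts(table, count_field)
    totals: dict[str, int] = {}
    for (_, t), v in counts.items():
        totals[t] = totals.get(t, 0) + v
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if n > len(ranked):
        log.info("top_occupancy: n=%d exceeds number of TFs (%d); returning all", n, len(ranked))
    return ranked[:n]
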