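"""Genomic interval arithmetic: the coordinate currency of the pipeline.

All coordinates are 0-based half-open (BED-native). GFF3's 1-based closed
coordinates are converted once, at read time, in :mod:`mirreg.io_formats`.
Overlap queries ignore strand: ChIP-seq peaks are unstranded evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

STRAND_FWD = "+"
STRAND_REV = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_FWD, STRAND_REV, STRAND_NONE})


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``length = end - start``
    is therefore always positive for a valid interval.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"interval with empty chromosome name: {self!r}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(
                f"invalid strand {self.strand!r} for {self.chrom}:{self.start}-{self.end}"
                f" (expected one of {sorted(_VALID_STRANDS)})"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics).

        Strand is ignored. Abutting intervals ([100,200) vs [200,300)) do
        not overlap.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff ``other`` lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:[{self.start},{self.end})/{self.strand}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Functional alias for :meth:`GenomicInterval.overlaps`."""
    return a.overlaps(b)


@dataclass
class IntervalSet:
    """An ordered collection of intervals, optionally in merged form.

    When ``merged`` is True the intervals are sorted by (chrom, start) and
    pairwise disjoint, with abutting runs coalesced (union-of-covered-bases
    semantics, matching how clustered ChIP-seq evidence tracks merge
    contiguous sites).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    merged: bool = False

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_iterable(cls, xs: Iterable[GenomicInterval]) -> "IntervalSet":
        return cls(list(xs))

    def merge(self) -> "IntervalSet":
        return merge_intervals(self)


def merge_intervals(xs: IntervalSet | Iterable[GenomicInterval]) -> IntervalSet:
    """Coalesce overlapping or abutting intervals per chromosome.

    The union of covered bases is preserved exactly; strand information is
    dropped (merged evidence is unstranded). Idempotent; an empty input
    yields an empty merged set.
    """
    items = list(xs.intervals if isinstance(xs, IntervalSet) else xs)
    if not items:
        return IntervalSet([], merged=True)
    items.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = items[0].chrom, items[0].start, items[0].end
    for iv in items[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:  # overlap or abut
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(out, merged=True)


class OverlapIndex:
    """Interval-tree index over a fixed peak set for repeated region queries.

    Build once per peak set; :meth:`count` and :meth:`query` then run in
    O(log n + k). Equivalent by construction to the brute-force pairwise
    scan (tested against it on random instances).
    """

    def __init__(self, peaks: IntervalSet | Iterable[GenomicInterval]) -> None:
        items = list(peaks.intervals if isinstance(peaks, IntervalSet) else peaks)
        self._trees: dict[str, IntervalTree] = {}
        for i, iv in enumerate(items):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
        self._items = items

    def query(self, region: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(region.start, region.end), key=lambda h: h.data)
        return [self._items[h.data] for h in hits]

    def query_indices(self, region: GenomicInterval) -> set[int]:
        """Positions (in construction order) of peaks overlapping region."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(region.start, region.end)}

    def count(self, region: GenomicInterval) -> int:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(region.start, region.end))


def count_overlapping(
    region: GenomicInterval, peaks: IntervalSet | Iterable[GenomicInterval]
) -> int:
    """Number of peaks overlapping ``region`` by >= 1 bp.

    Accepts merged or raw peak sets; the caller decides whether evidence was
    merged first (see :func:`mirreg.occupancy.tabulate_occupancy`).
    """
    return OverlapIndex(peaks).count(region)


def count_overlapping_naive(
    region: GenomicInterval, peaks: IntervalSet | Iterable[GenomicInterval]
) -> int:
    """Brute-force O(n) pairwise scan; the oracle for :func:`count_overlapping`."""
    items = peaks.intervals if isinstance(peaks, IntervalSet) else peaks
    return sum(1 for p in items if region.overlaps(p))
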