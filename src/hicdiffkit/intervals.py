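"""Genomic interval primitives shared across the toolkit.

Coordinates are BED-style 0-based half-open throughout; a genomic position
maps to bin index ``start // resolution``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on a single chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def bin_index(self, resolution: int) -> int:
        """Bin holding the interval midpoint."""
        return self.midpoint // resolution

    def bin_range(self, resolution: int) -> range:
        """All bins overlapped by the interval."""
        return range(self.start // resolution, -(-self.end // resolution))

    def overlaps(self, other: "GenomicInterval", slack: int = 0) -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end + slack
            and other.start < self.end + slack
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sort and coalesce overlapping/adjacent runs."""
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom])
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def covered_bases(target: GenomicInterval, intervals: Sequence[GenomicInterval]) -> int:
    """Bases of ``target`` covered by the union of ``intervals``."""
    total = 0
    for iv in merge_intervals(intervals):
        if iv.chrom != target.chrom:
            continue
        total += max(0, min(iv.end, target.end) - max(iv.start, target.start))
    return total


def segment_nonoverlapping_tads(
    tads: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Segment a chromosome by the edges of (possibly nested) TADs.

    Every TAD start and end is treated as a boundary; consecutive boundary
    pairs become disjoint segments tiling [min edge, max edge). Nested and
    overlapping domains therefore contribute their internal edges instead
    of being double counted.
    """
    tads = list(tads)
    if not tads:
        return []
    chroms = {t.chrom for t in tads}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    edges = np.unique([c for t in tads for c in (t.start, t.end)])
    return [
        GenomicInterval(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])
    ]
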