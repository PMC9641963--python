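"""Genomic interval primitives shared across the package.

All intervals are 0-based, half-open ``(scaffold, start, end)``.
"""
from __future__ import annotations

from typing import Iterable, NamedTuple


class GenomicInterval(NamedTuple):
    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge overlapping or touching (start, end) pairs into a disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Non-redundant base count of a set of intervals (union length)."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold, []).append((iv.start, iv.end))
    return sum(
        e - s for ivs in by_scaffold.values() for s, e in merge_intervals(ivs)
    )


def overlap_bases(start: int, end: int, merged: list[tuple[int, int]]) -> int:
    """Bases of [start, end) covered by an already-merged interval list."""
    covered = 0
    for s, e in merged:
        if s >= end:
            break
        if e > start:
            covered += min(e, end) - max(s, start)
    return covered


def covered_fraction(
    interval: GenomicInterval, track: dict[str, list[tuple[int, int]]]
) -> float:
    """Fraction of ``interval`` covered by a merged per-scaffold track."""
    if interval.length <= 0:
        return 0.0
    merged = track.get(interval.scaffold, [])
    return overlap_bases(interval.start, interval.end, merged) / interval.length


def build_track(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Group and merge intervals into a per-scaffold coverage track."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold, []).append((iv.start, iv.end))
    return {k: merge_intervals(v) for k, v in by_scaffold.items()}
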