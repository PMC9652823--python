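"""Genomic interval primitives and a light interval index.

All internal coordinates are 0-based half-open on the forward genomic
strand. Format converters (GTF: 1-based closed, BED: 0-based half-open)
live in the parsers, never here.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))

    @property
    def key(self) -> tuple:
        """Identity key (chrom, start, end, strand) used to collapse
        identical introns shared across isoforms."""
        return (self.chrom, self.start, self.end, self.strand)


class IntervalIndex:
    """Static per-chromosome interval lookup.

    Entries are (start, end, payload). Query is binary search on sorted
    starts pruned by a running maximum of ends; adequate for annotation-
    scale data without an external interval-tree dependency.
    """

    def __init__(self) -> None:
        self._entries: dict[str, list[tuple[int, int, object]]] = {}
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        self._built = False

    def add(self, chrom: str, start: int, end: int, payload: object = None) -> None:
        self._entries.setdefault(chrom, []).append((start, end, payload))
        self._built = False

    def build(self) -> "IntervalIndex":
        for chrom, entries in self._entries.items():
            entries.sort(key=lambda e: (e[0], e[1]))
            self._starts[chrom] = [e[0] for e in entries]
            running = []
            mx = -1
            for _, end, _ in entries:
                mx = max(mx, end)
                running.append(mx)
            self._maxend[chrom] = running
        self._built = True
        return self

    def query(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        """All entries intersecting [start, end) on chrom."""
        if not self._built:
            self.build()
        entries = self._entries.get(chrom)
        if not entries:
            return []
        starts = self._starts[chrom]
        maxend = self._maxend[chrom]
        # entries with start >= end can never overlap
        hi = bisect.bisect_left(starts, end)
        out = []
        i = hi - 1
        while i >= 0:
            if maxend[i] <= start:
                break  # nothing to the left can reach the query
            s, e, payload = entries[i]
            if e > start:
                out.append((s, e, payload))
            i -= 1
        out.reverse()
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def __iter__(self) -> Iterator[tuple[str, int, int, object]]:
        for chrom, entries in self._entries.items():
            for s, e, p in entries:
                yield chrom, s, e, p


def read_bed(path_or_lines: "str | Iterable[str]") -> IntervalIndex:
    """Load a BED file (0-based half-open) into an IntervalIndex.

    Only the first three columns are used; the name column, when
    present, becomes the payload.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    idx = IntervalIndex()
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else None
        idx.add(chrom, start, end, name)
    return idx.build()
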