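"""Per-base coverage tracks (bedGraph-backed step functions)."""

from __future__ import annotations

from typing import Iterable

import numpy as np


class CoverageTrack:
    """A per-chromosome step function over the genome.

    Bases not covered by any record have value 0. Records must be
    non-overlapping per chromosome (the bedGraph contract).
    """

    def __init__(self) -> None:
        self._raw: dict[str, list[tuple[int, int, float]]] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._built = False

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if end <= start:
            raise ValueError("empty coverage segment")
        self._raw.setdefault(chrom, []).append((start, end, float(value)))
        self._built = False

    def build(self) -> "CoverageTrack":
        for chrom, segs in self._raw.items():
            segs.sort()
            for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping coverage segments on {chrom}")
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=float)
            self._arrays[chrom] = (starts, ends, values)
        self._built = True
        return self

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._raw

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end) as a dense array."""
        if not self._built:
            self.build()
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._arrays:
            return out
        starts, ends, values = self._arrays[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(starts[i], start)
            b = min(ends[i], end)
            if b > a:
                out[a - start : b - start] = values[i]
        return out

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over the (possibly fractional) range."""
        if not self._built:
            self.build()
        if chrom not in self._arrays:
            return 0.0
        starts, ends, values = self._arrays[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        total = 0.0
        for i in range(lo, hi):
            a = max(float(starts[i]), start)
            b = min(float(ends[i]), end)
            if b > a:
                total += (b - a) * values[i]
        return total

    def median(self, chrom: str, start: int, end: int) -> float:
        """Median per-base coverage over [start, end), zeros included."""
        vals = self.values(chrom, start, end)
        return float(np.median(vals))


def read_bedgraph(source: "str | Iterable[str]") -> CoverageTrack:
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    track = CoverageTrack()
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        track.add(chrom, int(start), int(end), float(value))
    return track.build()


def write_bedgraph(track_segments: Iterable[tuple[str, int, int, float]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track_segments:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
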