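"""Minimal sorted half-open genomic interval sets.

Intervals are 0-based half-open internally; 1-based variant positions are
converted at the query boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np


def _merge(pairs: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent [start, end) pairs."""
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    out = [list(pairs[0])]
    for start, end in pairs[1:]:
        if start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return np.asarray(out, dtype=np.int64)


@dataclass
class GenomicIntervals:
    """A set of non-overlapping half-open intervals per chromosome."""

    _by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "GenomicIntervals":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if end < start:
                raise ValueError(f"interval end {end} before start {start}")
            if end > start:
                grouped.setdefault(chrom, []).append((start, end))
        return cls(
            {c: _merge(np.asarray(v, dtype=np.int64)) for c, v in grouped.items()}
        )

    def to_tuples(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, int(s), int(e))
            for chrom in sorted(self._by_chrom)
            for s, e in self._by_chrom[chrom]
        ]

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.to_tuples())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervals):
            return NotImplemented
        return self.to_tuples() == other.to_tuples()

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        arr = self._by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            return False
        p0 = pos - 1
        i = int(np.searchsorted(arr[:, 0], p0, side="right")) - 1
        return bool(i >= 0 and p0 < arr[i, 1])

    def intersect(self, other: "GenomicIntervals") -> "GenomicIntervals":
        out: dict[str, np.ndarray] = {}
        for chrom in set(self._by_chrom) & set(other._by_chrom):
            a, b = self._by_chrom[chrom], other._by_chrom[chrom]
            pieces = []
            i = j = 0
            while i < len(a) and j < len(b):
                start = max(a[i, 0], b[j, 0])
                end = min(a[i, 1], b[j, 1])
                if start < end:
                    pieces.append((start, end))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.asarray(pieces, dtype=np.int64)
        return GenomicIntervals(out)

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._by_chrom.values())
        )

    def is_empty(self) -> bool:
        return self.total_length() == 0
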