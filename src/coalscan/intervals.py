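"""Genomic interval sets with BED semantics (0-based, half-open).

The pipeline's bin/region bookkeeping: accepted 1-kbp bins, chained
callable regions, multi-sample intersections and fixed-size scan windows
are all ``IntervalSet`` objects.  Coordinates are 0-based half-open
internally and in BED files; pileup/VCF I/O elsewhere is 1-based.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from typing import Optional

import numpy as np
import pandas as pd

Interval = tuple[str, int, int]


class IntervalSet:
    """Sorted, non-overlapping intervals grouped by chromosome.

    Parameters
    ----------
    intervals
        Iterable of ``(chrom, start, end)`` with ``start < end``.
    metadata
        Optional per-interval records (same order as ``intervals``),
        e.g. callable fraction or mean depth of an accepted bin.
    """

    def __init__(
        self,
        intervals: Iterable[Interval],
        metadata: Optional[Sequence[dict]] = None,
    ):
        ivs = list(intervals)
        if metadata is not None:
            metadata = list(metadata)
            if len(metadata) != len(ivs):
                raise ValueError("metadata length must match intervals")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i][0], ivs[i][1], ivs[i][2]))
        self._ivs: list[Interval] = [ivs[i] for i in order]
        self.metadata = [metadata[i] for i in order] if metadata is not None else None
        self._validate()

    def _validate(self) -> None:
        prev: Optional[Interval] = None
        for chrom, start, end in self._ivs:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative start {chrom}:{start}-{end}")
            if prev is not None and prev[0] == chrom and end_overlaps(prev, (chrom, start, end)):
                raise ValueError(
                    f"overlapping intervals {prev} and {(chrom, start, end)}"
                )
            prev = (chrom, start, end)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self._ivs)

    def __iter__(self):
        return iter(self._ivs)

    def __getitem__(self, i):
        return self._ivs[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:
        return f"IntervalSet({len(self._ivs)} intervals, {self.total_length()} bp)"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, _, _ in self._ivs:
            seen.setdefault(c)
        return list(seen)

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self._ivs)

    def by_chrom(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) on one chromosome."""
        rows = [(s, e) for c, s, e in self._ivs if c == chrom]
        return np.asarray(rows, dtype=np.int64).reshape(-1, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self.by_chrom(chrom)
        if arr.size == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean membership array of ``length`` positions on ``chrom``."""
        out = np.zeros(length, dtype=bool)
        for s, e in self.by_chrom(chrom):
            out[s:min(e, length)] = True
        return out

    # -- algebra -----------------------------------------------------------
    def chain(self) -> "IntervalSet":
        """Merge runs of exactly adjacent intervals (``end_i == start_{i+1}``).

        Gaps of any size, including 1 bp, are never bridged.  Idempotent.
        """
        merged: list[Interval] = []
        for chrom, start, end in self._ivs:
            if merged and merged[-1][0] == chrom and merged[-1][2] == start:
                merged[-1] = (chrom, merged[-1][1], end)
            else:
                merged.append((chrom, start, end))
        return IntervalSet(merged)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Interval] = []
        for chrom in self.chroms():
            a = self.by_chrom(chrom)
            b = other.by_chrom(chrom)
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((chrom, int(s), int(e)))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    # -- I/O ---------------------------------------------------------------
    def to_bed(self, path, values: Optional[Sequence[float]] = None) -> None:
        """Write BED3, or BED4/bedGraph when per-interval values are given."""
        rows = []
        for k, (chrom, start, end) in enumerate(self._ivs):
            row = [chrom, start, end]
            if values is not None:
                row.append(values[k])
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(
            (str(c), int(s), int(e))
            for c, s, e in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
        )

    @classmethod
    def windows(cls, chrom_lengths: dict[str, int], size: int) -> "IntervalSet":
        """Tile each chromosome with fixed-size windows; the final partial
        window is kept (callers that need fixed-size comparability flag it)."""
        out = []
        for chrom, length in chrom_lengths.items():
            for s in range(0, length, size):
                out.append((chrom, s, min(s + size, length)))
        return cls(out)


def end_overlaps(a: Interval, b: Interval) -> bool:
    return a[0] == b[0] and a[2] > b[1] and b[2] > a[1]


def intersect_samples(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Positions present in every sample's interval set.

    Commutative and associative; total length never exceeds the smallest
    input.  Raises on an empty input list.
    """
    if len(sets) == 0:
        raise ValueError("intersect_samples requires at least one interval set")
    acc = sets[0]
    for s in sets[1:]:
        acc = acc.intersect(s)
    return acc
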