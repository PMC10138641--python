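"""Interval algebra over capture designs.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
An :class:`IntervalSet` is the canonical container for a capture design, a gene
panel or any other collection of genomic regions; after construction it is
always sorted and merged, so ``total_bases`` is the exact size of the union of
its input intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "merge",
    "multi_intersect",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A sorted, merged set of genomic intervals.

    Overlapping or abutting input intervals are merged at construction, so two
    IntervalSets covering the same bases compare equal regardless of how their
    inputs were fragmented.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        # per-chromosome merged (starts, ends) arrays; chroms in sorted order
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(by_chrom):
            pairs = sorted(by_chrom[chrom])
            starts: list[int] = []
            ends: list[int] = []
            for s, e in pairs:
                if ends and s <= ends[-1]:  # overlap or abut -> merge
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._chroms[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    # -- basic protocol ----------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, (starts, ends) in self._chroms.items():
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(starts) for starts, _ in self._chroms.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"IntervalSet({self.label or 'unlabelled'}: {len(self)} intervals, {self.total_bases} bases)"

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    @property
    def total_bases(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self._chroms.values())
        )

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged (starts, ends) arrays for one chromosome (empty if absent)."""
        if chrom in self._chroms:
            return self._chroms[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    # -- set algebra -------------------------------------------------------

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based ``positions`` on ``chrom``."""
        positions = np.asarray(positions)
        starts, ends = self.arrays(chrom)
        if starts.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[valid] = positions[valid] < ends[idx[valid]]
        return out

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of ``[start, end)`` on ``chrom`` covered by this set."""
        starts, ends = self.arrays(chrom)
        if starts.size == 0 or end <= start:
            return 0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())

    def intersection(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        out: list[GenomicInterval] = []
        for chrom in self.chroms:
            a_starts, a_ends = self.arrays(chrom)
            b_starts, b_ends = other.arrays(chrom)
            if b_starts.size == 0:
                continue
            i = j = 0
            while i < a_starts.size and j < b_starts.size:
                s = max(a_starts[i], b_starts[j])
                e = min(a_ends[i], b_ends[j])
                if e > s:
                    out.append(GenomicInterval(chrom, int(s), int(e)))
                if a_ends[i] <= b_ends[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out, label=label or f"{self.label}&{other.label}")

    def union(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        return IntervalSet(
            list(self) + list(other), label=label or f"{self.label}|{other.label}"
        )

    def pad(self, padding: int, label: str = "") -> "IntervalSet":
        """Extend every interval by ``padding`` on both sides (clamped at 0)."""
        if padding < 0:
            raise ValueError("padding must be >= 0")
        return IntervalSet(
            (
                GenomicInterval(iv.chrom, max(0, iv.start - padding), iv.end + padding)
                for iv in self
            ),
            label=label or self.label,
        )


def merge(intervals: Iterable[GenomicInterval], label: str = "") -> IntervalSet:
    """Merge arbitrary (unsorted, overlapping, abutting) intervals.

    ``total_bases`` of the result equals the size of the union of input bases.
    Malformed intervals (``end <= start``) raise at GenomicInterval
    construction with the offending record identified.
    """
    return IntervalSet(intervals, label=label)


def multi_intersect(designs: Sequence[IntervalSet]) -> dict[frozenset[str], int]:
    """Exclusive-region base counts for 2-4 capture designs.

    For every non-empty subset S of designs, returns the number of bases
    covered by exactly the designs in S (and no other). The counts over all
    subsets sum to the size of the union, mirroring a multi-way BED
    intersection.
    """
    if not 2 <= len(designs) <= 4:
        raise ValueError(f"multi_intersect requires 2-4 designs, got {len(designs)}")
    labels = [d.label or f"design{i}" for i, d in enumerate(designs)]
    if len(set(labels)) != len(labels):
        raise ValueError(f"design labels must be unique: {labels}")

    counts: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(designs) + 1)
        for c in combinations(labels, r)
    }
    all_chroms = sorted({c for d in designs for c in d.chroms})
    for chrom in all_chroms:
        # sweep over breakpoints: membership is constant between breakpoints
        edges: set[int] = set()
        for d in designs:
            starts, ends = d.arrays(chrom)
            edges.update(starts.tolist())
            edges.update(ends.tolist())
        pts = np.asarray(sorted(edges), dtype=np.int64)
        if pts.size < 2:
            continue
        seg_starts = pts[:-1]
        seg_lens = np.diff(pts)
        member = np.stack([d.contains(chrom, seg_starts) for d in designs])
        for k in range(seg_starts.size):
            present = frozenset(
                labels[i] for i in range(len(designs)) if member[i, k]
            )
            if present:
                counts[present] += int(seg_lens[k])
    return counts


# -- BED I/O ----------------------------------------------------------------


def read_bed(path: str | Path, label: str = "") -> IntervalSet:
    """Read a BED3+ file (tab-separated, 0-based half-open)."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals, label=label or path.stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
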