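"""Per-sample alignment metrics: insert size, duplicates, on-target rate, depth.

Alignments are reduced at ingestion to a minimal :class:`AlignmentRecord`
(unclipped 5' ends of both mates, aligned reference blocks, template length,
summed base qualities and flags) — everything the duplicate marker and the
coverage metrics need, and nothing else. SAM/BAM files are read through pysam;
SAM 1-based positions become 0-based here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .intervals import IntervalSet

__all__ = [
    "AlignmentRecord",
    "CoverageProfile",
    "read_alignments",
    "insert_size_stats",
    "read_overlap",
    "mark_duplicates",
    "on_target_rate",
    "depth_profile",
]

# |tlen| above this is treated as an artefactual pairing, not a real fragment
DEFAULT_MAX_INSERT = 2000


@dataclass
class AlignmentRecord:
    """Minimal alignment fields needed by the sample metrics."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost aligned position
    strand: str  # '+' or '-'
    unclipped_5p: int  # 0-based 5' unclipped alignment start
    mate_chrom: str | None
    mate_unclipped_5p: int | None
    mate_strand: str | None
    tlen: int
    aligned_blocks: tuple[tuple[int, int], ...]  # 0-based half-open, ascending
    mapped: bool = True
    proper_pair: bool = False
    is_read1: bool = True
    base_quality_sum: int = 0
    duplicate: bool = False

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.aligned_blocks)


@dataclass
class CoverageProfile:
    """Per-base depth over the bases of a target IntervalSet.

    ``depth`` is a flat array over all target bases, ordered by
    (chrom, position) following the merged interval order of ``target``.
    """

    target: IntervalSet
    depth: np.ndarray
    include_duplicates: bool = True

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.size != self.target.total_bases:
            raise ValueError(
                f"depth length {self.depth.size} != target bases {self.target.total_bases}"
            )
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("negative depth")

    @property
    def mean(self) -> float:
        return float(self.depth.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.depth))

    def restrict(self, subregion: IntervalSet) -> "CoverageProfile":
        """Depth profile over the bases of ``subregion`` ∩ target."""
        sub = self.target.intersection(subregion, label=subregion.label)
        parts = []
        for iv in sub:
            offs = _positions_to_indices(self.target, iv.chrom, np.arange(iv.start, iv.end))
            parts.append(self.depth[offs])
        depth = np.concatenate(parts) if parts else np.empty(0, dtype=self.depth.dtype)
        return CoverageProfile(sub, depth, self.include_duplicates)


def _base_indexer(target: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Per-chrom (starts, ends, offset) where offset is the flat index of the
    first base of that chromosome's first interval."""
    index = {}
    offset = 0
    for chrom in target.chroms:
        starts, ends = target.arrays(chrom)
        index[chrom] = (starts, ends, offset)
        offset += int((ends - starts).sum())
    return index


def _positions_to_indices(
    target: IntervalSet, chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Flat depth-array indices of target bases at ``positions`` (must be on target)."""
    starts, ends, offset = _base_indexer(target)[chrom]
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    idx = np.searchsorted(starts, positions, side="right") - 1
    return offset + cum[idx] + (positions - starts[idx])


# -- ingestion ---------------------------------------------------------------


def _unclipped_5p(read: pysam.AlignedSegment) -> int:
    """0-based 5' fragment end, undoing soft/hard clipping."""
    cigar = read.cigartuples or []
    if read.is_reverse:
        tail = 0
        for op, ln in reversed(cigar):
            if op in (4, 5):  # S, H
                tail += ln
            else:
                break
        return read.reference_end - 1 + tail
    head = 0
    for op, ln in cigar:
        if op in (4, 5):
            head += ln
        else:
            break
    return read.reference_start - head


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped primary alignments from a SAM/BAM file.

    Secondary and supplementary alignments are excluded from all metrics.
    Mate unclipped-5' coordinates are resolved by pairing records on read
    name, so both mates must be present for paired metrics.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            quals = read.query_qualities
            records.append(
                AlignmentRecord(
                    name=read.query_name,
                    chrom=read.reference_name,
                    pos=read.reference_start,
                    strand="-" if read.is_reverse else "+",
                    unclipped_5p=_unclipped_5p(read),
                    mate_chrom=None,
                    mate_unclipped_5p=None,
                    mate_strand=None,
                    tlen=read.template_length,
                    aligned_blocks=tuple(read.get_blocks()),
                    mapped=True,
                    proper_pair=read.is_proper_pair,
                    is_read1=read.is_read1 or not read.is_paired,
                    base_quality_sum=int(sum(quals)) if quals is not None else 0,
                )
            )
    _resolve_mates(records)
    return records


def _resolve_mates(records: Sequence[AlignmentRecord]) -> None:
    by_name: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_name.setdefault(r.name, []).append(r)
    for group in by_name.values():
        if len(group) == 2:
            a, b = group
            a.mate_chrom, a.mate_unclipped_5p, a.mate_strand = (
                b.chrom,
                b.unclipped_5p,
                b.strand,
            )
            b.mate_chrom, b.mate_unclipped_5p, b.mate_strand = (
                a.chrom,
                a.unclipped_5p,
                a.strand,
            )


# -- metrics -----------------------------------------------------------------


def insert_size_stats(
    records: Iterable[AlignmentRecord], max_insert: int = DEFAULT_MAX_INSERT
) -> dict[str, float]:
    """Median and mean fragment length over proper pairs.

    Each pair is counted once (via its read-1 record); pairs with
    ``|tlen|`` of 0 or above ``max_insert`` are excluded as outliers.
    """
    sizes = [
        abs(r.tlen)
        for r in records
        if r.proper_pair and r.is_read1 and 0 < abs(r.tlen) <= max_insert
    ]
    if not sizes:
        raise ValueError("no proper pairs with usable template length")
    arr = np.asarray(sizes)
    return {
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "n_pairs": len(sizes),
    }


def read_overlap(read_length: int, insert_size: float) -> float:
    """Overlapping bases of two mates: ``max(0, 2*read_length - insert)``.

    With 2x150 bp reads and a 206 bp fragment the mates overlap by 94 bp.
    """
    if read_length <= 0 or insert_size <= 0:
        raise ValueError("read_length and insert_size must be positive")
    return max(0.0, 2 * read_length - insert_size)


def mark_duplicates(records: Sequence[AlignmentRecord]) -> float:
    """Flag PCR duplicates in place; return the duplicate rate.

    Reads sharing the coordinate key (chrom, unclipped 5' end, strand) of
    both mates form one duplicate group; the pair with the highest summed
    base quality (ties: first encountered) stays unflagged, all others are
    flagged. Unpaired mapped reads use a single-end key. The rate is
    flagged mapped reads / mapped reads.
    """
    groups: dict[tuple, list[list[AlignmentRecord]]] = {}
    paired: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        if not r.mapped:
            continue
        r.duplicate = False
        if r.mate_chrom is not None:
            paired.setdefault(r.name, []).append(r)
        else:
            key = ("se", r.chrom, r.unclipped_5p, r.strand)
            groups.setdefault(key, []).append([r])
    for name, pair in paired.items():
        ends = sorted(
            (r.chrom, r.unclipped_5p, r.strand) for r in pair
        )
        key = ("pe",) + tuple(x for end in ends for x in end)
        groups.setdefault(key, []).append(pair)

    n_mapped = sum(1 for r in records if r.mapped)
    n_dup = 0
    for members in groups.values():
        if len(members) == 1:
            continue
        best = max(range(len(members)), key=lambda i: sum(r.base_quality_sum for r in members[i]))
        for i, unit in enumerate(members):
            if i != best:
                for r in unit:
                    r.duplicate = True
                n_dup += len(unit)
    return n_dup / n_mapped if n_mapped else 0.0


def on_target_rate(
    records: Iterable[AlignmentRecord], target: IntervalSet
) -> float:
    """Fraction of aligned bases of mapped reads that fall on target.

    Counts aligned (CIGAR-matched) bases only — soft-clipped bases and
    deleted reference positions do not contribute. Duplicates are included:
    the denominator is everything the sequencer produced and mapped.
    """
    if target.total_bases == 0:
        raise ValueError("empty target")
    on = total = 0
    for r in records:
        if not r.mapped:
            continue
        for s, e in r.aligned_blocks:
            total += e - s
            on += target.overlap_bases(r.chrom, s, e)
    if total == 0:
        raise ValueError("no mapped bases")
    return on / total


def depth_profile(
    records: Iterable[AlignmentRecord],
    target: IntervalSet,
    include_duplicates: bool = True,
) -> CoverageProfile:
    """Per-base depth over target bases from qualifying reads.

    ``depth[b]`` counts aligned read bases overlapping target base ``b``;
    with ``include_duplicates=False`` duplicate-flagged reads are skipped
    (records must already carry duplicate flags).
    """
    n = target.total_bases
    # difference array per chromosome over local coordinates, then gather
    diffs: dict[str, np.ndarray] = {}
    spans: dict[str, tuple[int, int]] = {}
    for chrom in target.chroms:
        starts, ends = target.arrays(chrom)
        lo, hi = int(starts[0]), int(ends[-1])
        spans[chrom] = (lo, hi)
        diffs[chrom] = np.zeros(hi - lo + 1, dtype=np.int64)
    for r in records:
        if not r.mapped or (not include_duplicates and r.duplicate):
            continue
        if r.chrom not in diffs:
            continue
        lo, hi = spans[r.chrom]
        d = diffs[r.chrom]
        for s, e in r.aligned_blocks:
            s, e = max(s, lo), min(e, hi)
            if e > s:
                d[s - lo] += 1
                d[e - lo] -= 1
    out = np.empty(n, dtype=np.int64)
    pos = 0
    for chrom in target.chroms:
        lo, _ = spans[chrom]
        cum = np.cumsum(diffs[chrom][:-1])
        starts, ends = target.arrays(chrom)
        for s, e in zip(starts.tolist(), ends.tolist()):
            out[pos : pos + e - s] = cum[s - lo : e - lo]
            pos += e - s
    return CoverageProfile(target, out, include_duplicates)
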