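"""Shared fixtures and per-base brute-force oracles.

The oracles deliberately avoid the library's interval machinery: membership
is evaluated with plain boolean arrays over a toy genome, so any agreement
with the fast implementations is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from kiteval import (
    GenomicInterval,
    IntervalSet,
    SimulationConfig,
    simulate_experiment,
)


# -- oracles -----------------------------------------------------------------


def bool_mask(iset: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base membership of ``iset`` on one chromosome of known length."""
    mask = np.zeros(length, dtype=bool)
    for iv in iset:
        if iv.chrom == chrom:
            mask[iv.start : min(iv.end, length)] = True
    return mask


def oracle_union_bases(
    intervals: list[GenomicInterval], chrom_lengths: dict[str, int]
) -> int:
    total = 0
    for chrom, length in chrom_lengths.items():
        mask = np.zeros(length, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start : min(iv.end, length)] = True
        total += int(mask.sum())
    return total


def oracle_depth(records, target: IntervalSet, chrom_lengths, include_duplicates=True):
    """Per-target-base pileup by direct per-base counting."""
    depth = {c: np.zeros(l, dtype=np.int64) for c, l in chrom_lengths.items()}
    for r in records:
        if not r.mapped or (not include_duplicates and r.duplicate):
            continue
        for s, e in r.aligned_blocks:
            depth[r.chrom][s:e] += 1
    out = []
    for iv in target:
        out.append(depth[iv.chrom][iv.start : iv.end])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def random_intervals(rng, chrom_lengths, n, max_len=200):
    out = []
    chroms = list(chrom_lengths)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# -- fixtures ----------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """A 5,000-pair simulated experiment shared by read-only tests."""
    config = SimulationConfig(n_read_pairs=5_000, seed=11)
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_sim):
    """The small experiment written out as SAM/FASTQ/BED/GTF files."""
    d = tmp_path_factory.mktemp("sim")
    small_sim.write_sam(d / "sample.sam")
    small_sim.write_fastq(d / "r1.fastq", d / "r2.fastq")
    small_sim.write_bed(d / "design.bed")
    small_sim.write_gtf(d / "annotation.gtf")
    small_sim.write_truth(d / "truth.json")
    return d
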