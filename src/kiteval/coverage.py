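"""Coverage rate, uniformity metrics, downsampling and effort curves.

The sequencing-effort analysis mimics the wet-lab question "how many reads do
I need?": read pairs are subsampled to each effort level, duplicates are
re-marked, per-base depth is recomputed and the fraction of target bases at or
above each depth threshold is tabulated. With nested subsampling (the
default) every smaller effort is a subset of the next larger one, so the
curves are monotone in effort by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment import (
    AlignmentRecord,
    CoverageProfile,
    depth_profile,
    mark_duplicates,
)
from .intervals import IntervalSet

__all__ = [
    "CoverageRateTable",
    "UniformityMetrics",
    "EffortGrid",
    "coverage_rate",
    "fold80",
    "evenness",
    "downsample",
    "effort_curves",
    "minimal_effort",
    "panel_coverage_report",
]

DEFAULT_DEPTHS = (15, 30, 50, 100)
DEFAULT_EFFORTS_M = (5, 10, 20, 40, 60, 80, 100)  # million read pairs


@dataclass
class CoverageRateTable:
    """Fraction of target bases covered at >= each depth threshold."""

    rates: dict[int, float]
    effort: int | None = None  # read pairs used, if downsampled

    def __getitem__(self, depth: int) -> float:
        return self.rates[depth]

    @property
    def thresholds(self) -> list[int]:
        return sorted(self.rates)


@dataclass
class UniformityMetrics:
    fold80: float | None  # None when the 20th-percentile depth is zero
    evenness: float


@dataclass
class EffortGrid:
    """Per-effort coverage-rate tables (efforts ascending, in read pairs)."""

    tables: dict[int, CoverageRateTable]

    @property
    def efforts(self) -> list[int]:
        return sorted(self.tables)

    def rate(self, effort: int, depth: int) -> float:
        return self.tables[effort][depth]


def coverage_rate(
    profile: CoverageProfile, thresholds: Sequence[int] = DEFAULT_DEPTHS
) -> CoverageRateTable:
    """rate[n] = fraction of target bases with depth >= n.

    "Covered at nX" is inclusive: a base at exactly 30X counts toward the
    30X rate.
    """
    if profile.depth.size == 0:
        raise ValueError("empty coverage profile")
    d = profile.depth
    return CoverageRateTable(
        {int(n): float((d >= n).sum() / d.size) for n in thresholds}
    )


def fold80(profile: CoverageProfile) -> float | None:
    """Fold-80 base penalty: mean depth / 20th-percentile depth.

    The fold increase in (non-zero) coverage needed to bring 80% of target
    bases up to the observed mean; 1.0 means perfectly uniform coverage.
    The 20th percentile is the depth at ascending rank ceil(0.2*N) over all
    target bases, zeros included, so at least 80% of bases sit at or above
    it. Returns None (undefined, insufficient coverage) when that
    percentile is zero.
    """
    d = np.sort(profile.depth)
    if d.size == 0:
        raise ValueError("empty coverage profile")
    p20 = int(d[max(0, math.ceil(0.2 * d.size) - 1)])
    if p20 == 0:
        return None
    return float(d.mean() / p20)


def evenness(profile: CoverageProfile, method: str = "truncated_mean") -> float:
    """Evenness score in percent; 100 iff coverage is perfectly uniform.

    ``truncated_mean`` (default): E = 100 * sum(min(depth, C)) / (C * N)
    with C the mean depth — the fraction of the ideal uniform read mass
    that the observed profile retains once depth above the mean is
    discarded.

    ``discrete``: E = 100 * mean over i in 1..round(C) of
    fraction(depth >= i) — the discrete-sum variant built from the
    cumulative coverage distribution. Both score uniform coverage at
    exactly 100 and are invariant to scaling every depth by a constant
    (the discrete form up to rounding of C).
    """
    d = profile.depth
    if d.size == 0 or d.sum() == 0:
        raise ValueError("evenness undefined for all-zero coverage")
    c = d.mean()
    if method == "truncated_mean":
        return float(100.0 * np.minimum(d, c).sum() / (c * d.size))
    if method == "discrete":
        cr = max(1, round(c))
        levels = np.arange(1, cr + 1)
        frac = (d[:, None] >= levels[None, :]).mean(axis=0)
        return float(100.0 * frac.mean())
    raise ValueError(f"unknown evenness method: {method}")


def uniformity(profile: CoverageProfile) -> UniformityMetrics:
    return UniformityMetrics(fold80=fold80(profile), evenness=evenness(profile))


# -- downsampling ------------------------------------------------------------


def _pairs(records: Sequence[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    by_name: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_name.setdefault(r.name, []).append(r)
    return by_name


def downsample(
    records: Sequence[AlignmentRecord], target_count: int, seed: int
) -> list[AlignmentRecord]:
    """Select exactly ``target_count`` read pairs uniformly without replacement.

    Mates are never separated: sampling operates on fragment names. The
    same (input, seed) always yields the same subsample.
    """
    by_name = _pairs(records)
    names = sorted(by_name)
    if target_count > len(names):
        raise ValueError(
            f"requested {target_count} pairs but only {len(names)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(names), size=target_count, replace=False)
    out: list[AlignmentRecord] = []
    for i in sorted(chosen.tolist()):
        out.extend(by_name[names[i]])
    return out


def effort_curves(
    records: Sequence[AlignmentRecord],
    target: IntervalSet,
    efforts: Sequence[int],
    thresholds: Sequence[int] = DEFAULT_DEPTHS,
    seed: int = 0,
    nested: bool = True,
    remove_duplicates: bool = True,
) -> EffortGrid:
    """Coverage-rate tables at increasing sequencing efforts (read pairs).

    Per effort: subsample pairs -> re-mark duplicates -> depth profile
    (duplicates removed by default) -> coverage rates. ``nested=True`` draws
    one random permutation and takes prefixes, so each smaller effort is a
    subset of every larger one and rates are exactly monotone in effort;
    ``nested=False`` draws each effort independently.
    """
    efforts = sorted(efforts)
    by_name = _pairs(records)
    names = sorted(by_name)
    if efforts and efforts[-1] > len(names):
        raise ValueError(
            f"largest effort {efforts[-1]} exceeds available pairs {len(names)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(names))
    tables: dict[int, CoverageRateTable] = {}
    for k, effort in enumerate(efforts):
        if nested:
            idx = perm[:effort]
            sub: list[AlignmentRecord] = []
            for i in sorted(idx.tolist()):
                sub.extend(by_name[names[i]])
        else:
            sub = downsample(records, effort, seed=int(rng.integers(2**31)))
        if remove_duplicates:
            mark_duplicates(sub)
        profile = depth_profile(sub, target, include_duplicates=not remove_duplicates)
        table = coverage_rate(profile, thresholds)
        table.effort = effort
        tables[effort] = table
    return EffortGrid(tables)


def minimal_effort(
    grid: EffortGrid, depth: int, required_rate: float
) -> int | None:
    """Smallest effort whose rate at ``depth`` reaches ``required_rate``.

    Returns None when no effort in the grid reaches the requirement
    ("not reached").
    """
    for effort in grid.efforts:
        if grid.rate(effort, depth) >= required_rate:
            return effort
    return None


def panel_coverage_report(
    records: Sequence[AlignmentRecord],
    panel: IntervalSet,
    efforts: Sequence[int],
    thresholds: Sequence[int] = DEFAULT_DEPTHS,
    seed: int = 0,
    **kwargs,
) -> EffortGrid:
    """Effort curves restricted to a gene panel (or the OMIM gene set)."""
    if panel.total_bases == 0:
        raise ValueError("empty panel")
    return effort_curves(records, panel, efforts, thresholds, seed=seed, **kwargs)


def grid_to_rows(grid: EffortGrid) -> list[dict[str, float]]:
    """Tabular form: one row per effort, one column per depth threshold."""
    rows = []
    for effort in grid.efforts:
        table = grid.tables[effort]
        row: dict[str, float] = {"effort_pairs": effort}
        for n in table.thresholds:
            row[f"pct_ge_{n}x"] = 100.0 * table[n]
        rows.append(row)
    return rows
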