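"""Run-level sequencing quality: Q-scores, chastity, Q30 and instrument thresholds.

Cluster density, %PF and PhiX% come from the sequencer software and are
ingested as reported; Q30 is both ingested and recomputable from FASTQ so the
two can be cross-checked.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "RunSummary",
    "Verdict",
    "INSTRUMENT_DENSITY",
    "phred_from_error",
    "error_from_phred",
    "chastity",
    "passes_chastity_filter",
    "q30_from_fastq",
    "evaluate_run",
]

# Acceptable raw cluster density ranges (K/mm^2) per instrument/chemistry
INSTRUMENT_DENSITY: dict[str, tuple[float, float]] = {
    "miniseq-high-mid": (170, 220),
    "miseq-v2": (1000, 1200),
    "miseq-v3": (1200, 1400),
    "nextseq-v2-high-mid": (170, 220),
    "hiseq2500-v1-v2": (850, 1000),
    "hiseq2500-v3": (750, 850),
    "hiseq2500-v4": (950, 1050),
}

CHASTITY_MIN = 0.6  # a read fails if any of its first 25 cycles drops below this
CHASTITY_CYCLES = 25
DEFAULT_PF_MIN = 65.0  # %
DEFAULT_Q30_MIN = 80.0  # %; lower may be acceptable for FFPE/degraded DNA
DEFAULT_PHIX_MIN = 0.3  # %; ~1% is the ideal spike-in
PHIX_IDEAL = 1.0


@dataclass
class RunSummary:
    """Sequencer-reported run metrics."""

    instrument: str
    cluster_density: float  # K/mm^2
    percent_pf: float
    percent_q30: float
    percent_phix_aligned: float

    def __post_init__(self) -> None:
        for name in ("percent_pf", "percent_q30", "percent_phix_aligned"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.cluster_density <= 0:
            raise ValueError("cluster_density must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunSummary":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Verdict:
    metric: str
    value: float
    rule: str
    passed: bool
    note: str = ""


def phred_from_error(error_rate: float) -> float:
    """Q = -10 * log10(e)."""
    if not 0 < error_rate <= 1:
        raise ValueError(f"error rate must be in (0, 1], got {error_rate}")
    return -10.0 * math.log10(error_rate)


def error_from_phred(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def chastity(intensity_brightest: float, intensity_second: float) -> float:
    """Ia / (Ia + Ib): purity of the brightest base call."""
    if intensity_brightest < 0 or intensity_second < 0:
        raise ValueError("intensities must be non-negative")
    total = intensity_brightest + intensity_second
    if total == 0:
        raise ValueError("both intensities zero")
    return intensity_brightest / total


def passes_chastity_filter(cycle_chastities: Sequence[float]) -> bool:
    """A cluster fails if any chastity < 0.6 within the first 25 cycles."""
    return all(c >= CHASTITY_MIN for c in cycle_chastities[:CHASTITY_CYCLES])


def q30_from_fastq(paths: Sequence[str | Path] | str | Path) -> float:
    """Percent of base calls at Phred quality >= 30 across FASTQ files.

    Accepts plain or gzipped FASTQ with Phred+33 qualities. The threshold
    is inclusive: Q exactly 30 counts.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    n = n30 = 0
    for path in paths:
        with pysam.FastxFile(str(path)) as fq:
            for read in fq:
                quals = read.get_quality_array()
                if quals is None:
                    continue
                n += len(quals)
                n30 += sum(1 for q in quals if q >= 30)
    if n == 0:
        raise ValueError("no bases found in FASTQ input")
    return 100.0 * n30 / n


def evaluate_run(
    summary: RunSummary,
    density_table: Mapping[str, tuple[float, float]] | None = None,
    pf_min: float = DEFAULT_PF_MIN,
    q30_min: float = DEFAULT_Q30_MIN,
    phix_min: float = DEFAULT_PHIX_MIN,
) -> list[Verdict]:
    """Pass/fail verdicts for the four run metrics.

    Threshold comparisons are inclusive (>=) at the stated bounds. Failures
    carry the usual cause as a note.
    """
    table = INSTRUMENT_DENSITY if density_table is None else dict(density_table)
    if summary.instrument not in table:
        raise KeyError(
            f"unknown instrument {summary.instrument!r}; known: {sorted(table)}"
        )
    lo, hi = table[summary.instrument]
    verdicts = [
        Verdict(
            "cluster_density",
            summary.cluster_density,
            f"{lo}-{hi} K/mm^2",
            lo <= summary.cluster_density <= hi,
            ""
            if lo <= summary.cluster_density <= hi
            else "inaccurate library quantification causing over- or under-clustering",
        ),
        Verdict(
            "percent_pf",
            summary.percent_pf,
            f">={pf_min}%",
            summary.percent_pf >= pf_min,
            "" if summary.percent_pf >= pf_min else "over-clustering",
        ),
        Verdict(
            "percent_q30",
            summary.percent_q30,
            f">={q30_min}%",
            summary.percent_q30 >= q30_min,
            ""
            if summary.percent_q30 >= q30_min
            else "poor DNA quality or degraded sequencing reagents",
        ),
        Verdict(
            "percent_phix_aligned",
            summary.percent_phix_aligned,
            f">={phix_min}% (ideally ~{PHIX_IDEAL}%)",
            summary.percent_phix_aligned >= phix_min,
            ""
            if summary.percent_phix_aligned >= phix_min
            else "insufficient PhiX spike-in for library complexity",
        ),
    ]
    return verdicts
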