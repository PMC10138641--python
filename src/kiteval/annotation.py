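"""Gene annotation: transcript models, design partition and panel construction.

Gene models are read from GTF/GFF-style files (``exon`` and ``CDS`` features
required) or from refFlat-style tab-separated tables. A capture design is
partitioned into coding / UTR / intron / intergenic base counts; a clinical
gene panel is built as the padded union of a gene list's exons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "DesignPartition",
    "read_gtf",
    "read_refflat",
    "partition_design",
    "build_panel_bed",
    "write_partition_table",
]

DEFAULT_EXON_PADDING = 25  # bp added on each side of every exon in a panel


@dataclass
class GeneModel:
    """One transcript: exon and CDS intervals plus gene symbol and strand.

    Invariant: every CDS interval lies within some exon; exons of one
    transcript do not overlap each other.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        exon_set = IntervalSet(self.exons)
        if exon_set.total_bases != sum(len(e) for e in self.exons):
            raise ValueError(f"{self.transcript}: overlapping exons")
        for c in self.cds:
            if exon_set.overlap_bases(c.chrom, c.start, c.end) != len(c):
                raise ValueError(f"{self.transcript}: CDS {c} not contained in exons")


@dataclass
class DesignPartition:
    """Base counts of a design split by annotation category."""

    label: str
    coding_bases: int
    utr_bases: int
    intron_bases: int
    intergenic_bases: int

    @property
    def total_bases(self) -> int:
        return (
            self.coding_bases
            + self.utr_bases
            + self.intron_bases
            + self.intergenic_bases
        )

    @property
    def noncoding_bases(self) -> int:
        """UTR + intron, the merged 'non-coding' category."""
        return self.utr_bases + self.intron_bases


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a GTF file (exon/CDS features).

    GTF coordinates are 1-based inclusive and are converted to 0-based
    half-open on ingestion.
    """
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = dict(_GTF_ATTR.findall(attrs))
            tid = a.get("transcript_id")
            gene = a.get("gene_name") or a.get("gene_id") or ""
            if tid is None:
                raise ValueError(f"{path}:{lineno}: missing transcript_id")
            model = models.setdefault(tid, GeneModel(gene, tid, chrom, strand))
            iv = GenomicInterval(chrom, int(start) - 1, int(end))
            (model.exons if feature == "exon" else model.cds).append(iv)
    out = list(models.values())
    for m in out:
        m.exons.sort()
        m.cds.sort()
    return out


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a refFlat-style table.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (UCSC refFlat; 0-based half-open).
    """
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            gene, tid, chrom, strand = f[0], f[1], f[2], f[3]
            cds_start, cds_end = int(f[6]), int(f[7])
            exon_starts = [int(x) for x in f[9].rstrip(",").split(",")]
            exon_ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, s, e) for s, e in zip(exon_starts, exon_ends)
            ]
            cds = []
            if cds_end > cds_start:
                for iv in exons:
                    s, e = max(iv.start, cds_start), min(iv.end, cds_end)
                    if e > s:
                        cds.append(GenomicInterval(chrom, s, e))
            models.append(GeneModel(gene, tid, chrom, strand, exons, cds))
    return models


def _category_sets(annotation: Iterable[GeneModel]) -> dict[str, IntervalSet]:
    """CDS / UTR / intron IntervalSets over all transcripts (pre-precedence)."""
    cds, utr, intron = [], [], []
    for m in annotation:
        cds.extend(m.cds)
        exon_set = IntervalSet(m.exons)
        cds_set = IntervalSet(m.cds)
        # UTR = exonic minus CDS, per transcript
        for iv in m.exons:
            starts, ends = cds_set.arrays(iv.chrom)
            pos = iv.start
            for cs, ce in zip(starts.tolist(), ends.tolist()):
                if ce <= iv.start or cs >= iv.end:
                    continue
                if cs > pos:
                    utr.append(GenomicInterval(iv.chrom, pos, min(cs, iv.end)))
                pos = max(pos, ce)
            if pos < iv.end:
                utr.append(GenomicInterval(iv.chrom, pos, iv.end))
        # introns: gaps between consecutive exons of the transcript
        exons = sorted(m.exons)
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                intron.append(GenomicInterval(m.chrom, a.end, b.start))
    return {
        "coding": IntervalSet(cds, "coding"),
        "utr": IntervalSet(utr, "utr"),
        "intron": IntervalSet(intron, "intron"),
    }


def partition_design(
    design: IntervalSet, annotation: Iterable[GeneModel]
) -> DesignPartition:
    """Assign every targeted base to exactly one annotation category.

    When transcripts disagree about a base, precedence is
    coding > UTR > intron > intergenic, so the four counts are disjoint and
    sum to ``design.total_bases``. Unannotated bases are intergenic.
    """
    cats = _category_sets(annotation)
    coding = design.intersection(cats["coding"]).total_bases
    # precedence: subtract higher categories before counting lower ones
    utr_only = cats["utr"]
    coding_set = cats["coding"]
    utr_bases = _minus_count(design.intersection(utr_only), coding_set)
    exonic = coding_set.union(cats["utr"])
    intron_bases = _minus_count(design.intersection(cats["intron"]), exonic)
    intergenic = design.total_bases - coding - utr_bases - intron_bases
    return DesignPartition(design.label, coding, utr_bases, intron_bases, intergenic)


def _minus_count(a: IntervalSet, b: IntervalSet) -> int:
    """Bases in ``a`` not covered by ``b``."""
    return a.total_bases - a.intersection(b).total_bases


def build_panel_bed(
    genes: Sequence[str],
    annotation: Iterable[GeneModel],
    padding: int = DEFAULT_EXON_PADDING,
    label: str = "panel",
) -> tuple[IntervalSet, list[str]]:
    """Build a gene-panel IntervalSet from a symbol list.

    The panel is the union over all transcripts of the listed genes of every
    exon extended by ``padding`` bases on both sides (clamped at position 0,
    so nearby canonical splice sites are included), then merged. Symbols not
    found in the annotation are returned in the skipped list, never silently
    dropped.
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    by_gene: dict[str, list[GenomicInterval]] = {}
    for m in annotation:
        by_gene.setdefault(m.gene, []).extend(m.exons)
    intervals: list[GenomicInterval] = []
    skipped: list[str] = []
    for symbol in genes:
        exons = by_gene.get(symbol)
        if not exons:
            skipped.append(symbol)
            continue
        intervals.extend(
            GenomicInterval(e.chrom, max(0, e.start - padding), e.end + padding)
            for e in exons
        )
    return IntervalSet(intervals, label=label), skipped


def write_partition_table(
    partitions: Sequence[DesignPartition], path: str | Path
) -> None:
    cols = [
        "label",
        "coding_bases",
        "utr_bases",
        "intron_bases",
        "intergenic_bases",
        "total_bases",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in partitions:
            fh.write(
                f"{p.label}\t{p.coding_bases}\t{p.utr_bases}\t{p.intron_bases}"
                f"\t{p.intergenic_bases}\t{p.total_bases}\n"
            )
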