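"""Synthetic sequencing experiments with known ground truth.

Generates a toy genome layout, a capture design, gene annotation, simulated
paired-end alignments (insert-size distribution, duplicate fraction,
off-target fraction and per-interval capture non-uniformity all
controllable), FASTQ with a controllable Q30, and variant sets with a
controllable Ts/Tv — each accompanied by a truth ledger sufficient to compute
every expected metric by direct count.

Alignments are generated directly on the toy reference (no mapper in the
loop): a fragment is placed either fully inside one target interval or fully
outside the target, both mates align end-to-end, and duplicate pairs re-emit
a chosen fragment at identical coordinates with fresh base qualities — the
same coordinate signature the duplicate marker keys on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .alignment import AlignmentRecord
from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalSet
from .variants import VariantRecord

__all__ = ["SimulationConfig", "SimulatedExperiment", "simulate_experiment", "simulate_variants"]

_QUAL_HIGH = 37  # per-base quality drawn at q30_target probability
_QUAL_LOW = 14


@dataclass
class SimulationConfig:
    """Knobs of one simulated capture-sequencing experiment.

    The defaults describe a NextSeq-style 2x150 bp paired-end library on a
    1 Mb toy genome with a 20% capture target, a ~206 bp fragment
    distribution and Medexome-like duplicate (12%) and off-target (26%)
    fractions. ``nonuniformity_shape`` is the shape k of a gamma
    distribution of per-target-interval capture efficiencies (mean 1);
    k -> infinity gives uniform capture, small k concentrates coverage.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    design_fraction: float = 0.2
    target_interval_length: int = 2500
    n_read_pairs: int = 50_000
    read_length: int = 150
    insert_mean: float = 206.0
    insert_sd: float = 30.0
    max_insert: int = 2000
    duplicate_fraction: float = 0.12
    off_target_fraction: float = 0.26
    nonuniformity_shape: float = float("inf")
    q30_target: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        for name in ("design_fraction", "duplicate_fraction", "off_target_fraction", "q30_target"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        min_chrom = min(self.chrom_lengths.values())
        if self.target_interval_length > min_chrom:
            raise ValueError("target intervals do not fit the smallest chromosome")
        if self.insert_mean > self.target_interval_length:
            raise ValueError(
                f"mean insert {self.insert_mean} exceeds target interval length "
                f"{self.target_interval_length}: fragments cannot be placed"
            )


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    records: list[AlignmentRecord]  # coordinate-sorted
    design: IntervalSet
    annotation: list[GeneModel]
    truth: dict
    # per-read payloads for file output, aligned with `records`
    _seqs: list[str] = field(default_factory=list, repr=False)
    _quals: list[np.ndarray] = field(default_factory=list, repr=False)

    # -- writers -----------------------------------------------------------

    def write_sam(self, path: str | Path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": int(l)}
                for c, l in self.config.chrom_lengths.items()
            ],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            tid = {c: i for i, c in enumerate(self.config.chrom_lengths)}
            for rec, seq, qual in zip(self.records, self._seqs, self._quals):
                a = pysam.AlignedSegment()
                a.query_name = rec.name
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in qual)
                )
                a.reference_id = tid[rec.chrom]
                a.reference_start = rec.pos
                a.cigarstring = f"{len(seq)}M"
                a.template_length = rec.tlen
                a.next_reference_id = tid[rec.mate_chrom]
                a.next_reference_start = rec.mate_unclipped_5p if rec.mate_strand == "+" else (
                    rec.mate_unclipped_5p - len(seq) + 1
                )
                flag = 0x1 | 0x2  # paired, proper
                if rec.strand == "-":
                    flag |= 0x10
                if rec.mate_strand == "-":
                    flag |= 0x20
                flag |= 0x40 if rec.is_read1 else 0x80
                a.flag = flag
                out.write(a)

    def write_fastq(self, path_r1: str | Path, path_r2: str | Path) -> None:
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for rec, seq, qual in zip(self.records, self._seqs, self._quals):
                fh = f1 if rec.is_read1 else f2
                qs = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{rec.name}\n{seq}\n+\n{qs}\n")

    def write_bed(self, path: str | Path) -> None:
        from .intervals import write_bed

        write_bed(self.design, path)

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.annotation:
                for feature, ivs in (("exon", m.exons), ("CDS", m.cds)):
                    for iv in ivs:
                        attrs = f'gene_id "{m.gene}"; transcript_id "{m.transcript}"; gene_name "{m.gene}";'
                        fh.write(
                            f"{iv.chrom}\ttoy\t{feature}\t{iv.start + 1}\t{iv.end}"
                            f"\t.\t{m.strand}\t.\t{attrs}\n"
                        )

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _build_design(config: SimulationConfig) -> IntervalSet:
    """Evenly spaced fixed-length target intervals filling design_fraction."""
    intervals = []
    L = config.target_interval_length
    for chrom, length in config.chrom_lengths.items():
        n_iv = max(1, round(length * config.design_fraction / L))
        spacing = length // n_iv
        for k in range(n_iv):
            start = k * spacing + (spacing - L) // 2
            intervals.append(GenomicInterval(chrom, start, start + L))
    return IntervalSet(intervals, label="sim-design")


def _build_annotation(design: IntervalSet) -> list[GeneModel]:
    """One toy gene per target interval: UTR-CDS-intron-CDS-UTR."""
    models = []
    for i, iv in enumerate(design):
        s = iv.start
        gene = f"GENE{i:04d}"
        m = GeneModel(
            gene=gene,
            transcript=f"{gene}.t1",
            chrom=iv.chrom,
            strand="+" if i % 2 == 0 else "-",
            exons=[
                GenomicInterval(iv.chrom, s, s + 800),
                GenomicInterval(iv.chrom, s + 1200, s + 2500),
            ],
            cds=[
                GenomicInterval(iv.chrom, s + 100, s + 800),
                GenomicInterval(iv.chrom, s + 1200, s + 2000),
            ],
        )
        models.append(m)
    return models


def _complement(design: IntervalSet, chrom_lengths: dict[str, int], min_len: int) -> list[GenomicInterval]:
    out = []
    for chrom, length in chrom_lengths.items():
        starts, ends = design.arrays(chrom)
        pos = 0
        for s, e in zip(starts.tolist(), ends.tolist()):
            if s - pos >= min_len:
                out.append(GenomicInterval(chrom, pos, s))
            pos = e
        if length - pos >= min_len:
            out.append(GenomicInterval(chrom, pos, length))
    return out


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one experiment: alignments + design + annotation + truth.

    Exactly ``round(n_read_pairs * duplicate_fraction)`` of the emitted
    pairs are PCR duplicates (re-emissions of a unique fragment chosen with
    replacement); each unique fragment is placed fully on target with
    probability ``1 - off_target_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _build_design(config)
    annotation = _build_annotation(design)
    target_ivs = list(design)
    off_ivs = _complement(design, config.chrom_lengths, min_len=config.max_insert + 10)
    if not off_ivs and config.off_target_fraction > 0:
        raise ValueError("no off-target space for the requested geometry")

    n = config.n_read_pairs
    n_dup = round(n * config.duplicate_fraction)
    n_unique = n - n_dup
    rl = config.read_length

    # per-target-interval capture weights: length x gamma(k, 1/k) multiplier
    k = config.nonuniformity_shape
    if np.isinf(k):
        mult = np.ones(len(target_ivs))
    else:
        mult = rng.gamma(shape=k, scale=1.0 / k, size=len(target_ivs))
    t_len = np.array([len(iv) for iv in target_ivs], dtype=float)
    t_w = t_len * mult
    t_w /= t_w.sum()
    o_len = np.array([len(iv) for iv in off_ivs], dtype=float) if off_ivs else np.empty(0)
    o_w = o_len / o_len.sum() if off_ivs else o_len

    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_unique)
    inserts = np.clip(np.rint(inserts), rl, config.max_insert).astype(np.int64)
    on_target = rng.random(n_unique) >= config.off_target_fraction

    chroms: list[str] = []
    starts = np.empty(n_unique, dtype=np.int64)
    iv_choice_on = rng.choice(len(target_ivs), size=n_unique, p=t_w if t_w.size else None)
    iv_choice_off = (
        rng.choice(len(off_ivs), size=n_unique, p=o_w) if off_ivs else np.zeros(n_unique, int)
    )
    u = rng.random(n_unique)
    seen: set[tuple[str, int, int]] = set()
    for i in range(n_unique):
        iv = target_ivs[iv_choice_on[i]] if on_target[i] else off_ivs[iv_choice_off[i]]
        ins = min(inserts[i], len(iv))
        inserts[i] = ins
        start = iv.start + int(u[i] * (len(iv) - ins + 1))
        # unique fragments must carry distinct coordinate keys; redraw the
        # rare chance collision so only injected duplicates share a key
        while (iv.chrom, start, ins) in seen:
            start = iv.start + int(rng.integers(0, len(iv) - ins + 1))
        seen.add((iv.chrom, start, ins))
        starts[i] = start
        chroms.append(iv.chrom)

    # duplicates re-emit a unique fragment at identical coordinates
    dup_of = rng.choice(n_unique, size=n_dup, replace=True) if n_dup else np.empty(0, int)

    frag_chrom = chroms + [chroms[j] for j in dup_of]
    frag_start = np.concatenate([starts, starts[dup_of]]) if n_dup else starts
    frag_insert = np.concatenate([inserts, inserts[dup_of]]) if n_dup else inserts
    is_dup_truth = np.zeros(n, dtype=bool)
    is_dup_truth[n_unique:] = True

    records: list[AlignmentRecord] = []
    seqs: list[str] = []
    quals: list[np.ndarray] = []
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    order = sorted(range(n), key=lambda i: (frag_chrom[i], int(frag_start[i]), i))
    for idx in order:
        name = f"frag{idx:07d}"
        chrom = frag_chrom[idx]
        s = int(frag_start[idx])
        ins = int(frag_insert[idx])
        r1_start, r2_start = s, s + ins - rl
        five_r1, five_r2 = s, s + ins - 1
        for which, (pos, five, strand, mate_five, mate_strand, tlen) in enumerate(
            [
                (r1_start, five_r1, "+", five_r2, "-", ins),
                (r2_start, five_r2, "-", five_r1, "+", -ins),
            ]
        ):
            q = np.where(
                rng.random(rl) < config.q30_target, _QUAL_HIGH, _QUAL_LOW
            ).astype(np.int64)
            seq = "".join(bases[rng.integers(0, 4, size=rl)])
            records.append(
                AlignmentRecord(
                    name=name,
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    unclipped_5p=five,
                    mate_chrom=chrom,
                    mate_unclipped_5p=mate_five,
                    mate_strand=mate_strand,
                    tlen=tlen,
                    aligned_blocks=((pos, pos + rl),),
                    mapped=True,
                    proper_pair=True,
                    is_read1=which == 0,
                    base_quality_sum=int(q.sum()),
                )
            )
            seqs.append(seq)
            quals.append(q)

    # records were built pair-by-pair in fragment-start order; re-sort reads
    # themselves by coordinate for a coordinate-sorted stream
    sort_idx = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in sort_idx]
    seqs = [seqs[i] for i in sort_idx]
    quals = [quals[i] for i in sort_idx]

    truth = {
        "config": {
            k: (v if not isinstance(v, float) or np.isfinite(v) else "inf")
            for k, v in asdict(config).items()
        },
        "n_pairs": n,
        "n_duplicate_pairs": int(n_dup),
        "expected_duplicate_rate": n_dup / n if n else 0.0,
        "realized_on_target_pair_fraction": float(
            (np.concatenate([on_target, on_target[dup_of]]) if n_dup else on_target).mean()
        )
        if n
        else 0.0,
        "realized_median_insert": float(np.median(frag_insert)),
        "duplicate_pair_names": [f"frag{int(i):07d}" for i in range(n_unique, n)],
    }
    return SimulatedExperiment(config, records, design, annotation, truth, seqs, quals)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def simulate_variants(
    n: int,
    tstv_target: float,
    region: IntervalSet,
    seed: int = 0,
    vcf_path: str | Path | None = None,
) -> list[VariantRecord]:
    """Simulate SNVs with transitions at probability tstv/(1+tstv).

    Positions are unique within the region; at tstv_target = 0.5 the
    substitution mixture is uniform over the 12 ordered base changes.
    Optionally writes a minimal VCF v4.2.
    """
    if tstv_target <= 0:
        raise ValueError("tstv_target must be positive")
    if n > region.total_bases:
        raise ValueError(
            f"{n} variants requested but region has only {region.total_bases} bases"
        )
    rng = np.random.default_rng(seed)
    # flat index over region bases -> (chrom, pos)
    base_map: list[tuple[str, int, int]] = []  # (chrom, start, end)
    for iv in region:
        base_map.append((iv.chrom, iv.start, iv.end))
    lens = np.array([e - s for _, s, e in base_map])
    offsets = np.concatenate([[0], np.cumsum(lens)])
    flat = rng.choice(int(lens.sum()), size=n, replace=False)
    flat.sort()
    p_ts = tstv_target / (1.0 + tstv_target)
    refs = rng.integers(0, 4, size=n)
    is_ts = rng.random(n) < p_ts
    tv_pick = rng.integers(0, 2, size=n)
    bases = "ACGT"
    variants = []
    for i in range(n):
        j = int(np.searchsorted(offsets, flat[i], side="right") - 1)
        chrom, s, _ = base_map[j]
        pos0 = s + int(flat[i] - offsets[j])
        ref = bases[refs[i]]
        alt = _TRANSITION[ref] if is_ts[i] else _TRANSVERSIONS[ref][tv_pick[i]]
        variants.append(VariantRecord(chrom, pos0 + 1, ref, (alt,), True))
    if vcf_path is not None:
        _write_vcf(variants, region, vcf_path)
    return variants


def _write_vcf(variants: Sequence[VariantRecord], region: IntervalSet, path: str | Path) -> None:
    chrom_max: dict[str, int] = {}
    for iv in region:
        chrom_max[iv.chrom] = max(chrom_max.get(iv.chrom, 0), iv.end)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kiteval-simulate\n")
        for chrom, ln in sorted(chrom_max.items()):
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\n"
            )
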