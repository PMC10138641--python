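"""Transition/transversion ratio from variant calls.

The Ts/Tv ratio is an aggregate indicator of variant-call quality: random
base-calling errors push it toward the uniform-substitution limit of 0.5,
while genuine human variation sits near 2 genome-wide and a little above 3 in
coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .intervals import IntervalSet

__all__ = [
    "VariantRecord",
    "classify_substitution",
    "tstv_ratio",
    "read_vcf",
]

_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    filter_pass: bool = True


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G and C<->T, 'transversion' for the other eight."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def tstv_ratio(
    variants: Iterable[VariantRecord],
    region: IntervalSet | None = None,
    include_filtered: bool = False,
) -> float | None:
    """Ts/Tv over SNVs, optionally restricted to a region.

    Multi-allelic records are decomposed per alt allele; indels and MNVs are
    ignored; filter-failed records are excluded unless ``include_filtered``.
    Returns None (undefined) when no transversion qualifies.
    """
    ts = tv = 0
    for v in variants:
        if not v.filter_pass and not include_filtered:
            continue
        if region is not None and not bool(
            region.contains(v.chrom, [v.pos - 1])[0]
        ):
            continue
        if len(v.ref) != 1 or v.ref.upper() not in _BASES:
            continue
        for alt in v.alts:
            if len(alt) != 1 or alt.upper() not in _BASES or alt.upper() == v.ref.upper():
                continue
            if classify_substitution(v.ref, alt) == "transition":
                ts += 1
            else:
                tv += 1
    if tv == 0:
        return None
    return ts / tv


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read VCF v4.x (optionally bgzipped) via cyvcf2."""
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        out.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                filter_pass=v.FILTER is None,  # cyvcf2: None means PASS/'.'
            )
        )
    return out
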