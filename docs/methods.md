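# Methods

## Coordinates and interval algebra

All genomic arithmetic uses the BED convention (0-based, half-open);
SAM/GTF 1-based positions are converted at ingestion. An `IntervalSet` is
canonical: sorted by (chrom, start) and merged, with abutting intervals
coalesced, so `total_bases` is exactly the union size and set operations are
well defined regardless of input fragmentation. Multi-way design
intersection sweeps the breakpoint set of all designs per chromosome;
membership is constant between breakpoints, so exclusive-subset base counts
are exact and sum to the union size by construction.

Design partition assigns every targeted base to exactly one category with
precedence **CDS > UTR > intron > intergenic** when transcripts disagree
(e.g. a base coding in one isoform and intronic in another). This precedence
is required for the four counts to be disjoint and to sum to the design
size; CDS-first reflects the clinical emphasis on coding sequence. All
transcripts of a gene contribute by default — restricting to one canonical
transcript per gene is possible by filtering the `GeneModel` list before the
call, but no canonical-transcript table is bundled.

Gene panels are built as the union of all exons of all transcripts of the
listed symbols, each exon padded by 25 bp (default) on both sides to capture
canonical splice sites, clamped at position 0. Chromosome-length clamping is
not applied unless lengths are known to the caller (pad first, intersect
with a genome-wide set if needed). Unknown symbols are returned explicitly,
never dropped silently.

## Sample metrics

**Insert size** is the median (and mean) of |TLEN| over proper pairs,
counting each pair once and excluding |TLEN| = 0 or > 2000 bp; the cutoff
(configurable) keeps the median robust against chimeric pairings while being
far above any plausible fragment from a 200–250 bp library. The mate
overlap for 2×L bp reads is max(0, 2L − insert).

**Duplicate marking** uses the coordinate key
(chrom, unclipped 5′ end, strand) of *both* mates, with the two ends
order-normalised; unpaired reads fall back to a single-end key. Within a
key group, the pair with the highest summed base quality is kept (ties:
first encountered, so output is deterministic for identical input); the
duplicate rate is flagged mapped reads over mapped reads. Optical-duplicate
subclassification is out of scope — synthetic data carries no flowcell
geometry.

**On-target rate** counts aligned bases (CIGAR M/=/X blocks) inside the
target over all aligned bases of mapped primary reads, duplicates included
(the denominator is what the sequencer produced). Soft-clipped bases and
deleted reference positions do not contribute. No near-target padding is
applied by default. Secondary and supplementary alignments are excluded
from every metric.

**Depth profiles** are per-base pileups over target bases (zeros included),
computed via difference arrays per chromosome — O(reads + span) and exact
against a per-base counting oracle. Coverage rate at nX is inclusive
(depth ≥ n): a base at exactly 30X counts as "covered at 30X".

**Uniformity.** The fold-80 base penalty is mean depth divided by the
20th-percentile depth, with the percentile taken at ascending rank
⌈0.2·N⌉ over all target bases so that at least 80% of bases sit at or above
it; it is 1.0 exactly iff coverage is constant, and is reported as
undefined (None) rather than infinite when the percentile is zero. The
evenness score defaults to the truncated-mean form
E = 100·Σ min(dᵢ, C)/(C·N), C = mean depth: the fraction of the ideal
uniform read mass retained after discarding depth above the mean. A
discrete variant (mean over i = 1..round(C) of the fraction of bases ≥ i)
is available behind `method="discrete"`; both are 100 exactly at uniformity,
bounded by 100, and invariant to scaling all depths by a constant (the
discrete form up to the rounding of C). Both are implemented because the
score is cited in the field without a single canonical formula.

**Ts/Tv** counts transitions (A↔G, C↔T) over transversions across
biallelic-decomposed SNVs; indels and MNVs are ignored and filter-failed
records excluded by default. Uniform random substitutions give 0.5 in
expectation (4 of 12 ordered changes are transitions); genuine human
variation sits near 2 genome-wide and a little above 3 in CDS, which is why
the ratio serves as an aggregate call-quality indicator. An optional region
restriction supports the CDS-vs-whole-design contrast; results are reported
both ways because published kit tables rarely state which was used.

## Effort curves and minimal effort

Downsampling selects read pairs (never splitting mates) uniformly without
replacement with a seeded generator; identical input and seed give identical
output. Effort curves default to *nested* subsampling — one permutation,
prefixes per effort — so rates are monotone non-decreasing in effort by
construction, with an independent-per-effort mode available to mimic
independent FASTQ subsampling. Curves are computed after duplicate
re-marking on each subsample, on dedup depth by default (a with-duplicates
mode exists). Efforts are counted in read pairs internally; published
"M reads" labels are carried through as labels. `minimal_effort` returns the
smallest grid effort whose rate at the requested depth meets the
requirement, or None ("not reached") — it does not interpolate between grid
points.

## Thresholds and reporting

Boundary semantics follow the wording of the underlying rules: ">" and
"under" are strict (a duplicate rate of exactly 20% fails "under 20%", a
Ts/Tv of exactly 2.4 fails "> 2.4"), "at least"/"≥" are inclusive. Insert
size, fold-80 and evenness carry no hard bound (the acceptable value is
method- and library-dependent) and are reported as advisory. The known
tension that well-regarded kits sit at 72–74% on-target against an "> 80%"
rule is preserved: the verdict records the fail, and interpretation is left
to the ranking, which by default orders kits by (1) total threshold
failures, (2) mean duplicate rate, (3) minimal effort to 90% at 30X — the
factors that actually discriminate kits in practice — rather than inventing
a composite score. Per-column best markers are only placed where a
direction of merit exists (insert size and Ts/Tv have none). Report floats
use fixed formats so regeneration from identical inputs is byte-identical.

Run-level metrics (cluster density, %PF, PhiX%) are ingested as
sequencer-reported — recomputing them needs raw instrument data with no
public format — while Q30 is also recomputable from FASTQ (Phred+33,
inclusive at Q30); a discrepancy above 2 points between reported and
recomputed Q30 triggers a warning. The Q30 bound is overridable for
degraded-DNA (e.g. FFPE) contexts. The PhiX "ideal ~1%" is informational;
only the ≥0.3% bound is enforced.

## Synthetic data

The generator emulates a paired-end 2×150 bp capture library on a toy
genome (default: two chromosomes totalling 1 Mb, a 20% target in 2.5 kb
intervals). Its defaults mirror a realistic mid-size exome library:
fragment length Normal(206, 30) truncated to [read length, 2 kb], 12%
duplicate pairs, 26% off-target fragments, uniform capture, 85% of bases at
Q ≥ 30. Fragments are placed fully inside one target interval (probability
1 − off-target fraction, interval chosen ∝ length × a gamma(k, 1/k)
efficiency multiplier — k → ∞ is uniform capture, small k skews coverage)
or fully outside the target, so the injected on-target fraction equals the
base-level on-target rate exactly. Exactly round(n·d) of the n pairs are
duplicates: re-emissions of a unique fragment (chosen with replacement)
at identical coordinates with fresh qualities, and unique fragments are
guaranteed distinct coordinate keys, so the marked duplicate rate recovers
d up to rounding. Alignments are generated directly — no mapper in the
loop — with consistent CIGAR/TLEN, and all outputs (SAM, FASTQ, BED, GTF,
VCF, truth JSON) are byte-identical under a fixed seed.

What the simulator does **not** model: sequencing errors and indels (beyond
quality strings), soft-clipping, GC and probe-thermodynamic bias, optical
duplicates, repeat regions or real genome sequence. Passing parameter
recovery therefore validates the metric implementations and their
plumbing, not robustness to mapper artefacts on real data. Two finite-depth
effects are worth knowing when interpreting uniformity on simulated data:
per-base depth at mean C carries Poisson-like noise, putting the evenness
expectation near 100·(1 − 1/√(2πC)) rather than 100; and because fragments
sit fully inside intervals, coverage ramps over roughly one insert length
at each interval edge, which lowers evenness further for short intervals.
Both vanish only in the deep-coverage, long-interval limit, which is how
the asymptotic uniformity checks are constructed.

## Problem sizes in the test suite

The shared simulated fixture uses 5,000 read pairs on the 1 Mb toy genome;
parameter-recovery checks run one 50,000-pair experiment (duplicate and
on-target fractions recovered within ±0.01 absolute, median insert within
±2 bp) and 20,000 simulated SNVs (Ts/Tv within ±0.05 at the fixed seed;
the binomial sd of the ratio at that n is ≈0.043, so seed-robust unit tests
use a 3σ band). Oracle-equivalence suites run 200 randomised trials against
per-base brute-force counting on genomes ≤ 10 kb. These sizes were chosen
so the whole suite completes in well under a minute while keeping Monte
Carlo tolerances meaningful.
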