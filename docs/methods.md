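# Methods

## The distance model

OTU inference here rests on a pairwise genetic distance designed for
circular-consensus (CCS) long reads. Each pair of reads is aligned
globally (Needleman–Wunsch) under affine gap scoring; the alignment is
then post-processed in two steps before any differences are counted:

1. **Terminal gap stripping.** Leading and trailing columns covered by
   a terminal gap run in either row are removed. Terminal gaps reflect
   differences in sequenced fragment length (e.g. a trimmed read
   against a full amplicon), not sequence divergence, and would
   otherwise dominate the distance.
2. **Single-base indel removal.** Internal gap runs of length exactly
   one are deleted from both rows. Isolated 1-bp insertions/deletions
   are the dominant residual error of CCS consensus calling, and
   counting them as differences systematically inflates OTU numbers at
   thresholds of a few percent. Gap runs of length ≥ 2 are kept: they
   are far more likely to be genuine indel variation. Run structure is
   taken from the input alignment in a single pass, so a deletion that
   creates new adjacencies does not trigger further removals.

The distance is

    d = (mismatches + indel events) / examined columns

with the following conventions:

* every surviving gap run counts **once** as an indel event, and its
  columns are **collapsed to one** examined column, so a k-base indel
  and a single substitution carry equal weight. The alternative
  convention — full run length in the denominator — is available via
  `Scoring(collapse_gap_runs=False)`; the two interpretations are both
  defensible readings of "each indel counted once" and the collapsed
  form is the default because it makes the event weighting explicit;
* columns containing N in either row are excluded from numerator and
  denominator. Merged-pair spacers (see below) are removed entirely
  before alignment;
* d is clipped into [0, 1] (the clip can only engage on pathological
  inputs, e.g. alignments that are mostly gap runs).

An MSA-based variant (`msa_distance`) computes, for each pair of rows
of a multiple sequence alignment, the fraction of differing sites among
columns where both rows carry a plain base. It exists for comparison;
on benchmark data the pairwise-alignment distance clusters better.

### Alignment scoring and determinism

Defaults are the EDNAFULL-style match +5 / mismatch −4 with gap open 10
and gap extend 0.5; a gap run of length k costs `open + (k−1)·extend`.
All four parameters are configurable. Traceback ties are resolved with
a fixed diagonal > up > left priority, and the reported alignment is
therefore identical across runs and platforms. N scores 0 against
anything (neutral); since N columns are excluded from the distance this
only affects gap placement near N runs.

The dynamic program (three-state Gotoh) is JIT-compiled and keeps
scores in rolling rows, storing only byte-sized traceback matrices. An
optional diagonal **band** (half-width beyond the length difference,
`band=−1` = full matrix) restricts the DP. Banding is exact whenever
the optimal path stays inside the band, which holds for same-locus
amplicons whose indel imbalance is far below the band width; the test
suite checks band/full agreement on mutated pairs. The benchmark
recipes use band 50–60 for roughly an order-of-magnitude speedup; for
arbitrary inputs the full matrix remains the default.

Strand orientation (`orient`) aligns each read and its reverse
complement against an anchor panel (by default sampled from the input
itself) and keeps the better strand, with ties keeping the input
orientation. This replaces an external-database search with the same
contract and no download.

The all-versus-all matrix is computed in memory and exported as a
lower-triangular TSV; at the problem sizes this package targets
(thousands of reads) the full matrix is small, so no on-disk triangular
store is used. The `jobs` parameter distributes pairs over a thread
pool (the kernel releases the GIL) and is guaranteed not to change the
result.

## Clustering

Agglomerative clustering is implemented directly (complete, average and
single linkage via Lance–Williams updates) rather than delegated, for
one reason: deterministic tie-breaking. Among equal-height candidate
merges, the pair whose clusters hold the lexicographically smallest
member ids merges first, which makes the dendrogram independent of
input order even with tied distances. On tie-free matrices the merge
heights coincide with SciPy's implementation (tested).

Complete linkage is the default: an OTU cut at height h then never
contains two sequences more distant than h, which is the property that
lets a cut height be read as "100·(1−h) % sequence similarity". Cuts
are inclusive (merges at height ≤ h are kept), so "3 % similarity"
admits dissimilarity exactly 0.03. OTU labels are assigned by
decreasing OTU size as `OTU_1, OTU_2, ...`; size ties are ordered by
the smallest member id (a proxy that needs no distance matrix at
labelling time). The number of clusters is non-increasing in h, and
heights are non-decreasing along the merge sequence for all three
linkage rules.

OTU tables are per-OTU × per-sample read counts; `normalized()` gives
per-sample relative abundances and `zscored()` the per-sample
centered/scaled variant used for heat-map display. The minimum-support
filter keeps OTUs with ≥ 10 reads by default (inclusive). OTU
representatives minimize the mean distance to the other members, with
singletons representing themselves and exact ties resolved
lexicographically.

### Mixed-technology analysis

`hybrid_analysis` trims long CCS reads to the short-read region (fixed
read coordinates or an IUPAC primer pair; reads lacking the region are
dropped and counted), sub-samples the short reads to the CCS count
(seeded), pools the two sets, clusters once, and classifies every OTU
with enough support as shared or technology-specific. For the shared
OTUs richest in CCS reads, the *full-length* CCS members are
re-clustered at the same threshold: more than one resulting cluster
means the long reads resolve sub-OTUs invisible at short-read length.
The quality diagnostic compares mean per-read quality between small and
large OTUs (two-sample KS and Welch t statistics, reporting only); a
missing group is flagged rather than an error.

The pass-count binning experiment is a composition of existing
operations rather than a bespoke one: partition CCS reads by `passes`
(e.g. bins [3,9), [9,15), [15,24), ≥24), draw equal-size subsamples
with `subsample_records`, and cluster each bin separately.

## The simulator

The synthetic reference database reproduces the statistical *shape* of
a curated full-length 16S collection, not its sequences: a random root
is mutated into genus ancestors (default divergence 0.10 per site) and
each into genomes (default 0.03), at 1550 bp so that all amplicon
intervals fit. These defaults put congeneric genomes a few percent
apart and genera ~15–20 % apart, which is what makes 1–6 % thresholds
meaningful. Database hygiene mirrors standard practice: exact
duplicates removed, length > 1400 bp enforced, genera with more than
1000 genomes down-sampled to 100.

Mock communities sample 100/250/500 genomes (low/medium/high
complexity; an explicit count is accepted for scaled runs) without
replacement, 10 replicates per level by default. Amplicons are cut at
fixed alignment intervals per technology — 389–801 (V4, 2×150),
227–801 (V3–V4, 2×250 and 450 bp CCS), 4–801 (V1–V4, 750 bp CCS),
4–1506 (V1–V6, 1450 bp CCS) — or located by degenerate primer pairs on
either strand for arbitrary references.

**CCS reads**: per-read accuracy ~ Normal(0.99, 0.01), truncated (not
resampled) at 1.0 and floored just above 0; the error count is
Binomial(L, 1−accuracy); error types are drawn
mismatch:insertion:deletion = 6:21:73 and placed uniformly. Qualities
are flat at the phred equivalent of the drawn accuracy, and a pass
count is annotated through a simple monotone map of accuracy — the map
is synthetic, present only so pass-binning recipes can be exercised.
**Short reads**: the two amplicon ends are read with a substitution
rate rising linearly from 0.1 % (5') to 1 % (3' of each mate) — a
deliberately simple monotone stand-in for a learned platform profile —
and merged with a 10-base N spacer (spacer positions carry quality 0
and a recorded interval honored by every downstream per-base
statistic). Each genome is down-sampled to exactly 20 reads, and every
read set is shuffled (seeded) before clustering so input order cannot
influence results. Reads are generated at the target depth directly
rather than over-generated and discarded.

What the simulator does **not** emulate: chimeras, per-cycle quality
structure of real short-read runs, length-dependent CCS pass/accuracy
coupling, primer-site mutations, and abundance skew (every genome is
equally deep). Passing benchmarks therefore demonstrate the pipeline's
behaviour under idealized error structure, not performance on real
biopsy data.

## Evaluation

The adjusted Rand index follows the Hubert–Arabie form computed from
the contingency table. Degenerate conventions: a 1×1 table (both
partitions one cluster) scores 1; any other case where the expected
index equals the maximum index (e.g. both partitions all singletons)
scores 0. Precision is size-weighted cluster purity; recall is
size-weighted class integrity; both reduce to 1 on perfect clustering.
`threshold_sweep` clusters once and cuts at every threshold, reporting
OTU counts, singleton counts, ARI, precision, recall and the
best-ARI row; medians across replicates use the mean-of-middle
convention for even counts. A least-squares ARI~read-length helper is
provided for reporting; it is routine statistics, not part of the
method.

## Problem sizes and numerical choices

The shipped benchmark recipes are scaled to desk hardware as the
package's own defaults: the bookkeeping harness runs the full printed
configuration (100,000 reads at low complexity, 500,000 at high) but
streams read sets to a sink so memory stays bounded, and the
directional comparison uses 3 replicates × 25 genomes × 5 reads per
genome with a band of 60, which preserves the qualitative contrast
between full-length CCS and merged 2×150 reads while keeping the
all-versus-all alignment stage to a few minutes. Distances are exact
float64; equality ties in clustering are broken by id as described; all
random draws go through NumPy generators seeded explicitly, and every
CLI run records its seeds in a manifest.

## Known limitations

* The banded alignment is heuristic for highly divergent pairs (it may
  overestimate their distance slightly); this cannot move distances
  across the 1–6 % thresholds of interest.
* The agglomeration is O(n³) worst case with an O(n²) memory matrix;
  it targets the tens of thousands of reads regime, not millions (no
  k-mer prefilter is provided).
* Chimera detection is out of scope; the preprocessing accepts an
  externally computed per-read score table via the quality-filter
  interfaces rather than implementing detection.
* The entropy module consumes a pre-computed alignment; producing a
  secondary-structure-aware MSA is out of scope.
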