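# longotu

Long-read-aware OTU picking for 16S rRNA amplicon data.

Clustering short 16S reads into operational taxonomic units (OTUs) is
hampered by the fact that a short amplicon sees only one or two
hypervariable regions of the gene. Circular-consensus (CCS) long reads
span many more of them, but carry a characteristic error mode — isolated
single-base insertions and deletions — that inflates naive distance
estimates and therefore OTU counts. `longotu` implements an OTU
inference pipeline built around that observation, together with the
simulation machinery needed to benchmark it, for microbiome researchers
working with mixed short-read (merged paired-end) and CCS amplicon data.

## Method

For every pair of reads, a global Needleman–Wunsch alignment with
affine gap costs (match +5, mismatch −4, gap open 10, gap extend 0.5)
is post-processed by

1. stripping terminal alignment gaps, and
2. deleting internal gap runs of length exactly one (the dominant CCS
   consensus error),

and converted to a genetic distance

```
d = (mismatches + indel events) / examined columns
```

where each surviving multi-base gap run counts once as an indel event
and occupies a single examined column, so a k-base indel weighs the
same as one substitution. Columns with N in either row are excluded.
The resulting dissimilarity matrix is clustered agglomeratively
(complete linkage by default, so every OTU cut at height *h* has
diameter ≤ *h*), and cutting the tree at dissimilarities 0.01–0.06
yields OTUs at 1–6 % sequence-similarity thresholds. Downstream
utilities cover OTU tables with per-sample normalized abundances,
minimum-support filtering (≥10 reads by default), representative-
sequence selection (minimum mean intra-OTU distance), mixed-technology
"hybrid" OTU analysis with full-length sub-OTU refinement, Shannon
entropy profiling of hypervariable regions, and adjusted-Rand-index
(ARI) evaluation against simulation ground truth.

## Worked example

Simulate a 10-genome mock community, cluster full-length CCS reads and
score the result against the genome-of-origin truth:

```python
from longotu.mocksim import synth_reference_db, build_mocks, simulate_community_reads
from longotu.align import distance_matrix
from longotu.evaluate import threshold_sweep

db = synth_reference_db(n_genera=8, genomes_per_genus=5, seed=11)
mock = build_mocks(db, complexity=10, n_replicates=1, seed=7)[0]
reads = simulate_community_reads(mock, "ccs_1450", reads_per_genome=5, seed=3)
dm = distance_matrix(reads, band=60)
print(threshold_sweep(dm, mock.truth).to_string(index=False))
```

```
   h  n_otus  n_singletons      ari  precision  recall  best
0.01      11             1 0.977818        1.0    0.98 False
0.02      10             0 1.000000        1.0    1.00  True
0.03      10             0 1.000000        1.0    1.00 False
0.04      10             0 1.000000        1.0    1.00 False
0.05      10             0 1.000000        1.0    1.00 False
0.06      10             0 1.000000        1.0    1.00 False
```

At a 1 % threshold the residual CCS error still splits one genome into
two OTUs (11 OTUs, one singleton, ARI 0.98); from 2 % on, the 10
genomes are recovered exactly (ARI = 1, cluster purity and per-genome
recall both 1).

The same pipeline is available from the shell:

```bash
longotu simulate --complexity 10 --replicates 1 --technologies ccs_1450 \
    --reads-per-genome 5 --seed 3 --outdir sim/
longotu dist --input sim/n10_rep00_ccs_1450.fastq --band 60 --out d.tsv
longotu cluster --dist d.tsv --h 0.03 --min-reads 10 --outdir otus/
longotu evaluate --dist d.tsv --truth sim/n10_rep00_ccs_1450.truth.tsv --out report.tsv
```

Other subcommands: `preprocess` (pair merging, quality/length filters,
barcode demultiplexing), `entropy` (windowed Shannon-entropy profile of
an alignment) and `hybrid` (joint short+long OTU inference with
sub-OTU refinement).

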