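# Methods

## Model and assumptions

covsketch estimates the per-sample depth of assembled contigs from k-mer
multiplicities instead of read alignments. The underlying model is the
standard Poisson shotgun-coverage model: for a contig truly present in a
sample at fold-coverage λ, the number of reads covering a given k-mer
position is approximately Poisson with rate λ·(R−k+1)/R, where R is the
read length (a read of length R covers R−k+1 k-mer start positions per
base position). Multiplicities of the contig's k-mers in the sample's read
set are therefore treated as (zero-truncated, since only matched k-mers
are observed) Poisson draws at the k-mer coverage rate, contaminated by
three real-world effects the estimators are built to resist: sequencing
errors (which thin true k-mers and create spurious low-count ones),
repeats and mobile elements (which inflate a minority of counts far above
the rate), and inter-sample strain divergence (which removes k-mers
entirely).

## Sketching

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement over {A,C,G,T}; windows containing any other character are
skipped, counting resumes at the next valid window) are subsampled by the
FracMinHash rule: keep a k-mer iff its 64-bit hash is strictly below
⌊2⁶⁴/c⌋. Because the rule depends only on the hash, the same k-mers are
sampled in reads and contigs, so containment can be computed table-free.
The hash is a seeded splitmix64-style finalizer applied to the 2-bit
encoding of the canonical k-mer: uniform enough that the kept fraction is
Binomial(·, 1/c) to high accuracy (property-tested), deterministic, and
portable; the seed is recorded in the sketch parameters and sketches are
only comparable when k, c and seed all agree — enforced with a hard error.
On the 2-bit encoding (A=0 < C=1 < G=2 < T=3), integer order equals
lexicographic order, so canonicalization is a single vectorized minimum.

Defaults: k = 31 (large enough that random 31-mer collisions between
unrelated genomes are negligible, small enough to tolerate ~1% divergence
and sequencing error; the conventional species-level containment choice),
c = 50 (samples ≈ 1/50 of k-mer space, about 1000 sampled k-mers on a
50 kb contig), hash seed 42. Reads are used as-is: no quality filtering,
no deduplication, no error correction.

## Presence calling

With N sampled contig k-mers and X of them found in the sample, the
containment ANI is (X/N)^(1/k) — under an independent-site divergence
model a contig at nucleotide identity *a* retains a fraction ≈ a^k of its
k-mers, so the k-th root recovers *a*. A contig is present iff X ≥ 8
(checked first, short-circuiting the ANI computation) and ANI ≥ 0.95, a
species-level boundary; otherwise depth and variance are 0. Both gates are
configurable (`--min-kmers`, `--min-ani`).

At low coverage, k-mers are missing because of shallow sampling rather
than divergence: the expected naive containment is a^k·(1−e^(−λ)). The
optional `--ani-adjust` mode divides the containment by 1−e^(−λ̂) (clamped
at 1) before taking the root, using the Poisson λ̂ below. It is off by
default because the naive estimate is already conservative in the right
direction for binning: at the coverages where the adjustment matters
(λ ≲ 0.4 per k-mer), depth estimates are too noisy to help a binner much,
and the default keeps the presence test a pure function of the match
fraction. Contigs shorter than k, or with zero sampled k-mers through
unlucky subsampling, are reported absent (depth 0) in every sample so
binners still see one row per contig.

## Depth estimation

Let M be the median matched multiplicity (mean of the middle two for even
sizes). Three regimes:

* **M ≤ 3 (Poisson regime).** λ̂ = 2·N₂/N₁, where N₁ and N₂ are the
  numbers of matched k-mers seen once and twice. For Poisson counts
  P(2)/P(1) = λ/2 identically, and the ratio is unchanged by zero
  truncation, which is exactly the defect of the naive mean at low
  coverage. Only the two lowest count bins are used, so repeat-inflated
  counts cannot leak in. If N₁ = 0 (impossible for genuinely low-coverage
  data except in degenerate tiny inputs) the plain mean is the fallback.
* **4 ≤ M ≤ 15 (robust mean).** The mean after discarding the largest
  ⌈0.1·n⌉ counts. The 10% trim mirrors the variance computation's
  90th-percentile cut; at these coverages the zero-truncation bias is
  already negligible (e^(−4) < 2%).
* **M > 15 (median).** The median itself; at high coverage it is an
  efficient, outlier-proof location estimate.

**Scale conversion.** The estimators above work on the k-mer multiplicity
scale. Binner depth files are on the per-base scale, so the result is
multiplied by R/(R−k+1) with R the sample's mean read length (recorded in
the sketch); the variance is multiplied by the square. For R = 150 and
k = 31 the factor is 1.25 — without it every depth would sit 20% low.
When R ≤ k (degenerate) the factor is 1.

**Variance.** Unbiased sample variance of the matched multiplicities after
sorting and dropping ⌊0.1·n⌋ values from each end. Fewer than two
surviving values give variance 0. Trimming both tails (rather than
bounding by nearest-rank percentile values) is what "removing the 10th and
90th percentile outliers" has to mean for small integer count lists: it
guarantees the extreme observations themselves are excluded regardless of
ties.

## Output

The MetaBAT2 `jgi_summarize_bam_contig_depths` layout: header
`contigName contigLen totalAvgDepth` followed by a depth and `-var` column
per sample, rows in assembly FASTA order, columns in sample input order,
`totalAvgDepth` the arithmetic mean of the row's depths. Numbers are
rendered at 6 significant digits with trailing zeros trimmed, making
output byte-deterministic. SemiBin2 accepts this file directly; MaxBin2
compatibility is a set of headerless two-column abundance files plus a
manifest (`--format maxbin2`). No third format exists.

## Work shape and concurrency

Each sample's reads are sketched exactly once per run regardless of the
number of assemblies (asserted by instrumented counters in the tests);
sketches persist to disk in a little-endian, magic-byte, versioned
container that round-trips bit-exactly and refuses unknown versions rather
than partially loading. Query parallelism is over per-sample columns with
plain threads; the contract is that results are byte-identical for any
worker count, which holds because each column is placed by index.

## Synthetic data

The simulator generates uniform random genomes, strain variants by
independent per-site substitution (probability 1 − target identity, to a
uniformly chosen different base — no indels), and reads with uniform start
positions on a circularized genome, uniform strand, and i.i.d. substitution
errors, so per-k-mer depth is Poisson(λ·(R−k+1)/R) with no edge effects.
Default test conditions follow the recovery checks: 50 kb genomes, 150 bp
reads, 0.1% error, c = 50, coverages 0.5–50×, 20 replicate seeds, and a
4-genome × 3-sample community with a known abundance matrix for the
end-to-end correlation and separability checks (problem sizes chosen so
each sampled contig carries ≈ 1000 k-mers, enough that subsampling noise
is a few percent).

What the simulator does **not** emulate — and hence what passing tests do
not show: real base-composition bias and GC-dependent coverage, indel and
homopolymer errors (long-read data), PCR duplicates, shared genes and
mobile elements between community members, and strain mixtures within a
sample. In particular, strain-resolved long-read assemblies can place two
>95%-identity strains in one sample, where the species-level ANI gate will
call both present; raising `--min-ani` trades that against multi-sample
sensitivity, and no HiFi-specific mode is provided.

## Numerical and design notes

* Keep-rule uses strict `<` against ⌊2⁶⁴/c⌋; c = 1 keeps everything.
* Median of an even count list: mean of the middle two order statistics;
  regime boundaries (M = 3/4, 15/16) are unit-tested on both sides.
* Unmatched (zero-multiplicity) k-mers never enter M, the trimmed mean, or
  the variance; absence is handled entirely by the containment gate.
* Ties in trimming are resolved by sort order, i.e. exactly n−⌈0.1·n⌉
  (depth) or n−2⌊0.1·n⌋ (variance) values survive regardless of ties.
* Sample names are read-file basenames with compression/format suffixes
  stripped; basename collisions are an error because depth columns would
  be ambiguous.
* Duplicate contig names within an assembly are a hard error (rows key on
  them).
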