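"""Presence calling and depth estimation for one contig against one sample.

A contig is called present in a sample when enough of its sampled k-mers are
found in the sample's table (minimum matched k-mers) and the containment ANI
— the k-th root of the matched fraction, an alignment-free estimate of the
average nucleotide identity between the contig and the sample's reads —
clears a species-level threshold (default 95%).  Absent contigs get depth 0.

For present contigs, depth follows a three-regime estimator keyed on the
median matched k-mer multiplicity M:

* M <= 3 (low coverage): a Poisson ratio estimator, lambda = 2*N2/N1, using
  the singleton and doubleton multiplicity bins, which is insensitive to the
  zero-truncation inherent in "matched" counts.
* 4 <= M <= 15: mean of the matched counts after trimming the largest 10%,
  robust to repeat-driven high counts.
* M > 15: the median itself.

The k-mer multiplicity scale is converted to per-base fold coverage using
the sample's mean read length (a read of length R contributes R-k+1 k-mer
positions per base position, so k-mer coverage underestimates base coverage
by (R-k+1)/R); the reported variance is the trimmed sample variance of the
matched multiplicities on the same per-base scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sketch import ContigSketch, SampleSketch, SketchParams

REGIME_ABSENT = "absent"
REGIME_POISSON = "poisson"
REGIME_ROBUST_MEAN = "robust_mean"
REGIME_MEDIAN = "median"

DEFAULT_MIN_KMERS = 8
DEFAULT_MIN_ANI = 0.95
ROBUST_TRIM_FRACTION = 0.1


@dataclass(frozen=True)
class QueryThresholds:
    """Presence-absence gates for a contig x sample query.

    min_kmers: minimum matched sampled k-mers before any coverage is
        computed (default 8).
    min_ani: containment-ANI presence threshold as a fraction (default
        0.95, a species-level boundary).
    ani_adjust: when True, divide the containment by the Poisson detection
        probability 1 - exp(-lambda) before the k-th root, compensating for
        k-mers missed purely through shallow coverage.
    """

    min_kmers: int = DEFAULT_MIN_KMERS
    min_ani: float = DEFAULT_MIN_ANI
    ani_adjust: bool = False

    def __post_init__(self) -> None:
        if self.min_kmers < 1:
            raise ValueError("min_kmers must be >= 1")
        if not (0.0 < self.min_ani <= 1.0):
            raise ValueError("min_ani must be in (0, 1]")


@dataclass
class ContainmentResult:
    """Match statistics and presence verdict for one contig x sample pair."""

    n_total: int
    n_matched: int
    counts: np.ndarray
    lambda_hat: float | None
    ani: float
    present: bool


@dataclass
class CoverageEstimate:
    """Depth and variance for one contig x sample pair."""

    depth: float
    variance: float
    regime: str
    M: float | None = None
    containment: ContainmentResult | None = None


def match_kmers(
    contig: ContigSketch, sample: SampleSketch
) -> tuple[int, np.ndarray]:
    """Look up a contig's sampled hashes in the sample table.

    Returns (n_total, counts) where counts holds the multiplicities of
    exactly the matched hashes; unmatched k-mers contribute nothing.
    """
    n_total = int(contig.kmer_hashes.size)
    if n_total == 0:
        return 0, np.empty(0, dtype=np.int64)
    hashes, table_counts = sample.sorted_table()
    if hashes.size == 0:
        return n_total, np.empty(0, dtype=np.int64)
    idx = np.searchsorted(hashes, contig.kmer_hashes)
    idx_clipped = np.minimum(idx, hashes.size - 1)
    hit = hashes[idx_clipped] == contig.kmer_hashes
    return n_total, table_counts[idx_clipped[hit]]


def containment_ani(
    n_matched: int, n_total: int, k: int, lambda_hat: float | None = None
) -> float:
    """Containment ANI: the k-th root of the matched k-mer fraction.

    With a finite lambda_hat, the containment is first divided by the
    Poisson detection probability 1 - exp(-lambda) (clamped to <= 1) so
    shallow coverage is not mistaken for sequence divergence.
    """
    if n_total <= 0:
        return 0.0
    containment = n_matched / n_total
    if lambda_hat is not None and math.isfinite(lambda_hat) and lambda_hat > 0:
        detect = 1.0 - math.exp(-lambda_hat)
        if detect > 0:
            containment = min(1.0, containment / detect)
    if containment <= 0.0:
        return 0.0
    return min(1.0, containment ** (1.0 / k))


def estimate_lambda(counts: np.ndarray) -> float | None:
    """Poisson coverage from the singleton/doubleton ratio.

    For Poisson counts, P(2)/P(1) = lambda/2, so lambda = 2*N2/N1; the
    ratio is unchanged by zero truncation.  Falls back to the plain mean
    when there are no singletons.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        return None
    n1 = int(np.count_nonzero(counts == 1))
    n2 = int(np.count_nonzero(counts == 2))
    if n1 > 0:
        return 2.0 * n2 / n1
    return float(np.mean(counts))


def effective_coverage(counts: np.ndarray) -> tuple[float, str, float]:
    """Three-regime depth on the k-mer multiplicity scale.

    Returns (depth, regime, M) where M is the median matched multiplicity.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("effective_coverage requires nonempty counts")
    m = float(np.median(counts))
    if m <= 3:
        depth = estimate_lambda(counts)
        regime = REGIME_POISSON
    elif m <= 15:
        n_trim = math.ceil(ROBUST_TRIM_FRACTION * counts.size)
        kept = np.sort(counts)[: counts.size - n_trim]
        # trimming everything can only happen for tiny count lists
        depth = float(np.mean(kept)) if kept.size else m
        regime = REGIME_ROBUST_MEAN
    else:
        depth = m
        regime = REGIME_MEDIAN
    return max(0.0, float(depth)), regime, m


def coverage_variance(counts: np.ndarray) -> float:
    """Sample variance of the matched multiplicities with both 10% tails
    trimmed (long-tailed outliers, e.g. mobile elements, are dropped)."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("coverage_variance requires nonempty counts")
    n_trim = int(math.floor(0.1 * counts.size))
    kept = np.sort(counts)[n_trim : counts.size - n_trim]
    if kept.size < 2:
        return 0.0
    return float(np.var(kept, ddof=1))


def read_length_correction(sample: SampleSketch) -> float:
    """Factor converting k-mer multiplicity coverage to per-base coverage.

    A read of length R covers R-k+1 k-mer start positions, so mean k-mer
    multiplicity is (R-k+1)/R of per-base depth; R is the sample's mean
    read length.  Degenerate read lengths (R <= k) get factor 1.
    """
    r = sample.mean_read_length
    k = sample.params.k
    if r <= k:
        return 1.0
    return r / (r - k + 1.0)


def query_containment(
    contig: ContigSketch,
    sample: SampleSketch,
    thresholds: QueryThresholds = QueryThresholds(),
    contig_params: SketchParams | None = None,
) -> ContainmentResult:
    """Match a contig against a sample and apply the presence gates.

    ContigSketch carries no params of its own; pass the owning assembly's
    params as ``contig_params`` to enforce comparability.
    """
    if contig_params is not None:
        contig_params.require_compatible(sample.params)
    n_total, counts = match_kmers(contig, sample)
    n_matched = int(counts.size)
    if n_matched < thresholds.min_kmers:
        return ContainmentResult(
            n_total=n_total,
            n_matched=n_matched,
            counts=counts,
            lambda_hat=None,
            ani=containment_ani(n_matched, n_total, sample.params.k),
            present=False,
        )
    lam = estimate_lambda(counts) if thresholds.ani_adjust else None
    ani = containment_ani(n_matched, n_total, sample.params.k, lambda_hat=lam)
    return ContainmentResult(
        n_total=n_total,
        n_matched=n_matched,
        counts=counts,
        lambda_hat=lam,
        ani=ani,
        present=ani >= thresholds.min_ani,
    )


def coverage_for_pair(
    contig: ContigSketch,
    sample: SampleSketch,
    thresholds: QueryThresholds = QueryThresholds(),
    contig_params: SketchParams | None = None,
) -> CoverageEstimate:
    """Full presence gate + depth + variance for one contig x sample pair.

    Absent contigs (too few matched k-mers, ANI below threshold, or no
    sampled k-mers at all) report depth 0 and variance 0.
    """
    containment = query_containment(contig, sample, thresholds, contig_params)
    if not containment.present:
        return CoverageEstimate(
            depth=0.0,
            variance=0.0,
            regime=REGIME_ABSENT,
            M=None,
            containment=containment,
        )
    depth_kmer, regime, m = effective_coverage(containment.counts)
    var_kmer = coverage_variance(containment.counts)
    factor = read_length_correction(sample)
    return CoverageEstimate(
        depth=depth_kmer * factor,
        variance=var_kmer * factor * factor,
        regime=regime,
        M=m,
        containment=containment,
    )
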