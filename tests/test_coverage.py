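"""Presence gating, containment ANI, and the three-regime depth estimator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import covsketch as cs
from covsketch.sketch import sketch_contig_sequence

from conftest import brute_force_kmer_counts


def make_pair(n_total: int, counts: list[int], params=None):
    """Synthetic contig/sample sketches with an exact match structure:
    the first len(counts) contig hashes are in the sample with the given
    multiplicities, the rest are unmatched."""
    params = params or cs.SketchParams()
    hashes = np.arange(1, n_total + 1, dtype=np.uint64)
    contig = cs.ContigSketch("ctg", 1000, hashes)
    table = {int(h): int(c) for h, c in zip(hashes, counts)}
    sample = cs.SampleSketch("s", params, kmer_counts=table)
    return contig, sample


class TestMatchKmers:
    def test_disjoint_sets(self):
        contig, _ = make_pair(10, [])
        sample = cs.SampleSketch("s", cs.SketchParams(), {10**6: 3})
        n_total, counts = cs.match_kmers(contig, sample)
        assert n_total == 10
        assert counts.size == 0

    def test_self_containment_at_c1(self, params_small):
        genome = cs.generate_genome(5_000, 12)
        contig = sketch_contig_sequence("g", genome, params_small)
        sample = cs.sketch_read_sequences([genome], params_small)
        n_total, counts = cs.match_kmers(contig, sample)
        assert n_total == contig.kmer_hashes.size
        assert counts.size == n_total

    def test_counts_match_bruteforce_read_occurrences(self, params_small):
        """At c=1, matched multiplicities equal exhaustive per-k-mer read
        occurrence counts for every sampled contig k-mer."""
        genome = cs.generate_genome(20_000, 13)
        contig = sketch_contig_sequence("g", genome, params_small)
        reads = cs.simulate_reads(genome, 3.0, 100, 0.0, seed=6)
        sample = cs.sketch_read_sequences(reads, params_small)
        _, counts = cs.match_kmers(contig, sample)

        oracle = brute_force_kmer_counts(reads, params_small.k)
        expected = []
        for kmer in brute_force_kmer_counts([genome], params_small.k):
            if oracle.get(kmer, 0) > 0:
                expected.append(oracle[kmer])
        assert sorted(counts.tolist()) == sorted(expected)

    def test_empty_contig(self):
        contig = cs.ContigSketch("tiny", 2, np.empty(0, dtype=np.uint64))
        sample = cs.SampleSketch("s", cs.SketchParams(), {1: 1})
        n_total, counts = cs.match_kmers(contig, sample)
        assert n_total == 0
        assert counts.size == 0


class TestContainmentAni:
    def test_full_containment(self):
        assert cs.containment_ani(1000, 1000, 31) == 1.0

    def test_empty_containment(self):
        assert cs.containment_ani(0, 1000, 31) == 0.0
        assert cs.containment_ani(0, 0, 31) == 0.0

    def test_closed_form_half(self):
        assert cs.containment_ani(500, 1000, 31) == pytest.approx(
            0.5 ** (1 / 31), abs=1e-9
        )

    def test_lambda_adjustment_boosts_and_clamps(self):
        naive = cs.containment_ani(500, 1000, 31)
        adjusted = cs.containment_ani(500, 1000, 31, lambda_hat=1.0)
        assert adjusted > naive
        # detection probability 1-e^-20 ~ 1: adjustment is a no-op
        assert cs.containment_ani(500, 1000, 31, lambda_hat=20.0) == pytest.approx(
            naive, abs=1e-4
        )
        # containment/detection > 1 clamps to ANI 1
        assert cs.containment_ani(900, 1000, 31, lambda_hat=0.5) == 1.0

    def test_mutated_contig_ani_recovery(self, params_default):
        """A contig at 98% identity to deeply sequenced reads reads out
        ANI ~ 0.98 (containment ~ 0.98^k under independent sites)."""
        genome = cs.generate_genome(50_000, 14)
        variant, realized = cs.mutate_genome(genome, 0.98, seed=15)
        contig = sketch_contig_sequence("v", variant, params_default)
        reads = cs.simulate_reads(genome, 20.0, 150, 0.0, seed=16)
        sample = cs.sketch_read_sequences(reads, params_default)
        result = cs.query_containment(contig, sample)
        assert result.ani == pytest.approx(realized, abs=0.005)


class TestEstimateLambda:
    def test_ratio_formula(self):
        # N1=4 singletons, N2=2 doubletons -> 2*2/4 = 1.0
        assert cs.estimate_lambda(np.array([1, 1, 1, 1, 2, 2, 7])) == 1.0

    def test_mean_fallback_without_singletons(self):
        assert cs.estimate_lambda(np.array([5, 5, 5])) == 5.0

    def test_empty_counts(self):
        assert cs.estimate_lambda(np.array([])) is None

    def test_zero_truncated_poisson_recovery(self):
        """The singleton/doubleton ratio is immune to zero truncation."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            draws = rng.poisson(1.5, size=40_000)
            counts = draws[draws > 0][:10_000]
            assert cs.estimate_lambda(counts) == pytest.approx(1.5, abs=0.1)


class TestEffectiveCoverage:
    def test_median_regime_constant_counts(self):
        depth, regime, m = cs.effective_coverage(np.full(100, 20))
        assert (depth, regime, m) == (20.0, cs.REGIME_MEDIAN, 20.0)

    def test_robust_mean_trims_top_decile(self):
        counts = np.array([5] * 9 + [100])
        depth, regime, m = cs.effective_coverage(counts)
        assert m == 5.0
        assert regime == cs.REGIME_ROBUST_MEAN
        assert depth == 5.0

    @pytest.mark.parametrize(
        "fill, expected_regime",
        [
            (3, cs.REGIME_POISSON),
            (4, cs.REGIME_ROBUST_MEAN),
            (15, cs.REGIME_ROBUST_MEAN),
            (16, cs.REGIME_MEDIAN),
        ],
    )
    def test_regime_boundaries(self, fill, expected_regime):
        _, regime, _ = cs.effective_coverage(np.full(20, fill))
        assert regime == expected_regime

    def test_even_size_median_is_mean_of_middle_two(self):
        # counts [3,3,4,4]: M = 3.5 -> robust mean regime
        _, regime, m = cs.effective_coverage(np.array([3, 3, 4, 4]))
        assert m == 3.5
        assert regime == cs.REGIME_ROBUST_MEAN

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            cs.effective_coverage(np.array([]))


class TestCoverageVariance:
    def test_constant_counts(self):
        assert cs.coverage_variance(np.full(50, 7)) == 0.0

    def test_tails_trimmed(self):
        counts = np.array([1, 10, 10, 10, 10, 10, 10, 10, 10, 100])
        assert cs.coverage_variance(counts) == 0.0

    def test_single_count(self):
        assert cs.coverage_variance(np.array([4])) == 0.0

    def test_hand_computed_value(self):
        # 1..10: trim one from each tail -> 2..9, unbiased variance 6.0
        assert cs.coverage_variance(np.arange(1, 11)) == 6.0


class TestCoverageForPair:
    def test_below_min_kmers_is_absent(self):
        contig, sample = make_pair(10, [5] * 7)
        est = cs.coverage_for_pair(contig, sample)
        assert (est.depth, est.variance, est.regime) == (0.0, 0.0, cs.REGIME_ABSENT)

    def test_eight_matched_kmers_with_high_ani_is_present(self):
        contig, sample = make_pair(8, [5] * 8)
        est = cs.coverage_for_pair(contig, sample)
        assert est.regime != cs.REGIME_ABSENT
        assert est.depth > 0

    def test_low_ani_is_absent_despite_many_matches(self):
        # 1000 of 8000 matched: ANI = 0.125^(1/31) ~ 0.935 < 0.95
        contig, sample = make_pair(8000, [5] * 1000)
        est = cs.coverage_for_pair(contig, sample)
        assert est.regime == cs.REGIME_ABSENT
        assert est.containment.ani < 0.95
        assert (est.depth, est.variance) == (0.0, 0.0)

    def test_no_sampled_kmers_is_absent(self):
        contig = cs.ContigSketch("tiny", 2, np.empty(0, dtype=np.uint64))
        sample = cs.SampleSketch("s", cs.SketchParams(), {1: 1})
        est = cs.coverage_for_pair(contig, sample)
        assert est.regime == cs.REGIME_ABSENT

    def test_zero_shared_kmers_zero_depth(self, params_small):
        """Unrelated random genomes share essentially nothing."""
        contig = sketch_contig_sequence(
            "a", cs.generate_genome(10_000, 100), params_small
        )
        sample = cs.sketch_read_sequences(
            cs.simulate_reads(cs.generate_genome(10_000, 200), 5.0, 100, 0.0, 1),
            params_small,
        )
        est = cs.coverage_for_pair(contig, sample)
        assert (est.depth, est.variance, est.regime) == (0.0, 0.0, cs.REGIME_ABSENT)

    def test_params_mismatch_raises(self):
        contig, sample = make_pair(10, [5] * 10)
        with pytest.raises(cs.ParamsMismatchError):
            cs.coverage_for_pair(
                contig, sample, contig_params=cs.SketchParams(k=21)
            )

    def test_read_length_correction_applied(self):
        """k-mer multiplicities are rescaled to per-base depth by R/(R-k+1)."""
        contig, sample = make_pair(100, [20] * 100)
        sample.n_reads = 100
        sample.n_bases_processed = 15_000  # mean read length 150, k=31
        est = cs.coverage_for_pair(contig, sample)
        assert est.depth == pytest.approx(20.0 * 150 / 120)
        # without read statistics the factor degrades to 1
        contig2, sample2 = make_pair(100, [20] * 100)
        assert cs.coverage_for_pair(contig2, sample2).depth == 20.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        n_matched=st.integers(0, 60),
        n_extra=st.integers(0, 60),
        min_kmers=st.integers(1, 20),
        min_ani=st.floats(0.5, 1.0),
        bump_kmers=st.integers(0, 10),
        bump_ani=st.floats(0.0, 0.2),
    )
    def test_monotone_presence(
        self, n_matched, n_extra, min_kmers, min_ani, bump_kmers, bump_ani
    ):
        """Raising either threshold never converts absent to present."""
        contig, sample = make_pair(n_matched + n_extra, [3] * n_matched)
        loose = cs.QueryThresholds(min_kmers=min_kmers, min_ani=min_ani)
        strict = cs.QueryThresholds(
            min_kmers=min_kmers + bump_kmers, min_ani=min(1.0, min_ani + bump_ani)
        )
        if contig.kmer_hashes.size == 0:
            return
        loose_present = cs.query_containment(contig, sample, loose).present
        strict_present = cs.query_containment(contig, sample, strict).present
        assert not (strict_present and not loose_present)

    def test_self_mapping_depth_recovery(self, params_default):
        """Deep error-free reads from the contig's own genome recover the
        simulated coverage within 15%."""
        genome = cs.generate_genome(50_000, 44)
        contig = sketch_contig_sequence("g", genome, params_default)
        depths = []
        for seed in range(5):
            reads = cs.simulate_reads(genome, 10.0, 150, 0.0, seed=seed)
            sample = cs.sketch_read_sequences(reads, params_default)
            est = cs.coverage_for_pair(contig, sample)
            assert est.regime != cs.REGIME_ABSENT
            depths.append(est.depth)
        assert np.median(depths) == pytest.approx(10.0, rel=0.15)
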