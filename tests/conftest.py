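"""Shared fixtures and independent brute-force oracles.

The oracles count k-mers by plain string slicing and dictionary updates,
independent of the package's vectorized rolling-hash path; only the final
hash/keep mapping is shared so tables can be compared key-by-key.
"""

from __future__ import annotations

import pytest

from covsketch import SketchParams, keep_kmer, kmer_hash

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_force_kmer_counts(seqs, k: int) -> dict[str, int]:
    """Exhaustive canonical k-mer counter over read strings."""
    counts: dict[str, int] = {}
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if any(ch not in "ACGT" for ch in window):
                continue
            rc = revcomp(window)
            canon = window if window <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def brute_force_sample_table(seqs, params: SketchParams) -> dict[int, int]:
    """Expected hash->multiplicity table: exhaustive counts restricted to
    k-mers passing the FracMinHash keep rule."""
    table: dict[int, int] = {}
    for kmer, count in brute_force_kmer_counts(seqs, params.k).items():
        h = kmer_hash(kmer, params)
        if keep_kmer(h, params.c):
            table[h] = table.get(h, 0) + count
    return table


def brute_force_contig_hashes(seq: str, params: SketchParams) -> set[int]:
    """Expected distinct sampled hash set of one contig."""
    return set(brute_force_sample_table([seq], params).keys())


@pytest.fixture(scope="session")
def params_small() -> SketchParams:
    """Tiny k, no subsampling: every k-mer visible, for oracle tests."""
    return SketchParams(k=21, c=1)


@pytest.fixture(scope="session")
def params_default() -> SketchParams:
    return SketchParams()
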