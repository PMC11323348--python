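"""Subsampled canonical k-mer sketching of reads and contigs.

Reads are turned into a per-sample hash table mapping sampled canonical
k-mer hashes to their multiplicities; assemblies are turned into per-contig
sets of sampled k-mer hashes.  Subsampling uses the FracMinHash rule: a
k-mer is kept iff its 64-bit hash falls below ``floor(2^64 / c)``, so the
same deterministic fraction (about ``1/c``) of k-mer space is retained in
every dataset sketched with the same parameters, and a contig's sampled
k-mers can be looked up directly in any sample's table.
"""

from __future__ import annotations

import gzip
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("covsketch")

DEFAULT_K = 31
DEFAULT_C = 50
DEFAULT_HASH_SEED = 42

MAGIC = b"COVSKTCH"
FORMAT_VERSION = 1
SAMPLE_SKETCH_SUFFIX = ".smsk"
ASSEMBLY_SKETCH_SUFFIX = ".ctsk"

_SAMPLE_KIND = 0
_ASSEMBLY_KIND = 1

# 2-bit base codes; anything outside ACGT/acgt is 4 and invalidates its windows
_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODES[_b] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# instrumentation: how many read-sketching passes / file opens have happened
IO_COUNTERS = {"read_sketch_passes": 0, "read_file_opens": 0}


def reset_io_counters() -> None:
    for key in IO_COUNTERS:
        IO_COUNTERS[key] = 0


class SketchError(Exception):
    """Base class for sketching failures."""


class SketchFormatError(SketchError):
    """Raised when a sketch container is corrupt or has the wrong version."""


class ParamsMismatchError(SketchError):
    """Raised when sketches with different (k, c, hash_seed) are compared."""


@dataclass(frozen=True)
class SketchParams:
    """Parameters that make two sketches comparable.

    k must be odd so a k-mer is never its own reverse complement; c is the
    FracMinHash subsampling denominator (fraction kept is about 1/c);
    hash_seed seeds the 64-bit k-mer hash.
    """

    k: int = DEFAULT_K
    c: int = DEFAULT_C
    hash_seed: int = DEFAULT_HASH_SEED
    format_version: int = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")

    def compatible_with(self, other: "SketchParams") -> bool:
        return (
            self.k == other.k
            and self.c == other.c
            and self.hash_seed == other.hash_seed
        )

    def require_compatible(self, other: "SketchParams") -> None:
        if not self.compatible_with(other):
            raise ParamsMismatchError(
                f"sketch parameters differ: (k={self.k}, c={self.c}, "
                f"seed={self.hash_seed}) vs (k={other.k}, c={other.c}, "
                f"seed={other.hash_seed})"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(window: str) -> str | None:
    """Return the lexicographically smaller of a window and its reverse
    complement, or None if the window contains a non-ACGT character."""
    up = window.upper()
    if any(b not in "ACGT" for b in up):
        return None
    rc = reverse_complement(up)
    return up if up <= rc else rc


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64-style finalizer; uniform, deterministic, portable."""
    x = x.astype(np.uint64, copy=True)
    x ^= np.uint64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def kmer_hash(kmer: str, params: SketchParams) -> int:
    """Hash of a single k-mer after canonicalization (test/debug helper)."""
    canon = canonical_kmer(kmer)
    if canon is None:
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    if len(canon) != params.k:
        raise ValueError(f"expected a {params.k}-mer, got length {len(canon)}")
    codes = _CODES[np.frombuffer(canon.encode("ascii"), dtype=np.uint8)]
    value = np.uint64(0)
    for code in codes:
        value = (value << np.uint64(2)) | np.uint64(code)
    return int(_mix64(np.array([value], dtype=np.uint64), params.hash_seed)[0])


def keep_threshold(c: int) -> int:
    return (1 << 64) // c


def keep_kmer(kmer_hash, c: int):
    """FracMinHash keep rule: hash < floor(2^64 / c).

    Accepts a scalar or a uint64 array; with c=1 everything is kept.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c == 1:
        if np.isscalar(kmer_hash) or isinstance(kmer_hash, (int, np.integer)):
            return True
        return np.ones(np.asarray(kmer_hash).shape, dtype=bool)
    thr = np.uint64(keep_threshold(c))
    if np.isscalar(kmer_hash) or isinstance(kmer_hash, (int, np.integer)):
        return bool(np.uint64(kmer_hash) < thr)
    return np.asarray(kmer_hash, dtype=np.uint64) < thr


def _encode(data: bytes) -> np.ndarray:
    return _CODES[np.frombuffer(data, dtype=np.uint8)]


def _canonical_hashes(codes: np.ndarray, params: SketchParams) -> np.ndarray:
    """Hashes of the canonical k-mers of every valid window, in window order.

    Windows containing a code > 3 (ambiguous base or sequence separator)
    are dropped; their garbage rolling values never survive the mask.
    """
    k = params.k
    n = codes.size
    n_windows = n - k + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    bad = np.concatenate(([0], np.cumsum(codes > 3, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n_windows, dtype=np.uint64)
    rev = np.zeros(n_windows, dtype=np.uint64)
    rcodes = np.uint64(3) - c64  # wraps for invalid codes; masked below
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | c64[j : j + n_windows]
        rev |= rcodes[j : j + n_windows] << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)[valid]
    return _mix64(canon, params.hash_seed)


def hashes_for_sequence(seq: str, params: SketchParams) -> np.ndarray:
    """Sampled (keep-rule-passing) canonical k-mer hashes of one sequence."""
    hashes = _canonical_hashes(_encode(seq.encode("ascii")), params)
    return hashes[keep_kmer(hashes, params.c)]


def _batch_hashes(seqs: Sequence[str], params: SketchParams) -> np.ndarray:
    """Sampled hashes pooled over a batch of sequences.

    Sequences are joined with a separator byte so one vectorized pass
    handles the whole batch; windows spanning the separator are invalid.
    """
    if not seqs:
        return np.empty(0, dtype=np.uint64)
    blob = b"\n".join(s.encode("ascii") for s in seqs)
    hashes = _canonical_hashes(_encode(blob), params)
    return hashes[keep_kmer(hashes, params.c)]


@dataclass
class SampleSketch:
    """One sample's subsampled k-mer -> multiplicity table."""

    sample_name: str
    params: SketchParams
    kmer_counts: dict[int, int] = field(default_factory=dict)
    n_bases_processed: int = 0
    n_reads: int = 0

    # cached sorted arrays for fast vectorized matching
    _hashes_sorted: np.ndarray | None = field(default=None, repr=False)
    _counts_sorted: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_kmers_sampled(self) -> int:
        return len(self.kmer_counts)

    @property
    def mean_read_length(self) -> float:
        if self.n_reads == 0:
            return 0.0
        return self.n_bases_processed / self.n_reads

    def sorted_table(self) -> tuple[np.ndarray, np.ndarray]:
        if self._hashes_sorted is None:
            hashes = np.fromiter(
                self.kmer_counts.keys(), dtype=np.uint64, count=len(self.kmer_counts)
            )
            counts = np.fromiter(
                self.kmer_counts.values(), dtype=np.int64, count=len(self.kmer_counts)
            )
            order = np.argsort(hashes, kind="stable")
            self._hashes_sorted = hashes[order]
            self._counts_sorted = counts[order]
        return self._hashes_sorted, self._counts_sorted

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSketch):
            return NotImplemented
        return (
            self.sample_name == other.sample_name
            and self.params == other.params
            and self.kmer_counts == other.kmer_counts
            and self.n_bases_processed == other.n_bases_processed
            and self.n_reads == other.n_reads
        )


@dataclass
class ContigSketch:
    """Distinct sampled k-mer hashes of one contig (sorted uint64 array)."""

    contig_name: str
    length_bp: int
    kmer_hashes: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigSketch):
            return NotImplemented
        return (
            self.contig_name == other.contig_name
            and self.length_bp == other.length_bp
            and np.array_equal(self.kmer_hashes, other.kmer_hashes)
        )


@dataclass
class AssemblySketch:
    assembly_name: str
    params: SketchParams
    contigs: list[ContigSketch] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblySketch):
            return NotImplemented
        return (
            self.assembly_name == other.assembly_name
            and self.params == other.params
            and self.contigs == other.contigs
        )


# ---------------------------------------------------------------------------
# sequence file reading (FASTA/FASTQ, plain or gzip, detected by content)
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(handle: IO[str]) -> str:
    first = handle.read(1)
    handle.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SketchFormatError(
        "cannot detect sequence format (expected FASTA '>' or FASTQ '@')"
    )


def iter_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) records from a FASTA/FASTQ file (gzip OK)."""
    with _open_maybe_gzip(path) as handle:
        fmt = _detect_format(handle)
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq)


def sample_name_from_path(path: str | Path) -> str:
    """Read-file basename with compression and sequence suffixes stripped."""
    name = Path(path).name
    for suffix in (".gz", ".bgz"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    for suffix in (".fastq", ".fq", ".fasta", ".fa", ".fna"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return name


# ---------------------------------------------------------------------------
# sketch construction
# ---------------------------------------------------------------------------

_BATCH_BASES = 4_000_000


def _finalize_counts(chunks: list[np.ndarray]) -> dict[int, int]:
    if not chunks:
        return {}
    pooled = np.concatenate(chunks)
    if pooled.size == 0:
        return {}
    uniq, counts = np.unique(pooled, return_counts=True)
    return dict(zip(uniq.tolist(), counts.tolist()))


def sketch_read_sequences(
    seqs: Iterable[str], params: SketchParams, sample_name: str = "sample"
) -> SampleSketch:
    """Sketch an in-memory collection of read sequences into one sample table."""
    chunks: list[np.ndarray] = []
    batch: list[str] = []
    batch_bases = 0
    n_bases = 0
    n_reads = 0
    for seq in seqs:
        batch.append(seq)
        batch_bases += len(seq)
        n_bases += len(seq)
        n_reads += 1
        if batch_bases >= _BATCH_BASES:
            chunks.append(_batch_hashes(batch, params))
            batch, batch_bases = [], 0
    if batch:
        chunks.append(_batch_hashes(batch, params))
    return SampleSketch(
        sample_name=sample_name,
        params=params,
        kmer_counts=_finalize_counts(chunks),
        n_bases_processed=n_bases,
        n_reads=n_reads,
    )


def sketch_reads(
    read_files: Sequence[str | Path],
    params: SketchParams,
    sample_name: str | None = None,
) -> SampleSketch:
    """Sketch one sample's read files (paired files are pooled) into a
    k-mer -> multiplicity table.

    The result is independent of read order and of how reads are split
    across the sample's files.
    """
    if not read_files:
        raise ValueError("at least one read file is required")
    if sample_name is None:
        sample_name = sample_name_from_path(read_files[0])
    IO_COUNTERS["read_sketch_passes"] += 1

    def _all_reads() -> Iterator[str]:
        for path in read_files:
            path = Path(path)
            if not path.exists():
                raise FileNotFoundError(f"read file not found: {path}")
            IO_COUNTERS["read_file_opens"] += 1
            for _, seq in iter_sequences(path):
                yield seq

    sketch = sketch_read_sequences(_all_reads(), params, sample_name)
    if sketch.n_reads == 0:
        logger.warning("sample %s: no reads found; sketch is empty", sample_name)
    return sketch


def sketch_contig_sequence(name: str, seq: str, params: SketchParams) -> ContigSketch:
    hashes = np.unique(hashes_for_sequence(seq, params)) if len(seq) >= params.k else (
        np.empty(0, dtype=np.uint64)
    )
    return ContigSketch(contig_name=name, length_bp=len(seq), kmer_hashes=hashes)


def sketch_contigs(
    fasta_path: str | Path,
    params: SketchParams,
    assembly_name: str | None = None,
) -> AssemblySketch:
    """Sketch every contig of an assembly FASTA into distinct sampled hashes.

    Contig names are the first whitespace-delimited header token; duplicate
    names are a hard error because depth output is keyed on them.
    """
    fasta_path = Path(fasta_path)
    if assembly_name is None:
        assembly_name = sample_name_from_path(fasta_path)
    contigs: list[ContigSketch] = []
    seen: set[str] = set()
    for name, seq in iter_sequences(fasta_path):
        if name in seen:
            raise SketchError(f"duplicate contig name {name!r} in {fasta_path}")
        seen.add(name)
        contigs.append(sketch_contig_sequence(name, seq, params))
    return AssemblySketch(assembly_name=assembly_name, params=params, contigs=contigs)


# ---------------------------------------------------------------------------
# persistence: little-endian versioned container
# ---------------------------------------------------------------------------


def _write_str(handle: IO[bytes], text: str) -> None:
    data = text.encode("utf-8")
    handle.write(struct.pack("<I", len(data)))
    handle.write(data)


def _read_exact(handle: IO[bytes], n: int) -> bytes:
    data = handle.read(n)
    if len(data) != n:
        raise SketchFormatError("truncated sketch file")
    return data


def _read_str(handle: IO[bytes]) -> str:
    (n,) = struct.unpack("<I", _read_exact(handle, 4))
    return _read_exact(handle, n).decode("utf-8")


def _write_params(handle: IO[bytes], params: SketchParams) -> None:
    handle.write(struct.pack("<IIq", params.k, params.c, params.hash_seed))


def _read_params(handle: IO[bytes], version: int) -> SketchParams:
    k, c, seed = struct.unpack("<IIq", _read_exact(handle, 16))
    return SketchParams(k=k, c=c, hash_seed=seed, format_version=version)


def write_sketch(sketch: SampleSketch | AssemblySketch, path: str | Path) -> None:
    """Serialize a sketch; ``read_sketch(write_sketch(x)) == x`` bit-exactly."""
    path = Path(path)
    with open(path, "wb") as handle:
        handle.write(MAGIC)
        if isinstance(sketch, SampleSketch):
            handle.write(struct.pack("<BH", _SAMPLE_KIND, FORMAT_VERSION))
            _write_params(handle, sketch.params)
            _write_str(handle, sketch.sample_name)
            hashes, counts = sketch.sorted_table()
            handle.write(
                struct.pack(
                    "<QQQ", sketch.n_bases_processed, sketch.n_reads, hashes.size
                )
            )
            handle.write(hashes.astype("<u8").tobytes())
            handle.write(counts.astype("<u8").tobytes())
        elif isinstance(sketch, AssemblySketch):
            handle.write(struct.pack("<BH", _ASSEMBLY_KIND, FORMAT_VERSION))
            _write_params(handle, sketch.params)
            _write_str(handle, sketch.assembly_name)
            handle.write(struct.pack("<I", len(sketch.contigs)))
            for contig in sketch.contigs:
                _write_str(handle, contig.contig_name)
                handle.write(
                    struct.pack("<QQ", contig.length_bp, contig.kmer_hashes.size)
                )
                handle.write(contig.kmer_hashes.astype("<u8").tobytes())
        else:
            raise TypeError(f"cannot serialize {type(sketch).__name__}")


def read_sketch(path: str | Path) -> SampleSketch | AssemblySketch:
    path = Path(path)
    with open(path, "rb") as handle:
        magic = handle.read(len(MAGIC))
        if magic != MAGIC:
            raise SketchFormatError(
                f"{path}: not a sketch file (bad magic bytes {magic!r})"
            )
        kind, version = struct.unpack("<BH", _read_exact(handle, 3))
        if version != FORMAT_VERSION:
            raise SketchFormatError(
                f"{path}: unsupported sketch format version {version}, "
                f"expected {FORMAT_VERSION}"
            )
        params = _read_params(handle, version)
        name = _read_str(handle)
        if kind == _SAMPLE_KIND:
            n_bases, n_reads, n_entries = struct.unpack("<QQQ", _read_exact(handle, 24))
            hashes = np.frombuffer(_read_exact(handle, 8 * n_entries), dtype="<u8")
            counts = np.frombuffer(_read_exact(handle, 8 * n_entries), dtype="<u8")
            return SampleSketch(
                sample_name=name,
                params=params,
                kmer_counts=dict(
                    zip(hashes.tolist(), counts.astype(np.int64).tolist())
                ),
                n_bases_processed=n_bases,
                n_reads=n_reads,
            )
        if kind == _ASSEMBLY_KIND:
            (n_contigs,) = struct.unpack("<I", _read_exact(handle, 4))
            contigs = []
            for _ in range(n_contigs):
                contig_name = _read_str(handle)
                length_bp, n_hashes = struct.unpack("<QQ", _read_exact(handle, 16))
                hashes = np.frombuffer(
                    _read_exact(handle, 8 * n_hashes), dtype="<u8"
                ).astype(np.uint64)
                contigs.append(
                    ContigSketch(
                        contig_name=contig_name,
                        length_bp=length_bp,
                        kmer_hashes=hashes,
                    )
                )
            return AssemblySketch(assembly_name=name, params=params, contigs=contigs)
        raise SketchFormatError(f"{path}: unknown sketch kind {kind}")
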