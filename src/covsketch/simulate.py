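"""Synthetic communities with known coverage for testing the estimators.

Generates uniform random genomes, strain variants at a controlled average
nucleotide identity (independent per-site substitutions, no indels), and
shotgun reads at a controlled fold-coverage.  Read start positions are
uniform on a circularized genome so per-base depth is Poisson(coverage)
without edge effects; sequencing errors are i.i.d. substitutions.  Every
output is exactly reproducible from its seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _CODE_OF[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def generate_genome(length: int, seed: int) -> str:
    """Uniform random nucleotide sequence; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_genome(
    genome: str, target_identity: float, seed: int
) -> tuple[str, float]:
    """Substitute each site independently with probability 1 - identity.

    Substituted sites get a uniformly chosen *different* base.  Returns the
    variant and the realized identity.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    codes = _encode(genome)
    if target_identity == 1.0:
        return genome, 1.0
    rng = np.random.default_rng(seed)
    hit = rng.random(codes.size) < (1.0 - target_identity)
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    mutated = codes.copy()
    mutated[hit] = (mutated[hit] + shift) % 4
    realized = 1.0 - hit.sum() / codes.size
    return _decode(mutated), float(realized)


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Shotgun reads at a known fold-coverage.

    Read count is round(coverage * |genome| / read_length); starts are
    uniform on the circularized genome; strands are uniform; substitution
    errors are i.i.d. at error_rate.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    n_reads = int(round(coverage * len(genome) / read_length))
    if n_reads == 0:
        return []
    rng = np.random.default_rng(seed)
    codes = _encode(genome)
    doubled = np.concatenate([codes, codes[: read_length - 1]])
    starts = rng.integers(0, len(genome), size=n_reads)
    reads = doubled[starts[:, None] + np.arange(read_length)[None, :]]
    flip = rng.random(n_reads) < 0.5
    reads[flip] = 3 - reads[flip, ::-1]
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4
    letters = _BASES[reads]
    return [row.tobytes().decode("ascii") for row in letters]


def write_fastq(
    reads: list[str], path: str | Path, name_prefix: str = "read"
) -> None:
    """Write reads as FASTQ with constant quality; gzip if path ends .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for i, seq in enumerate(reads):
            handle.write(f"@{name_prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


@dataclass
class CommunitySpec:
    """A multi-genome, multi-sample synthetic community.

    abundance is a genomes x samples matrix of true fold-coverages; each
    sample's FASTQ pools reads of all genomes at its column's coverages.
    """

    n_genomes: int
    genome_length_bp: int | list[int]
    abundance: np.ndarray
    read_length: int = 150
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=np.float64)
        if self.abundance.shape[0] != self.n_genomes:
            raise ValueError("abundance must have one row per genome")
        if (self.abundance < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def genome_lengths(self) -> list[int]:
        if isinstance(self.genome_length_bp, int):
            return [self.genome_length_bp] * self.n_genomes
        return list(self.genome_length_bp)


@dataclass
class CommunityFixture:
    """Paths and ground truth for one generated community."""

    contigs_fasta: Path
    sample_fastqs: list[Path]
    truth_table: Path
    genomes: list[str]
    contig_names: list[str]
    contig_genome_index: list[int]
    abundance: np.ndarray

    def contig_truth(self) -> np.ndarray:
        """Contigs x samples matrix of true fold-coverage."""
        return self.abundance[self.contig_genome_index, :]


def build_community(
    spec: CommunitySpec,
    out_dir: str | Path,
    fragment_bp: int | None = None,
    gzip_fastq: bool = False,
) -> CommunityFixture:
    """Write genomes (as a contigs FASTA, optionally fragmented), per-sample
    FASTQ pools, and a per-genome truth table of true coverages."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    genome_seeds, read_seeds = root.spawn(2)
    lengths = spec.genome_lengths()

    genomes = [
        generate_genome(length, seed)
        for length, seed in zip(
            lengths, genome_seeds.generate_state(spec.n_genomes)
        )
    ]

    contig_records: list[tuple[str, str]] = []
    contig_genome_index: list[int] = []
    for g, genome in enumerate(genomes):
        if fragment_bp is None:
            contig_records.append((f"g{g}", genome))
            contig_genome_index.append(g)
        else:
            for j in range(0, len(genome), fragment_bp):
                frag = genome[j : j + fragment_bp]
                contig_records.append((f"g{g}_frag{j // fragment_bp}", frag))
                contig_genome_index.append(g)
    contigs_fasta = out_dir / "contigs.fa"
    write_fasta(contig_records, contigs_fasta)

    read_seed_grid = read_seeds.generate_state(spec.n_genomes * spec.n_samples)
    suffix = ".fq.gz" if gzip_fastq else ".fq"
    sample_fastqs: list[Path] = []
    for s in range(spec.n_samples):
        reads: list[str] = []
        for g, genome in enumerate(genomes):
            reads.extend(
                simulate_reads(
                    genome,
                    coverage=float(spec.abundance[g, s]),
                    read_length=spec.read_length,
                    error_rate=spec.error_rate,
                    seed=int(read_seed_grid[g * spec.n_samples + s]),
                )
            )
        path = out_dir / f"sample{s}{suffix}"
        write_fastq(reads, path, name_prefix=f"s{s}")
        sample_fastqs.append(path)

    truth_table = out_dir / "truth.tsv"
    with open(truth_table, "w") as handle:
        handle.write(
            "genome\t" + "\t".join(f"sample{s}" for s in range(spec.n_samples)) + "\n"
        )
        for g in range(spec.n_genomes):
            row = "\t".join(format(v, ".6g") for v in spec.abundance[g])
            handle.write(f"g{g}\t{row}\n")

    return CommunityFixture(
        contigs_fasta=contigs_fasta,
        sample_fastqs=sample_fastqs,
        truth_table=truth_table,
        genomes=genomes,
        contig_names=[name for name, _ in contig_records],
        contig_genome_index=contig_genome_index,
        abundance=spec.abundance,
    )
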