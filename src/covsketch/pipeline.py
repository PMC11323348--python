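"""Multi-sample x multi-assembly coverage workflow.

The cost structure is the point: each sample's reads are sketched exactly
once (the expensive linear pass), after which querying any number of
assemblies against the stored tables is cheap — n read passes plus n x m
fast query rounds, instead of n x m alignment runs.  Sample sketches are
written to disk and loaded at most once per assembly query round.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import QueryThresholds, REGIME_ABSENT, coverage_for_pair
from .depthio import DepthMatrix, write_maxbin_abundance, write_metabat_depth
from .sketch import (
    ASSEMBLY_SKETCH_SUFFIX,
    SAMPLE_SKETCH_SUFFIX,
    AssemblySketch,
    SampleSketch,
    SketchError,
    SketchParams,
    read_sketch,
    sample_name_from_path,
    sketch_contigs,
    sketch_reads,
    write_sketch,
)

logger = logging.getLogger("covsketch")

FORMAT_METABAT2 = "metabat2"
FORMAT_MAXBIN2 = "maxbin2"


@dataclass
class RunConfig:
    """Everything one coverage run needs."""

    sample_specs: list[tuple[str, list[Path]]]
    assembly_paths: list[Path]
    params: SketchParams = field(default_factory=SketchParams)
    thresholds: QueryThresholds = field(default_factory=QueryThresholds)
    output_format: str = FORMAT_METABAT2
    out_dir: Path = Path(".")
    threads: int = 1
    keep_resident: bool = False

    def __post_init__(self) -> None:
        if not self.sample_specs:
            raise ValueError("at least one sample is required")
        if not self.assembly_paths:
            raise ValueError("at least one assembly is required")
        names = [name for name, _ in self.sample_specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate sample names: {names}")
        if self.output_format not in (FORMAT_METABAT2, FORMAT_MAXBIN2):
            raise ValueError(f"unknown output format {self.output_format!r}")


def sample_specs_from_paths(
    read_paths: Sequence[str | Path],
    pair1: Sequence[str | Path] = (),
    pair2: Sequence[str | Path] = (),
) -> list[tuple[str, list[Path]]]:
    """One single-end sample per --reads file plus one per --pair1/--pair2
    mate pair; duplicate basenames are rejected (output columns key on them)."""
    if len(pair1) != len(pair2):
        raise ValueError("--pair1 and --pair2 must list the same number of files")
    specs: list[tuple[str, list[Path]]] = []
    for path in read_paths:
        specs.append((sample_name_from_path(path), [Path(path)]))
    for p1, p2 in zip(pair1, pair2):
        specs.append((sample_name_from_path(p1), [Path(p1), Path(p2)]))
    names = [name for name, _ in specs]
    if len(set(names)) != len(names):
        raise ValueError(
            f"sample names derived from file basenames collide: {sorted(names)}"
        )
    return specs


def _is_sketch_file(path: Path) -> bool:
    return path.suffix in (SAMPLE_SKETCH_SUFFIX, ASSEMBLY_SKETCH_SUFFIX)


def _up_to_date(target: Path, sources: Sequence[Path]) -> bool:
    if not target.exists():
        return False
    mtime = target.stat().st_mtime
    return all(src.stat().st_mtime <= mtime for src in sources)


def cmd_sketch(
    sample_specs: Sequence[tuple[str, Sequence[str | Path]]] = (),
    assembly_paths: Sequence[str | Path] = (),
    params: SketchParams = SketchParams(),
    out_dir: str | Path = ".",
    force: bool = False,
) -> tuple[list[Path], list[tuple[Path, Exception]]]:
    """Write one .smsk per sample and one .ctsk per assembly.

    Up-to-date sketches are skipped unless forced.  Failures are collected
    per input so one bad file does not abort the rest; the CLI exits
    nonzero if any input failed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    failures: list[tuple[Path, Exception]] = []
    for name, files in sample_specs:
        files = [Path(f) for f in files]
        target = out_dir / f"{name}{SAMPLE_SKETCH_SUFFIX}"
        if not force and _up_to_date(target, files):
            logger.info("sample %s: sketch up to date, skipping", name)
            continue
        try:
            write_sketch(sketch_reads(files, params, sample_name=name), target)
            written.append(target)
        except Exception as exc:  # noqa: BLE001 - per-file failure contract
            logger.error("sample %s (%s): %s", name, files, exc)
            failures.append((files[0], exc))
    for path in assembly_paths:
        path = Path(path)
        name = sample_name_from_path(path)
        target = out_dir / f"{name}{ASSEMBLY_SKETCH_SUFFIX}"
        if not force and _up_to_date(target, [path]):
            logger.info("assembly %s: sketch up to date, skipping", name)
            continue
        try:
            write_sketch(sketch_contigs(path, params, assembly_name=name), target)
            written.append(target)
        except Exception as exc:  # noqa: BLE001
            logger.error("assembly %s: %s", path, exc)
            failures.append((path, exc))
    return written, failures


def _load_sample(
    spec: tuple[str, Sequence[Path]], params: SketchParams
) -> SampleSketch:
    name, files = spec
    if len(files) == 1 and _is_sketch_file(Path(files[0])):
        sketch = read_sketch(files[0])
        if not isinstance(sketch, SampleSketch):
            raise SketchError(f"{files[0]} is not a sample sketch")
        return sketch
    return sketch_reads([Path(f) for f in files], params, sample_name=name)


def _load_assembly(path: Path, params: SketchParams) -> AssemblySketch:
    if _is_sketch_file(path):
        sketch = read_sketch(path)
        if not isinstance(sketch, AssemblySketch):
            raise SketchError(f"{path} is not an assembly sketch")
        return sketch
    return sketch_contigs(path, params)


def compute_depth_matrix(
    assembly: AssemblySketch,
    samples: Sequence[SampleSketch],
    thresholds: QueryThresholds = QueryThresholds(),
    threads: int = 1,
) -> DepthMatrix:
    """Query every contig of one assembly against every sample.

    Columns follow the given sample order and rows the assembly's FASTA
    order regardless of worker count, so results are scheduling-invariant.
    """
    for sample in samples:
        assembly.params.require_compatible(sample.params)

    def _column(j: int) -> tuple[np.ndarray, np.ndarray, int]:
        sample = samples[j]
        depth = np.zeros(len(assembly.contigs))
        var = np.zeros(len(assembly.contigs))
        n_absent = 0
        for i, contig in enumerate(assembly.contigs):
            est = coverage_for_pair(contig, sample, thresholds)
            depth[i] = est.depth
            var[i] = est.variance
            n_absent += est.regime == REGIME_ABSENT
        return depth, var, n_absent

    indices = range(len(samples))
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            columns = list(pool.map(_column, indices))
    else:
        columns = [_column(j) for j in indices]

    n_contigs = len(assembly.contigs)
    depth = np.column_stack([c[0] for c in columns]) if columns else np.zeros((n_contigs, 0))
    var = np.column_stack([c[1] for c in columns]) if columns else np.zeros((n_contigs, 0))
    for sample, (_, _, n_absent) in zip(samples, columns):
        logger.info(
            "assembly %s vs sample %s: %d contigs, %.1f%% absent",
            assembly.assembly_name,
            sample.sample_name,
            n_contigs,
            100.0 * n_absent / n_contigs if n_contigs else 0.0,
        )
    return DepthMatrix(
        assembly_name=assembly.assembly_name,
        contig_names=[c.contig_name for c in assembly.contigs],
        contig_lengths=[c.length_bp for c in assembly.contigs],
        sample_names=[s.sample_name for s in samples],
        depth=depth,
        variance=var,
    )


def cmd_coverage(config: RunConfig) -> list[Path]:
    """Run the full workflow: (auto-)sketch, query, write depth tables.

    Raw read files are sketched exactly once no matter how many assemblies
    are queried.  Sample sketches stored on disk are by default loaded per
    assembly round and released afterwards (memory stays one-sample-deep);
    ``keep_resident`` holds them all in memory for speed.  Returns the
    written output paths, one depth file (or MaxBin2 abundance file set)
    per assembly.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)

    # samples backed by raw reads are sketched once, up front
    resident: dict[int, SampleSketch] = {}
    for idx, (name, files) in enumerate(config.sample_specs):
        from_file = len(files) == 1 and _is_sketch_file(Path(files[0]))
        if not from_file or config.keep_resident:
            resident[idx] = _load_sample((name, files), config.params)

    def _samples_for_round() -> list[SampleSketch]:
        return [
            resident[idx]
            if idx in resident
            else _load_sample(spec, config.params)
            for idx, spec in enumerate(config.sample_specs)
        ]

    assemblies = [_load_assembly(Path(p), config.params) for p in config.assembly_paths]

    # fail on any parameter mismatch before writing anything
    first_round = _samples_for_round()
    reference = first_round[0].params
    for sketch in [*first_round, *assemblies]:
        reference.require_compatible(sketch.params)

    outputs: list[Path] = []
    for assembly in assemblies:
        samples = first_round if first_round is not None else _samples_for_round()
        first_round = None
        matrix = compute_depth_matrix(
            assembly, samples, config.thresholds, threads=config.threads
        )
        del samples
        if config.output_format == FORMAT_METABAT2:
            out = config.out_dir / f"{assembly.assembly_name}.depth.tsv"
            write_metabat_depth(matrix, out)
            outputs.append(out)
        else:
            outputs.extend(
                write_maxbin_abundance(matrix, config.out_dir / assembly.assembly_name)
            )
    return outputs
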