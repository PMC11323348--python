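"""Binner-ready coverage tables.

Writes the tab-separated depth layout produced by MetaBAT2's
``jgi_summarize_bam_contig_depths`` script (header ``contigName contigLen
totalAvgDepth <s1> <s1>-var ...``, one row per contig) and MaxBin2-style
two-column per-sample abundance files, and parses the MetaBAT2 layout back.
Output is byte-deterministic: fixed column order (FASTA contig order, CLI
sample order) and fixed number rendering (6 significant digits, trailing
zeros trimmed so 3.0 prints as ``3``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class DepthFormatError(ValueError):
    """Raised when a depth file does not follow the expected layout."""


@dataclass
class DepthMatrix:
    """Contigs x samples table of (depth, variance) for one assembly."""

    assembly_name: str
    contig_names: list[str]
    contig_lengths: list[int]
    sample_names: list[str]
    depth: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        shape = (len(self.contig_names), len(self.sample_names))
        if self.depth.shape != shape or self.variance.shape != shape:
            raise ValueError(
                f"matrix shapes {self.depth.shape}/{self.variance.shape} do not "
                f"match {len(self.contig_names)} contigs x "
                f"{len(self.sample_names)} samples"
            )
        if len(self.contig_lengths) != len(self.contig_names):
            raise ValueError("contig_lengths does not match contig_names")
        if (self.depth < 0).any() or (self.variance < 0).any():
            raise ValueError("depths and variances must be non-negative")

    @property
    def total_avg_depth(self) -> np.ndarray:
        if len(self.sample_names) == 0:
            return np.zeros(len(self.contig_names))
        return self.depth.mean(axis=1)


def format_number(x: float) -> str:
    """6 significant digits, trailing zeros trimmed (3.0 -> '3')."""
    return format(float(x), ".6g")


def write_metabat_depth(matrix: DepthMatrix, path: str | Path) -> None:
    """Write a MetaBAT2/jgi-layout depth file (3 + 2n columns)."""
    path = Path(path)
    header = ["contigName", "contigLen", "totalAvgDepth"]
    for name in matrix.sample_names:
        header.extend([name, f"{name}-var"])
    lines = ["\t".join(header)]
    totals = matrix.total_avg_depth
    for i, (name, length) in enumerate(
        zip(matrix.contig_names, matrix.contig_lengths)
    ):
        fields = [name, str(int(length)), format_number(totals[i])]
        for j in range(len(matrix.sample_names)):
            fields.append(format_number(matrix.depth[i, j]))
            fields.append(format_number(matrix.variance[i, j]))
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_maxbin_abundance(matrix: DepthMatrix, out_dir: str | Path) -> list[Path]:
    """Write one headerless two-column (contig, depth) file per sample plus a
    manifest listing the files in sample order (MaxBin2 ``-abund_list``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for j, sample in enumerate(matrix.sample_names):
        path = out_dir / f"{matrix.assembly_name}.{sample}.abund.tsv"
        lines = [
            f"{name}\t{format_number(matrix.depth[i, j])}"
            for i, name in enumerate(matrix.contig_names)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(path)
    manifest = out_dir / f"{matrix.assembly_name}.abund_list.txt"
    manifest.write_text("".join(f"{p}\n" for p in paths))
    return paths + [manifest]


def read_depth_file(path: str | Path) -> DepthMatrix:
    """Parse a MetaBAT2-layout depth file back into a DepthMatrix."""
    path = Path(path)
    with open(path) as handle:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            raise DepthFormatError(f"{path}: empty file")
        header = header_line.split("\t")
        if header[:3] != ["contigName", "contigLen", "totalAvgDepth"]:
            raise DepthFormatError(
                f"{path}: expected header to start with contigName, contigLen, "
                f"totalAvgDepth; got {header[:3]}"
            )
        tail = header[3:]
        if len(tail) % 2 != 0:
            raise DepthFormatError(
                f"{path}: odd number of sample columns ({len(tail)}) after the "
                "first three; a depth-only dialect belongs to the MaxBin2 "
                "abundance reader"
            )
        sample_names = []
        for j in range(0, len(tail), 2):
            name, var_name = tail[j], tail[j + 1]
            if var_name != f"{name}-var":
                raise DepthFormatError(
                    f"{path}: column {4 + j + 1} should be {name!r}-var, got "
                    f"{var_name!r}; depth-only files belong to the MaxBin2 "
                    "abundance reader"
                )
            sample_names.append(name)
        contig_names: list[str] = []
        contig_lengths: list[int] = []
        depth_rows: list[list[float]] = []
        var_rows: list[list[float]] = []
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise DepthFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got "
                    f"{len(fields)}"
                )
            contig_names.append(fields[0])
            contig_lengths.append(int(float(fields[1])))
            values = [float(v) for v in fields[3:]]
            depth_rows.append(values[0::2])
            var_rows.append(values[1::2])
    n, m = len(contig_names), len(sample_names)
    return DepthMatrix(
        assembly_name=path.name.split(".")[0],
        contig_names=contig_names,
        contig_lengths=contig_lengths,
        sample_names=sample_names,
        depth=np.array(depth_rows, dtype=np.float64).reshape(n, m),
        variance=np.array(var_rows, dtype=np.float64).reshape(n, m),
    )
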