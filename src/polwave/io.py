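"""Genomic file formats and the shared coordinate conventions.

All in-memory coordinates are 0-based half-open (BED convention).  GTF input
(1-based closed) is converted on read.  Coverage is stored binned, per
chromosome and strand; a bedGraph record's value is interpreted as density
per ``bin_size`` bp, so an interval spanning a fraction of a bin contributes
pro-rata by overlap length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "Peak",
    "StrandedCoverage",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_bedgraph",
    "write_bedgraph",
]


class BedParseError(ValueError):
    """Malformed record in a BED-family file; message names the line."""


def _norm_strand(s: str) -> str:
    # tolerate the typographic minus that shows up in copied annotation
    if s in (PLUS,):
        return PLUS
    if s in (MINUS, "−"):
        return MINUS
    raise ValueError(f"unknown strand character: {s!r}")


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names with their lengths in bp."""

    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.chrom_lengths)) != len(self.chrom_lengths):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in assembly") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class GeneModel:
    """One transcript per gene; TSS/TES are strand-aware termini."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "strand", _norm_strand(self.strand))
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == PLUS else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == PLUS else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called interval (0-based half-open) with an enrichment score."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")
        if self.score < 0:
            raise ValueError(f"peak {self.name}: negative score")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class StrandedCoverage:
    """Binned nonnegative signal per chromosome and strand.

    ``values[chrom][strand]`` is a float array of length
    ``ceil(chrom_length / bin_size)``; a bin's value is the read mass
    assigned to that bin.
    """

    assembly: GenomeAssembly
    bin_size: int
    values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom in self.assembly.chrom_names:
            per_strand = self.values.setdefault(chrom, {})
            for strand in STRANDS:
                nb = self.assembly.n_bins(chrom, self.bin_size)
                if strand in per_strand:
                    arr = np.asarray(per_strand[strand], dtype=float)
                    if arr.shape != (nb,):
                        raise ValueError(
                            f"{chrom}{strand}: expected {nb} bins, got {arr.shape}"
                        )
                    if (arr < 0).any():
                        raise ValueError(f"{chrom}{strand}: negative coverage")
                    per_strand[strand] = arr
                else:
                    per_strand[strand] = np.zeros(nb)

    @classmethod
    def zeros(cls, assembly: GenomeAssembly, bin_size: int) -> "StrandedCoverage":
        return cls(assembly=assembly, bin_size=bin_size)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[chrom][_norm_strand(strand)]

    @property
    def total_reads(self) -> float:
        """Total mass over both strands (the library size)."""
        return float(
            sum(arr.sum() for per in self.values.values() for arr in per.values())
        )

    def strand_total(self, strand: str) -> float:
        strand = _norm_strand(strand)
        return float(sum(per[strand].sum() for per in self.values.values()))

    def window_sum(self, chrom: str, strand: str, start: float, end: float) -> float:
        """Read mass in [start, end), pro-rata at partially covered bins.

        Out-of-bounds windows are clipped with a warning.
        """
        length = self.assembly.length(chrom)
        if start < 0 or end > length:
            warnings.warn(
                f"window [{start}, {end}) clipped to chromosome {chrom} bounds",
                stacklevel=2,
            )
            start, end = max(start, 0.0), min(end, float(length))
        if end <= start:
            return 0.0
        arr = self.get(chrom, strand)
        cum = np.concatenate(([0.0], np.cumsum(arr)))
        edges = np.arange(arr.size + 1, dtype=float) * self.bin_size
        lo, hi = np.interp([start, end], edges, cum)
        return float(hi - lo)

    def scaled(self, factor: float) -> "StrandedCoverage":
        out = StrandedCoverage.zeros(self.assembly, self.bin_size)
        for chrom, per in self.values.items():
            for strand, arr in per.items():
                out.values[chrom][strand] = arr * factor
        return out


# ---------------------------------------------------------------------------
# BED peaks


def read_bed(path) -> list[Peak]:
    """Read BED3–BED6 into peaks, preserving input order.

    Missing name/score fall back to "." and 0.  Strand (column 6) is ignored
    here; peaks are unstranded intervals.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                peaks.append(Peak(fields[0], start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\n")


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(path, format: str = "bed12") -> list[GeneModel]:
    """Read transcripts as one GeneModel each from BED12 or GTF.

    Duplicate gene_ids are passed through; deduplication (e.g. picking one
    transcript per gene) is the caller's job.
    """
    if format == "bed12":
        return _read_genes_bed12(path)
    if format == "gtf":
        return _read_genes_gtf(path)
    raise ValueError(f"unknown gene-model format: {format!r}")


def _read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: BED12 needs >= 6 columns")
            try:
                genes.append(
                    GeneModel(
                        gene_id=fields[3],
                        chrom=fields[0],
                        strand=fields[5],
                        start=int(fields[1]),
                        end=int(fields[2]),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _read_genes_gtf(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise BedParseError(f"{path}:{lineno}: GTF needs 9 columns")
            if fields[2] != "transcript":
                continue
            attrs = _parse_gtf_attrs(fields[8])
            gene_id = attrs.get("transcript_id") or attrs.get("gene_id")
            if gene_id is None:
                raise BedParseError(f"{path}:{lineno}: no transcript_id/gene_id")
            try:
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=fields[0],
                        strand=fields[6],
                        # GTF is 1-based closed
                        start=int(fields[3]) - 1,
                        end=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_gtf_attrs(s: str) -> dict[str, str]:
    attrs = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def write_gene_models(genes, path) -> None:
    """Write genes as minimal BED12 (single block spanning the gene)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.length},\t0,\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, assembly: GenomeAssembly, bin_size: int, strand: str,
                  coverage: StrandedCoverage | None = None) -> StrandedCoverage:
    """Read one bedGraph file into the given strand of a coverage object.

    A record's value is density per ``bin_size`` bp: an interval contributes
    ``value * overlap_bp / bin_size`` to each bin it touches, so total mass
    ``sum(value * length) / bin_size`` is conserved.
    """
    strand = _norm_strand(strand)
    if coverage is None:
        coverage = StrandedCoverage.zeros(assembly, bin_size)
    elif coverage.bin_size != bin_size or coverage.assembly is not assembly:
        raise ValueError("coverage bin_size/assembly mismatch")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom = fields[0]
            if chrom not in assembly.chrom_lengths:
                raise ValueError(f"{path}:{lineno}: chromosome {chrom!r} not in assembly")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if not (0 <= start < end <= assembly.length(chrom)):
                raise BedParseError(f"{path}:{lineno}: interval outside assembly bounds")
            _deposit_density(coverage.get(chrom, strand), bin_size,
                             start, end, value)
    return coverage


def _deposit_density(arr: np.ndarray, bin_size: int, start: int, end: int,
                     density: float) -> None:
    """Add ``density`` (per bin_size bp) over [start, end): full bins get
    exactly ``density``, edge bins the pro-rata fraction."""
    i0, i1 = start // bin_size, (end - 1) // bin_size
    if i0 == i1:
        arr[i0] += density * (end - start) / bin_size
        return
    arr[i0] += density * ((i0 + 1) * bin_size - start) / bin_size
    arr[i1] += density * (end - i1 * bin_size) / bin_size
    if i1 > i0 + 1:
        arr[i0 + 1:i1] += density


def write_bedgraph(coverage: StrandedCoverage, path, strand: str) -> None:
    """Write one strand as bedGraph, run-length merging equal bins, zeros omitted.

    Round-trips exactly against :func:`read_bedgraph` at the same bin size.
    """
    strand = _norm_strand(strand)
    with open(path, "w") as fh:
        for chrom in coverage.assembly.chrom_names:
            arr = coverage.get(chrom, strand)
            length = coverage.assembly.length(chrom)
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for b0, b1 in zip(starts, ends):
                v = arr[b0]
                if v == 0:
                    continue
                lo = int(b0) * coverage.bin_size
                hi = min(int(b1) * coverage.bin_size, length)
                fh.write(f"{chrom}\t{lo}\t{hi}\t{float(v)!r}\n")


def deposit(arr: np.ndarray, bin_size: int, start: float, end: float,
            mass: float) -> None:
    """Distribute ``mass`` uniformly over [start, end) into bins, pro-rata.

    In-place; clips silently at the array bounds (callers validate earlier).
    """
    if end <= start or mass <= 0:
        return
    span = end - start
    start = max(start, 0.0)
    end = min(end, arr.size * bin_size)
    if end <= start:
        return
    rate = mass / span  # per bp
    i0 = int(start // bin_size)
    i1 = int((end - 1e-9) // bin_size)  # last touched bin
    if i0 == i1:
        arr[i0] += rate * (end - start)
        return
    arr[i0] += rate * ((i0 + 1) * bin_size - start)
    arr[i1] += rate * (end - i1 * bin_size)
    if i1 > i0 + 1:
        arr[i0 + 1:i1] += rate * bin_size
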