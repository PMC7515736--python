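"""Interval algebra and readers/writers for the genomic formats the pipeline touches.

All internal coordinates are 0-based half-open. narrowPeak/BED/bedGraph are
read and written natively (already 0-based half-open); gene tables may arrive
as 1-based GFF3, converted once at the parsing boundary. Chromosome names are
passed through verbatim — no "chr" normalization is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "CalledPeak",
    "CoverageTrack",
    "GeneModel",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_gff3_genes",
    "overlap_fraction",
    "reciprocal_match",
]


class FormatError(ValueError):
    """Raised on malformed records in any supported on-disk format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CalledPeak:
    """One peak-caller record (MACS2 narrowPeak dialect)."""

    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0
    neg_log10_p: float = 0.0
    name: str = "."
    signal: float = 0.0
    neg_log10_q: float = -1.0

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.interval.length):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")

    @property
    def summit(self) -> int:
        """Absolute summit position (bp)."""
        return self.interval.start + self.summit_offset


@dataclass
class CoverageTrack:
    """Per-base read coverage with the library size used for RPM scaling.

    ``rpm(chrom)`` returns coverage × 1e6 / library_size (reads per million).
    """

    coverage: dict[str, np.ndarray]
    library_size: float

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for chrom, vec in self.coverage.items():
            if np.any(np.asarray(vec) < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def rpm(self, chrom: str) -> np.ndarray:
        return np.asarray(self.coverage[chrom], dtype=float) * 1e6 / self.library_size

    def window_mean_rpm(self, interval: GenomicInterval) -> float:
        """Mean RPM per bp over the window, clipped at chromosome bounds.

        Clipping uses the actually covered width as divisor (logged).
        """
        vec = self.coverage.get(interval.chrom)
        if vec is None:
            return 0.0
        lo = max(0, interval.start)
        hi = min(len(vec), interval.end)
        if hi <= lo:
            return 0.0
        if lo != interval.start or hi != interval.end:
            logger.warning(
                "window %s:%d-%d clipped to chromosome bounds [0,%d)",
                interval.chrom, interval.start, interval.end, len(vec),
            )
        seg = np.asarray(vec[lo:hi], dtype=float)
        return float(seg.sum() * 1e6 / self.library_size / (hi - lo))


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware transcription start/termination sites.

    On the + strand TSS < TTS; on the − strand TSS > TTS. ``exons`` is an
    optional tuple of (start, end) half-open intervals in genome coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tts:
            raise ValueError(f"{self.gene_id}: TSS == TTS")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand requires TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand requires TSS > TTS")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tts), max(self.tss, self.tts)
        return GenomicInterval(self.chrom, lo, hi)


# ---------------------------------------------------------------------------
# narrowPeak

def read_narrowpeak(path: str | Path) -> list[CalledPeak]:
    """Read an ENCODE narrowPeak (10-column) file.

    A summit offset of −1 (unset) maps to the interval midpoint with a
    warning. Order is preserved.
    """
    peaks: list[CalledPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = float(fields[4])
            signal = float(fields[6])
            neg_log10_p = float(fields[7])
            neg_log10_q = float(fields[8])
            summit = int(fields[9])
            if summit == -1:
                summit = (end - start) // 2
                warnings.warn(
                    f"{path}:{lineno}: summit offset -1 mapped to midpoint {summit}"
                )
            peaks.append(
                CalledPeak(
                    interval=GenomicInterval(chrom, start, end),
                    summit_offset=summit,
                    score=score,
                    neg_log10_p=neg_log10_p,
                    name=name,
                    signal=signal,
                    neg_log10_q=neg_log10_q,
                )
            )
    return peaks


def _fmt(x: float) -> str:
    """Stable float formatting: integers print without a trailing .0."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_narrowpeak(peaks: Iterable[CalledPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        _fmt(p.score),
                        ".",
                        _fmt(p.signal),
                        _fmt(p.neg_log10_p),
                        _fmt(p.neg_log10_q),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; non-ACGT letters kept as-is."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}")
        genome[record.id] = seq
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(
    path: str | Path,
    chrom_sizes: dict[str, int],
    library_size: float,
) -> CoverageTrack:
    """Expand a bedGraph into per-base vectors for the given chromosomes."""
    coverage = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in coverage:
                continue
            coverage[chrom][start:end] = value
    return CoverageTrack(coverage=coverage, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write run-length-compressed bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, vec in track.coverage.items():
            vec = np.asarray(vec)
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


# ---------------------------------------------------------------------------
# Gene models

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the tab-separated gene-model table (gene_id, chrom, strand, TSS, TTS).

    Coordinates are 0-based as written by this package.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns")
            gene_id, chrom, strand, tss, tts = fields[:5]
            exons: tuple[tuple[int, int], ...] = ()
            if len(fields) >= 6 and fields[5]:
                exons = tuple(
                    (int(a), int(b))
                    for a, b in (pair.split("-") for pair in fields[5].split(","))
                )
            genes.append(GeneModel(gene_id, chrom, strand, int(tss), int(tts), exons))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tTSS\tTTS\texons\n")
        for g in genes:
            exon_str = ",".join(f"{a}-{b}" for a, b in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\t{exon_str}\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene (and exon) lines from GFF3; 1-based closed coordinates
    converted to 0-based half-open at this boundary.

    TSS/TTS derive from the gene span by strand: + genes have TSS = start,
    − genes TSS = end.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start1, end1, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            start, end = int(start1) - 1, int(end1)
            if ftype == "gene":
                gid = attrs.get("ID", attrs.get("gene_id", f"{chrom}:{start}"))
                spans[gid] = (chrom, strand, start, end)
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                exons.setdefault(parent, []).append((start, end))
    genes = []
    for gid, (chrom, strand, start, end) in spans.items():
        tss, tts = (start, end) if strand == "+" else (end, start)
        genes.append(
            GeneModel(gid, chrom, strand, tss, tts, tuple(sorted(exons.get(gid, []))))
        )
    return genes


# ---------------------------------------------------------------------------
# Interval algebra

def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """(fraction of a overlapped by b, fraction of b overlapped by a).

    Different chromosomes give (0.0, 0.0) rather than an error.
    """
    ov = a.overlap_length(b)
    return ov / a.length, ov / b.length


def reciprocal_match(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    f: float,
    mode: str = "either",
) -> list[tuple[int, int]]:
    """All (i, j) index pairs whose overlap fractions satisfy the rule.

    mode="either": fraction-of-A >= f OR fraction-of-B >= f (bedtools -e
    semantics with -f/-F); mode="both": AND. Each A interval may match
    several B intervals; every qualifying pair is reported.
    """
    if not (0 < f <= 1):
        raise ValueError(f"overlap fraction must be in (0, 1], got {f}")
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, b in enumerate(set_b):
        by_chrom.setdefault(b.chrom, []).append((j, b))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[1].start)
    matches: list[tuple[int, int]] = []
    for i, a in enumerate(set_a):
        for j, b in by_chrom.get(a.chrom, []):
            if b.start >= a.end:
                break
            fa, fb = overlap_fraction(a, b)
            ok = (fa >= f or fb >= f) if mode == "either" else (fa >= f and fb >= f)
            if ok:
                matches.append((i, j))
    return matches
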