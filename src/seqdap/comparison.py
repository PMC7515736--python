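"""Union peak catalogue for two experiments, common/specific labels, CFR.

Two width-normalized consensus peaks collapse into one catalogue entry when
they satisfy the geometric rule: the overlap covers at least 80% of the
smaller peak AND each peak has less than 50% of its length non-overlapping.
Entries are then labelled common or complex-specific by a 2-fold coverage
criterion, and ranked by the coverage fold reduction CFR = cov_A / cov_B
(experiment A is conventionally the tetramer, B the dimer, so decile 1 —
the highest CFR — holds the regions most dependent on tetramerization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import CoverageTrack, GenomicInterval
from .pooling import HALF_WIDTH, ConsensusPeak

logger = logging.getLogger(__name__)

__all__ = [
    "UnionPeak",
    "build_union_catalogue",
    "classify",
    "cfr_rank_and_deciles",
    "profile_matrices",
]


@dataclass
class UnionPeak:
    """One entry of the two-experiment union catalogue."""

    chrom: str
    summit: int
    cov_a: float = 0.0
    cov_b: float = 0.0
    label: str = "common"
    origin: str = "both"  # both | A_only | B_only (geometric provenance)
    cfr: float = float("nan")
    cfr_rank: int = -1
    decile: int = -1

    @property
    def interval(self) -> GenomicInterval:
        start = max(0, self.summit - HALF_WIDTH)
        return GenomicInterval(self.chrom, start, self.summit + HALF_WIDTH + 1)


def _geometric_match(a: GenomicInterval, b: GenomicInterval,
                     overlap_f: float, nonoverlap_max: float) -> bool:
    ov = a.overlap_length(b)
    if ov == 0:
        return False
    smaller = min(a.length, b.length)
    if ov < overlap_f * smaller:
        return False
    # each peak must have less than `nonoverlap_max` of its length non-overlapping
    return (1 - ov / a.length) < nonoverlap_max and (1 - ov / b.length) < nonoverlap_max


def build_union_catalogue(
    cons_a: Sequence[ConsensusPeak],
    cons_b: Sequence[ConsensusPeak],
    tracks_a: Sequence[CoverageTrack],
    tracks_b: Sequence[CoverageTrack],
    overlap_f: float = 0.8,
    nonoverlap_max: float = 0.5,
) -> list[UnionPeak]:
    """Join two consensus sets into one catalogue of union peaks.

    Matched pairs keep the summit of the experiment with the higher mean
    coverage, re-windowed to ±200 bp; unmatched peaks enter on their own.
    One-to-many ambiguity resolves to the largest-overlap pairing (ties to
    the lower-coordinate partner, logged); cov_A and cov_B are recomputed
    over every entry's window from each experiment's replicate tracks.
    """
    # candidate pairs satisfying the geometric rule
    pairs: list[tuple[int, int, int]] = []  # (overlap, ia, ib)
    b_sorted = sorted(range(len(cons_b)), key=lambda j: (cons_b[j].chrom, cons_b[j].summit))
    for ia, pa in enumerate(cons_a):
        for jb in b_sorted:
            pb = cons_b[jb]
            if pb.chrom != pa.chrom:
                continue
            if pb.interval.start >= pa.interval.end:
                break
            if _geometric_match(pa.interval, pb.interval, overlap_f, nonoverlap_max):
                pairs.append((pa.interval.overlap_length(pb.interval), ia, jb))
    # greedy largest-overlap resolution; ties broken by coordinates (logged)
    pairs.sort(key=lambda t: (-t[0], cons_a[t[1]].chrom, cons_a[t[1]].summit,
                              cons_b[t[2]].summit))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, ia, jb in pairs:
        if ia in used_a or jb in used_b:
            continue
        used_a.add(ia)
        used_b.add(jb)
        matched.append((ia, jb))

    def mean_cov(iv: GenomicInterval, tracks: Sequence[CoverageTrack]) -> float:
        return float(np.mean([t.window_mean_rpm(iv) for t in tracks])) if tracks else 0.0

    entries: list[UnionPeak] = []
    for ia, jb in matched:
        pa, pb = cons_a[ia], cons_b[jb]
        summit = pa.summit if pa.mean_norm_cov >= pb.mean_norm_cov else pb.summit
        entries.append(UnionPeak(chrom=pa.chrom, summit=summit, origin="both"))
    for ia, pa in enumerate(cons_a):
        if ia not in used_a:
            entries.append(UnionPeak(chrom=pa.chrom, summit=pa.summit, origin="A_only"))
    for jb, pb in enumerate(cons_b):
        if jb not in used_b:
            entries.append(UnionPeak(chrom=pb.chrom, summit=pb.summit, origin="B_only"))
    for e in entries:
        e.cov_a = mean_cov(e.interval, tracks_a)
        e.cov_b = mean_cov(e.interval, tracks_b)
        e.label = classify(e)
        e.cfr = e.cov_a / e.cov_b if e.cov_b > 0 else float("inf")
        if not np.isfinite(e.cfr):
            logger.info(
                "entry %s:%d has zero cov_B; CFR flagged infinite and excluded "
                "from ratio-ranked outputs", e.chrom, e.summit,
            )
    entries.sort(key=lambda e: (e.chrom, e.summit))
    logger.info(
        "union catalogue: %d entries (%d matched, %d A-only, %d B-only)",
        len(entries), len(matched),
        sum(e.origin == "A_only" for e in entries),
        sum(e.origin == "B_only" for e in entries),
    )
    return entries


def classify(entry: UnionPeak, fold: float = 2.0) -> str:
    """common | A_specific | B_specific by the fold-coverage criterion.

    A peak is specific to one experiment when its coverage is at least
    ``fold`` times the other's. Both coverages zero labels common, with a
    warning.
    """
    a, b = entry.cov_a, entry.cov_b
    if a == 0 and b == 0:
        warnings.warn(
            f"entry {entry.chrom}:{entry.summit} has zero coverage in both "
            "experiments; labelled common"
        )
        return "common"
    if a >= fold * b:
        return "A_specific"
    if b >= fold * a:
        return "B_specific"
    return "common"


def cfr_rank_and_deciles(entries: Sequence[UnionPeak]) -> list[UnionPeak]:
    """Annotate entries with descending-CFR rank and decile index 1..10.

    Only finite-CFR entries are ranked; decile 1 holds the top 10% CFR.
    Deciles are equal-count bins with remainders given to the earliest
    deciles; ties are broken by coordinate.
    """
    finite = [e for e in entries if np.isfinite(e.cfr)]
    skipped = len(entries) - len(finite)
    if skipped:
        logger.info("cfr_rank_and_deciles: %d infinite-CFR entries excluded", skipped)
    if len(finite) < 10:
        warnings.warn(
            f"only {len(finite)} rankable entries; deciles will be degenerate"
        )
    finite.sort(key=lambda e: (-e.cfr, e.chrom, e.summit))
    n = len(finite)
    base, rem = divmod(n, 10)
    sizes = [base + (1 if d < rem else 0) for d in range(10)]
    idx = 0
    for d, size in enumerate(sizes, start=1):
        for _ in range(size):
            finite[idx].cfr_rank = idx + 1
            finite[idx].decile = d
            idx += 1
    return finite


def profile_matrices(
    entries: Sequence[UnionPeak],
    tracks_a: Sequence[CoverageTrack],
    tracks_b: Sequence[CoverageTrack],
    window: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Summit-centered coverage heatmap rows (sorted by CFR descending) and
    per-experiment mean intensity curves.

    Returns (matrix_A, matrix_B, mean_curve_A, mean_curve_B); each matrix is
    entries × window with RPM values averaged over replicates,
    zero-filled (and logged) where the window leaves the chromosome.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    ranked = sorted(
        (e for e in entries if np.isfinite(e.cfr)),
        key=lambda e: (-e.cfr, e.chrom, e.summit),
    )
    half = window // 2

    def rows(tracks: Sequence[CoverageTrack]) -> np.ndarray:
        mat = np.zeros((len(ranked), window))
        for i, e in enumerate(ranked):
            acc = np.zeros(window)
            for t in tracks:
                vec = t.coverage.get(e.chrom)
                if vec is None:
                    continue
                lo, hi = e.summit - half, e.summit + half
                clo, chi = max(0, lo), min(len(vec), hi)
                if clo != lo or chi != hi:
                    logger.info(
                        "profile window %s:%d-%d zero-filled at chromosome edge",
                        e.chrom, lo, hi,
                    )
                if chi > clo:
                    acc[clo - lo : chi - lo] += (
                        np.asarray(vec[clo:chi], dtype=float) * 1e6 / t.library_size
                    )
            mat[i] = acc / max(len(tracks), 1)
        return mat

    mat_a, mat_b = rows(tracks_a), rows(tracks_b)
    return mat_a, mat_b, mat_a.mean(axis=0), mat_b.mean(axis=0)


def write_union_bed(entries: Sequence[UnionPeak], path) -> None:
    """BED6+ columns: cov_A, cov_B, label, cfr, decile."""
    with open(path, "w") as fh:
        for k, e in enumerate(entries):
            iv = e.interval
            cfr = f"{e.cfr:.6g}" if np.isfinite(e.cfr) else "inf"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tunion_{k}\t0\t.\t"
                f"{e.cov_a:.6g}\t{e.cov_b:.6g}\t{e.label}\t{cfr}\t{e.decile}\n"
            )
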