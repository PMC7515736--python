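"""Collapse replicate peak calls into width-normalized consensus peaks.

Reproducibility across replicates is assessed by support count plus Fisher
combination of the per-replicate peak p-values (the MACS2 −log10 p carried
in the narrowPeak input): a merged region is kept when it is supported by at
least ``min_replicates`` replicates AND the Fisher-combined p-value over the
supporting replicates is at most ``reproducibility_alpha`` (default 1e-4).
Retained regions are scanned for sub-peaks via single-linkage clustering of
the contributing summits and width-normalized to summit ± 200 bp (a 401-bp
window); each window gets the mean across replicates of its mean per-bp RPM
coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import CalledPeak, CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusPeak",
    "pool_replicates",
    "split_and_normalize",
    "mean_normalized_coverage",
    "consensus_peaks",
    "HALF_WIDTH",
]

HALF_WIDTH = 200  # "peak widths normalized to +/- 200 bp around the maximum"


@dataclass
class ConsensusPeak:
    """Summit-centered 401-bp consensus window."""

    chrom: str
    summit: int
    mean_norm_cov: float = 0.0
    support: int = 0
    combined_neg_log10_p: float = 0.0

    @property
    def interval(self) -> GenomicInterval:
        start = self.summit - HALF_WIDTH
        if start < 0:
            logger.warning(
                "consensus window at %s:%d clipped at chromosome start",
                self.chrom, self.summit,
            )
            start = 0
        return GenomicInterval(self.chrom, start, self.summit + HALF_WIDTH + 1)


@dataclass
class CandidateRegion:
    """Merged overlapping-peak region with its supporting evidence."""

    interval: GenomicInterval
    summits: list[int]
    support: int
    combined_neg_log10_p: float


def _fisher_neg_log10(best_nlp: Sequence[float]) -> tuple[float, float]:
    """Fisher-combine per-replicate −log10 p values.

    Returns (combined p, combined −log10 p); chi-square statistic is
    2·ln(10)·Σ(−log10 p) on 2k degrees of freedom.
    """
    stat = 2.0 * math.log(10.0) * float(sum(best_nlp))
    df = 2 * len(best_nlp)
    p = float(stats.chi2.sf(stat, df))
    nlp = -stats.chi2.logsf(stat, df) / math.log(10.0)
    return p, float(nlp)


def pool_replicates(
    replicate_peaks: Sequence[Sequence[CalledPeak]],
    reproducibility_alpha: float = 1e-4,
    min_replicates: int = 2,
    allow_single_replicate: bool = False,
) -> list[CandidateRegion]:
    """Merge overlapping peaks across replicates into reproducible regions.

    A region is retained when supported by >= ``min_replicates`` distinct
    replicates and the Fisher-combined p over the supporting replicates'
    best peaks is <= ``reproducibility_alpha``. All contributing summits are
    carried forward for sub-peak splitting.
    """
    if len(replicate_peaks) < 2 and not allow_single_replicate:
        raise ValueError(
            "at least 2 replicates required; pass allow_single_replicate=True "
            "to bypass reproducibility filtering for a single replicate"
        )
    tagged: list[tuple[str, int, int, int, int, float]] = []
    for r, peaks in enumerate(replicate_peaks):
        for p in peaks:
            tagged.append(
                (p.interval.chrom, p.interval.start, p.interval.end, r,
                 p.summit, p.neg_log10_p)
            )
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    regions: list[CandidateRegion] = []
    i = 0
    n_dropped_support = n_dropped_alpha = 0
    while i < len(tagged):
        chrom, start, end = tagged[i][0], tagged[i][1], tagged[i][2]
        members = [tagged[i]]
        j = i + 1
        while j < len(tagged) and tagged[j][0] == chrom and tagged[j][1] < end:
            end = max(end, tagged[j][2])
            members.append(tagged[j])
            j += 1
        i = j
        reps = {m[3] for m in members}
        support = len(reps)
        min_req = 1 if len(replicate_peaks) == 1 else min_replicates
        if support < min_req:
            n_dropped_support += 1
            continue
        best_per_rep = {}
        for m in members:
            best_per_rep[m[3]] = max(best_per_rep.get(m[3], 0.0), m[5])
        p, nlp = _fisher_neg_log10(list(best_per_rep.values()))
        if p > reproducibility_alpha:
            n_dropped_alpha += 1
            continue
        regions.append(
            CandidateRegion(
                interval=GenomicInterval(chrom, start, end),
                summits=sorted(m[4] for m in members),
                support=support,
                combined_neg_log10_p=nlp,
            )
        )
    logger.info(
        "pool_replicates: %d regions kept, %d dropped (support), %d dropped (alpha)",
        len(regions), n_dropped_support, n_dropped_alpha,
    )
    return regions


def _round_half_down(x: float) -> int:
    """Round to nearest integer; exact halves round down (1002.5 -> 1002)."""
    return math.ceil(x - 0.5)


def split_and_normalize(
    region: CandidateRegion, merge_distance: int = HALF_WIDTH
) -> list[ConsensusPeak]:
    """Split a region into sub-peaks and width-normalize to 401 bp.

    Contributing summits are clustered by single linkage with the given
    merge distance; each cluster's representative summit is the
    round-half-down mean of its members, and one [s−200, s+201) window is
    emitted per cluster. Output windows may extend past the original region.
    """
    if not region.summits:
        raise ValueError("region carries no summits")
    summits = sorted(region.summits)
    clusters: list[list[int]] = [[summits[0]]]
    for s in summits[1:]:
        if s - clusters[-1][-1] <= merge_distance:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    peaks = []
    for cl in clusters:
        s = _round_half_down(sum(cl) / len(cl))
        peaks.append(
            ConsensusPeak(
                chrom=region.interval.chrom,
                summit=s,
                support=region.support,
                combined_neg_log10_p=region.combined_neg_log10_p,
            )
        )
    return peaks


def mean_normalized_coverage(
    peak: ConsensusPeak, replicate_tracks: Sequence[CoverageTrack]
) -> float:
    """Mean across replicates of the window's mean per-bp RPM coverage.

    Windows clipped at a chromosome edge use the covered width as divisor
    (logged inside the track accessor).
    """
    if not replicate_tracks:
        raise ValueError("no coverage tracks supplied")
    vals = [t.window_mean_rpm(peak.interval) for t in replicate_tracks]
    return float(np.mean(vals))


def consensus_peaks(
    replicate_peaks: Sequence[Sequence[CalledPeak]],
    replicate_tracks: Sequence[CoverageTrack],
    reproducibility_alpha: float = 1e-4,
    min_replicates: int = 2,
    merge_distance: int = HALF_WIDTH,
    allow_single_replicate: bool = False,
) -> list[ConsensusPeak]:
    """Full pooling stage: merge, filter, split, width-normalize, coverage."""
    regions = pool_replicates(
        replicate_peaks,
        reproducibility_alpha=reproducibility_alpha,
        min_replicates=min_replicates,
        allow_single_replicate=allow_single_replicate,
    )
    out: list[ConsensusPeak] = []
    for region in regions:
        for peak in split_and_normalize(region, merge_distance=merge_distance):
            peak.mean_norm_cov = mean_normalized_coverage(peak, replicate_tracks)
            out.append(peak)
    out.sort(key=lambda p: (p.chrom, p.summit))
    logger.info("consensus_peaks: %d width-normalized peaks", len(out))
    return out


def write_consensus_bed(peaks: Sequence[ConsensusPeak], path) -> None:
    """BED6+ with mean_norm_cov, support, combined −log10 p extra columns."""
    with open(path, "w") as fh:
        for k, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tconsensus_{k}\t0\t.\t"
                f"{p.mean_norm_cov:.6g}\t{p.support}\t{p.combined_neg_log10_p:.6g}\n"
            )


def read_consensus_bed(path) -> list[ConsensusPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            peaks.append(
                ConsensusPeak(
                    chrom=f[0],
                    summit=int(f[2]) - HALF_WIDTH - 1,
                    mean_norm_cov=float(f[6]),
                    support=int(f[7]),
                    combined_neg_log10_p=float(f[8]),
                )
            )
    return peaks
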