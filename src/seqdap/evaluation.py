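"""Model evaluation: GC/origin-matched unbound negatives, AUROC, score tests.

The negative set mirrors the bound regions in count, length, genomic origin
class (promoter, intron, exon, intergenic) and GC content (binned), while
never overlapping any peak of the experiment — the background a motif model
must beat for its AUROC to mean anything. AUROC is computed by the
Mann–Whitney rank statistic with mid-ranked ties; best-score distributions
between two region sets are compared by Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneModel, GenomicInterval
from .motifs import PWM, TFFM1, scan_scores

logger = logging.getLogger(__name__)

__all__ = [
    "NegativeSet",
    "OriginIndex",
    "sample_matched_negatives",
    "compute_auroc",
    "compare_best_scores",
    "best_scores",
]

ORIGIN_CLASSES = ("exon", "intron", "promoter", "intergenic")
PROMOTER_UPSTREAM = 3000  # reuses the regulatory-region upstream extent


@dataclass
class NegativeSet:
    """Matched unbound regions with their origin class and GC fraction."""

    regions: list[GenomicInterval]
    origins: list[str]
    gc: list[float]
    seed: int

    def sequences(self, genome: dict[str, str]) -> list[str]:
        return [genome[r.chrom][r.start : r.end] for r in self.regions]


class OriginIndex:
    """Classify a genomic position into exon/intron/promoter/intergenic.

    Precedence (configurable): exon > intron > promoter > intergenic. The
    promoter is the 3-kb window upstream of the TSS, strand-aware. Gene
    models without exon annotation classify their whole body as exon.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        precedence: tuple[str, ...] = ("exon", "intron", "promoter", "intergenic"),
        promoter_upstream: int = PROMOTER_UPSTREAM,
    ) -> None:
        self.precedence = precedence
        self._exons: dict[str, list[tuple[int, int]]] = {}
        self._bodies: dict[str, list[tuple[int, int]]] = {}
        self._promoters: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            body = g.body
            self._bodies.setdefault(g.chrom, []).append((body.start, body.end))
            exons = g.exons if g.exons else ((body.start, body.end),)
            for a, b in exons:
                self._exons.setdefault(g.chrom, []).append((a, b))
            if g.strand == "+":
                prom = (max(0, g.tss - promoter_upstream), g.tss)
            else:
                prom = (g.tss, g.tss + promoter_upstream)
            if prom[1] > prom[0]:
                self._promoters.setdefault(g.chrom, []).append(prom)
        for d in (self._exons, self._bodies, self._promoters):
            for lst in d.values():
                lst.sort()

    @staticmethod
    def _in(intervals: list[tuple[int, int]] | None, pos: int) -> bool:
        if not intervals:
            return False
        import bisect

        i = bisect.bisect_right(intervals, (pos, float("inf"))) - 1
        # walk back over intervals that might still cover pos
        while i >= 0:
            a, b = intervals[i]
            if a <= pos < b:
                return True
            if b <= pos and a < pos - 50000:
                break
            i -= 1
        return False

    def classify(self, chrom: str, pos: int) -> str:
        checks = {
            "exon": lambda: self._in(self._exons.get(chrom), pos),
            "intron": lambda: (
                self._in(self._bodies.get(chrom), pos)
                and not self._in(self._exons.get(chrom), pos)
            ),
            "promoter": lambda: self._in(self._promoters.get(chrom), pos),
            "intergenic": lambda: True,
        }
        for cls in self.precedence:
            if checks[cls]():
                return cls
        return "intergenic"


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)


def sample_matched_negatives(
    positives: Sequence[GenomicInterval],
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    all_peaks: Sequence[GenomicInterval],
    gc_bin: float = 0.05,
    seed: int = 0,
    max_widen: int = 6,
    origin_index: OriginIndex | None = None,
) -> NegativeSet:
    """One unbound region per positive, matched on length, origin class and
    GC bin (regions classified at their midpoint), sampled without
    replacement.

    An exhausted (origin, GC-bin) stratum widens its GC window stepwise
    (logged); a stratum still empty after ``max_widen`` widenings raises an
    error naming it.
    """
    rng = np.random.default_rng(seed)
    index = origin_index or OriginIndex(genes)
    peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in all_peaks:
        peak_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for lst in peak_by_chrom.values():
        lst.sort()

    def overlaps_peak(chrom: str, start: int, end: int) -> bool:
        import bisect

        lst = peak_by_chrom.get(chrom)
        if not lst:
            return False
        i = bisect.bisect_right(lst, (end, float("inf")))
        for a, b in lst[max(0, i - 50) : i]:
            if a < end and start < b:
                return True
        return False

    chroms = sorted(genome)
    weights = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    taken: set[tuple[str, int]] = set()
    regions, origins, gcs = [], [], []
    for p in positives:
        seq = genome[p.chrom][p.start : p.end]
        want_origin = index.classify(p.chrom, (p.start + p.end) // 2)
        want_gc = gc_fraction(seq)
        length = p.length
        found = None
        for widen in range(max_widen + 1):
            tol = gc_bin / 2 + widen * gc_bin
            if widen:
                logger.info(
                    "stratum (%s, GC %.2f) widened to +/-%.3f", want_origin, want_gc, tol
                )
            for _ in range(4000):
                ci = rng.choice(len(chroms), p=weights)
                chrom = chroms[ci]
                if len(genome[chrom]) <= length:
                    continue
                start = int(rng.integers(0, len(genome[chrom]) - length))
                if (chrom, start) in taken:
                    continue
                end = start + length
                if overlaps_peak(chrom, start, end):
                    continue
                if index.classify(chrom, (start + end) // 2) != want_origin:
                    continue
                cand_seq = genome[chrom][start:end]
                if "N" in cand_seq:
                    continue
                if abs(gc_fraction(cand_seq) - want_gc) > tol:
                    continue
                found = (chrom, start, end, gc_fraction(cand_seq))
                break
            if found:
                break
        if not found:
            raise RuntimeError(
                f"could not sample an unbound region for stratum "
                f"(origin={want_origin}, GC~{want_gc:.2f}, len={length})"
            )
        chrom, start, end, gc = found
        taken.add((chrom, start))
        regions.append(GenomicInterval(chrom, start, end))
        origins.append(want_origin)
        gcs.append(gc)
    return NegativeSet(regions=regions, origins=origins, gc=gcs, seed=seed)


def best_scores(model: PWM | TFFM1, sequences: Sequence[str]) -> np.ndarray:
    """Best site score per region (the scanning statistic the AUROC uses)."""
    out = np.empty(len(sequences))
    for i, s in enumerate(sequences):
        sc = scan_scores(model, s)
        out[i] = sc.max(initial=0.0) if sc.size else 0.0
    return out


def compute_auroc(
    model: PWM | TFFM1,
    positive_seqs: Sequence[str],
    negative_seqs: Sequence[str],
) -> tuple[float, np.ndarray]:
    """AUROC of best-score discrimination, plus ROC points.

    AUROC uses the Mann–Whitney rank formulation with mid-ranked ties;
    the returned ROC points are (FPR, TPR) at every score cut.
    """
    if not len(positive_seqs) or not len(negative_seqs):
        raise ValueError("both region sets must be non-empty")
    pos = best_scores(model, positive_seqs)
    neg = best_scores(model, negative_seqs)
    return auroc_from_scores(pos, neg)


def auroc_from_scores(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[float, np.ndarray]:
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)  # mid-rank ties
    r_pos = ranks[: len(pos)].sum()
    auroc = (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    # ROC points at every distinct threshold, descending
    order = np.argsort(-scores, kind="stable")
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])[order]
    sorted_scores = scores[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    tpr = np.r_[0.0, tp[distinct] / len(pos)]
    fpr = np.r_[0.0, fp[distinct] / len(neg)]
    return float(auroc), np.column_stack([fpr, tpr])


def compare_best_scores(
    regions_x: Sequence[str],
    regions_y: Sequence[str],
    model: PWM | TFFM1,
) -> tuple[float, float]:
    """Welch's t statistic and two-sided p for best scores of X vs Y."""
    if len(regions_x) < 2 or len(regions_y) < 2:
        raise ValueError("need at least 2 regions per set")
    x = best_scores(model, regions_x)
    y = best_scores(model, regions_y)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def write_roc_tsv(points: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.8g}\t{tpr:.8g}\n")
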